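"""Stacked within-person 1-1-1 mediation with Monte-Carlo inference.

The mediation model asks whether the within-person effect of lagged emotion
differentiation on emotion intensity runs through emotion-regulation
variability.  Predictor, mediator and outcome all live at the assessment
level (a 1-1-1 design) with person-level random paths.

Because the model is inherently multivariate (two equations), the data are
*stacked*: each complete analysis row becomes two rows, one carrying the
mediator as the response (selector ``s_m = 1``) and one the outcome
(``s_y = 1``).  A single univariate mixed model on the stacked data with
selector-specific intercepts and predictors then estimates both equations
simultaneously:

* mediator side:  ``ERV_t   = im + a * W[ED_{t-1}] + controls``
* outcome side:   ``INT_t   = iy + b * W[ERV_t] + c' * W[ED_{t-1}] + controls``

Person-level random deviations a_i, b_i (and selector intercepts) carry a
full covariance matrix.  The within-person indirect effect is

    indirect = a * b + cov(a_i, b_i)

and its confidence interval comes from the Monte-Carlo method: draw
(a*, b*) from the bivariate normal of the fixed-effect estimates, draw the
path covariance from a normal with its asymptotic SE, and take percentiles
of ``a* b* + cov*``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

__all__ = [
    "stack_for_mediation",
    "fit_1m",
    "monte_carlo_indirect",
    "co_moderation",
    "MediationResult",
    "MonteCarloCI",
]


def stack_for_mediation(
    table: pd.DataFrame,
    predictor: str = "na_ed_w_lag",
    mediator: str = "erv_full",
    outcome: str = "na_int",
    mediator_within: str = "erv_full_w",
    covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Stack complete analysis rows into mediator/outcome row pairs.

    Each complete row (no missing value among predictor, mediator, outcome,
    ``mediator_within`` and covariates) yields two stacked rows sharing all
    analysis columns, plus ``z`` (the response: mediator value on the
    ``s_m = 1`` row, outcome value on the ``s_y = 1`` row) and the mutually
    exclusive selectors ``s_m`` / ``s_y``.

    Raises
    ------
    ValueError
        If a required column is absent.
    """
    required = [predictor, mediator, outcome, mediator_within, *covariates]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    cc = table.dropna(subset=required).copy()
    m_rows = cc.copy()
    m_rows["z"] = m_rows[mediator]
    m_rows["s_m"], m_rows["s_y"] = 1.0, 0.0
    y_rows = cc.copy()
    y_rows["z"] = y_rows[outcome]
    y_rows["s_m"], y_rows["s_y"] = 0.0, 1.0
    stacked = pd.concat([m_rows, y_rows], ignore_index=True)
    stacked.attrs["mediation_columns"] = {
        "predictor": predictor, "mediator": mediator, "outcome": outcome,
        "mediator_within": mediator_within, "covariates": list(covariates),
    }
    return stacked


@dataclass
class MediationResult:
    """Fixed paths, random-path covariance and indirect effect of model 1M."""

    a: float
    b: float
    cprime: float
    se_a: float
    se_b: float
    se_cprime: float
    cov_fe_ab: np.ndarray        # 2x2 asymptotic covariance of (a, b)
    sigma_ab: float              # estimated cov of person-level a_i, b_i
    se_sigma_ab: float
    var_a_re: float
    var_b_re: float
    indirect: float              # a*b + sigma_ab
    params: pd.DataFrame
    cov_re: pd.DataFrame
    n_obs: int
    n_persons: int
    converged: bool
    sigma_ab_estimable: bool
    meta: dict = field(default_factory=dict)
    mc_ci: tuple[float, float] | None = None
    n_draws: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("params", "cov_re", "cov_fe_ab")}
        d["params"] = self.params.reset_index().to_dict(orient="records")
        d["cov_fe_ab"] = np.asarray(self.cov_fe_ab).tolist()
        return d


def _stacked_design(
    stacked: pd.DataFrame,
    predictor: str,
    mediator_within: str,
    covariates: tuple[str, ...],
    moderator: str | None,
    random_intercepts: bool,
):
    """Fixed/random design matrices for the stacked mediation model."""
    s_m = stacked["s_m"].to_numpy(dtype=float)
    s_y = stacked["s_y"].to_numpy(dtype=float)
    xp = stacked[predictor].to_numpy(dtype=float)
    xm = stacked[mediator_within].to_numpy(dtype=float)
    names = ["int_m", "int_y", "a", "b", "cprime"]
    cols = [s_m, s_y, s_m * xp, s_y * xm, s_y * xp]
    for c in covariates:
        v = stacked[c].to_numpy(dtype=float)
        names += [f"m:{c}", f"y:{c}"]
        cols += [s_m * v, s_y * v]
    if "dataset_id" in stacked.columns:
        levels = sorted(stacked["dataset_id"].unique())
        for lev in levels[1:]:
            d = (stacked["dataset_id"] == lev).to_numpy(dtype=float)
            names += [f"m:dataset[{lev}]", f"y:dataset[{lev}]"]
            cols += [s_m * d, s_y * d]
    if moderator is not None:
        w = stacked[moderator].to_numpy(dtype=float)
        names += ["m:mod", "y:mod", "mod:a", "mod:b"]
        cols += [s_m * w, s_y * w, s_m * w * xp, s_y * w * xm]
    # identically-zero columns (degenerate moderators/covariates) are dropped
    keep = [i for i, c in enumerate(cols) if np.any(c != 0.0)]
    names = [names[i] for i in keep]
    x = np.column_stack([cols[i] for i in keep])
    if random_intercepts:
        re_names = ["int_m", "int_y", "a", "b"]
        z = np.column_stack([s_m, s_y, s_m * xp, s_y * xm])
    else:
        re_names = ["a", "b"]
        z = np.column_stack([s_m * xp, s_y * xm])
    return x, names, z, re_names


def fit_1m(
    stacked: pd.DataFrame,
    predictor: str | None = None,
    mediator_within: str | None = None,
    covariates: tuple[str, ...] | None = None,
    random_intercepts: bool = True,
    moderator: str | None = None,
    maxiter: int = 300,
) -> MediationResult:
    """Fit the stacked mediation model and assemble the indirect effect.

    Column roles default to the metadata recorded by
    :func:`stack_for_mediation`.  Random effects are the two selector
    intercepts plus the person-level a and b deviations with full
    covariance; ``random_intercepts=False`` keeps only the path deviations.
    Non-convergence triggers staged simplification (diagonal covariance,
    then no random intercepts), logged in ``meta``; if the a-b covariance is
    not estimable the indirect effect is reported from the path product
    alone with ``sigma_ab_estimable=False``.

    The residual variance is common to the mediator and outcome rows, so the
    two responses should be on comparable scales (they are, after the 0-10
    rescaling of all indices).
    """
    info = stacked.attrs.get("mediation_columns", {})
    predictor = predictor or info.get("predictor", "na_ed_w_lag")
    mediator_within = mediator_within or info.get("mediator_within", "erv_full_w")
    if covariates is None:
        covariates = tuple(info.get("covariates", ()))
    if stacked["person_id"].nunique() < 3:
        raise ValueError("need at least 3 persons")

    x, fe_names, z, re_names = _stacked_design(
        stacked, predictor, mediator_within, covariates, moderator,
        random_intercepts,
    )
    y = stacked["z"].to_numpy(dtype=float)
    groups = stacked["person_id"].to_numpy()

    log: list[str] = []
    attempts = [("full", random_intercepts)]
    if random_intercepts:
        attempts += [("diagonal", True), ("full", False)]
    attempts += [("diagonal", False)]
    res = None
    for structure, with_int in attempts:
        xx, nn, zz, rn = (x, fe_names, z, re_names) if with_int == random_intercepts \
            else _stacked_design(stacked, predictor, mediator_within,
                                 covariates, moderator, with_int)
        free = None
        if structure == "diagonal":
            free = MixedLMParams.from_components(
                fe_params=np.ones(xx.shape[1]), cov_re=np.eye(zz.shape[1])
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, xx, groups=groups, exog_re=zz)
            res = model.fit(method="lbfgs", reml=True, free=free,
                            maxiter=maxiter)
            if not res.converged and structure == "full":
                # warm-start the full covariance from a diagonal fit; cold
                # starts often stall when the path covariance sits near its
                # positive-semidefiniteness boundary
                diag_free = MixedLMParams.from_components(
                    fe_params=np.ones(xx.shape[1]), cov_re=np.eye(zz.shape[1])
                )
                diag = model.fit(method="lbfgs", reml=True, free=diag_free,
                                 maxiter=maxiter)
                if diag.converged:
                    start = MixedLMParams.from_components(
                        fe_params=diag.fe_params,
                        cov_re=np.asarray(diag.cov_re),
                    )
                    warm = model.fit(method="lbfgs", reml=True,
                                     start_params=start, maxiter=maxiter)
                    if warm.converged:
                        res = warm
                        log.append("full covariance recovered by "
                                   "warm-starting from a diagonal fit")
        if res.converged:
            if (structure, with_int) != attempts[0]:
                log.append(f"simplified to structure={structure!r}, "
                           f"random_intercepts={with_int}")
            fe_names, re_names = nn, rn
            sigma_ab_estimable = structure != "diagonal"
            break
        log.append(f"non-convergence (structure={structure!r}, "
                   f"random_intercepts={with_int})")
        sigma_ab_estimable = structure != "diagonal"
    if not res.converged:
        fe_names, re_names = nn, rn
        log.append("all structures failed; last fit returned flagged")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bse_fe_arr = np.asarray(res.bse_fe)
        bse_re = np.asarray(res.bse_re)
        cov_all = np.asarray(res.cov_params())
    est = pd.Series(res.fe_params, index=fe_names)
    se = pd.Series(bse_fe_arr, index=fe_names)
    params = pd.DataFrame({
        "estimate": est, "se": se, "z": est / se,
        "p": 2 * stats.norm.sf(np.abs(est / se)),
        "ci95_lower": est - 1.959963984540054 * se,
        "ci95_upper": est + 1.959963984540054 * se,
    })
    params.index.name = "term"
    k_re = len(re_names)
    cov_re = pd.DataFrame(np.asarray(res.cov_re), index=re_names, columns=re_names)
    ia, ib = re_names.index("a"), re_names.index("b")
    sigma_ab = float(cov_re.iloc[ia, ib]) if sigma_ab_estimable else 0.0
    # SE of the a-b covariance from the packed lower-triangle order
    tri = [(i, j) for i in range(k_re) for j in range(i + 1)]
    try:
        se_sigma_ab = float(bse_re[tri.index((max(ia, ib), min(ia, ib)))])
    except (IndexError, ValueError):
        se_sigma_ab = np.nan
    if sigma_ab_estimable and not np.isfinite(se_sigma_ab):
        sigma_ab_estimable = False
        warnings.warn(
            "a-b path covariance not estimable; indirect effect reported "
            "without the covariance term",
            RuntimeWarning,
            stacklevel=2,
        )
    ja, jb = fe_names.index("a"), fe_names.index("b")
    cov_fe = cov_all[np.ix_([ja, jb], [ja, jb])]
    a_h, b_h = float(est["a"]), float(est["b"])
    return MediationResult(
        a=a_h, b=b_h, cprime=float(est["cprime"]),
        se_a=float(se["a"]), se_b=float(se["b"]), se_cprime=float(se["cprime"]),
        cov_fe_ab=cov_fe,
        sigma_ab=sigma_ab,
        se_sigma_ab=se_sigma_ab if sigma_ab_estimable else 0.0,
        var_a_re=float(cov_re.iloc[ia, ia]),
        var_b_re=float(cov_re.iloc[ib, ib]),
        indirect=a_h * b_h + sigma_ab,
        params=params,
        cov_re=cov_re,
        n_obs=len(stacked),
        n_persons=stacked["person_id"].nunique(),
        converged=bool(res.converged),
        sigma_ab_estimable=sigma_ab_estimable,
        meta={"simplification_log": log, "moderator": moderator,
              "random_intercepts": random_intercepts},
    )


@dataclass
class MonteCarloCI:
    """Percentile confidence interval of the indirect effect."""

    lower: float
    upper: float
    level: float
    n_draws: int
    seed: int
    n_clipped: int        # covariance draws clipped to the PSD bound
    point: float

    def to_dict(self) -> dict:
        return asdict(self)


def monte_carlo_indirect(
    result: MediationResult,
    n_draws: int = 20000,
    seed: int = 0,
    level: float = 0.95,
) -> MonteCarloCI:
    """Monte-Carlo percentile CI for ``indirect = a*b + sigma_ab``.

    Draws (a*, b*) from the bivariate normal of the fixed-effect estimates
    and sigma_ab* from a normal with its asymptotic SE; covariance draws
    violating the positive-semidefiniteness bound implied by the estimated
    path variances (|sigma_ab*| <= sqrt(var_a * var_b)) are clipped to the
    bound and counted.

    Raises
    ------
    ValueError
        If the fixed-effect covariance of (a, b) is not positive
        semidefinite.
    """
    cov = np.asarray(result.cov_fe_ab, dtype=float)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10 * max(eig.max(), 1.0):
        raise ValueError("covariance matrix of the (a, b) fixed effects is "
                         "not positive semidefinite")
    rng = np.random.default_rng(seed)
    ab = rng.multivariate_normal([result.a, result.b], cov, size=n_draws,
                                 method="cholesky" if eig.min() > 0 else "svd")
    if result.sigma_ab_estimable and result.se_sigma_ab > 0:
        sab = rng.normal(result.sigma_ab, result.se_sigma_ab, size=n_draws)
        lim = np.sqrt(max(result.var_a_re, 0.0) * max(result.var_b_re, 0.0))
        n_clipped = int(np.sum(np.abs(sab) > lim))
        sab = np.clip(sab, -lim, lim)
    else:
        sab = np.full(n_draws, result.sigma_ab)
        n_clipped = 0
    draws = ab[:, 0] * ab[:, 1] + sab
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return MonteCarloCI(
        lower=float(lo), upper=float(hi), level=level,
        n_draws=n_draws, seed=seed, n_clipped=n_clipped,
        point=result.indirect,
    )


def co_moderation(
    stacked: pd.DataFrame,
    moderator: str,
    **fit_kwargs,
) -> MediationResult:
    """Model 1M with a person-level co-moderator of both paths.

    Adds cross-level interactions ``moderator x W[predictor]`` on the
    mediator side (a-path) and ``moderator x W[mediator]`` on the outcome
    side (b-path), plus selector-specific moderator main effects.  The two
    interaction coefficients appear as ``mod:a`` and ``mod:b`` in
    ``result.params``.
    """
    return fit_1m(stacked, moderator=moderator, **fit_kwargs)
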
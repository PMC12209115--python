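"""Multilevel cross-lag models, equivalence testing and moderators.

The cross-lag models regress a momentary index on the within-person
components of the lagged (or concurrent) predictors, their between-person
components, and covariates (centered time, grand-mean-centered age, a
female indicator).  Observations nest in persons; persons nest in datasets.
Person-level structure is a random intercept plus random slopes for the
within-person predictors with a full covariance matrix; the dataset level
(five groups) is absorbed by fixed indicator columns, recorded in the fit
metadata.

Residual AR(1) is available as feasible GLS: the model is fitted, the
lag-1 autocorrelation of the conditional residuals within persons is
estimated, rows are quasi-differenced (Prais-Winsten style, treating
successive retained assessments as equally spaced) and the model is
refitted; two to three passes suffice.  Quasi-differencing transforms the
random-effect design consistently, so the mixed-model structure is
preserved.

On non-convergence the random-effect structure is simplified in stages
(full covariance -> diagonal -> intercept only), each step logged in the
fit metadata; a silent bad fit is never returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

__all__ = [
    "ModelSpec",
    "ModelFit",
    "EquivalenceResult",
    "fit_crosslag",
    "tost_equivalence",
    "add_moderators",
    "between_person_effects",
    "canned_spec",
    "MODEL_IDS",
]

Z90 = stats.norm.ppf(0.95)   # 1.6449
Z95 = stats.norm.ppf(0.975)  # 1.9600

#: TOST equivalence bounds: the reference fixed slope from the power analysis.
TOST_BOUND = 0.187


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one cross-lag mixed model.

    ``within`` columns are person-centered time-varying predictors (entered
    as fixed effects and, unless listed in ``fixed_only``, as random
    slopes); ``between`` columns are person-level; ``covariates`` are
    fixed-only controls (time, age, gender).  ``interactions`` are
    (moderator, predictor) pairs added as product terms with the moderator
    main effect.
    """

    outcome: str
    within: tuple[str, ...]
    between: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    fixed_only: tuple[str, ...] = ()
    dataset_effect: str = "fixed"       # "fixed" indicator columns or "none"
    ar1: bool = False
    re_structure: str = "full"          # "full" | "diagonal" | "intercept"

    @property
    def random(self) -> tuple[str, ...]:
        return tuple(c for c in self.within if c not in self.fixed_only)


@dataclass
class ModelFit:
    """Results of one mixed-model fit."""

    params: pd.DataFrame          # term-indexed: estimate, se, z, p, CI bounds
    cov_re: pd.DataFrame          # random-effect covariance (person level)
    bse_re: pd.Series             # SEs of the packed RE (co)variances
    cov_params_fe: pd.DataFrame   # asymptotic covariance of fixed effects
    resid_var: float
    ar1_rho: float | None
    n_obs: int
    n_persons: int
    n_datasets: int
    converged: bool
    spec: ModelSpec
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params.reset_index().to_dict(orient="records"),
            "cov_re": self.cov_re.to_dict(),
            "resid_var": self.resid_var,
            "ar1_rho": self.ar1_rho,
            "n_obs": self.n_obs,
            "n_persons": self.n_persons,
            "n_datasets": self.n_datasets,
            "converged": self.converged,
            "spec": asdict(self.spec),
            "meta": self.meta,
        }


@dataclass
class EquivalenceResult:
    """Two one-sided tests conclusion for one fixed effect."""

    effect: str
    estimate: float
    se: float
    ci90: tuple[float, float]
    bounds: tuple[float, float]
    concluded: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _check_rank(x: np.ndarray, names: list[str]):
    """Raise naming (nearly) collinear columns when the design is deficient."""
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [names[i] for i in np.where(diag <= tol)[0]]
        raise ValueError(
            f"rank-deficient fixed-effect design (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {bad or names}"
        )


def _build_design(data: pd.DataFrame, spec: ModelSpec):
    """Assemble fixed and random design matrices plus names, complete cases."""
    needed = set([spec.outcome, *spec.within, *spec.between, *spec.covariates])
    for mod, pred in spec.interactions:
        needed.update((mod, pred))
    needed = [c for c in needed]
    cc = data.dropna(subset=needed).copy()
    if cc.empty:
        raise ValueError("no complete-case rows for this model")

    fe_names = ["Intercept"]
    cols = [np.ones(len(cc))]
    for c in list(spec.within) + list(spec.between) + list(spec.covariates):
        fe_names.append(c)
        cols.append(cc[c].to_numpy(dtype=float))
    for mod, pred in spec.interactions:
        if mod not in fe_names:
            fe_names.append(mod)
            cols.append(cc[mod].to_numpy(dtype=float))
        fe_names.append(f"{mod}:{pred}")
        cols.append((cc[mod] * cc[pred]).to_numpy(dtype=float))
    n_datasets = cc["dataset_id"].nunique() if "dataset_id" in cc else 1
    if spec.dataset_effect == "fixed" and n_datasets > 1:
        ds_levels = sorted(cc["dataset_id"].unique())
        for lev in ds_levels[1:]:
            fe_names.append(f"dataset[{lev}]")
            cols.append((cc["dataset_id"] == lev).to_numpy(dtype=float))
    # identically-zero columns (e.g. a constant-zero moderator) carry no
    # information; drop them so degenerate moderators reduce to the base model
    keep = [i for i, c in enumerate(cols) if i == 0 or np.any(c != 0.0)]
    fe_names = [fe_names[i] for i in keep]
    x = np.column_stack([cols[i] for i in keep])
    _check_rank(x, fe_names)

    re_names = ["Intercept"]
    z_cols = [np.ones(len(cc))]
    for c in spec.random:
        re_names.append(c)
        z_cols.append(cc[c].to_numpy(dtype=float))
    z = np.column_stack(z_cols)
    return cc, x, fe_names, z, re_names, n_datasets


def _fit_mixed(y, x, z, groups, re_structure, maxiter=300):
    """One MixedLM fit with the requested random-effect structure.

    A non-converged full-covariance fit is retried warm-started from a
    converged diagonal fit before giving up (boundary covariances often
    defeat a cold start).
    """
    k_fe, k_re = x.shape[1], z.shape[1]
    if re_structure == "intercept":
        z = z[:, :1]
        k_re = 1
        re_structure = "full"
    model = MixedLM(y, x, groups=groups, exog_re=z)
    free = None
    if re_structure == "diagonal" and k_re > 1:
        free = MixedLMParams.from_components(
            fe_params=np.ones(k_fe), cov_re=np.eye(k_re)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="lbfgs", reml=True, free=free, maxiter=maxiter)
        if not res.converged and re_structure == "full" and k_re > 1:
            diag_free = MixedLMParams.from_components(
                fe_params=np.ones(k_fe), cov_re=np.eye(k_re)
            )
            diag = model.fit(method="lbfgs", reml=True, free=diag_free,
                             maxiter=maxiter)
            if diag.converged:
                start = MixedLMParams.from_components(
                    fe_params=diag.fe_params, cov_re=np.asarray(diag.cov_re)
                )
                warm = model.fit(method="lbfgs", reml=True,
                                 start_params=start, maxiter=maxiter)
                if warm.converged:
                    res = warm
    return res, z


def _quasi_diff(y, x, z, groups, rho):
    """Prais-Winsten transform within persons for AR(1) residuals."""
    yt, xt, zt = y.copy(), x.copy(), z.copy()
    first = np.ones(len(y), dtype=bool)
    first[1:] = groups[1:] != groups[:-1]
    inner = ~first
    yt[inner] = y[inner] - rho * y[:-1][inner[1:]]
    xt[inner] = x[inner] - rho * x[:-1][inner[1:]]
    zt[inner] = z[inner] - rho * z[:-1][inner[1:]]
    scale = np.sqrt(1.0 - rho ** 2)
    yt[first] *= scale
    xt[first] *= scale
    zt[first] *= scale
    return yt, xt, zt


def _resid_rho(res, y, x, z, groups):
    """Lag-1 autocorrelation of conditional residuals within persons."""
    fe = res.fe_params
    resid = y - x @ fe
    uniq, inv = np.unique(groups, return_inverse=True)
    try:
        re = res.random_effects
        b = np.vstack([np.asarray(re[g])[: z.shape[1]] for g in uniq])
        resid = resid - np.einsum("ij,ij->i", z, b[inv])
    except (ValueError, np.linalg.LinAlgError):
        # singular RE covariance (boundary fit): fall back to removing the
        # person means, i.e. the intercept part of the random effects
        pm = np.bincount(inv, weights=resid) / np.bincount(inv)
        resid = resid - pm[inv]
    inner = np.ones(len(y), dtype=bool)
    inner[0] = False
    inner[1:] = groups[1:] == groups[:-1]
    e1, e0 = resid[inner], resid[np.roll(inner, -1)]
    denom = float(np.sum(resid ** 2))
    if denom <= 0:
        return 0.0
    return float(np.clip(np.sum(e1 * e0) / denom, -0.99, 0.99))


def fit_crosslag(data: pd.DataFrame, spec: ModelSpec, maxiter: int = 300) -> ModelFit:
    """Fit one cross-lag mixed model.

    Expects ``data`` to carry ``person_id`` (and ``dataset_id`` unless the
    dataset effect is disabled) plus every column the spec names; only
    complete cases on those columns are used.  See the module docstring for
    the random-effects, dataset-level and AR(1) treatment.
    """
    if data["person_id"].nunique() < 3:
        raise ValueError("need at least 3 persons")
    # AR(1) quasi-differencing and grouping assume person-contiguous rows in
    # assessment order
    if "obs_index" in data.columns:
        data = data.sort_values(["person_id", "obs_index"], kind="stable")
    else:
        data = data.sort_values(["person_id"], kind="stable")
    cc2, x, fe_names, z, re_names, n_datasets = _build_design(data, spec)
    y = cc2[spec.outcome].to_numpy(dtype=float)
    groups = cc2["person_id"].to_numpy()

    log: list[str] = []
    structure = spec.re_structure
    rho = 0.0
    ar1_applied = False
    res = None
    for attempt_structure in {"full": ["full", "diagonal", "intercept"],
                              "diagonal": ["diagonal", "intercept"],
                              "intercept": ["intercept"]}[structure]:
        ys, xs, zs = y, x, z
        if spec.ar1:
            # feasible GLS: estimate rho from a first pass, then refit on
            # quasi-differenced data (successive retained assessments are
            # treated as equally spaced)
            res0, z_used = _fit_mixed(y, x, z, groups, attempt_structure, maxiter)
            rho = _resid_rho(res0, y, x, z_used, groups)
            for _ in range(2):
                ys, xs, zs = _quasi_diff(y, x, z, groups, rho)
                res, z_used = _fit_mixed(ys, xs, zs, groups, attempt_structure, maxiter)
                rho_new = rho + _resid_rho(res, ys, xs, z_used, groups)
                rho_new = float(np.clip(rho_new, -0.99, 0.99))
                if abs(rho_new - rho) < 1e-3:
                    rho = rho_new
                    break
                rho = rho_new
            ar1_applied = True
        else:
            res, z_used = _fit_mixed(ys, xs, zs, groups, attempt_structure, maxiter)
        if res.converged:
            if attempt_structure != structure:
                log.append(f"random-effect structure simplified to "
                           f"{attempt_structure!r} after non-convergence")
            structure = attempt_structure
            break
        log.append(f"non-convergence with structure {attempt_structure!r}")
    if res is None or not res.converged:
        log.append("all structures failed to converge; returning last fit flagged")

    with warnings.catch_warnings():
        # boundary variance components yield NaN SEs for themselves; benign
        warnings.simplefilter("ignore", RuntimeWarning)
        bse_fe_arr = np.asarray(res.bse_fe)
        bse_re_arr = np.asarray(res.bse_re)
        cov_all = np.asarray(res.cov_params())
    est = pd.Series(res.fe_params, index=fe_names)
    se = pd.Series(bse_fe_arr, index=fe_names)
    params = pd.DataFrame({
        "estimate": est,
        "se": se,
        "z": est / se,
        "p": 2 * stats.norm.sf(np.abs(est / se)),
        "ci95_lower": est - Z95 * se,
        "ci95_upper": est + Z95 * se,
        "ci90_lower": est - Z90 * se,
        "ci90_upper": est + Z90 * se,
    })
    params.index.name = "term"
    k_used = z_used.shape[1]
    cov_re = pd.DataFrame(np.asarray(res.cov_re),
                          index=re_names[:k_used], columns=re_names[:k_used])
    tri = [(i, j) for i in range(k_used) for j in range(i + 1)]
    bse_re = pd.Series(
        bse_re_arr,
        index=[f"{re_names[i]}x{re_names[j]}" for i, j in tri],
    )
    cov_fe = pd.DataFrame(cov_all[: len(fe_names), : len(fe_names)],
                          index=fe_names, columns=fe_names)
    return ModelFit(
        params=params,
        cov_re=cov_re,
        bse_re=bse_re,
        cov_params_fe=cov_fe,
        resid_var=float(res.scale),
        ar1_rho=rho if spec.ar1 else None,
        n_obs=len(cc2),
        n_persons=cc2["person_id"].nunique(),
        n_datasets=n_datasets,
        converged=bool(res.converged),
        spec=spec,
        meta={
            "re_structure_used": structure,
            "dataset_effect": ("fixed_dummies" if spec.dataset_effect == "fixed"
                               and n_datasets > 1 else "none"),
            "ar1_requested": spec.ar1,
            "ar1_applied": ar1_applied,
            "simplification_log": log,
        },
    )


def tost_equivalence(
    fit: ModelFit,
    effect: str,
    bound: float = TOST_BOUND,
) -> EquivalenceResult:
    """Two one-sided tests: is the fixed effect equivalent to zero?

    Equivalence is concluded when the 90% Wald CI of the effect lies
    strictly inside (-bound, +bound).
    """
    row = fit.params.loc[effect]
    lo, hi = float(row["ci90_lower"]), float(row["ci90_upper"])
    return EquivalenceResult(
        effect=effect,
        estimate=float(row["estimate"]),
        se=float(row["se"]),
        ci90=(lo, hi),
        bounds=(-bound, bound),
        concluded=bool(-bound < lo and hi < bound),
    )


def add_moderators(spec: ModelSpec, moderator: str, predictors=None) -> ModelSpec:
    """Augment a spec with a moderator main effect and its interactions.

    By default the moderator interacts with every within-person predictor;
    pass ``predictors`` to restrict.  The focal main effects stay in the
    model, so robustness can be judged from their (now moderation-adjusted)
    estimates.
    """
    preds = tuple(predictors) if predictors is not None else spec.within
    new = spec.interactions + tuple((moderator, p) for p in preds)
    return replace(spec, interactions=new)


def zero_intensity_indicator(raw_intensity) -> np.ndarray:
    """Indicator of measurement occasions with zero (raw) intensity."""
    x = np.asarray(raw_intensity, dtype=float)
    out = np.where(np.isnan(x), np.nan, (x == 0.0).astype(float))
    return out


def between_person_effects(fit: ModelFit) -> pd.DataFrame:
    """Between-person fixed-effect rows of a fit (trait-level associations)."""
    if fit.n_persons < 2:
        raise ValueError("between-person effects need at least 2 persons")
    rows = [c for c in fit.spec.between if c in fit.params.index]
    return fit.params.loc[rows]


MODEL_IDS = ("1A", "1B", "1C", "2A", "2B")


def canned_spec(
    model: str,
    valence: str = "neg",
    ar1: bool = False,
    concurrent_er_intensity: bool = True,
) -> ModelSpec:
    """Column specification of the five canned cross-lag models.

    1A: lagged differentiation -> regulation variability (full index);
    1B/1C: same predictor, one variability subcomponent as outcome with the
    other as covariate; 2A: concurrent regulation variability ->
    differentiation (the regulation items refer to the interval since the
    previous beep, so same-assessment pairing is the lagged comparison);
    2B: both subcomponents as simultaneous predictors of differentiation.

    Column names follow the pipeline convention: ``{index}_w``/``{index}_b``
    for within/between components and ``_lag`` suffixes from lag alignment.
    """
    if valence not in ("neg", "pos"):
        raise ValueError("valence must be 'neg' or 'pos'")
    ed = "na_ed" if valence == "neg" else "pa_ed"
    inten = "na_int" if valence == "neg" else "pa_int"
    er_int = "er_int_w" if concurrent_er_intensity else "er_int_w_lag"
    covs = ("time_c", "age_c", "female")
    common = dict(covariates=covs, ar1=ar1, fixed_only=())
    if model == "1A":
        return ModelSpec(
            outcome="erv_full",
            within=(f"{ed}_w_lag", f"{inten}_w_lag", er_int),
            between=(f"{ed}_b", f"{inten}_b", "er_int_b"),
            **common,
        )
    if model in ("1B", "1C"):
        outcome = "erv_switch" if model == "1B" else "erv_endorse"
        other = "erv_endorse_w" if model == "1B" else "erv_switch_w"
        return ModelSpec(
            outcome=outcome,
            within=(f"{ed}_w_lag", f"{inten}_w_lag", er_int, other),
            between=(f"{ed}_b", f"{inten}_b", "er_int_b"),
            **common,
        )
    if model == "2A":
        return ModelSpec(
            outcome=ed,
            within=("erv_full_w", f"{inten}_w_lag", er_int),
            between=("erv_full_b", f"{inten}_b", "er_int_b"),
            **common,
        )
    if model == "2B":
        return ModelSpec(
            outcome=ed,
            within=("erv_switch_w", "erv_endorse_w", f"{inten}_w_lag", er_int),
            between=("erv_switch_b", "erv_endorse_b", f"{inten}_b", "er_int_b"),
            **common,
        )
    raise ValueError(f"unknown model id {model!r}; expected one of {MODEL_IDS}")
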
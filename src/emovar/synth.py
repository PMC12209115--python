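"""Synthetic ESM data generators.

Two fidelity levels:

* :func:`gen_index_level` simulates the derived index series directly
  (differentiation -> regulation variability -> intensity) from known
  cross-lag and mediation parameters.  It is the primary surface for
  estimator-recovery and coverage studies, because the derived indices are
  nonlinear functions of items and exact truth cannot be pushed through the
  item level.

* :func:`gen_item_level` simulates raw item ratings for the five-study
  design: a latent AR(1) affect factor per valence drives the same-valence
  emotion items with time-varying loading heterogeneity (so momentary
  differentiation fluctuates), and the regulation items follow a Markov
  regime-switching compositional process with a random-walk endorsement
  level (so both Bray-Curtis subcomponents fluctuate).  Truth at this level
  is qualitative; it feeds end-to-end pipeline tests.

Reproducibility: a single global seed is expanded into independent
per-person substreams via ``numpy.random.SeedSequence.spawn`` in a fixed
order (dataset by dataset, person by person), so output is bit-identical
for a given seed and independent of chunking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .design import StudyDesign, SyntheticTruth, default_designs

__all__ = [
    "LatentParams",
    "gen_index_level",
    "gen_item_level",
    "item_icc_report",
    "ICC_BAND",
]

#: calibration band for per-item intraclass correlations of the item-level
#: generator (the pooled studies report item ICCs from 0.19 to 0.64).
ICC_BAND = (0.19, 0.64)


def _ar1(rng: np.random.Generator, n: int, phi: float, marginal_sd: float = 1.0):
    """Stationary AR(1) series with the requested marginal SD."""
    from scipy.signal import lfilter

    innov_sd = marginal_sd * np.sqrt(1.0 - phi ** 2)
    e = innov_sd * rng.normal(size=n)
    e[0] = marginal_sd * rng.normal()   # draw from the stationary law
    return lfilter([1.0], [1.0, -phi], e)


# ---------------------------------------------------------------------------
# index-level generator
# ---------------------------------------------------------------------------

def gen_index_level(
    designs: list[StudyDesign] | StudyDesign,
    truth: SyntheticTruth,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate index-level series with known cross-lag/mediation truth.

    Returns a long table with columns ``dataset_id, person_id, obs_index,
    ed`` (exogenous differentiation series, lag-1 predictor), ``erv``
    (mediator), ``intensity`` (outcome), ``trait`` (standard-normal person
    covariate that moderates a_i when ``truth.a_mod != 0``), ``age``,
    ``female``, and a boolean ``missing`` flag (missing-completely-at-random
    at each design's ``missing_rate``), together with the truth object.

    Within each person, ``erv[t] = im_i + a_i * ed[t-1] + eps`` and
    ``intensity[t] = iy_i + b_i * erv[t] + cprime * ed[t-1] + eps`` for
    t = 1..T, with ``ed[0]`` an extra pre-series draw so every retained
    assessment has a defined lag.
    """
    if isinstance(designs, StudyDesign):
        designs = [designs]
    if not designs:
        raise ValueError("need at least one study design")
    for d in designs:
        if d.n_obs < 3:
            raise ValueError(f"series length {d.n_obs} < 3 in {d.dataset_id}")

    cov_ab = truth.rho_ab * truth.sd_a * truth.sd_b
    cov = np.array([[truth.sd_a ** 2, cov_ab], [cov_ab, truth.sd_b ** 2]])
    root = np.random.SeedSequence(truth.seed)
    streams = root.spawn(sum(d.n_persons for d in designs))

    frames = []
    s = 0
    for d in designs:
        for p in range(d.n_persons):
            rng = np.random.default_rng(streams[s])
            s += 1
            t_n = d.n_obs
            trait = rng.normal()
            dev = rng.multivariate_normal(np.zeros(2), cov)
            a_i = truth.a_true + truth.a_mod * trait + dev[0]
            b_i = truth.b_true + dev[1]
            im = truth.sd_im * rng.normal()
            iy = truth.sd_iy * rng.normal()
            ed = _ar1(rng, t_n + 1, truth.phi)   # ed[0] is the pre-series lag
            lag = ed[:-1]
            erv = im + a_i * lag + truth.sigma_m * rng.normal(size=t_n)
            inten = (iy + b_i * erv + truth.cprime_true * lag
                     + truth.sigma_y * rng.normal(size=t_n))
            miss = rng.random(t_n) < d.missing_rate
            age = d.age_mean + d.age_sd * rng.normal()
            female = int(rng.random() < d.prop_female)
            frames.append(pd.DataFrame({
                "dataset_id": d.dataset_id,
                "person_id": f"{d.dataset_id}_p{p + 1:04d}",
                "obs_index": np.arange(1, t_n + 1),
                "ed": ed[1:],
                "ed_lag": lag,
                "erv": erv,
                "intensity": inten,
                "trait": trait,
                "age": age,
                "female": female,
                "missing": miss,
            }))
    table = pd.concat(frames, ignore_index=True)
    return table, truth


# ---------------------------------------------------------------------------
# item-level generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentParams:
    """Latent-mechanism parameters of the item-level generator.

    These mechanisms are stand-ins chosen to reproduce qualitative features
    of real ESM data (fluctuating differentiation, both variability
    subcomponents, item ICCs inside :data:`ICC_BAND`); they are not estimated
    from any dataset.

    Parameters (all on the internal 0-10 rating scale):

    * ``affect_phi`` / ``affect_sd`` -- AR(1) coefficient and marginal SD of
      the latent affect factor of each valence.
    * ``loading_het`` -- SD of the multiplicative loading noise
      ``lambda_jt = 1 + loading_het * eta_jt``; 0 makes all same-valence
      items move in lockstep (minimal differentiation).
    * ``item_noise_sd`` -- unique item noise SD.
    * ``person_sd`` -- SD of person-level item means (drives between-person
      ICC).
    * ``pa_anchor`` / ``na_anchor`` / ``er_anchor`` -- grand anchors of the
      person-level item means per scale (moderate positive affect, low
      negative affect and regulation).
    * ``n_regimes`` / ``regime_stay`` -- number of strategy-emphasis regimes
      per person and the Markov self-transition probability (occasional
      switches produce balanced variation).
    * ``endorse_sd`` / ``endorse_phi`` -- mean-reverting endorsement-level
      process (produces abundance gradients).
    * ``compliance_sd`` -- between-person SD of compliance used to spread a
      design's mean observation rate over persons (matched by a Beta law).
    """

    affect_phi: float = 0.5
    affect_sd: float = 0.9
    loading_het: float = 1.0
    item_noise_sd: float = 1.1
    person_sd: float = 1.0
    pa_anchor: float = 5.8
    na_anchor: float = 1.4
    er_anchor: float = 2.3
    n_regimes: int = 3
    regime_stay: float = 0.95
    endorse_sd: float = 0.55
    endorse_phi: float = 0.8
    compliance_sd: float = 0.23
    rt_log_mean: float = 7.6
    rt_log_sd: float = 0.35


def _beta_from_mean_sd(mean: float, sd: float):
    """Beta(a, b) parameters matching a mean and SD (sd clipped if needed)."""
    sd = min(sd, 0.97 * np.sqrt(mean * (1 - mean)))
    nu = mean * (1 - mean) / sd ** 2 - 1.0
    return max(mean * nu, 0.05), max((1 - mean) * nu, 0.05)


def _emotion_items(rng, t_n, k, anchor, lp: LatentParams):
    """Latent-factor emotion items: person means + shared factor + noise."""
    mu = anchor + lp.person_sd * rng.normal(size=k)
    f = _ar1(rng, t_n, lp.affect_phi, lp.affect_sd)
    lam = 1.0 + lp.loading_het * rng.normal(size=(t_n, k))
    x = mu[None, :] + lam * f[:, None] + lp.item_noise_sd * rng.normal(size=(t_n, k))
    return np.clip(x, 0.0, 10.0)


def _er_items(rng, t_n, k, anchor, lp: LatentParams):
    """Compositional regulation items: regime switching x endorsement level."""
    # person-specific emphasis profiles, mean weight 1 across strategies
    regimes = rng.dirichlet(np.ones(k), size=lp.n_regimes) * k
    state = rng.integers(lp.n_regimes)
    states = np.empty(t_n, dtype=int)
    for t in range(t_n):
        if rng.random() > lp.regime_stay:
            state = rng.integers(lp.n_regimes)
        states[t] = state
    level_i = anchor + 0.35 * anchor * rng.normal()      # trait endorsement
    g = np.exp(_ar1(rng, t_n, lp.endorse_phi, lp.endorse_sd))
    x = (max(level_i, 0.3) * g)[:, None] * regimes[states]
    x = x + lp.item_noise_sd * 0.6 * rng.normal(size=(t_n, k))
    return np.clip(x, 0.0, 10.0)


def _to_native(x: np.ndarray, lo: float, hi: float):
    """Map internal 0-10 ratings onto a design's native instrument scale."""
    return lo + x / 10.0 * (hi - lo)


def gen_item_level(
    designs: list[StudyDesign] | None = None,
    latent: LatentParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate raw item-level ESM records for the given designs.

    Returns a long table with one row per *answered* assessment:
    ``dataset_id, person_id, day, beep, obs_index, rt_ms, age, female`` and
    item columns ``pa_1..pa_k, na_1..na_k, er_1..er_k`` on each design's
    native instrument scale (datasets with fewer items leave the surplus
    pooled columns missing).  Missingness is injected per design as
    missing-completely-at-random rows, with person-level compliance spread
    by a Beta law around the design's mean.
    """
    designs = default_designs() if designs is None else designs
    latent = LatentParams() if latent is None else latent
    if not designs:
        raise ValueError("need at least one study design")

    root = np.random.SeedSequence(seed)
    streams = root.spawn(sum(d.n_persons for d in designs))
    frames = []
    s = 0
    for d in designs:
        t_n = d.n_obs
        day = np.repeat(np.arange(1, d.n_days + 1), d.beeps_per_day)
        beep = np.tile(np.arange(1, d.beeps_per_day + 1), d.n_days)
        for p in range(d.n_persons):
            rng = np.random.default_rng(streams[s])
            s += 1
            pa = _emotion_items(rng, t_n, d.n_pa_items, latent.pa_anchor, latent)
            na = _emotion_items(rng, t_n, d.n_na_items, latent.na_anchor, latent)
            er = _er_items(rng, t_n, d.n_er_items, latent.er_anchor, latent)
            rec = {
                "dataset_id": d.dataset_id,
                "person_id": f"{d.dataset_id}_p{p + 1:04d}",
                "day": day,
                "beep": beep,
                "obs_index": np.arange(1, t_n + 1),
                "rt_ms": rng.lognormal(latent.rt_log_mean, latent.rt_log_sd, t_n),
                "age": d.age_mean + d.age_sd * rng.normal(),
                "female": int(rng.random() < d.prop_female),
            }
            for j in range(d.n_pa_items):
                rec[f"pa_{j + 1}"] = _to_native(pa[:, j], d.item_scale_min, d.item_scale_max)
            for j in range(d.n_na_items):
                rec[f"na_{j + 1}"] = _to_native(na[:, j], d.item_scale_min, d.item_scale_max)
            for j in range(d.n_er_items):
                rec[f"er_{j + 1}"] = _to_native(er[:, j], d.item_scale_min, d.item_scale_max)
            df = pd.DataFrame(rec)
            if d.missing_rate > 0:
                a_b, b_b = _beta_from_mean_sd(1.0 - d.missing_rate, latent.compliance_sd)
                compliance = rng.beta(a_b, b_b)
                df = df[rng.random(t_n) < compliance]
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    # stable pooled column order: ids, then items by scale and number
    id_cols = ["dataset_id", "person_id", "day", "beep", "obs_index",
               "rt_ms", "age", "female"]
    item_cols = sorted(
        (c for c in table.columns if c not in id_cols),
        key=lambda c: (("pa", "na", "er").index(c.split("_")[0]), int(c.split("_")[1])),
    )
    return table[id_cols + item_cols]


def item_icc_report(
    table: pd.DataFrame,
    item_cols: list[str] | None = None,
    band: tuple[float, float] = ICC_BAND,
) -> pd.DataFrame:
    """Per-item intraclass correlations (between-person variance share).

    ICC_j = var(person means) / (var(person means) + var(within-person
    deviations)) for each item, computed per dataset on whatever scale the
    column is in (the ICC is scale-free).  Items outside ``band`` are
    flagged and a warning is emitted: they may carry too little (or almost
    only) within-person variance for momentary indices.
    """
    if item_cols is None:
        item_cols = [c for c in table.columns
                     if c.split("_")[0] in ("pa", "na", "er")]
    rows = []
    for ds, grp in table.groupby("dataset_id", sort=False):
        for col in item_cols:
            vals = grp[["person_id", col]].dropna()
            if vals.empty:
                continue
            pm = vals.groupby("person_id")[col].mean()
            within = vals[col] - vals["person_id"].map(pm)
            b_var = float(pm.var(ddof=1))
            w_var = float(within.var(ddof=1))
            icc = b_var / (b_var + w_var) if b_var + w_var > 0 else np.nan
            rows.append({"dataset_id": ds, "item": col, "icc": icc,
                         "in_band": bool(band[0] <= icc <= band[1])})
    rep = pd.DataFrame(rows)
    n_out = int((~rep["in_band"]).sum())
    if n_out:
        warnings.warn(
            f"{n_out} item ICC(s) outside the calibration band {band}",
            RuntimeWarning,
            stacklevel=2,
        )
    return rep
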
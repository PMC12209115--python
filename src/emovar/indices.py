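"""Momentary indices computed from experience-sampling item ratings.

Three families of per-assessment ("momentary") indices are computed from a
person's T x k item matrix (T assessments, k items of one scale, ratings on
0-10 after rescaling):

* **intensity** -- the plain mean of the available items at each moment.

* **momentary emotion differentiation** -- a per-moment decomposition of the
  average-measures consistency intraclass correlation (ICC) across the
  emotion items of one valence.  High consistency (items moving in lockstep
  around the person's item means) means poorly differentiated emotions.  The
  index has an upper bound of 0 (attained when the item deviations at a
  moment cancel exactly) and no lower bound; values closer to 0 indicate
  better differentiation at that moment.

* **emotion-regulation variability** -- Bray-Curtis dissimilarity between the
  strategy-endorsement profile at the moment of interest and the profiles at
  the person's other moments, additively partitioned (Baselga) into a
  balanced-variation part ("strategy switching") and an abundance-gradient
  part ("endorsement change"), and rescaled to 0-10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "intensity_mean",
    "momentary_ed",
    "icc_consistency",
    "bray_curtis_pair",
    "momentary_erv",
    "compute_indices",
    "ScaleColumns",
]

#: additive constant applied to emotion-regulation ratings before Bray-Curtis,
#: so that two all-zero moments are comparable (their dissimilarity is 0).
ER_SHIFT = 0.001

#: multiplicative rescaling of the Bray-Curtis indices from [0, 1] to [0, 10].
ERV_SCALE = 10.0


def intensity_mean(values) -> np.ndarray:
    """Mean of the available items per moment.

    Parameters
    ----------
    values : array-like, shape (T, k)
        Item ratings; NaN marks a missing item.

    Returns
    -------
    ndarray, shape (T,)
        Row means over non-missing items; NaN where every item is missing.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(x, axis=1)


def _anova_parts(values):
    """Item-center a T x k matrix and return the two-way ANOVA pieces.

    Returns ``(usable, rbar, ms_e, ms_r, t_usable)`` where *usable* is the
    boolean mask of moments with every item observed, *rbar* the per-moment
    mean item deviation, and MS_E / MS_R the residual and between-moment
    mean squares of the item-centered ratings.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a T x k item matrix")
    t_all, k = x.shape
    if k < 2:
        raise ValueError(f"need >= 2 items, got {k}")
    usable = ~np.isnan(x).any(axis=1)
    tu = int(usable.sum())
    if tu < 3:
        return usable, None, np.nan, np.nan, tu
    xu = x[usable]
    d = xu - xu.mean(axis=0)          # remove person-level item means
    rbar = d.mean(axis=1)             # moment effect (mean deviation)
    resid = d - rbar[:, None]
    ms_e = float((resid ** 2).sum() / ((tu - 1) * (k - 1)))
    ms_r = float(k * (rbar ** 2).sum() / (tu - 1))
    return usable, rbar, ms_e, ms_r, tu


def momentary_ed(values) -> np.ndarray:
    """Momentary emotion-differentiation index for one person.

    For item deviations ``d_jt = x_jt - mean_t(x_jt)`` with moment mean
    ``rbar_t`` and residual mean square ``MS_E`` (two-way moments x items
    layout), the index is::

        ED_t = -k * rbar_t**2 / MS_E

    The numerator varies by moment while the denominator is a person-level
    constant, so the series decomposes the consistency ICC moment by moment:
    the person mean of ED_t equals ``-((T-1)/T) * MS_R/MS_E``, a strictly
    decreasing function of ICC consistency.  ED_t <= 0 always, with 0 at
    moments whose item deviations cancel exactly.

    Returns NaN for moments with a missing item, for persons with fewer than
    3 usable moments, and (with a warning) when MS_E == 0, i.e. the items are
    perfectly parallel and the index is undefined.
    """
    x = np.asarray(values, dtype=float)
    usable, rbar, ms_e, _, tu = _anova_parts(x)
    out = np.full(x.shape[0], np.nan)
    if tu < 3:
        return out
    k = x.shape[1]
    if not ms_e > 0:
        warnings.warn(
            "MS_E is zero (perfectly parallel items); momentary "
            "differentiation is undefined for this person",
            RuntimeWarning,
            stacklevel=2,
        )
        return out
    out[usable] = -k * rbar ** 2 / ms_e
    return out


def icc_consistency(values) -> float:
    """Average-measures consistency ICC over a T x k item matrix.

    ``ICC = (MS_R - MS_E) / MS_R`` with MS_R the between-moment mean square
    of the item-centered ratings.  1 when items are perfectly parallel,
    about 0 for independent items, negative when items move against each
    other.  NaN with fewer than 3 usable moments.
    """
    _, _, ms_e, ms_r, tu = _anova_parts(values)
    if tu < 3 or not ms_r > 0:
        return np.nan
    return (ms_r - ms_e) / ms_r


def bray_curtis_pair(u, v) -> tuple[float, float, float]:
    """Bray-Curtis dissimilarity of two profiles with Baselga's partition.

    With ``A = sum_j min(u_j, v_j)``, ``B = sum_j max(u_j - v_j, 0)`` and
    ``C = sum_j max(v_j - u_j, 0)``:

    * ``full = (B + C) / (2A + B + C)`` -- total dissimilarity in [0, 1];
    * ``bal  = min(B, C) / (A + min(B, C))`` -- balanced variation
      (quantity substituted between strategies, "switching");
    * ``gra  = full - bal`` -- abundance gradient (overall quantity change,
      "endorsement change").

    Identical profiles (including two all-zero profiles) give (0, 0, 0).

    Raises
    ------
    ValueError
        If the vectors differ in length or contain negative entries.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1-d vectors of equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative entries")
    b = float(np.clip(u - v, 0, None).sum())
    c = float(np.clip(v - u, 0, None).sum())
    if b + c == 0.0:
        return 0.0, 0.0, 0.0
    a = float(np.minimum(u, v).sum())
    full = (b + c) / (2 * a + b + c)
    m = min(b, c)
    bal = m / (a + m) if a + m > 0 else 0.0
    return full, bal, full - bal


def _pairwise_bc(x: np.ndarray):
    """Vectorised pairwise Bray-Curtis matrices (full, bal, gra) over rows."""
    a = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=-1)
    diff = x[:, None, :] - x[None, :, :]
    b = np.clip(diff, 0, None).sum(axis=-1)
    c = b.T
    bc = b + c
    denom = 2 * a + bc
    with np.errstate(invalid="ignore", divide="ignore"):
        full = np.where(bc > 0, bc / np.where(denom > 0, denom, 1.0), 0.0)
        m = np.minimum(b, c)
        am = a + m
        bal = np.where(am > 0, m / np.where(am > 0, am, 1.0), 0.0)
        bal = np.where(bc > 0, bal, 0.0)
    return full, bal, full - bal


def momentary_erv(
    values,
    mode: str = "all_moments",
    shift: float = ER_SHIFT,
    scale: float = ERV_SCALE,
) -> np.ndarray:
    """Momentary emotion-regulation variability for one person.

    Parameters
    ----------
    values : array-like, shape (T, k)
        Regulation-strategy ratings (0-10).  NaN rows are unusable.
    mode : {"all_moments", "successive"}
        ``all_moments`` (default): each moment is compared with every other
        usable moment of the same person and the pairwise indices are
        averaged.  ``successive``: each moment is compared only with the
        previous usable moment (sensitivity specification); the first usable
        moment is NaN.
    shift : float
        Constant added to every rating before the comparison so that two
        all-zero moments are still comparable.
    scale : float
        Final multiplicative rescaling (default 10, giving a 0-10 range).

    Returns
    -------
    ndarray, shape (T, 3)
        Columns (full, switching, endorsement); NaN rows where the moment is
        unusable or fewer than 2 usable moments exist.  ``full`` equals
        ``switching + endorsement`` exactly, in every mode.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a T x k item matrix")
    if (x < 0).any():
        raise ValueError("regulation ratings must be nonnegative")
    t_all = x.shape[0]
    out = np.full((t_all, 3), np.nan)
    usable = ~np.isnan(x).any(axis=1)
    idx = np.flatnonzero(usable)
    if idx.size < 2:
        return out
    xu = x[idx] + shift
    if mode == "all_moments":
        full, bal, gra = _pairwise_bc(xu)
        n = idx.size
        for comp, mat in zip(range(3), (full, bal, gra)):
            out[idx, comp] = scale * (mat.sum(axis=1) / (n - 1))
    elif mode == "successive":
        for j in range(1, idx.size):
            f, b_, g = bray_curtis_pair(xu[j], xu[j - 1])
            out[idx[j]] = (scale * f, scale * b_, scale * g)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


@dataclass(frozen=True)
class ScaleColumns:
    """Item-column names of the three scales for one dataset."""

    pa: tuple[str, ...]
    na: tuple[str, ...]
    er: tuple[str, ...]


# column names of the per-assessment index table
INDEX_COLUMNS = (
    "pa_int",
    "na_int",
    "er_int",
    "pa_ed",
    "na_ed",
    "erv_full",
    "erv_switch",
    "erv_endorse",
)


def compute_indices(
    table: pd.DataFrame,
    scales: ScaleColumns | dict[str, ScaleColumns],
    erv_mode: str = "all_moments",
) -> pd.DataFrame:
    """Compute all momentary indices for a long-format (rescaled) table.

    Parameters
    ----------
    table : DataFrame
        One row per person-assessment with ``dataset_id``, ``person_id``,
        ``obs_index`` and the item columns, all on the 0-10 scale.
    scales : ScaleColumns or mapping dataset_id -> ScaleColumns
        Which columns form the PA, NA and ER scales (per dataset when the
        pooled datasets use different item sets).
    erv_mode : str
        Passed to :func:`momentary_erv`.

    Returns
    -------
    DataFrame
        The input id/demographic columns plus the eight index columns
        (``pa_int, na_int, er_int, pa_ed, na_ed, erv_full, erv_switch,
        erv_endorse``), one row per input row.
    """
    keep = [c for c in table.columns if not c.split("_")[0] in ("pa", "na", "er")]
    out = table[keep].copy()
    for col in INDEX_COLUMNS:
        out[col] = np.nan
    for (ds, _person), grp in table.groupby(["dataset_id", "person_id"], sort=False):
        sc = scales[ds] if isinstance(scales, dict) else scales
        loc = grp.index
        pa = grp[list(sc.pa)].to_numpy(dtype=float)
        na = grp[list(sc.na)].to_numpy(dtype=float)
        er = grp[list(sc.er)].to_numpy(dtype=float)
        out.loc[loc, "pa_int"] = intensity_mean(pa)
        out.loc[loc, "na_int"] = intensity_mean(na)
        out.loc[loc, "er_int"] = intensity_mean(er)
        out.loc[loc, "pa_ed"] = momentary_ed(pa)
        out.loc[loc, "na_ed"] = momentary_ed(na)
        erv = momentary_erv(er, mode=erv_mode)
        out.loc[loc, "erv_full"] = erv[:, 0]
        out.loc[loc, "erv_switch"] = erv[:, 1]
        out.loc[loc, "erv_endorse"] = erv[:, 2]
    return out
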
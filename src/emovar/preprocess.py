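"""Preprocessing: rescaling, exclusions, compliance, centering, lags.

Conventions used throughout the pipeline:

* item ratings are linearly rescaled to 0-10 before anything else;
* persons are excluded when a whole scale (all PA, all NA or all ER items
  pooled) shows zero variance across their assessments, or when their mean
  reaction time is below 500 ms (careless responding);
* every index is split into a within-person component (raw minus person
  mean, the time-varying part) and a between-person component (person mean
  minus the pooled grand mean, the trait-like part) *before* lagging;
* lagging shifts by one assessment within person (overnight pairs are kept
  by default, since the models treat assessments as equally spaced);
* the time covariate is centered at the midpoint of the 70-observation
  schedule (observation 35.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "rescale_items",
    "apply_exclusions",
    "ExclusionReport",
    "compliance",
    "person_center",
    "CenteredSeries",
    "add_centered",
    "center_time",
    "align_lags",
    "multicollinearity_screen",
]

RT_THRESHOLD_MS = 500.0
TIME_CENTER = 35.5  # midpoint of 70 scheduled observations


def rescale_items(table: pd.DataFrame, scale_map) -> pd.DataFrame:
    """Linearly rescale item columns to 0-10.

    ``x' = (x - min) / (max - min) * 10``; missing values stay missing.

    Parameters
    ----------
    table : DataFrame
        Long-format records with a ``dataset_id`` column.
    scale_map : mapping
        Either ``{column: (min, max)}`` applied to every dataset, or
        ``{dataset_id: {column: (min, max)}}`` when instruments differ.

    Raises
    ------
    ValueError
        If a declared bound pair has min >= max, or an observed rating falls
        outside its declared bounds (the error names the rows).
    """
    nested = scale_map and isinstance(next(iter(scale_map.values())), dict)
    out = table.copy()
    for ds, grp in table.groupby("dataset_id", sort=False):
        bounds = scale_map.get(ds, {}) if nested else scale_map
        for col, (lo, hi) in bounds.items():
            if lo >= hi:
                raise ValueError(f"invalid bounds for {col!r}: min {lo} >= max {hi}")
            if col not in table.columns:
                continue
            vals = grp[col]
            bad = vals.notna() & ((vals < lo) | (vals > hi))
            if bad.any():
                where = grp.index[bad][:5].tolist()
                raise ValueError(
                    f"{int(bad.sum())} rating(s) in column {col!r} of dataset "
                    f"{ds!r} outside declared bounds [{lo}, {hi}] "
                    f"(first rows: {where})"
                )
            out.loc[grp.index, col] = (vals - lo) / (hi - lo) * 10.0
    return out


@dataclass
class ExclusionReport:
    """Per-dataset counts of persons removed by each pre-registered rule."""

    zero_variance: dict = field(default_factory=dict)
    fast_rt: dict = field(default_factory=dict)
    n_before: int = 0
    n_after: int = 0
    excluded_persons: list = field(default_factory=list)
    empty_output: bool = False

    @property
    def n_excluded(self) -> int:
        return self.n_before - self.n_after

    def to_dict(self) -> dict:
        return asdict(self)


def apply_exclusions(
    table: pd.DataFrame,
    scales,
    rt_col: str = "rt_ms",
    rt_threshold: float = RT_THRESHOLD_MS,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop persons with a zero-variance scale or fast mean reaction times.

    Zero variance is assessed on the pooled item vector of each scale
    (all PA items stacked over the person's assessments, likewise NA and
    ER): a person rating every item of a scale identically at every beep
    carries no usable signal for that scale's indices.  The reaction-time
    rule removes persons with mean RT strictly below ``rt_threshold``.

    Parameters
    ----------
    scales : ScaleColumns or mapping dataset_id -> ScaleColumns
        Item columns per scale (see :class:`emovar.indices.ScaleColumns`).

    Returns
    -------
    (filtered table, ExclusionReport)
    """
    report = ExclusionReport(n_before=table["person_id"].nunique())
    drop: list[tuple[str, str, str]] = []
    for (ds, person), grp in table.groupby(["dataset_id", "person_id"], sort=False):
        sc = scales[ds] if isinstance(scales, dict) else scales
        reason = None
        for cols in (sc.pa, sc.na, sc.er):
            present = [c for c in cols if c in grp.columns]
            vals = grp[present].to_numpy(dtype=float).ravel()
            vals = vals[~np.isnan(vals)]
            if vals.size == 0 or np.nanstd(vals) == 0.0:
                reason = "zero_variance"
                break
        if reason is None and rt_col in grp.columns:
            if np.nanmean(grp[rt_col].to_numpy(dtype=float)) < rt_threshold:
                reason = "fast_rt"
        if reason:
            drop.append((ds, person, reason))
    for ds, person, reason in drop:
        counts = getattr(report, reason)
        counts[ds] = counts.get(ds, 0) + 1
        report.excluded_persons.append({"dataset_id": ds, "person_id": person,
                                        "reason": reason})
    dropped = {p for _, p, _ in drop}
    out = table[~table["person_id"].isin(dropped)].copy()
    report.n_after = out["person_id"].nunique()
    report.empty_output = out.empty
    return out, report


def compliance(table: pd.DataFrame, designs) -> tuple[pd.Series, float, float]:
    """Per-person compliance and its pooled mean/SD.

    Compliance is the fraction of scheduled assessments answered; the
    schedule size comes from each dataset's design (70 by default).

    Returns ``(per_person, pooled_mean, pooled_sd)``.
    """
    n_obs = {d.dataset_id: d.n_obs for d in designs}
    counts = table.groupby(["dataset_id", "person_id"], sort=False).size()
    per_person = counts / counts.index.get_level_values("dataset_id").map(n_obs)
    per_person.name = "compliance"
    return per_person, float(per_person.mean()), float(per_person.std(ddof=1))


@dataclass
class CenteredSeries:
    """Within/between decomposition of one series: raw = grand + between + within."""

    raw: np.ndarray
    within: np.ndarray
    between: np.ndarray
    grand_mean: float


def person_center(values, persons) -> CenteredSeries:
    """Split a series into within- and between-person components.

    ``within = raw - person mean`` (missing where raw is missing) and
    ``between = person mean - grand mean``, with the grand mean taken over
    the pooled sample.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    p = pd.Series(np.asarray(persons))
    grand = float(s.mean())
    pm = s.groupby(p).transform("mean")
    return CenteredSeries(
        raw=s.to_numpy(),
        within=(s - pm).to_numpy(),
        between=(pm - grand).to_numpy(),
        grand_mean=grand,
    )


def add_centered(table: pd.DataFrame, cols, person_col: str = "person_id") -> pd.DataFrame:
    """Append ``{col}_w`` and ``{col}_b`` columns for each named column."""
    out = table.copy()
    for col in cols:
        cs = person_center(out[col], out[person_col])
        out[f"{col}_w"] = cs.within
        out[f"{col}_b"] = cs.between
    return out


def center_time(obs_index, center: float = TIME_CENTER) -> np.ndarray:
    """Centered time covariate: observation index minus the schedule midpoint."""
    return np.asarray(obs_index, dtype=float) - center


def align_lags(
    table: pd.DataFrame,
    lag_cols,
    person_col: str = "person_id",
    break_at_day: bool = False,
    required: list[str] | None = None,
) -> pd.DataFrame:
    """Create one-assessment lags within person and flag complete rows.

    For every column in ``lag_cols`` a ``{col}_lag`` column is added holding
    the person's value at the *previous scheduled assessment*
    (``obs_index - 1``).  The lag is missing at each person's first
    assessment, whenever the previous assessment was not answered (rows are
    only paired across a one-assessment interval, never across gaps), and at
    the first beep of each day when ``break_at_day``.  Lags never cross
    persons or datasets.  A boolean ``complete`` column marks rows with no
    missing value among ``required`` (default: the lag columns plus the
    originals).

    Raises
    ------
    ValueError
        If a person has duplicated ``obs_index`` values.
    """
    id_keys = ([person_col, "dataset_id"] if "dataset_id" in table.columns
               else [person_col])
    dup = table.duplicated(id_keys + ["obs_index"])
    if dup.any():
        who = table.loc[dup, [person_col, "obs_index"]].iloc[0]
        raise ValueError(
            f"duplicated obs_index {who['obs_index']} for person {who[person_col]!r}"
        )
    out = table.sort_values(id_keys + ["obs_index"], kind="stable").copy()
    grp_keys = id_keys + ["day"] if break_at_day else id_keys
    g = out.groupby(grp_keys, sort=False)
    adjacent = g["obs_index"].diff() == 1
    for col in lag_cols:
        out[f"{col}_lag"] = g[col].shift(1).where(adjacent)
    if required is None:
        required = list(lag_cols) + [f"{c}_lag" for c in lag_cols]
    required = [c for c in required if c in out.columns]
    out["complete"] = out[required].notna().all(axis=1)
    return out


def multicollinearity_screen(
    table: pd.DataFrame,
    scales,
    threshold: float = 0.80,
) -> pd.DataFrame:
    """Within-person item correlations per scale, flagging pairs >= threshold.

    Items are person-centered (persons constant on an item contribute
    nothing) and Pearson correlations are computed on the pooled centered
    values, per dataset and scale.
    """
    rows = []
    for ds, grp in table.groupby("dataset_id", sort=False):
        sc = scales[ds] if isinstance(scales, dict) else scales
        for scale_name in ("pa", "na", "er"):
            cols = [c for c in getattr(sc, scale_name) if c in grp.columns]
            if len(cols) < 2:
                continue
            centered = grp[cols] - grp.groupby("person_id")[cols].transform("mean")
            corr = centered.corr()
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    r = float(corr.iloc[i, j])
                    rows.append({
                        "dataset_id": ds, "scale": scale_name,
                        "item_a": cols[i], "item_b": cols[j], "r": r,
                        "flagged": bool(abs(r) >= threshold),
                    })
    return pd.DataFrame(rows)
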
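"""Descriptive statistics, results assembly and pipeline orchestration.

The descriptives table mirrors the momentary-index summary of the pooled
sample: per index, the theoretical bounds, pooled mean, between-person SD
(SD of person means), within-person SD (SD of the pooled person-centered
values), and within-person minimum/maximum (the mean over persons of each
person's own minimum/maximum — an interpretation, since several summaries
fit that label).

The results table is keyed by hypothesis: H1 (differentiation -> subsequent
regulation variability), H2 (regulation variability -> subsequent
differentiation, judged by equivalence testing), H3 (between-person
association), and the exploratory mediation rows (a, b, c' paths and the
indirect effect).  Arrow notation marks temporal precedence.

``run_pipeline`` chains generate/read -> rescale -> exclusions -> indices ->
centering/lags -> models (+ optional mediation) -> descriptives and writes
every artifact with its run configuration, so identical configs replay to
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as prep
from .design import StudyDesign, SyntheticTruth, default_designs
from .indices import ScaleColumns, compute_indices
from .mediation import fit_1m, monte_carlo_indirect, stack_for_mediation
from .multilevel import MODEL_IDS, canned_spec, fit_crosslag, tost_equivalence
from .synth import LatentParams, gen_item_level

__all__ = [
    "descriptives",
    "results_table",
    "RunConfig",
    "run_pipeline",
    "scale_columns_for",
    "scale_map_for",
    "prepare_analysis_table",
]

# theoretical bounds of each momentary index
INDEX_BOUNDS = {
    "pa_int": (0.0, 10.0),
    "na_int": (0.0, 10.0),
    "er_int": (0.0, 10.0),
    "pa_ed": (-np.inf, 0.0),
    "na_ed": (-np.inf, 0.0),
    "erv_full": (0.0, 10.0),
    "erv_switch": (0.0, 10.0),
    "erv_endorse": (0.0, 10.0),
}


def descriptives(
    index_table: pd.DataFrame,
    index_cols=None,
    person_col: str = "person_id",
    within_sd: str = "pooled",
) -> pd.DataFrame:
    """Five-statistic descriptive row per momentary index.

    ``within_sd="pooled"`` (default) computes the within-person SD on the
    pooled person-centered values (observation-weighted);
    ``within_sd="mean_of_person"`` averages per-person SDs instead.
    """
    if index_cols is None:
        index_cols = [c for c in INDEX_BOUNDS if c in index_table.columns]
    rows = []
    for col in index_cols:
        sub = index_table[[person_col, col]].dropna()
        by_person = sub.groupby(person_col)[col]
        pm = by_person.mean()
        centered = sub[col] - sub[person_col].map(pm)
        if within_sd == "pooled":
            wsd = float(centered.std(ddof=1))
        elif within_sd == "mean_of_person":
            wsd = float(by_person.std(ddof=1).mean())
        else:
            raise ValueError(f"unknown within_sd mode {within_sd!r}")
        lo, hi = INDEX_BOUNDS.get(col, (np.nan, np.nan))
        rows.append({
            "index": col,
            "min_possible": lo,
            "max_possible": hi,
            "mean": float(sub[col].mean()),
            "between_sd": float(pm.std(ddof=1)),
            "within_sd": wsd,
            "within_min": float(by_person.min().mean()),
            "within_max": float(by_person.max().mean()),
        })
    return pd.DataFrame(rows).set_index("index")


def results_table(fits: dict, tost=None, mediation=None) -> pd.DataFrame:
    """Hypothesis-keyed export of model results with arrow notation.

    ``fits`` maps model ids ("1A".."2B") to :class:`ModelFit`; ``tost`` is
    the H2 equivalence result; ``mediation`` a (MediationResult,
    MonteCarloCI) pair.  Significance is a 95% CI excluding zero; every
    number is read off the fit objects, never recomputed.
    """
    rows = []

    def fixed_row(hyp, label, fit, term):
        p = fit.params.loc[term]
        lo, hi = float(p["ci95_lower"]), float(p["ci95_upper"])
        rows.append({
            "hypothesis": hyp, "effect": label,
            "estimate": float(p["estimate"]),
            "ci95_lower": lo, "ci95_upper": hi,
            "significant": bool(lo > 0 or hi < 0),
            "model": fit.spec.outcome,
        })

    labels = {
        "1A": ("H1", "ED -> ERV"),
        "1B": ("H1", "ED -> switching"),
        "1C": ("H1", "ED -> endorsement"),
        "2A": ("H2", "ERV -> ED"),
        "2B": ("H2", "switching/endorsement -> ED"),
    }
    for mid, fit in fits.items():
        hyp, label = labels.get(mid, ("RQ", mid))
        focal = fit.spec.within[0]
        fixed_row(hyp, label, fit, focal)
        if mid == "2A":      # H3 uses the between component of model 2A
            fixed_row("H3", "ED <-> ERV (between)", fit, fit.spec.between[0])
    if tost is not None:
        rows.append({
            "hypothesis": "H2", "effect": f"TOST {tost.effect}",
            "estimate": tost.estimate,
            "ci95_lower": tost.ci90[0], "ci95_upper": tost.ci90[1],
            "significant": bool(tost.concluded),
            "model": "equivalence (90% CI vs +/-0.187)",
        })
    if mediation is not None:
        med, ci = mediation
        for path, est, se in (("a-path: ED -> ERV", med.a, med.se_a),
                              ("b-path: ERV -> intensity", med.b, med.se_b),
                              ("c'-path: ED -> intensity", med.cprime, med.se_cprime)):
            lo, hi = est - 1.959963984540054 * se, est + 1.959963984540054 * se
            rows.append({"hypothesis": "RQ", "effect": path, "estimate": est,
                         "ci95_lower": lo, "ci95_upper": hi,
                         "significant": bool(lo > 0 or hi < 0), "model": "1M"})
        rows.append({
            "hypothesis": "RQ",
            "effect": "indirect (a*b + path covariance)",
            "estimate": med.indirect,
            "ci95_lower": ci.lower, "ci95_upper": ci.upper,
            "significant": bool(ci.lower > 0 or ci.upper < 0),
            "model": "1M (Monte-Carlo CI)",
        })
    return pd.DataFrame(rows)


def scale_columns_for(design: StudyDesign) -> ScaleColumns:
    """Item-column names implied by a study design."""
    return ScaleColumns(
        pa=tuple(f"pa_{j + 1}" for j in range(design.n_pa_items)),
        na=tuple(f"na_{j + 1}" for j in range(design.n_na_items)),
        er=tuple(f"er_{j + 1}" for j in range(design.n_er_items)),
    )


def scale_map_for(designs) -> dict:
    """Per-dataset rescaling bounds {dataset_id: {item: (min, max)}}."""
    out = {}
    for d in designs:
        sc = scale_columns_for(d)
        out[d.dataset_id] = {c: (d.item_scale_min, d.item_scale_max)
                             for c in (*sc.pa, *sc.na, *sc.er)}
    return out


def prepare_analysis_table(
    records: pd.DataFrame,
    designs,
    erv_mode: str = "all_moments",
    break_at_day: bool = False,
) -> tuple[pd.DataFrame, prep.ExclusionReport]:
    """Rescale, exclude, index, center and lag a raw item-level table."""
    scales = {d.dataset_id: scale_columns_for(d) for d in designs}
    rescaled = prep.rescale_items(records, scale_map_for(designs))
    kept, report = prep.apply_exclusions(rescaled, scales)
    idx = compute_indices(kept, scales, erv_mode=erv_mode)
    idx = prep.add_centered(
        idx, [c for c in INDEX_BOUNDS if c in idx.columns]
    )
    idx["time_c"] = prep.center_time(idx["obs_index"])
    idx["age_c"] = idx["age"] - idx["age"].mean()
    lag_cols = [c for c in ("na_ed_w", "pa_ed_w", "na_int_w", "pa_int_w",
                            "er_int_w", "na_ed", "pa_ed", "na_int", "pa_int")
                if c in idx.columns]
    table = prep.align_lags(idx, lag_cols, break_at_day=break_at_day)
    return table, report


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    seed: int = 0
    designs: list = field(default_factory=default_designs)
    valence: str = "neg"
    erv_mode: str = "all_moments"
    models: tuple[str, ...] = ("1A", "2A")
    mediation: bool = True
    mediation_draws: int = 20000
    ar1: bool = False
    break_at_day: bool = False
    input_csv: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        unknown = [m for m in self.models if m not in MODEL_IDS]
        if unknown:
            raise ValueError(f"unknown model id(s) {unknown}; valid: {MODEL_IDS}")
        if self.valence not in ("neg", "pos"):
            raise ValueError("valence must be 'neg' or 'pos'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "designs" in raw:
            raw["designs"] = [StudyDesign(**d) for d in raw["designs"]]
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["designs"] = [dd.to_dict() if hasattr(dd, "to_dict") else dd
                        for dd in self.designs]
        d["models"] = list(self.models)
        return d


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(path: Path, obj):
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_json_default) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return (and optionally write) the bundle.

    Stages: generate or read records -> preprocess -> indices -> centering
    and lags -> cross-lag models (with the H2 equivalence test when model
    2A runs) -> stacked mediation -> descriptives and the hypothesis table.
    Any stage failure is re-raised with the stage name.  Output JSON/CSV is
    deterministic for a given config (no timestamps), so replaying the same
    config is byte-identical.
    """
    stage = "generate"
    try:
        if config.input_csv:
            records = pd.read_csv(config.input_csv)
        else:
            records = gen_item_level(config.designs, seed=config.seed)
        stage = "preprocess/indices"
        table, excl = prepare_analysis_table(
            records, config.designs, erv_mode=config.erv_mode,
            break_at_day=config.break_at_day,
        )
        comp_pp, comp_mean, comp_sd = prep.compliance(records, config.designs)

        stage = "models"
        ed = "na_ed" if config.valence == "neg" else "pa_ed"
        fits, tost = {}, None
        for mid in config.models:
            spec = canned_spec(mid, valence=config.valence, ar1=config.ar1)
            fits[mid] = fit_crosslag(table, spec)
            if mid == "2A":
                tost = tost_equivalence(fits[mid], "erv_full_w")

        stage = "mediation"
        med_pair = None
        if config.mediation:
            inten = "na_int" if config.valence == "neg" else "pa_int"
            stacked = stack_for_mediation(
                table, predictor=f"{ed}_w_lag", mediator="erv_full",
                outcome=inten, mediator_within="erv_full_w",
                covariates=(f"{inten}_w_lag", "er_int_w", "time_c",
                            "age_c", "female"),
            )
            med = fit_1m(stacked)
            ci = monte_carlo_indirect(med, n_draws=config.mediation_draws,
                                      seed=config.seed)
            med.mc_ci = (ci.lower, ci.upper)
            med.n_draws, med.seed = ci.n_draws, ci.seed
            med_pair = (med, ci)

        stage = "report"
        desc = descriptives(table)
        results = results_table(fits, tost=tost, mediation=med_pair)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    bundle = {
        "config": config.to_dict(),
        "exclusions": excl.to_dict(),
        "compliance": {"mean": comp_mean, "sd": comp_sd},
        "descriptives": desc,
        "results": results,
        "fits": fits,
        "tost": tost,
        "mediation": med_pair,
        "analysis_table": table,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(out / "run_config.json", config.to_dict())
        _write_json(out / "exclusions.json", excl.to_dict())
        _write_json(out / "compliance.json", bundle["compliance"])
        desc.to_csv(out / "descriptives.csv", float_format="%.10g")
        results.to_csv(out / "results_table.csv", index=False,
                       float_format="%.10g")
        _write_json(out / "model_fits.json",
                    {mid: f.to_dict() for mid, f in fits.items()})
        if tost is not None:
            _write_json(out / "tost.json", tost.to_dict())
        if med_pair is not None:
            _write_json(out / "mediation.json",
                        {"fit": med_pair[0].to_dict(),
                         "mc_ci": med_pair[1].to_dict()})
    return bundle
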
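"""End-to-end analysis: flags, outcomes, accuracy tables, DeLong comparisons.

The orchestration mirrors a diagnostic-accuracy study layout:

* a primary table ("table2") of per-chart accuracy (2x2 metrics and the
  chart-alone AUC) on the full analyzable cohort;
* a combined-model table ("table3") on the HbA1c-available subset, where
  each chart flag is combined with HbA1c (continuous and/or dichotomized at
  6.5%) in a logistic model and AUCs are compared flag-alone vs flag+HbA1c
  per chart, and pairwise between charts;
* a sensitivity-analysis table ("table4") of chart-alone AUCs restricted to
  subjects with obesity (BMI >= 30), late scans (GA >= 32 weeks) and the
  HbA1c-available subset.

All pairwise AUC comparisons use the DeLong method on paired scores; no
multiple-testing correction is applied and raw p-values are reported.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .charts import (
    BirthweightReference,
    GrowthChart,
    is_lga_at_birth,
    load_birthweight_reference,
    load_chart,
)
from .diagnostics import (
    DiagnosticsError,
    SeparationError,
    auc_with_ci,
    confusion_matrix,
    delong_compare,
    diagnostic_metrics,
    fit_logistic,
    roc_auc,
)
from .efw import hadlock_c_log10_efw
from .simulate import COHORT_COLUMNS, read_cohort_csv

__all__ = [
    "AnalysisConfig",
    "AnalysisResult",
    "PipelineError",
    "select_hba1c",
    "apply_subset",
    "annotate_cohort",
    "run_analysis",
    "write_report",
    "SUBSETS",
    "HBA1C_THRESHOLD",
]

SUBSETS = ("all", "bmi_ge_30", "scan_ge_32w", "hba1c_available")
HBA1C_THRESHOLD = 6.5
_HBA1C_MODES = ("continuous", "threshold_6_5", "both")


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis options; chart/reference paths may be supplied here or
    the loaded objects passed to :func:`run_analysis` directly."""

    chart_paths: dict = field(default_factory=dict)
    bw_reference_path: str | None = None
    hba1c_mode: str = "both"
    subset: str = "all"
    ci_level: float = 0.95
    output_dir: str | None = None
    seed: int = 0
    scan_subset_min_weeks: float = 32.0   # inclusive boundary of the late-scan subset
    prob_cutoff: float = 0.5              # dichotomizes combined-model probabilities
    stratum_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.hba1c_mode not in _HBA1C_MODES:
            raise PipelineError(f"hba1c_mode must be one of {_HBA1C_MODES}")
        if self.subset not in SUBSETS:
            raise PipelineError(f"subset must be one of {SUBSETS}")
        if not 0.5 < self.ci_level < 1.0:
            raise PipelineError("ci_level must be in (0.5, 1)")

    @classmethod
    def from_json(cls, source) -> "AnalysisConfig":
        text = source
        try:
            p = Path(str(source))
            if p.exists():
                text = p.read_text()
        except OSError:
            pass  # not a path: treat as a JSON string
        doc = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


# ---------------------------------------------------------------------------
# Record-level rules
# ---------------------------------------------------------------------------

def select_hba1c(measurements: pd.DataFrame, ga_delivery: Mapping[str, float]) -> pd.DataFrame:
    """One HbA1c per subject: the latest measurement after 20 weeks.

    ``measurements`` has columns subject_id, ga_weeks, hba1c_pct (repeated
    rows per subject allowed).  Only measurements strictly after 20 weeks
    qualify; among those the one with the greatest GA (closest to delivery)
    is kept.  Subjects with no qualifying measurement get a missing value.
    A measurement dated after its subject's delivery is an error.
    """
    req = {"subject_id", "ga_weeks", "hba1c_pct"}
    if not req <= set(measurements.columns):
        raise PipelineError(f"measurements need columns {sorted(req)}")
    out = pd.DataFrame(
        {"hba1c_pct": np.nan, "ga_hba1c_weeks": np.nan},
        index=pd.Index(list(ga_delivery.keys()), name="subject_id"),
    )
    for sid, grp in measurements.groupby("subject_id"):
        if sid not in ga_delivery:
            raise PipelineError(f"no delivery GA for subject {sid!r}")
        delivery = float(ga_delivery[sid])
        if (grp["ga_weeks"] > delivery + 1e-9).any():
            raise PipelineError(
                f"subject {sid!r}: HbA1c measurement GA exceeds delivery GA {delivery:g}"
            )
        eligible = grp[grp["ga_weeks"] > 20.0]
        if eligible.empty:
            continue
        row = eligible.loc[eligible["ga_weeks"].idxmax()]
        out.loc[sid, "hba1c_pct"] = float(row["hba1c_pct"])
        out.loc[sid, "ga_hba1c_weeks"] = float(row["ga_weeks"])
    return out


def apply_subset(cohort: pd.DataFrame, subset: str, scan_min_weeks: float = 32.0) -> pd.DataFrame:
    """Pure row filter implementing the sensitivity-analysis subsets."""
    if subset == "all":
        return cohort
    if subset == "bmi_ge_30":
        return cohort[cohort["bmi"] >= 30.0]
    if subset == "scan_ge_32w":
        return cohort[cohort["ga_weeks"] >= scan_min_weeks]
    if subset == "hba1c_available":
        return cohort[cohort["hba1c_pct"].notna()]
    raise PipelineError(f"unknown subset {subset!r}; expected one of {SUBSETS}")


def _dedupe_scans(cohort: pd.DataFrame) -> pd.DataFrame:
    """One scan per subject: keep the scan closest to delivery (max GA)."""
    if not cohort["subject_id"].duplicated().any():
        return cohort
    idx = cohort.groupby("subject_id")["ga_weeks"].idxmax()
    return cohort.loc[sorted(idx)].reset_index(drop=True)


def annotate_cohort(
    cohort: pd.DataFrame,
    charts: Mapping[str, GrowthChart],
    bw_ref: BirthweightReference,
    stratum_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Add EFW, the birth outcome and one flag/percentile pair per chart."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise PipelineError(f"cohort is missing columns {missing}")
    df = _dedupe_scans(cohort).copy()
    df["efw_g"] = 10.0 ** hadlock_c_log10_efw(df["bpd_cm"], df["ac_cm"], df["fl_cm"])
    df["lga_birth"] = is_lga_at_birth(
        df["birth_weight_g"].to_numpy(), df["ga_delivery_weeks"].to_numpy(),
        df["infant_sex"].to_numpy(), bw_ref,
    )
    smap = stratum_map or {}
    for name, chart in charts.items():
        if chart.strata is not None:
            strata = df["race_eth"].map(lambda r: smap.get(r, r)).to_numpy()
            pct = np.array([
                chart.percentile(e, g, stratum=s)
                for e, g, s in zip(df["efw_g"], df["ga_weeks"], strata)
            ])
        else:
            pct = chart.percentile(df["efw_g"].to_numpy(), df["ga_weeks"].to_numpy())
        df[f"pct_{name}"] = pct
        df[f"flag_{name}"] = pct >= 90.0
    return df


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _metric_cols(prefix: str, metric) -> dict:
    if metric is None:
        return {f"{prefix}_pct": np.nan, f"{prefix}_lo": np.nan, f"{prefix}_hi": np.nan}
    return {
        f"{prefix}_pct": metric.pct,
        f"{prefix}_lo": 100.0 * metric.ci_low,
        f"{prefix}_hi": 100.0 * metric.ci_high,
    }


def _accuracy_row(flags, outcomes, ci_level: float) -> dict:
    cm = confusion_matrix(flags, outcomes)
    summ = diagnostic_metrics(cm, ci_level=ci_level)
    row = {"n": cm.total, "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        row.update(_metric_cols(name, getattr(summ, name)))
    return row


def _auc_cols(scores, outcomes, ci_level: float) -> dict:
    auc = auc_with_ci(scores, outcomes, ci_level=ci_level)
    return {"auc": auc.point, "auc_lo": auc.ci_low, "auc_hi": auc.ci_high}


def _pairwise(scores_by_name: dict, outcomes) -> dict[str, dict[str, float]]:
    """DeLong p-values for every ordered pair of score vectors."""
    out: dict[str, dict[str, float]] = {k: {} for k in scores_by_name}
    names = list(scores_by_name)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cmp_ = delong_compare(scores_by_name[a], scores_by_name[b], outcomes)
            out[a][b] = cmp_.p_value
            out[b][a] = cmp_.p_value
    return out


@dataclass
class AnalysisResult:
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    manifest: dict
    annotated: pd.DataFrame = field(repr=False, default=None)


def _combined_scores(df: pd.DataFrame, flag_col: str, mode: str):
    """Fitted probabilities of the flag+HbA1c logistic model, or None on
    separation (recorded by the caller)."""
    predictors = pd.DataFrame({"flag": df[flag_col].astype(float)})
    if mode == "continuous":
        predictors["hba1c"] = df["hba1c_pct"].astype(float)
    else:
        predictors["hba1c_ge_6_5"] = (df["hba1c_pct"] >= HBA1C_THRESHOLD).astype(float)
    model = fit_logistic(df["lga_birth"].to_numpy(), predictors)
    return model.fitted_probabilities


def run_analysis(
    cohort,
    config: AnalysisConfig | None = None,
    charts: Mapping[str, GrowthChart] | None = None,
    bw_ref: BirthweightReference | None = None,
) -> AnalysisResult:
    """Full accuracy analysis of a cohort against one or more charts."""
    config = config or AnalysisConfig()
    if isinstance(cohort, (str, Path)):
        cohort = read_cohort_csv(cohort)
    if charts is None:
        if not config.chart_paths:
            raise PipelineError("no charts: pass `charts` or set chart_paths in config")
        charts = {name: load_chart(p) for name, p in config.chart_paths.items()}
    if bw_ref is None:
        if config.bw_reference_path is None:
            raise PipelineError("no birth-weight reference given")
        bw_ref = load_birthweight_reference(config.bw_reference_path)

    df = annotate_cohort(cohort, charts, bw_ref, stratum_map=config.stratum_map)
    df = apply_subset(df, config.subset, config.scan_subset_min_weeks)
    if df.empty:
        raise PipelineError(f"subset {config.subset!r} left no subjects")
    outcomes = df["lga_birth"].to_numpy()
    ci = config.ci_level

    # ---- table 2: per-chart accuracy on the analyzed cohort --------------
    flag_scores = {name: df[f"flag_{name}"].to_numpy().astype(float) for name in charts}
    pairwise2 = _pairwise(flag_scores, outcomes)
    rows2 = []
    for name in charts:
        flags = df[f"flag_{name}"].to_numpy()
        row = {"chart": name}
        row.update(_accuracy_row(flags, outcomes, ci))
        row.update(_auc_cols(flag_scores[name], outcomes, ci))
        for other, p in pairwise2[name].items():
            row[f"p_vs_{other}"] = p
        rows2.append(row)
    table2 = pd.DataFrame(rows2)

    # ---- table 3: flag +/- HbA1c on the HbA1c-available subset -----------
    sub = apply_subset(df, "hba1c_available")
    modes = {"continuous": ["continuous"], "threshold_6_5": ["threshold_6_5"],
             "both": ["continuous", "threshold_6_5"]}[config.hba1c_mode]
    rows3 = []
    if sub.empty or sub["lga_birth"].nunique() < 2:
        table3 = pd.DataFrame()
    else:
        out_sub = sub["lga_birth"].to_numpy()
        for mode in modes:
            scores_by_chart = {}
            notes = {}
            for name in charts:
                try:
                    scores_by_chart[name] = _combined_scores(sub, f"flag_{name}", mode)
                    notes[name] = ""
                except (SeparationError, DiagnosticsError) as exc:
                    scores_by_chart[name] = None
                    notes[name] = f"model not fitted: {exc}"
            fitted = {k: v for k, v in scores_by_chart.items() if v is not None}
            pairwise3 = _pairwise(fitted, out_sub) if len(fitted) > 1 else {k: {} for k in fitted}
            for name in charts:
                row = {"chart": name, "model": f"flag_plus_hba1c_{mode}", "note": notes[name]}
                scores = scores_by_chart[name]
                if scores is not None:
                    row.update(_accuracy_row(scores >= config.prob_cutoff, out_sub, ci))
                    row.update(_auc_cols(scores, out_sub, ci))
                    flag_only = sub[f"flag_{name}"].to_numpy().astype(float)
                    row["auc_flag_alone"] = roc_auc(flag_only, out_sub)
                    row["p_vs_flag_alone"] = delong_compare(scores, flag_only, out_sub).p_value
                    for other, p in pairwise3.get(name, {}).items():
                        row[f"p_vs_{other}"] = p
                rows3.append(row)
        table3 = pd.DataFrame(rows3)

    # ---- table 4: chart-alone AUCs in the sensitivity subsets ------------
    rows4 = []
    for subset in ("bmi_ge_30", "scan_ge_32w", "hba1c_available"):
        ssub = apply_subset(df, subset, config.scan_subset_min_weeks)
        if ssub.empty or ssub["lga_birth"].nunique() < 2:
            continue
        s_out = ssub["lga_birth"].to_numpy()
        s_scores = {name: ssub[f"flag_{name}"].to_numpy().astype(float) for name in charts}
        pairwise4 = _pairwise(s_scores, s_out)
        for name in charts:
            row = {"subset": subset, "chart": name, "n": int(len(ssub))}
            row.update(_auc_cols(s_scores[name], s_out, ci))
            for other, p in pairwise4[name].items():
                row[f"p_vs_{other}"] = p
            rows4.append(row)
    table4 = pd.DataFrame(rows4)

    manifest = {
        "package": {"name": "lgascreen", "version": __version__},
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "charts": {name: {"dialect": c.dialect, "name": c.name} for name, c in charts.items()},
        "bw_reference": bw_ref.name,
        "n_input": int(len(cohort)),
        "n_analyzed": int(len(df)),
        "n_lga": int(outcomes.sum()),
        "n_hba1c_available": int(df["hba1c_pct"].notna().sum()),
    }
    return AnalysisResult(table2=table2, table3=table3, table4=table4,
                          manifest=manifest, annotated=df)


def write_report(result: AnalysisResult, output_dir) -> list[Path]:
    """Write table2/3/4 CSVs and the JSON run manifest; returns the paths."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in ("table2", "table3", "table4"):
        p = outdir / f"{name}.csv"
        getattr(result, name).to_csv(p, index=False, float_format="%.10g")
        paths.append(p)
    p = outdir / "manifest.json"
    p.write_text(json.dumps(result.manifest, indent=1, sort_keys=True, default=str))
    paths.append(p)
    return paths
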
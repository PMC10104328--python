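"""End-to-end orchestration: four nested loops over datasets, gait subsets,
variability metrics and classifier families, producing a nine-cell report.

Outer to inner: (1) dataset (all horses / high-intensity / low-intensity by
the 4.0 mmol/L maximum plasma-lactate cutoff), (2) gait subset (walk, trot,
walk+trot), (3) variability metric (RMS, CV, SD, VAR), (4) classifier
family.  For each (dataset, subset) cell the best (metric, classifier)
combination by pooled LOSO accuracy is reported together with the selected
features and per-fold performance statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .feature_table import aggregate, feature_matrix, normalize_within_horse
from .features import extract_stride_features
from .preprocessing import detect_hoof_events, lowpass, segment_strides
from .selection import greedy_forward_selection, loso_cv, nca_weights, rank_features
from .synthetic import SyntheticCohort
from .types import DATASETS, FEATURE_NAMES, FORCED_FEATURES, GAIT_SUBSETS

logger = logging.getLogger(__name__)


def assign_intensity(group_mean_max_la: float, cutoff: float = 4.0) -> str:
    """Exercise-intensity label from a maximum plasma-lactate value
    (mmol/L): >= cutoff is 'high', below is 'low'."""
    if group_mean_max_la < 0:
        raise ValueError("plasma lactate cannot be negative")
    return "high" if group_mean_max_la >= cutoff else "low"


def extract_cohort_features(
    cohort: SyntheticCohort, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Filter, segment and feature-extract every recording of a cohort.

    Returns one row per valid stride with the 52 features and metadata.
    """
    config = config or PipelineConfig()
    pp, fc = config.preprocessing, config.features
    rows = []
    for (horse, trial, gait), streams in cohort.recordings.items():
        filtered = {loc: lowpass(s, pp.filter_order, pp.cutoff_hz)
                    for loc, s in streams.items()}
        events = detect_hoof_events(
            filtered["RF"], theta=pp.theta, smooth_s=pp.smooth_s,
            robust_window_strides=pp.robust_window_strides)
        windows = segment_strides(filtered, events, horse, trial, gait,
                                  mad_threshold=pp.mad_threshold)
        n_invalid = 0
        for w in windows:
            if not w.valid:
                n_invalid += 1
                continue
            rows.append(extract_stride_features(
                filtered, w, rom_fraction=fc.rom_fraction,
                stride_length_offset=fc.stride_length_offset))
        logger.info("extracted %s/%s/%s: %d strides (%d invalid)",
                    horse, trial, gait, len(windows), n_invalid)
    return pd.DataFrame(rows)


@dataclass
class ReportCell:
    """One (dataset, gait subset) cell of the classification report."""

    dataset: str
    gait_subset: str
    evaluable: bool = False
    reason: str = ""
    n_horses: int = 0
    n_strides_pre: int = 0
    n_strides_post: int = 0
    variability_metric: str = ""
    classifier: str = ""
    selected_features: list = field(default_factory=list)
    accuracy: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    accuracy_mean: float = np.nan
    accuracy_sd: float = np.nan
    sensitivity_mean: float = np.nan
    sensitivity_sd: float = np.nan
    specificity_mean: float = np.nan
    specificity_sd: float = np.nan
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    forced_comparison: dict = field(default_factory=dict)


@dataclass
class ClassificationReport:
    """Nine cells (3 datasets x 3 gait subsets) plus run metadata."""

    cells: list
    seed: int = 0

    def cell(self, dataset: str, gait_subset: str) -> ReportCell:
        for c in self.cells:
            if c.dataset == dataset and c.gait_subset == gait_subset:
                return c
        raise KeyError((dataset, gait_subset))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {k: v for k, v in vars(c).items()
                   if k not in ("selected_features", "forced_comparison")}
            row["selected_features"] = ";".join(c.selected_features)
            rows.append(row)
        return pd.DataFrame(rows)


def _subset_gaits(subset: str) -> tuple:
    return ("walk", "trot") if subset == "walk_trot" else (subset,)


def _forced_comparison(sub: pd.DataFrame) -> dict:
    """Raw pre/post means of the always-reported features (speed and the
    gait-event durations), averaged per horse then across horses."""
    out = {}
    per_horse = sub.groupby(["horse_id", "trial"])[list(FORCED_FEATURES)].mean()
    for f in FORCED_FEATURES:
        series = per_horse[f].groupby(level="trial").mean()
        out[f] = {"pre": float(series.get("pre", np.nan)),
                  "post": float(series.get("post", np.nan))}
    return out


def evaluate_subset(
    stride_features: pd.DataFrame,
    metric: str,
    classifier: str,
    config: PipelineConfig,
):
    """Aggregate -> NCA -> greedy selection -> LOSO for one subset and one
    (metric, classifier) combination.  Returns (SelectionResult, n_samples)
    or (None, reason)."""
    agg = aggregate(stride_features, metric=metric,
                    min_strides=config.aggregation.min_strides,
                    sliding_window=config.aggregation.sliding_window)
    if agg.empty:
        return None, "no horse-trial reached the minimum stride count"
    counts = agg.groupby("horse_id")["trial"].nunique()
    keep = counts.index[counts == 2]
    agg = agg[agg["horse_id"].isin(keep)]
    if agg["horse_id"].nunique() < 2:
        return None, "fewer than two horses with both trials"
    X, y, groups, cols = feature_matrix(agg)
    if X.shape[1] == 0:
        return None, "no finite feature columns"
    w = nca_weights(X, y, lam=config.selection.lam, seed=config.seed,
                    max_iter=config.selection.max_iter)
    ranking = rank_features(w, cols)
    if config.selection.force_include:
        # move the always-reported features to the head of the ranking
        forced = [c for f in FORCED_FEATURES for c in (f"mean_{f}", f"var_{f}") if c in cols]
        rest = [n for n in ranking.names if n not in forced]
        ranking.names = forced + rest
        ranking.weights = np.asarray([w[cols.index(n)] for n in ranking.names])
    sel = greedy_forward_selection(
        ranking, X, y, groups, cols, classifier=classifier, seed=config.seed,
        hyperparams=config.classifiers.hyperparams.get(classifier),
        max_features=config.selection.max_features)
    return sel, len(y)


def run_pipeline(cohort: SyntheticCohort, config: PipelineConfig | None = None,
                 stride_features: pd.DataFrame | None = None) -> ClassificationReport:
    """Run the full nested-loop analysis on a cohort.

    ``stride_features`` may be supplied to skip re-extraction.  Cells that
    cannot be evaluated (too few horses or strides) are marked
    not-evaluable and the run continues.  Deterministic given the config
    seed.
    """
    config = config or PipelineConfig()
    if stride_features is None:
        stride_features = extract_cohort_features(cohort, config)

    # intensity is assigned per exercise group (the discipline analog) from
    # the group's mean maximum lactate, as individual horses in a
    # high-intensity group may fall below the cutoff
    groups: dict = {}
    for h in cohort.horses:
        groups.setdefault(cohort.intensity_group.get(h, "all"), []).append(h)
    intensity = {}
    for grp, hs in groups.items():
        label = assign_intensity(
            float(np.mean([cohort.max_lactate[h] for h in hs])),
            config.datasets.la_cutoff)
        for h in hs:
            intensity[h] = label
    members = {
        "all": list(cohort.horses),
        "high": [h for h in cohort.horses if intensity[h] == "high"],
        "low": [h for h in cohort.horses if intensity[h] == "low"],
    }

    cells = []
    for dataset in DATASETS:
        for subset in GAIT_SUBSETS:
            cell = ReportCell(dataset=dataset, gait_subset=subset)
            cells.append(cell)
            gaits = _subset_gaits(subset)
            sub = stride_features[
                stride_features["horse_id"].isin(members[dataset])
                & stride_features["gait"].isin(gaits)]
            # strides with any undefined feature are excluded from aggregation
            sub = sub.dropna(subset=list(FEATURE_NAMES))
            if sub.empty or sub["horse_id"].nunique() < 2:
                cell.reason = "fewer than two horses with data"
                continue
            have_both = sub.groupby("horse_id")["trial"].nunique()
            sub = sub[sub["horse_id"].isin(have_both.index[have_both == 2])]
            if sub["horse_id"].nunique() < 2:
                cell.reason = "fewer than two horses with both trials"
                continue
            cell.n_strides_pre = int((sub["trial"] == "pre").sum())
            cell.n_strides_post = int((sub["trial"] == "post").sum())
            cell.forced_comparison = _forced_comparison(sub)
            norm = normalize_within_horse(sub)
            best = None
            for metric in config.aggregation.metrics:
                for clf in config.classifiers.menu:
                    sel, info = evaluate_subset(norm, metric, clf, config)
                    if sel is None:
                        cell.reason = str(info)
                        continue
                    acc = sel.result.metrics.accuracy
                    if best is None or acc > best[0]:
                        best = (acc, metric, clf, sel)
            if best is None:
                cell.reason = cell.reason or "no evaluable (metric, classifier) combination"
                continue
            _, metric, clf, sel = best
            res = sel.result
            cell.evaluable = True
            cell.reason = ""
            cell.n_horses = int(sub["horse_id"].nunique())
            cell.variability_metric = metric
            cell.classifier = clf
            cell.selected_features = sel.features
            cell.accuracy = res.metrics.accuracy
            cell.sensitivity = res.metrics.sensitivity
            cell.specificity = res.metrics.specificity
            cell.accuracy_mean = float(np.nanmean(res.fold_accuracy))
            cell.accuracy_sd = float(np.nanstd(res.fold_accuracy, ddof=1))
            cell.sensitivity_mean = float(np.nanmean(res.fold_sensitivity))
            cell.sensitivity_sd = float(np.nanstd(res.fold_sensitivity, ddof=1))
            cell.specificity_mean = float(np.nanmean(res.fold_specificity))
            cell.specificity_sd = float(np.nanstd(res.fold_specificity, ddof=1))
            cell.tp, cell.fp = res.counts.tp, res.counts.fp
            cell.tn, cell.fn = res.counts.tn, res.counts.fn
    return ClassificationReport(cells=cells, seed=config.seed)


def write_report(report: ClassificationReport, out_dir: str | Path) -> dict:
    """Write the report as a machine-readable CSV, a human-readable text
    table and a forced-feature comparison CSV.  Returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    csv_path = out / "report.csv"
    frame.to_csv(csv_path, index=False)

    forced_rows = []
    for c in report.cells:
        for f, v in c.forced_comparison.items():
            forced_rows.append({"dataset": c.dataset, "gait_subset": c.gait_subset,
                                "feature": f, "pre": v["pre"], "post": v["post"]})
    forced_path = out / "forced_features.csv"
    pd.DataFrame(forced_rows).to_csv(forced_path, index=False)

    txt_path = out / "report.txt"
    lines = ["Fatigue classification report (one cell per dataset x gait subset)",
             "=" * 68]
    for c in report.cells:
        lines.append(f"\n[{c.dataset} / {c.gait_subset}]")
        if not c.evaluable:
            lines.append(f"  not evaluable: {c.reason}")
            continue
        lines.append(f"  horses: {c.n_horses}   strides pre/post: "
                     f"{c.n_strides_pre}/{c.n_strides_post}")
        lines.append(f"  best variability metric: {c.variability_metric}   "
                     f"classifier: {c.classifier}")
        lines.append(f"  selected features: {', '.join(c.selected_features)}")
        lines.append(
            f"  accuracy {100 * c.accuracy_mean:.0f}±{100 * c.accuracy_sd:.0f}%  "
            f"sensitivity {100 * c.sensitivity_mean:.0f}±{100 * c.sensitivity_sd:.0f}%  "
            f"specificity {100 * c.specificity_mean:.0f}±{100 * c.specificity_sd:.0f}%  "
            f"(fold mean±SD; pooled accuracy {100 * c.accuracy:.1f}%)")
    txt_path.write_text("\n".join(lines) + "\n")
    return {"csv": csv_path, "forced": forced_path, "txt": txt_path}


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back the machine-readable report table."""
    return pd.read_csv(path)
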
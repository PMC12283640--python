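"""Per-class aggregation and classification metrics.

Classification quality is summarized by the confusion matrix (symptomatic
class treated as positive), accuracy, per-class precision and F1,
sensitivity, specificity, and AUC-ROC.  Overlap measurements are averaged
per class as mean +/- sample standard deviation over non-degenerate
samples, the layout of a per-class composition-influence table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .compositions import COMPOSITIONS
from .labels import ASY, CLASSES, SY
from .quantify import measurements_to_frame


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts with the SY class as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    """Percent-scale classification metrics plus AUC in [0, 1].

    A metric whose denominator is zero is reported as None with a named
    reason in ``undefined`` (never silently as 0).
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    precision: dict
    f1: dict
    auc: float | None
    undefined: dict

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": dict(self.precision),
            "f1": dict(self.f1),
            "auc": self.auc,
            "undefined": dict(self.undefined),
        }


def confusion_matrix(y_true: list[str], y_pred: list[str]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with SY positive; validates labels and lengths."""
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for t, p in zip(y_true, y_pred):
        if t not in CLASSES or p not in CLASSES:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        if t == SY:
            counts["tp" if p == SY else "fn"] += 1
        else:
            counts["fp" if p == SY else "tn"] += 1
    return ConfusionMatrix(**counts)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def classification_metrics(
    cm: ConfusionMatrix,
    scores: np.ndarray | None = None,
    y_true: list[str] | None = None,
) -> Metrics:
    """Accuracy, SE, SP, per-class precision/F1 and (optionally) AUC.

    Precision and F1 are computed for both classes, each treated as
    positive in turn; F1 is the harmonic mean of its class's precision and
    recall.  AUC uses the Mann-Whitney rank statistic over the provided
    per-sample SY probabilities (ties get half credit).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined = {}
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn)
    if sensitivity is None:
        undefined["sensitivity"] = "no positive (SY) samples"
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    if specificity is None:
        undefined["specificity"] = "no negative (ASY) samples"

    precision, f1 = {}, {}
    per_class = {
        SY: (cm.tp, cm.fp, cm.fn),
        ASY: (cm.tn, cm.fn, cm.fp),  # ASY as positive transposes the matrix
    }
    for label, (tp, fp, fn) in per_class.items():
        prec = _ratio(tp, tp + fp)
        rec = _ratio(tp, tp + fn)
        if prec is None:
            undefined[f"precision_{label}"] = f"no predictions for class {label}"
        precision[label] = prec
        if prec is None or rec is None or prec + rec == 0:
            undefined[f"f1_{label}"] = f"precision or recall undefined/zero for {label}"
            f1[label] = None
        else:
            f1[label] = 2 * prec * rec / (prec + rec)

    auc = None
    if scores is not None:
        if y_true is None:
            raise ValueError("AUC needs y_true alongside the scores")
        y_bin = np.asarray([t == SY for t in y_true])
        if y_bin.all() or not y_bin.any():
            undefined["auc"] = "AUC needs both classes among y_true"
        else:
            auc = float(roc_auc_score(y_bin, np.asarray(scores, dtype=float)))
    return Metrics(accuracy, sensitivity, specificity, precision, f1, auc, undefined)


_MEASUREMENT_COLUMNS = (
    ["gtplq_heatmap"]
    + [f"{c}_to_gt" for c in COMPOSITIONS]
    + [f"hmp_in_{c}" for c in COMPOSITIONS]
    + [f"hmp_{c}" for c in COMPOSITIONS]
)


def aggregate_by_class(
    measurements: pd.DataFrame | list,
    exclude_absent_compositions: bool = False,
) -> pd.DataFrame:
    """Per-class mean +/- sample std of every overlap measurement.

    Degenerate samples are excluded from the statistics and counted in
    ``n_degenerate_excluded``.  With ``exclude_absent_compositions`` the
    HMPin averages skip samples where the composition has zero area
    (otherwise their 0 convention enters the mean).  A single included
    sample reports std 0 with the ``single_sample`` flag set; a class with
    no usable samples is reported empty (NaN), never zero.
    """
    if not isinstance(measurements, pd.DataFrame):
        rows = [m.as_row() for m in measurements]
        measurements = measurements_to_frame(rows)
    if measurements.empty:
        raise ValueError("no measurements to aggregate")
    out = []
    for label in CLASSES:
        cls = measurements[measurements["class"] == label]
        good = cls[~cls["degenerate"].astype(bool)]
        n_deg = int(cls["degenerate"].astype(bool).sum())
        for col in _MEASUREMENT_COLUMNS:
            values = good[col]
            if exclude_absent_compositions and col.startswith("hmp_in_"):
                comp = col.removeprefix("hmp_in_")
                values = good.loc[good[f"present_{comp}"].astype(bool), col]
            n = int(values.notna().sum())
            mean = float(values.mean()) if n else np.nan
            std = float(values.std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan)
            out.append(
                {
                    "class": label,
                    "measurement": col,
                    "mean": mean,
                    "std": std,
                    "n_included": n,
                    "n_degenerate_excluded": n_deg,
                    "single_sample": n == 1,
                }
            )
    return pd.DataFrame(out)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def export_outputs(
    split,
    predictions: pd.DataFrame,
    measurements: pd.DataFrame,
    summaries: pd.DataFrame | None,
    out_dir: str | Path,
    metrics: Metrics | None = None,
    config: dict | None = None,
) -> dict:
    """Write metrics JSON, summary and measurement CSVs, plot data and run log.

    Returns a dict of written paths.  With an empty measurements table only
    the metrics are written and the summaries are skipped with a notice in
    the run log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    if split is not None:
        p = out_dir / "split.csv"
        split.to_frame().to_csv(p, index=False)
        written["split"] = p
    if predictions is not None:
        p = out_dir / "predictions.csv"
        predictions.to_csv(p, index=False)
        written["predictions"] = p
    if metrics is not None:
        p = out_dir / "metrics.json"
        p.write_text(json.dumps(metrics.to_dict(), indent=2))
        written["metrics"] = p

    notices = []
    if measurements is not None and not measurements.empty:
        p = out_dir / "measurements.csv"
        measurements.to_csv(p, index=False)
        written["measurements"] = p
        if summaries is not None:
            p = out_dir / "summary_by_class.csv"
            summaries.to_csv(p, index=False)
            written["summary"] = p
        # boxplot data + figure: composition share of plaque, by class
        box_cols = ["class"] + [f"{c}_to_gt" for c in COMPOSITIONS]
        box = measurements.loc[~measurements["degenerate"].astype(bool), box_cols]
        box.to_csv(out_dir / "boxplot_to_gt.csv", index=False)
        written["boxplot_data"] = out_dir / "boxplot_to_gt.csv"
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, label in zip(axes, CLASSES):
            data = [box.loc[box["class"] == label, f"{c}_to_gt"].dropna() for c in COMPOSITIONS]
            ax.boxplot(data, tick_labels=[c.upper() for c in COMPOSITIONS])
            ax.set_title(label)
            ax.set_ylabel("% of plaque area")
        fig.tight_layout()
        fig.savefig(out_dir / "boxplot_to_gt.png", dpi=100)
        plt.close(fig)
        # scatter data + figure: composition share vs covered share
        rows = []
        for _, r in measurements.iterrows():
            if r["degenerate"]:
                continue
            for c in COMPOSITIONS:
                rows.append({"class": r["class"], "composition": c,
                             "to_gt": r[f"{c}_to_gt"], "hmp_in": r[f"hmp_in_{c}"]})
        scatter = pd.DataFrame(rows)
        scatter.to_csv(out_dir / "scatter_to_gt_vs_hmp_in.csv", index=False)
        written["scatter_data"] = out_dir / "scatter_to_gt_vs_hmp_in.csv"
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, label in zip(axes, CLASSES):
            sub = scatter[scatter["class"] == label]
            ax.scatter(sub["to_gt"], sub["hmp_in"], s=4 + sub["to_gt"], alpha=0.5)
            ax.set_title(label)
            ax.set_xlabel("composition % of plaque")
            ax.set_ylabel("% of composition covered")
        fig.tight_layout()
        fig.savefig(out_dir / "scatter_to_gt_vs_hmp_in.png", dpi=100)
        plt.close(fig)
    else:
        notices.append("no measurements: summaries and plots skipped")

    log = {"config": config or {}, "config_hash": config_hash(config or {}), "notices": notices}
    p = out_dir / "run_log.json"
    p.write_text(json.dumps(log, indent=2, default=str))
    written["run_log"] = p
    return written
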
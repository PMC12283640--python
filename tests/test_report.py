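"""Confusion matrix, the five printed metric formulas, AUC and aggregation."""

import json

import numpy as np
import pandas as pd
import pytest

from plaquecam import (
    ConfusionMatrix,
    aggregate_by_class,
    classification_metrics,
    confusion_matrix,
    export_outputs,
    measurements_to_frame,
)
from plaquecam.labels import ASY, SY
from plaquecam.quantify import degenerate_row
from plaquecam.report import config_hash


def test_confusion_matrix_perfect_predictions():
    y = [ASY] * 23 + [SY] * 23
    cm = confusion_matrix(y, y)
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (23, 23, 0, 0)


def test_confusion_matrix_all_predicted_sy():
    y_true = [ASY] * 5 + [SY] * 7
    cm = confusion_matrix(y_true, [SY] * 12)
    assert cm.fp == 5 and cm.fn == 0 and cm.tp == 7 and cm.tn == 0


def test_confusion_matrix_swap_transposes():
    y_true = [ASY, ASY, SY, SY, SY]
    y_pred = [SY, ASY, SY, ASY, ASY]
    cm = confusion_matrix(y_true, y_pred)
    swapped = confusion_matrix(y_pred, y_true)
    assert (swapped.fp, swapped.fn) == (cm.fn, cm.fp)
    assert (swapped.tp, swapped.tn) == (cm.tp, cm.tn)


def test_confusion_matrix_input_validation():
    with pytest.raises(ValueError, match="length mismatch"):
        confusion_matrix([ASY], [])
    with pytest.raises(ValueError, match="unknown label"):
        confusion_matrix([ASY], ["??"])


def test_metrics_match_reported_test_set_values():
    """18 ASY and 19 SY correct of 23+23 reproduce the published rates."""
    cm = ConfusionMatrix(tp=19, tn=18, fp=5, fn=4)
    m = classification_metrics(cm)
    assert round(m.accuracy, 1) == 80.4
    assert round(m.sensitivity, 1) == 82.6
    assert round(m.specificity, 1) == 78.3
    assert round(m.precision[ASY], 1) == 81.8
    assert round(m.f1[ASY], 1) == 80.0
    assert round(m.precision[SY], 1) == 79.2
    assert round(m.f1[SY], 1) == 80.9


def test_metric_identities():
    cm = ConfusionMatrix(tp=7, tn=9, fp=3, fn=2)
    m = classification_metrics(cm)
    assert m.accuracy == pytest.approx(100 * (7 + 9) / 21)
    for label in (ASY, SY):
        p = m.precision[label]
        tp, fn = (cm.tp, cm.fn) if label == SY else (cm.tn, cm.fp)
        r = 100 * tp / (tp + fn)
        assert m.f1[label] == pytest.approx(2 * p * r / (p + r), abs=1e-9)
    # swapping class roles swaps sensitivity and specificity
    swapped = classification_metrics(ConfusionMatrix(tp=cm.tn, tn=cm.tp, fp=cm.fn, fn=cm.fp))
    assert swapped.sensitivity == pytest.approx(m.specificity)
    assert swapped.specificity == pytest.approx(m.sensitivity)


def test_zero_denominators_reported_as_undefined():
    cm = ConfusionMatrix(tp=0, tn=10, fp=0, fn=0)
    m = classification_metrics(cm)
    assert m.sensitivity is None
    assert "sensitivity" in m.undefined
    assert m.precision[SY] is None


def test_auc_endpoints():
    y = [ASY] * 5 + [SY] * 5
    cm = confusion_matrix(y, y)
    separated = classification_metrics(cm, scores=np.r_[np.zeros(5), np.ones(5)], y_true=y)
    assert separated.auc == 1.0
    flat = classification_metrics(cm, scores=np.full(10, 0.5), y_true=y)
    assert flat.auc == 0.5


@pytest.mark.parametrize("seed", range(5))
def test_auc_equals_concordant_pair_count(seed):
    rng = np.random.default_rng(seed)
    n = 40
    y = [SY if v else ASY for v in rng.random(n) < 0.5]
    if SY not in y or ASY not in y:
        y[0], y[1] = SY, ASY
    scores = np.round(rng.random(n), 1)  # coarse grid forces ties
    m = classification_metrics(confusion_matrix(y, y), scores=scores, y_true=y)
    pos = [s for s, t in zip(scores, y) if t == SY]
    neg = [s for s, t in zip(scores, y) if t == ASY]
    pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
    assert m.auc == pytest.approx(np.mean(pairs), abs=1e-12)


def _measurement_row(sample_id, label, hmp_bk, degenerate=False):
    if degenerate:
        return degenerate_row(sample_id, label, label)
    row = {"sample_id": sample_id, "class": label, "predicted": label, "gtplq_heatmap": 50.0}
    shares = {"bk": hmp_bk, "bl": 100 - hmp_bk, "g": 0, "y": 0, "o": 0, "r": 0}
    for c, v in shares.items():
        row[f"{c}_to_gt"] = v
        row[f"hmp_in_{c}"] = v
        row[f"hmp_{c}"] = v
        row[f"present_{c}"] = v > 0
    row["degenerate"] = False
    return row


def test_aggregate_two_sample_mean_and_std():
    frame = measurements_to_frame(
        [_measurement_row("a", SY, 20.0), _measurement_row("b", SY, 40.0),
         _measurement_row("c", ASY, 10.0), _measurement_row("d", ASY, 10.0)]
    )
    summary = aggregate_by_class(frame)
    row = summary[(summary["class"] == SY) & (summary.measurement == "hmp_bk")].iloc[0]
    assert row["mean"] == pytest.approx(30.0)
    assert row["std"] == pytest.approx(14.14, abs=0.005)
    assert row["n_included"] == 2


def test_aggregate_single_sample_std_convention():
    frame = measurements_to_frame(
        [_measurement_row("a", SY, 20.0), _measurement_row("b", ASY, 10.0)]
    )
    summary = aggregate_by_class(frame)
    row = summary[(summary["class"] == SY) & (summary.measurement == "hmp_bk")].iloc[0]
    assert row["std"] == 0.0 and bool(row["single_sample"])


def test_aggregate_excludes_and_counts_degenerate_samples():
    frame = measurements_to_frame(
        [_measurement_row("a", SY, 20.0), _measurement_row("b", SY, 0, degenerate=True),
         _measurement_row("c", ASY, 10.0)]
    )
    summary = aggregate_by_class(frame)
    sy_rows = summary[summary["class"] == SY]
    assert (sy_rows["n_degenerate_excluded"] == 1).all()
    assert (sy_rows["n_included"] == 1).all()


def test_aggregate_all_degenerate_class_reported_empty():
    frame = measurements_to_frame(
        [_measurement_row("a", SY, 0, degenerate=True), _measurement_row("c", ASY, 10.0)]
    )
    summary = aggregate_by_class(frame)
    row = summary[(summary["class"] == SY) & (summary.measurement == "hmp_bk")].iloc[0]
    assert np.isnan(row["mean"])  # empty, not zero


def test_aggregate_hmp_of_means_sum_to_100():
    rng = np.random.default_rng(2)
    rows = []
    for i in range(8):
        label = SY if i % 2 else ASY
        rows.append(_measurement_row(f"s{i}", label, float(rng.uniform(10, 90))))
    summary = aggregate_by_class(measurements_to_frame(rows))
    for label in (ASY, SY):
        total = summary[
            (summary["class"] == label)
            & summary.measurement.str.fullmatch(r"hmp_(bk|bl|g|y|o|r)")
        ]["mean"].sum()
        assert total == pytest.approx(100.0, abs=1e-9)


def test_export_outputs_round_trip(tmp_path):
    frame = measurements_to_frame(
        [_measurement_row("a", SY, 20.0), _measurement_row("b", ASY, 10.0)]
    )
    preds = pd.DataFrame(
        [{"sample_id": "a", "class": SY, "predicted": SY, "p_sy": 0.9},
         {"sample_id": "b", "class": ASY, "predicted": ASY, "p_sy": 0.1}]
    )
    cm = confusion_matrix(preds["class"].tolist(), preds["predicted"].tolist())
    metrics = classification_metrics(cm, scores=preds["p_sy"], y_true=preds["class"].tolist())
    summary = aggregate_by_class(frame)
    written = export_outputs(None, preds, frame, summary, tmp_path, metrics=metrics,
                             config={"seed": 1})
    for key in ("metrics", "measurements", "summary", "boxplot_data", "scatter_data", "run_log"):
        assert written[key].exists()
    reloaded = json.loads(written["metrics"].read_text())
    assert reloaded["accuracy"] == 100.0
    assert not pd.read_csv(written["summary"]).empty


def test_export_with_empty_measurements_writes_metrics_only(tmp_path):
    cm = ConfusionMatrix(1, 1, 0, 0)
    metrics = classification_metrics(cm)
    written = export_outputs(None, None, measurements_to_frame([]), None, tmp_path, metrics=metrics)
    assert "measurements" not in written
    log = json.loads(written["run_log"].read_text())
    assert any("no measurements" in n for n in log["notices"])


def test_config_hash_is_stable():
    assert config_hash({"a": 1, "b": 2}) == config_hash({"b": 2, "a": 1})
    assert config_hash({"a": 1}) != config_hash({"a": 2})
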
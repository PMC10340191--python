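"""ROC/AUC against the pairwise-ranking oracle, confusion metrics against
hand counts, and the activation-heatmap contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hrcxr.backbone import build_network
from hrcxr.data import normalize_gray_batch
from hrcxr.metrics import (
    UndefinedMetricError, activation_heatmap, confusion_metrics,
    evaluate_scores, heatmap_box_mass, roc_auc,
)
from conftest import make_mini_config


def mann_whitney_auc(scores, labels):
    """O(m^2) pairwise comparison oracle; ties count one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfectly_separated_scores_give_auc_one():
    labels = np.array([0] * 5 + [1] * 5)
    _, a = roc_auc(np.arange(10, dtype=float), labels)
    assert a == 1.0


def test_constant_scores_give_auc_half():
    labels = np.array([0, 1] * 10)
    _, a = roc_auc(np.full(20, 0.3), labels)
    assert a == 0.5


def test_auc_matches_pairwise_oracle(rng):
    m = 200
    scores = np.round(rng.random(m), 2)  # duplicates force tie handling
    labels = (rng.random(m) < 0.4).astype(int)
    _, a = roc_auc(scores, labels)
    assert abs(a - mann_whitney_auc(scores, labels)) <= 1e-10


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.random(100)
    labels = (rng.random(100) < 0.5).astype(int)
    _, a1 = roc_auc(scores, labels)
    _, a2 = roc_auc(np.exp(3 * scores) + 7, labels)
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_auc_complement_symmetry(rng):
    scores = rng.random(150)
    labels = (rng.random(150) < 0.3).astype(int)
    _, a1 = roc_auc(scores, labels)
    _, a2 = roc_auc(-scores, labels)
    assert a1 + a2 == pytest.approx(1.0, abs=1e-10)


def test_sensitivity_is_tpr_and_specificity_complements_fpr(rng):
    """At every score threshold the ROC vertex (FPR, TPR) matches the
    confusion-metric definitions of (1 - specificity, sensitivity)."""
    scores = rng.random(50)
    labels = (rng.random(50) < 0.5).astype(int)
    (fpr, tpr), _ = roc_auc(scores, labels)
    for thr in np.unique(np.clip(scores, 0.01, 0.99)):
        m = confusion_metrics(scores, labels, threshold=float(thr))
        assert m["sensitivity"] == pytest.approx(
            m["tp"] / (m["tp"] + m["fn"]))
        assert 1 - m["specificity"] == pytest.approx(
            m["fp"] / (m["fp"] + m["tn"]))
        # the (FPR, TPR) pair appears on the ROC polyline vertex set
        f = m["fp"] / (m["fp"] + m["tn"])
        t = m["tp"] / (m["tp"] + m["fn"])
        assert np.any(np.isclose(fpr, f) & np.isclose(tpr, t))


def test_single_class_labels_raise_named_error():
    with pytest.raises(UndefinedMetricError, match="positive"):
        roc_auc(np.random.default_rng(0).random(10), np.ones(10, dtype=int))


def test_confusion_metrics_printed_contingency_example():
    # TP=8, FN=2, TN=5, FP=5
    scores = np.array([0.9] * 8 + [0.1] * 2 + [0.2] * 5 + [0.8] * 5)
    labels = np.array([1] * 10 + [0] * 10)
    m = confusion_metrics(scores, labels)
    assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (8, 2, 5, 5)
    assert m["sensitivity"] == pytest.approx(0.8)
    assert m["specificity"] == pytest.approx(0.5)
    assert m["accuracy"] == pytest.approx(0.65)
    assert m["f1"] == pytest.approx(16 / 23)


def test_all_correct_predictions_give_all_ones():
    scores = np.array([0.9, 0.8, 0.1, 0.2])
    labels = np.array([1, 1, 0, 0])
    m = confusion_metrics(scores, labels)
    assert m["accuracy"] == m["sensitivity"] == m["specificity"] == m["f1"] == 1.0


def test_confusion_metrics_match_counting_oracle(rng):
    scores = rng.random((30, 14))
    labels = (rng.random((30, 14)) < 0.3).astype(int)
    rep = evaluate_scores(scores, labels)
    accs = []
    for j in range(14):
        tally = dict(tp=0, fp=0, fn=0, tn=0)
        for i in range(30):
            pred = scores[i, j] >= 0.5
            if pred and labels[i, j]:
                tally["tp"] += 1
            elif pred:
                tally["fp"] += 1
            elif labels[i, j]:
                tally["fn"] += 1
            else:
                tally["tn"] += 1
        assert (rep.per_class[j]["tp"], rep.per_class[j]["fp"],
                rep.per_class[j]["fn"], rep.per_class[j]["tn"]) == (
            tally["tp"], tally["fp"], tally["fn"], tally["tn"])
        accs.append((tally["tp"] + tally["tn"]) / 30)
    assert rep.accuracy == pytest.approx(np.mean(accs))
    assert rep.mean_auc == pytest.approx(np.nanmean(rep.per_class_auc))


def test_invalid_threshold_rejected():
    with pytest.raises(ValueError, match="threshold"):
        confusion_metrics(np.array([0.5]), np.array([1]), threshold=1.5)


# -- heatmaps ---------------------------------------------------------------

def test_heatmap_shape_range_and_degenerate_constant(rng):
    cfg = make_mini_config(num_classes=3)
    net = build_network(cfg, seed=0)
    x = normalize_gray_batch(
        rng.integers(0, 255, size=(1, 64, 64)).astype(np.uint8))
    hm = activation_heatmap(net, x)
    assert hm.shape == (64, 64)
    assert hm.min() >= 0.0 and hm.max() <= 1.0
    # constant activations: min-max span is zero -> all-zero map
    span_free = np.zeros((4, 4))
    mass, area = heatmap_box_mass(span_free, [(0, 0, 2, 2)])
    assert mass == 0.0 and area == pytest.approx(0.25)


def test_heatmap_box_mass_uniform_map_equals_area_fraction():
    hm = np.ones((10, 10))
    mass, area = heatmap_box_mass(hm, [(0, 0, 5, 10)])
    assert mass == pytest.approx(area) == pytest.approx(0.5)
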
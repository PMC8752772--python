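"""Confusion tallies, the uncertain-aware metric suite, AUC and label summaries."""

from collections import Counter

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from cnvimpact.annotation import ValidationError
from cnvimpact.evaluation import (
    ConfusionTable3x2,
    build_confusion,
    metrics_from_confusion,
    probability_distribution_by_label,
    roc_auc,
    round_percent,
)

# Published reference confusion tables for a loss-type and a gain-type
# classifier at the 0.95 threshold: counts of (predicted call, true label).
LOSS_REFERENCE = ConfusionTable3x2(
    benign_benign=1062,
    benign_pathogenic=11,
    uncertain_benign=221,
    uncertain_pathogenic=116,
    pathogenic_benign=6,
    pathogenic_pathogenic=413,
)
GAIN_REFERENCE = ConfusionTable3x2(
    benign_benign=1162,
    benign_pathogenic=13,
    uncertain_benign=97,
    uncertain_pathogenic=23,
    pathogenic_benign=2,
    pathogenic_pathogenic=115,
)


class TestBuildConfusion:
    def test_perfect_predictor(self):
        calls = ["benign", "pathogenic", "benign"]
        labels = ["benign", "pathogenic", "benign"]
        ct = build_confusion(calls, labels)
        assert ct.benign_benign == 2 and ct.pathogenic_pathogenic == 1
        assert ct.total == 3
        assert (
            ct.benign_pathogenic
            == ct.pathogenic_benign
            == ct.uncertain_benign
            == ct.uncertain_pathogenic
            == 0
        )

    def test_all_uncertain(self):
        ct = build_confusion(["uncertain"] * 4, [0, 1, 0, 1])
        assert ct.uncertain_benign == 2 and ct.uncertain_pathogenic == 2
        assert ct.total == 4

    def test_random_set_matches_hand_tally(self):
        rng = np.random.default_rng(0)
        calls = rng.choice(["benign", "uncertain", "pathogenic"], size=200)
        labels = rng.choice(["benign", "pathogenic"], size=200)
        ct = build_confusion(list(calls), list(labels))
        tally = Counter(zip(calls, labels))
        assert ct.benign_benign == tally[("benign", "benign")]
        assert ct.uncertain_pathogenic == tally[("uncertain", "pathogenic")]
        assert ct.pathogenic_benign == tally[("pathogenic", "benign")]
        assert ct.total == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            build_confusion(["benign"], [0, 1])


class TestMetricsFromConfusion:
    def test_loss_reference_metrics(self):
        m = metrics_from_confusion(LOSS_REFERENCE)
        assert round_percent(m.sensitivity) == 97.41
        assert round_percent(m.specificity) == 99.44
        assert round_percent(m.accuracy) == 98.86
        assert round(m.mcc, 4) == 0.9719
        assert round_percent(m.discovery_benign) == 82.39
        assert round_percent(m.discovery_pathogenic) == 76.48
        assert round_percent(m.precision_benign) == 98.97
        assert round_percent(m.precision_pathogenic) == 98.57
        assert round_percent(m.uncertain_fraction) == 18.43

    def test_gain_reference_metrics(self):
        m = metrics_from_confusion(GAIN_REFERENCE)
        assert round_percent(m.accuracy) == 98.84
        assert round_percent(m.sensitivity) == 89.84
        assert round_percent(m.specificity) == 99.83
        assert round(m.mcc, 4) == 0.9335
        assert round_percent(m.discovery_benign) == 92.15
        assert round_percent(m.discovery_pathogenic) == 76.16
        assert round_percent(m.precision_benign) == 98.89
        assert round_percent(m.precision_pathogenic) == 98.29
        assert round_percent(m.uncertain_fraction) == 8.50

    def test_mcc_agrees_with_sklearn_on_committed_calls(self):
        ct = LOSS_REFERENCE
        y_true = [0] * ct.benign_benign + [1] * ct.benign_pathogenic
        y_pred = [0] * (ct.benign_benign + ct.benign_pathogenic)
        y_true += [0] * ct.pathogenic_benign + [1] * ct.pathogenic_pathogenic
        y_pred += [1] * (ct.pathogenic_benign + ct.pathogenic_pathogenic)
        m = metrics_from_confusion(ct)
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_diagonal_table_is_perfect(self):
        ct = ConfusionTable3x2(10, 0, 0, 0, 0, 7)
        m = metrics_from_confusion(ct)
        assert m.accuracy == m.sensitivity == m.specificity == 1.0
        assert m.mcc == 1.0
        assert m.uncertain_fraction == 0.0
        assert m.included_fraction == 1.0

    def test_zero_denominators_reported_as_none(self):
        ct = ConfusionTable3x2(0, 0, 5, 5, 0, 0)  # everything uncertain
        m = metrics_from_confusion(ct)
        assert m.accuracy is None and m.mcc is None
        assert "accuracy" in m.undefined_metrics()
        assert m.uncertain_fraction == 1.0

    def test_included_plus_uncertain_is_one(self):
        for ct in (LOSS_REFERENCE, GAIN_REFERENCE):
            m = metrics_from_confusion(ct)
            assert m.included_fraction + m.uncertain_fraction == pytest.approx(1.0)

    def test_merging_tables_equals_pooling_calls(self):
        rng = np.random.default_rng(3)
        calls = rng.choice(["benign", "uncertain", "pathogenic"], size=300)
        labels = rng.choice(["benign", "pathogenic"], size=300)
        ct_a = build_confusion(list(calls[:120]), list(labels[:120]))
        ct_b = build_confusion(list(calls[120:]), list(labels[120:]))
        pooled = build_confusion(list(calls), list(labels))
        merged = ct_a + ct_b
        assert merged == pooled
        assert (
            metrics_from_confusion(merged).as_dict()
            == metrics_from_confusion(pooled).as_dict()
        )


def auc_all_pairs(probs, labels):
    """Exhaustive Mann-Whitney oracle: P(score_pos > score_neg) + 0.5 ties."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_independent_labels_near_half(self):
        rng = np.random.default_rng(5)
        p = rng.random(10_000)
        y = rng.integers(0, 2, size=10_000)
        assert roc_auc(p, y) == pytest.approx(0.5, abs=0.02)

    def test_hand_ranked_toy_set_matches_all_pairs(self):
        probs = [0.1, 0.4, 0.35, 0.8, 0.65, 0.35]
        labels = [0, 0, 1, 1, 1, 0]
        assert roc_auc(probs, labels) == pytest.approx(
            auc_all_pairs(probs, labels), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        p = rng.random(500)
        y = rng.integers(0, 2, size=500)
        assert roc_auc(p, y) == pytest.approx(roc_auc(p**3, y), abs=1e-12)
        assert roc_auc(p, y) == pytest.approx(
            roc_auc(np.log(p + 1e-9), y), abs=1e-12
        )

    def test_single_class_undefined(self):
        assert roc_auc([0.2, 0.8], [1, 1]) is None

    def test_included_only_mode_drops_abstentions(self):
        probs = [0.02, 0.97, 0.5, 0.6]
        labels = [0, 1, 1, 0]
        full = roc_auc(probs, labels, included_only=False)
        included = roc_auc(probs, labels, included_only=True, p_ct=0.95)
        assert included == 1.0
        assert full < 1.0


class TestProbabilityDistributionByLabel:
    def test_certain_pathogenic_group(self):
        out = probability_distribution_by_label([1.0, 1.0], ["pathogenic"] * 2)
        row = out.iloc[0]
        assert row["label"] == "pathogenic"
        assert row["frac_called_pathogenic"] == 1.0
        assert row["frac_called_benign"] == 0.0

    def test_absent_label_groups_omitted(self):
        out = probability_distribution_by_label([0.5], ["uncertain"])
        assert list(out["label"]) == ["uncertain"]

    def test_quantiles_match_direct_computation(self):
        rng = np.random.default_rng(9)
        # bimodal uncertain group
        p = np.concatenate([rng.beta(1, 10, 100), rng.beta(10, 1, 100)])
        out = probability_distribution_by_label(p, ["uncertain"] * 200)
        row = out.iloc[0]
        assert row["median"] == pytest.approx(np.quantile(p, 0.5))
        assert row["q25"] == pytest.approx(np.quantile(p, 0.25))
        assert row["n"] == 200
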
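import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polysides as ps
from polysides.metrics import UndefinedMetricError


# -- independent oracles ----------------------------------------------------


def auroc_pair_counting(scores, labels):
    """O(n^2) Mann-Whitney oracle: P(random positive outscores random
    negative), ties half credit."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def auprc_step_oracle(scores, labels):
    """Sum precision at each recall increment down the ranked list."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    n_pos = y.sum()
    area, tp = 0.0, 0
    for k, yk in enumerate(y, start=1):
        if yk:
            tp += 1
            area += (tp / k) * (1 / n_pos)
    return area

def ap_at_k_oracle(scores, labels, k=50):
    """Direct evaluation: AP(k') = TP-in-top-k' / k', averaged for k'=1..k."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    k = min(k, len(y))
    return float(np.mean([y[:kk].sum() / kk for kk in range(1, k + 1)]))


# -- auroc ------------------------------------------------------------------


class TestAuroc:
    def test_hand_example(self):
        sl = ps.ScoredLabels([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0])
        assert ps.auroc(sl) == pytest.approx(0.75)
        assert auroc_pair_counting([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_perfect_and_reversed(self):
        sl = ps.ScoredLabels([3, 2, 1, 0], [1, 1, 0, 0])
        assert ps.auroc(sl) == 1.0
        rev = ps.ScoredLabels([-3, -2, -1, 0], [1, 1, 0, 0])
        assert ps.auroc(rev) == 0.0

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            ps.auroc(ps.ScoredLabels([0.1, 0.2], [1, 1]))

    def test_agrees_with_pair_counting_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert ps.auroc(ps.ScoredLabels(scores, labels)) == pytest.approx(
                auroc_pair_counting(scores, labels), abs=1e-12
            )

    def test_sign_reversal_maps_to_complement(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        a = ps.auroc(ps.ScoredLabels(scores, labels))
        b = ps.auroc(ps.ScoredLabels(-scores, labels))
        assert a + b == pytest.approx(1.0)


class TestAuprc:
    def test_hand_stepped_curve(self):
        # single positive ranked last of four -> precision 1/4 at recall 1
        sl = ps.ScoredLabels([0.9, 0.8, 0.7, 0.1], [0, 0, 0, 1])
        assert ps.auprc(sl) == pytest.approx(0.25)

    def test_perfect_ranking(self):
        assert ps.auprc(ps.ScoredLabels([3, 2, 1], [1, 1, 0])) == 1.0

    def test_random_scores_approach_prevalence(self, rng):
        n, prevalence = 20000, 0.2
        labels = (rng.random(n) < prevalence).astype(int)
        scores = rng.normal(size=n)
        assert ps.auprc(ps.ScoredLabels(scores, labels)) == pytest.approx(
            prevalence, abs=0.02
        )

    def test_no_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            ps.auprc(ps.ScoredLabels([0.4, 0.6], [0, 0]))

    def test_agrees_with_step_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            scores = rng.normal(size=n)  # distinct scores: step curve is exact
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                continue
            assert ps.auprc(ps.ScoredLabels(scores, labels)) == pytest.approx(
                auprc_step_oracle(scores, labels), abs=1e-12
            )


class TestApAt50:
    def test_relevance_sequence_example(self):
        # ranked relevance [1, 0, 1]: (1/1 + 1/2 + 2/3) / 3
        sl = ps.ScoredLabels([0.9, 0.5, 0.3], [1, 0, 1])
        assert ps.ap_at_50(sl) == pytest.approx((1 + 0.5 + 2 / 3) / 3)

    def test_top50_all_positive_and_all_negative(self, rng):
        scores = np.arange(100.0)[::-1]
        labels = np.zeros(100, int)
        labels[:50] = 1  # the 50 highest-scored items are positive
        assert ps.ap_at_50(ps.ScoredLabels(scores, labels)) == 1.0
        assert ps.ap_at_50(ps.ScoredLabels(scores, 1 - labels)) == 0.0

    def test_truncates_to_n(self):
        sl = ps.ScoredLabels([0.9, 0.1], [1, 0])
        assert ps.ap_at_50(sl) == pytest.approx((1 + 0.5) / 2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ps.ap_at_50(ps.ScoredLabels([], []))

    def test_agrees_with_direct_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 120))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            assert ps.ap_at_50(ps.ScoredLabels(scores, labels)) == pytest.approx(
                ap_at_k_oracle(scores, labels), abs=1e-12
            )


class TestMonotoneInvariance:
    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_all_metrics_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            return
        transformed = np.exp(3 * scores) + 1  # strictly increasing
        for metric in (ps.auroc, ps.auprc, ps.ap_at_50):
            a = metric(ps.ScoredLabels(scores, labels))
            b = metric(ps.ScoredLabels(transformed, labels))
            assert a == pytest.approx(b, abs=1e-12)


class TestReports:
    def test_macro_is_group_average(self):
        g1 = ps.ScoredLabels([3, 2, 1, 0], [1, 1, 0, 0], group="se1")  # AUROC 1.0
        g2 = ps.ScoredLabels([3, 2, 1, 0], [1, 0, 1, 0], group="se2")  # AUROC 0.75
        report = ps.per_side_effect_report([g1, g2])
        assert report.macro["auroc"] == pytest.approx((1.0 + 0.75) / 2)

    def test_single_group_micro_equals_macro(self):
        g = ps.ScoredLabels([0.8, 0.6, 0.4, 0.1], [1, 0, 1, 0], group="se")
        report = ps.per_side_effect_report([g])
        assert report.micro["auroc"] == pytest.approx(report.macro["auroc"])

    def test_single_class_group_excluded_and_listed(self):
        good = ps.ScoredLabels([1, 0], [1, 0], group="ok")
        bad = ps.ScoredLabels([1, 0], [1, 1], group="onlypos")
        report = ps.per_side_effect_report([good, bad])
        assert report.excluded_groups == ["onlypos"]
        assert list(report.per_group["group"]) == ["ok"]

    def test_per_group_matches_bruteforce(self, rng):
        groups = []
        for gid in range(3):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, size=40)
            labels[0], labels[1] = 0, 1  # both classes guaranteed
            groups.append(ps.ScoredLabels(scores, labels, group=f"g{gid}"))
        report = ps.per_side_effect_report(groups)
        for _, row in report.per_group.iterrows():
            g = next(x for x in groups if x.group == row["group"])
            assert row["auroc"] == pytest.approx(
                auroc_pair_counting(g.scores, g.labels), abs=1e-12
            )
            assert row["ap50"] == pytest.approx(ap_at_k_oracle(g.scores, g.labels))

    def test_best_worst_ordering(self, rng):
        groups = [
            ps.ScoredLabels(rng.normal(size=30), rng.integers(0, 2, size=30), group=f"g{i}")
            for i in range(6)
        ]
        report = ps.per_side_effect_report(groups)
        best, worst = report.best_worst(n=2)
        assert (best["auprc"].values >= worst["auprc"].values).all()

    def test_markdown_render(self):
        g = ps.ScoredLabels([1, 0], [1, 0], group="se")
        md = ps.per_side_effect_report([g]).to_markdown()
        assert "| auroc |" in md


class TestAggregateRuns:
    def test_mean_and_sample_std(self):
        out = ps.aggregate_runs([{"auroc": 0.9}, {"auroc": 1.0}])
        assert out["auroc"][0] == pytest.approx(0.95)
        assert out["auroc"][1] == pytest.approx(np.std([0.9, 1.0], ddof=1))

    def test_identical_reports_zero_std(self):
        out = ps.aggregate_runs([{"ap50": 0.5}] * 5)
        assert out["ap50"] == (0.5, 0.0)

    def test_ten_fold_hand_check(self, rng):
        vals = rng.random(10)
        out = ps.aggregate_runs([{"m": v} for v in vals])
        assert out["m"][0] == pytest.approx(vals.mean())
        assert out["m"][1] == pytest.approx(vals.std(ddof=1))
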
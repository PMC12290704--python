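"""Accuracy metrics, AUC and rank-sum statistics against brute-force
oracles; heatmap aggregation invariants."""

import itertools

import numpy as np
import pytest

from atrophynet import (
    AttentionMaps,
    DisplacementField,
    EvalRecord,
    ImageGrid,
    aggregate_heatmap,
    auc,
    group_difference,
    risi_accuracy,
    sto_accuracy,
)

from conftest import make_ball_mask


def make_records(a_pooled, intervals, subject="s"):
    return [
        EvalRecord(subject, 0, 1, a, dt) for a, dt in zip(a_pooled, intervals)
    ]


class TestSTOAccuracy:
    def test_all_correct(self):
        records = make_records([-1.0, -2.0, 3.0], [1.0, 2.0, -1.0])
        assert sto_accuracy(records)["overall"] == 1.0

    def test_random_signs_sit_at_chance(self):
        rng = np.random.default_rng(0)
        records = make_records(rng.choice([-1.0, 1.0], 1000), np.ones(1000))
        assert sto_accuracy(records)["overall"] == pytest.approx(0.5, abs=0.05)

    def test_zero_change_counts_as_incorrect(self):
        assert sto_accuracy(make_records([0.0], [1.0]))["overall"] == 0.0

    def test_missing_group_reported_as_none(self):
        records = make_records([-1.0], [1.0], subject="a")
        out = sto_accuracy(records, groups={"a": "g1", "b": "g2"})
        assert out["g1"] == 1.0 and out["g2"] is None

    def test_invariant_under_subject_relabeling(self):
        rng = np.random.default_rng(1)
        pooled = rng.normal(size=200)
        r1 = make_records(pooled, np.ones(200), subject="x")
        r2 = make_records(pooled, np.ones(200), subject="y")
        assert sto_accuracy(r1)["overall"] == sto_accuracy(r2)["overall"]


class TestRISIAccuracy:
    def test_proportional_magnitudes_are_perfect(self):
        pairs = [(-1.0 * r, -3.0 * r) for r in (0.5, 1.0, 2.0)]
        assert risi_accuracy(pairs) == 1.0

    def test_permuted_magnitudes_sit_at_chance(self):
        rng = np.random.default_rng(2)
        mags = rng.uniform(0.1, 1.0, 2000)
        pairs = list(zip(mags[:1000], mags[1000:]))
        assert risi_accuracy(pairs) == pytest.approx(0.5, abs=0.05)

    def test_ties_count_as_failures(self):
        assert risi_accuracy([(-1.0, -1.0)]) == 0.0


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc([5.0] * 10, [0] * 5 + [1] * 5) == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=2000)
        labels = np.r_[np.zeros(1000), np.ones(1000)]
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_matches_brute_force_concordance(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        scores[::3] = np.round(scores[::3], 1)  # induce some ties
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        concordant = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg
        )
        assert auc(scores, labels) == pytest.approx(concordant / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])


def wilcoxon_exact_oracle(comp, ref):
    """Exact one-sided rank-sum p-value by enumerating all label
    assignments of the pooled sample (alternative: comp < ref)."""
    pooled = np.concatenate([comp, ref])
    n1 = len(comp)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    observed = ranks[:n1].sum()
    count = total = 0
    for subset in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if ranks[list(subset)].sum() <= observed:
            count += 1
    return count / total


class TestGroupDifference:
    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(3):
            comp = rng.normal(-0.03, 0.01, 5)
            ref = rng.normal(-0.02, 0.01, 6)
            rates = np.concatenate([ref, comp])
            labels = np.array(["ref"] * 6 + ["comp"] * 5)
            res = group_difference(rates, labels, "ref")
            assert res["comp"]["p"] == pytest.approx(
                wilcoxon_exact_oracle(comp, ref), abs=1e-10
            )

    def test_identical_groups_give_half(self):
        vals = np.linspace(-0.03, -0.01, 30)
        rates = np.concatenate([vals, vals])
        labels = np.array(["ref"] * 30 + ["comp"] * 30)
        res = group_difference(rates, labels, "ref")
        assert res["comp"]["p"] == pytest.approx(0.5, abs=0.01)
        assert res["comp"]["auc"] == pytest.approx(0.5, abs=1e-9)

    def test_strong_contrast_is_detected(self):
        rng = np.random.default_rng(6)
        ref = rng.normal(-0.01, 0.01, 30)
        comp = rng.normal(-0.04, 0.01, 30)
        rates = np.concatenate([ref, comp])
        labels = np.array(["ref"] * 30 + ["comp"] * 30)
        res = group_difference(rates, labels, "ref")
        assert res["comp"]["p"] < 0.001
        assert res["comp"]["auc"] >= 0.9

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            group_difference(np.zeros(3), np.array(["a"] * 3), "ref")


@pytest.fixture(scope="module")
def grid():
    return ImageGrid((20, 20, 20))


class TestHeatmap:
    def make_attention(self, grid, center=(10, 10, 10)):
        shrink = make_ball_mask(grid, center, 4)
        expand = make_ball_mask(grid, (4, 4, 4), 2)
        return AttentionMaps.from_masks(grid, shrink, expand)

    def test_single_pair_identity_warp_reproduces_the_mask(self, grid):
        att = self.make_attention(grid)
        hm = aggregate_heatmap([(att, DisplacementField.zero(grid))], grid)
        assert np.allclose(hm.shrink_freq, att.shrink, atol=1e-9)
        assert np.allclose(hm.expand_freq, att.expand, atol=1e-9)

    def test_repetition_does_not_change_frequencies(self, grid):
        att = self.make_attention(grid)
        items = [(att, DisplacementField.zero(grid))]
        one = aggregate_heatmap(items, grid)
        five = aggregate_heatmap(items * 5, grid)
        assert np.allclose(one.shrink_freq, five.shrink_freq)

    def test_frequencies_bounded_even_with_partial_coverage(self, grid):
        att = self.make_attention(grid)
        shift = np.full((*grid.shape, 3), 6.0)  # pushes part of the map outside
        warp = DisplacementField(grid, shift)
        hm = aggregate_heatmap(
            [(att, warp), (att, DisplacementField.zero(grid))], grid
        )
        assert hm.shrink_freq.max() <= 1.0 + 1e-9
        assert hm.shrink_freq.min() >= 0.0
        assert np.all(hm.shrink_freq[hm.coverage <= 1e-9] == 0)

    def test_missing_warp_skipped_with_warning(self, grid):
        att = self.make_attention(grid)
        with pytest.warns(UserWarning, match="skipped"):
            hm = aggregate_heatmap(
                [(att, None), (att, DisplacementField.zero(grid))], grid
            )
        assert np.allclose(hm.shrink_freq, att.shrink, atol=1e-9)
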
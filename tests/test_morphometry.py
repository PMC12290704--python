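"""Pair-change measures and annualised-rate estimation on ground truth."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from atrophynet import (
    AttentionMaps,
    DisplacementField,
    PairChange,
    PhantomSpec,
    age_adjust,
    annualized_rate,
    generate_cohort,
    pair_change,
)


@pytest.fixture(scope="module")
def two_year_cohort():
    spec = PhantomSpec(
        rate_range=(0.05, 0.05), n_timepoints=(2, 2), interval_range=(2.0, 2.0)
    )
    return generate_cohort(spec, 1, seed=1)


def truth_attention(cohort, j, i):
    shrink, expand = cohort.truth_masks(j, i)
    return AttentionMaps.from_masks(cohort.grid, shrink, expand)


class TestPairChange:
    def test_zero_field_gives_exact_zero(self, two_year_cohort):
        att = truth_attention(two_year_cohort, 0, 0)
        pc = pair_change(att, DisplacementField.zero(two_year_cohort.grid), 1.0)
        assert pc.a_shr == 0.0 and pc.a_exp == 0.0 and pc.a_pooled == 0.0

    def test_truth_masks_recover_fractional_loss(self, two_year_cohort):
        """5 %/yr over 2 years: shrink-region change is -10% of its volume."""
        att = truth_attention(two_year_cohort, 0, 0)
        field = two_year_cohort.truth_field(0, 0, 1)
        pc = pair_change(att, field, 2.0)
        v_shr_fixed = att.shrink.sum() * two_year_cohort.grid.voxel_volume
        assert pc.a_shr / v_shr_fixed == pytest.approx(-0.10, abs=0.02)
        assert pc.a_exp > 0 and pc.a_pooled < 0

    def test_reverse_registration_flips_the_sign(self, two_year_cohort):
        att = truth_attention(two_year_cohort, 0, 1)
        field = two_year_cohort.truth_field(0, 1, 0)
        pc = pair_change(att, field, -2.0)
        assert pc.a_shr > 0 and pc.a_pooled > 0

    def test_forward_reverse_antisymmetry(self, two_year_cohort):
        """With attention held fixed, reversing the registration direction
        negates the pooled change up to discretisation (5%)."""
        att = truth_attention(two_year_cohort, 0, 0)
        fwd = pair_change(att, two_year_cohort.truth_field(0, 0, 1), 2.0)
        rev = pair_change(att, two_year_cohort.truth_field(0, 1, 0), -2.0)
        assert fwd.a_pooled == pytest.approx(-rev.a_pooled, rel=0.05)

    def test_pooled_consistency_enforced(self):
        with pytest.raises(ValueError, match="a_pooled"):
            PairChange(a_shr=-1.0, a_exp=1.0, a_pooled=0.0, v_base=10.0, interval=1.0)


class TestAnnualizedRate:
    def test_single_pair_arithmetic(self):
        c = PairChange(a_shr=-15.0, a_exp=5.0, a_pooled=-20.0, v_base=1000.0,
                       interval=2.0)
        assert annualized_rate([c]) == pytest.approx(-0.01)

    def test_exact_line_through_origin(self):
        changes = [
            PairChange(a_shr=-10.0 * t, a_exp=0.0, a_pooled=-10.0 * t,
                       v_base=1000.0, interval=t, fixed_id=0)
            for t in (1.0, 2.0, 3.0)
        ]
        assert annualized_rate(changes) == pytest.approx(-0.01)

    def test_mixed_anchoring_rejected(self):
        changes = [
            PairChange(a_shr=-1.0, a_exp=0.0, a_pooled=-1.0, v_base=100.0,
                       interval=1.0, fixed_id=0),
            PairChange(a_shr=-1.0, a_exp=0.0, a_pooled=-1.0, v_base=100.0,
                       interval=1.0, fixed_id=1),
        ]
        with pytest.raises(ValueError, match="anchored"):
            annualized_rate(changes)

    def test_empty_and_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            annualized_rate([])
        bad = PairChange(a_shr=0.0, a_exp=0.0, a_pooled=0.0, v_base=1.0, interval=0.0)
        with pytest.raises(ValueError):
            annualized_rate([bad])

    def test_truth_mask_rates_track_simulated_rates(self):
        """Ground-truth attention recovers the simulated per-subject rates
        almost perfectly across a cohort (Spearman >= 0.95)."""
        cohort = generate_cohort(PhantomSpec(), 30, seed=11)
        est, true = [], []
        for j, s in enumerate(cohort.subjects):
            att = truth_attention(cohort, j, 0)
            changes = [
                pair_change(att, cohort.truth_field(j, 0, i), s.times[i], fixed_id=0)
                for i in range(1, len(s.times))
            ]
            est.append(annualized_rate(changes))
            true.append(s.rate)
        rho, _ = spearmanr(-np.asarray(est), true)
        assert rho >= 0.95


class TestAgeAdjust:
    def test_pure_age_effect_is_removed(self):
        ages = np.linspace(60, 90, 20)
        rates = 0.001 * ages
        adjusted = age_adjust(rates, ages, np.ones(20, dtype=bool))
        assert np.allclose(adjusted, 0.0, atol=1e-10)

    def test_age_independent_rates_are_mean_centred(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(60, 90, 30)
        rates = np.full(30, -0.02)
        adjusted = age_adjust(rates, ages, np.ones(30, dtype=bool))
        assert np.allclose(adjusted, rates - rates.mean(), atol=1e-9)

    def test_recovers_known_age_slope(self):
        rng = np.random.default_rng(1)
        n = 50
        ages = rng.uniform(60, 90, n)
        slope = 0.002
        rates = slope * ages + rng.normal(0, 0.001, n)
        fitted_slope, _ = np.polyfit(ages, rates - age_adjust(rates, ages,
                                                              np.ones(n, bool)), 1)
        assert fitted_slope == pytest.approx(slope, abs=0.0005)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            age_adjust(np.zeros(5), np.zeros(5) + 70.0, np.ones(5, bool))
        with pytest.raises(ValueError):
            age_adjust(np.zeros(5), np.linspace(60, 80, 5), np.array([0, 1]))
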
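"""Temporal-order and relative-interval losses against closed forms and a
brute-force ratio-binning oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atrophynet import (
    LossWeights,
    RISIBins,
    ratio_bin,
    risi_category_probs,
    risi_loss,
    sto_loss,
    total_loss,
)

finite_changes = st.floats(-0.5, 0.5, allow_nan=False, allow_infinity=False)


def brute_force_bin(a1: float, a2: float, bins: RISIBins) -> int:
    """Hard binning of |a1|/|a2| — the alpha -> infinity reference."""
    ratio = abs(a1) / abs(a2)
    return int(np.searchsorted(np.asarray(bins.boundaries), ratio, side="left"))


class TestSTOLoss:
    def test_uninformative_changes_give_two_ln_two(self):
        for y in (-1, 1):
            assert sto_loss(0.0, 0.0, y) == pytest.approx(2 * np.log(2), abs=1e-15)

    def test_correctly_signed_large_changes_drive_loss_to_zero(self):
        assert sto_loss(-1.0, 1.0, +1) < 1e-10
        assert sto_loss(1.0, -1.0, -1) < 1e-10

    def test_wrongly_signed_changes_are_punished(self):
        assert sto_loss(1.0, -1.0, +1) > 10

    @given(a_shr=finite_changes, a_exp=finite_changes, y=st.sampled_from([-1, 1]))
    @settings(max_examples=100, deadline=None)
    def test_sign_flip_symmetry(self, a_shr, a_exp, y):
        assert sto_loss(a_shr, a_exp, y) == pytest.approx(
            sto_loss(-a_shr, -a_exp, -y), abs=1e-10
        )

    def test_monotone_in_the_favoured_direction(self):
        grid = np.linspace(-0.2, 0.2, 21)
        losses = [sto_loss(a, 0.0, +1) for a in grid]
        assert all(a < b for a, b in zip(losses, losses[1:]))
        losses = [sto_loss(0.0, a, +1) for a in grid]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            sto_loss(0.0, 0.0, 0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a_shr, a_exp = rng.uniform(-0.2, 0.2, 2)
            y = int(rng.choice([-1, 1]))
            _, d_shr, d_exp = sto_loss(a_shr, a_exp, y, alpha=10.0, grad=True)
            eps = 1e-6
            num_shr = (
                sto_loss(a_shr + eps, a_exp, y, 10.0) - sto_loss(a_shr - eps, a_exp, y, 10.0)
            ) / (2 * eps)
            num_exp = (
                sto_loss(a_shr, a_exp + eps, y, 10.0) - sto_loss(a_shr, a_exp - eps, y, 10.0)
            ) / (2 * eps)
            assert d_shr == pytest.approx(num_shr, rel=1e-5, abs=1e-8)
            assert d_exp == pytest.approx(num_exp, rel=1e-5, abs=1e-8)


class TestRISICategoryProbs:
    def test_clear_quarter_ratio_lands_in_first_bin(self):
        probs = risi_category_probs(1.0, 4.0, RISIBins(alpha=50.0))
        assert probs[0] > 0.99

    def test_origin_gives_direct_formula_value(self):
        # every sigmoid is 1/2, each raw cone product 1/4 -> uniform
        probs = risi_category_probs(0.0, 0.0)
        assert np.allclose(probs, 0.25, atol=1e-12)

    def test_probabilities_form_a_simplex(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a1, a2 = rng.uniform(-1, 1, 2)
            probs = risi_category_probs(a1, a2)
            assert abs(probs.sum() - 1.0) < 1e-6
            assert np.all(probs >= 0) and np.all(probs <= 1)

    @given(a1=finite_changes, a2=finite_changes)
    @settings(max_examples=100, deadline=None)
    def test_simultaneous_sign_flip_invariance(self, a1, a2):
        assert np.allclose(
            risi_category_probs(a1, a2), risi_category_probs(-a1, -a2), atol=1e-12
        )

    def test_hard_limit_matches_brute_force_binning(self):
        """At alpha = 50 the argmax reproduces exact ratio binning for
        points bounded 10% away from the bin edges."""
        bins = RISIBins(alpha=50.0)
        rng = np.random.default_rng(2)
        n, agree = 1000, 0
        count = 0
        while count < n:
            a2 = rng.uniform(0.2, 1.0) * rng.choice([-1, 1])
            log_ratio = rng.uniform(np.log(0.05), np.log(8.0))
            ratio = float(np.exp(log_ratio))
            if any(abs(ratio / b - 1) < 0.10 for b in bins.boundaries):
                continue
            a1 = ratio * abs(a2) * rng.choice([-1, 1])
            count += 1
            probs = risi_category_probs(a1, a2, bins)
            if int(np.argmax(probs)) == brute_force_bin(a1, a2, bins):
                agree += 1
        assert agree / n >= 0.99

    def test_gradient_matches_finite_differences(self):
        bins = RISIBins(alpha=5.0)
        rng = np.random.default_rng(3)
        for _ in range(20):
            a1, a2 = rng.uniform(-0.5, 0.5, 2)
            probs, d1, d2 = risi_category_probs(a1, a2, bins, grad=True)
            eps = 1e-6
            num1 = (
                risi_category_probs(a1 + eps, a2, bins)
                - risi_category_probs(a1 - eps, a2, bins)
            ) / (2 * eps)
            num2 = (
                risi_category_probs(a1, a2 + eps, bins)
                - risi_category_probs(a1, a2 - eps, bins)
            ) / (2 * eps)
            assert np.allclose(d1, num1, atol=1e-4)
            assert np.allclose(d2, num2, atol=1e-4)


class TestRISILoss:
    def test_proportional_changes_give_small_loss(self):
        bins = RISIBins(alpha=200.0)
        a2 = 0.4
        a1 = 0.25 * a2
        loss = risi_loss(-a1, -a2, a1, a2, true_ratio=0.25, bins=bins)
        assert loss < 0.02

    def test_wrong_bin_gives_large_loss(self):
        bins = RISIBins(alpha=200.0)
        # changes imply ratio 3, truth says 0.25
        loss = risi_loss(-0.3, -0.1, 0.3, 0.1, true_ratio=0.25, bins=bins)
        assert loss > 3

    def test_boundary_ratio_goes_to_lower_bin(self):
        assert ratio_bin(1.0) == 1
        assert ratio_bin(0.5) == 0
        assert ratio_bin(2.0) == 2
        loss = risi_loss(-0.1, -0.1, 0.1, 0.1, true_ratio=1.0)
        assert np.isfinite(loss)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            ratio_bin(0.0)
        with pytest.raises(ValueError, match="ratio"):
            ratio_bin(float("inf"))


class TestTotalLoss:
    def test_weight_reductions_and_arithmetic(self):
        assert total_loss(0.3, 0.4, 0.9, LossWeights(1, 0)) == pytest.approx(0.7)
        assert total_loss(0.3, 0.4, 0.9, LossWeights(0, 1)) == pytest.approx(0.9)
        # per-branch STO terms are already summed upstream: 0.5 + 0.5 + 0.5
        assert total_loss(0.5, 0.5, 0.5, LossWeights(1, 1)) == pytest.approx(1.5)

    def test_non_finite_loss_rejected(self):
        with pytest.raises(FloatingPointError):
            total_loss(float("inf"), 0.0, 0.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-1.0, 0.0)
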
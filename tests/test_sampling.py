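"""Nested pair-of-pairs enumeration, QC filtering and augmentation."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from atrophynet import (
    AugmentConfig,
    ConfoundConfig,
    augment,
    enumerate_quadruples,
    generate_cohort,
    qc_filter,
    region_volumes,
)
from atrophynet.phantom import _random_smooth_field
from atrophynet.sampling import _rotation_matrix, rotate_field, rotate_volume_values
from atrophynet.training import cohort_pairs

from conftest import make_ball_mask


def brute_force_quadruples(times):
    """Literal application of the two constraints to all ordered 4-tuples:
    the unordered intervals nest, share at most one endpoint, and the
    first pair's interval is strictly the shorter one."""
    n = len(times)
    out = set()
    for i1, i2, i3, i4 in itertools.product(range(n), repeat=4):
        if i1 == i2 or i3 == i4:
            continue
        if times[i1] == times[i2] or times[i3] == times[i4]:
            continue
        lo_a, hi_a = sorted((times[i1], times[i2]))
        lo_b, hi_b = sorted((times[i3], times[i4]))
        if not (hi_a - lo_a < hi_b - lo_b):
            continue
        if not (lo_b <= lo_a and hi_a <= hi_b):
            continue
        if int(lo_a == lo_b) + int(hi_a == hi_b) > 1:
            continue
        out.add((i1, i2, i3, i4))
    return out


class TestEnumerateQuadruples:
    def test_two_timepoints_give_nothing(self):
        assert enumerate_quadruples([0.0, 1.0]) == []

    def test_three_equispaced_timepoints(self):
        """With times {0,1,2} only (0,1) and (1,2) nest inside (0,2);
        (0,1) vs (1,2) has no nesting and is excluded."""
        quads = enumerate_quadruples([0.0, 1.0, 2.0])
        unordered = {(min(q[0], q[1]), max(q[0], q[1]),
                      min(q[2], q[3]), max(q[2], q[3])) for q in quads}
        assert unordered == {(0, 1, 0, 2), (1, 2, 0, 2)}
        assert len(quads) == 8  # 4 temporal orientations each

    @pytest.mark.parametrize("n_times", [2, 3, 4, 5, 6])
    def test_matches_brute_force_for_small_subjects(self, n_times):
        rng = np.random.default_rng(n_times)
        for _ in range(5):
            times = sorted(rng.uniform(0, 6, n_times).tolist())
            assert set(enumerate_quadruples(times)) == brute_force_quadruples(times)

    def test_duplicate_timepoints_share_at_most_one_endpoint(self):
        # a shared endpoint is allowed once, never twice
        times = [0.0, 1.0, 3.0]
        quads = brute_force_quadruples(times)
        assert (0, 1, 0, 2) in quads  # shares t=0 only
        assert set(enumerate_quadruples(times)) == quads


@pytest.fixture(scope="module")
def small_pairs(small_spec):
    cohort = generate_cohort(small_spec, 3, seed=0)
    return cohort_pairs(cohort, forward_only=True)


@pytest.fixture(scope="module")
def pair(small_spec):
    cohort = generate_cohort(small_spec, 1, seed=2)
    return cohort_pairs(cohort, forward_only=True)[0]


class TestQCFilter:
    def test_zero_threshold_removes_nothing(self, small_pairs):
        kept, log = qc_filter(small_pairs, threshold=0.0)
        assert len(kept) == len(small_pairs)
        assert not log.rejected.any()

    def test_clean_cohort_fully_passes_default_threshold(self, small_pairs):
        kept, log = qc_filter(small_pairs)
        assert len(kept) == len(small_pairs), log

    def test_severe_artifacts_dominate_the_rejection_log(self, small_spec):
        noisy_spec = replace(small_spec, confounds=ConfoundConfig.severe())
        cohort = generate_cohort(noisy_spec, 3, seed=0)
        _, log = qc_filter(cohort_pairs(cohort, forward_only=True))
        assert log.rejected.mean() > 0.5


class TestAugment:
    def test_disabled_config_is_identity_up_to_normalization(self, pair):
        out = augment(pair, AugmentConfig(), seed=0)
        expected = (pair.fixed.values - pair.fixed.values.mean()) / pair.fixed.values.std()
        assert np.allclose(out.fixed.values, expected)
        assert np.array_equal(out.field.vectors, pair.field.vectors)
        assert out.order_label == pair.order_label

    def test_flipping_twice_restores_the_original(self, pair):
        from atrophynet.sampling import _flip, _flip_field

        axes = [0, 2]
        once = _flip(pair.fixed.values, axes)
        assert np.array_equal(_flip(once, axes), pair.fixed.values)
        once_f = _flip_field(pair.field.vectors, axes)
        assert np.array_equal(_flip_field(once_f, axes), pair.field.vectors)

    def test_label_and_interval_survive_augmentation(self, pair):
        cfg = AugmentConfig(flip_prob=1.0, erase_prob=1.0, rotate_prob=1.0,
                            max_rotation_deg=8.0)
        out = augment(pair, cfg, seed=5)
        assert out.order_label == pair.order_label
        assert out.interval == pair.interval

    def test_augmentation_is_deterministic_per_seed(self, pair):
        cfg = AugmentConfig(flip_prob=0.5, erase_prob=0.5)
        a = augment(pair, cfg, seed=9)
        b = augment(pair, cfg, seed=9)
        assert np.array_equal(a.fixed.values, b.fixed.values)
        assert np.array_equal(a.field.vectors, b.field.vectors)

    def test_oversized_crop_rejected(self, pair):
        with pytest.raises(ValueError, match="crop"):
            augment(pair, AugmentConfig(crop_shape=(99, 99, 99)), seed=0)

    def test_rotation_co_rotates_field_vectors(self, grid48):
        """Region volume change is invariant (to 3%) when mask and field
        are rotated together, which requires rotating the vectors too."""
        mask = make_ball_mask(grid48, (24, 24, 24), 9)
        field = _random_smooth_field(grid48, 1.5, 8.0, np.random.default_rng(0))
        v_fixed, v_moving = region_volumes(mask, field)
        rot = _rotation_matrix(12.0, axis=1)
        mask_rot = rotate_volume_values(mask, grid48, rot, cval=0.0)
        field_rot = rotate_field(field, rot)
        v_fixed_r, v_moving_r = region_volumes(mask_rot, field_rot)
        assert v_moving_r / v_fixed_r == pytest.approx(v_moving / v_fixed, rel=0.03)
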
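"""Training-sample assembly: nested pair-of-pairs, QC and augmentation.

A PairSample is an ordered scan pair with the displacement field registered
for that ordering (fixed = first element); reversing the temporal order is
a different registration, not the inverse field.  A QuadrupleSample joins
two pairs from one subject whose unordered interscan intervals nest — the
shorter interval lies inside the longer one, sharing at most one endpoint —
which is the precondition for the relative-interval loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import DisplacementField, ImageGrid, ScalarVolume
from .losses import RISIBins, ratio_bin
from .quality import DEFAULT_SSIM_THRESHOLD, ssim3d

__all__ = [
    "PairSample",
    "QuadrupleSample",
    "AugmentConfig",
    "enumerate_quadruples",
    "qc_filter",
    "augment",
    "rotate_volume_values",
    "rotate_field",
]


@dataclass
class PairSample:
    subject: str
    i1: int
    i2: int
    t1: float
    t2: float
    fixed: ScalarVolume
    moving: ScalarVolume
    field: DisplacementField
    side: str = ""  # metadata column for bilateral-structure use

    @property
    def interval(self) -> float:
        """Signed t2 - t1, years."""
        return self.t2 - self.t1

    @property
    def order_label(self) -> int:
        """+1 if presented in correct temporal order, -1 if reversed."""
        return 1 if self.t2 > self.t1 else -1


@dataclass
class QuadrupleSample:
    pair1: PairSample
    pair2: PairSample

    @property
    def true_ratio(self) -> float:
        return abs(self.pair1.interval) / abs(self.pair2.interval)

    def target_bin(self, bins: RISIBins | None = None) -> int:
        return ratio_bin(self.true_ratio, bins)


def _nested(times: list[float], inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    lo_i, hi_i = sorted((times[inner[0]], times[inner[1]]))
    lo_o, hi_o = sorted((times[outer[0]], times[outer[1]]))
    if not (lo_o <= lo_i and hi_i <= hi_o):
        return False
    shared = int(lo_i == lo_o) + int(hi_i == hi_o)
    return shared <= 1


def enumerate_quadruples(times: list[float]) -> list[tuple[int, int, int, int]]:
    """All valid pair-of-pairs index templates (i1, i2, i3, i4).

    The nested (strictly shorter) interval is canonically placed first;
    each unordered quadruple is emitted in all four temporal orientations
    (each pair forward and reversed).  Output order is deterministic.
    Returns an empty list when no quadruple satisfies the constraints
    (e.g. fewer than 3 timepoints).
    """
    n = len(times)
    if n < 2:
        raise ValueError("need at least 2 timepoints")
    out: list[tuple[int, int, int, int]] = []
    unordered = [(a, b) for a in range(n) for b in range(a + 1, n)
                 if times[a] != times[b]]
    for inner in unordered:
        len_inner = abs(times[inner[1]] - times[inner[0]])
        for outer in unordered:
            if inner == outer:
                continue
            len_outer = abs(times[outer[1]] - times[outer[0]])
            if not (len_inner < len_outer and _nested(times, inner, outer)):
                continue
            for p1 in (inner, inner[::-1]):
                for p2 in (outer, outer[::-1]):
                    out.append((*p1, *p2))
    return out


def qc_filter(
    pairs: list[PairSample], threshold: float = DEFAULT_SSIM_THRESHOLD
) -> tuple[list[PairSample], pd.DataFrame]:
    """Drop pairs whose fixed/moving SSIM falls below ``threshold``.

    Returns the retained pairs and a log with one row per input pair
    (subject, timepoints, score, rejected flag).
    """
    kept = []
    rows = []
    for p in pairs:
        score = ssim3d(p.fixed, p.moving)
        rejected = score < threshold
        rows.append(
            {"subject": p.subject, "i1": p.i1, "i2": p.i2,
             "ssim": score, "rejected": rejected}
        )
        if not rejected:
            kept.append(p)
    return kept, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentConfig:
    """Spatial/intensity augmentation; both scans and the field of a pair
    always receive the identical spatial transform."""

    normalize: bool = True
    flip_prob: float = 0.0  # per-axis flip probability
    rotate_prob: float = 0.0
    max_rotation_deg: float = 10.0
    erase_prob: float = 0.0
    erase_fraction: float = 0.2
    crop_shape: tuple[int, int, int] | None = None


def _zscore(values: np.ndarray) -> np.ndarray:
    std = values.std()
    return (values - values.mean()) / std if std > 0 else values - values.mean()


def _flip(values: np.ndarray, axes: list[int]) -> np.ndarray:
    return np.flip(values, axis=axes).copy() if axes else values


def _flip_field(vectors: np.ndarray, axes: list[int]) -> np.ndarray:
    if not axes:
        return vectors
    out = np.flip(vectors, axis=axes).copy()
    for ax in axes:
        out[..., ax] *= -1.0
    return out


def _rotation_matrix(angle_deg: float, axis: int) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    rot2 = np.array([[c, -s], [s, c]])
    other = [k for k in range(3) if k != axis]
    mat = np.eye(3)
    for a, i in enumerate(other):
        for b, j in enumerate(other):
            mat[i, j] = rot2[a, b]
    return mat


def _grid_center(grid: ImageGrid) -> np.ndarray:
    return np.asarray(grid.origin) + (np.asarray(grid.shape) - 1) / 2.0 * np.asarray(
        grid.spacing
    )


def rotate_volume_values(
    values: np.ndarray, grid: ImageGrid, rot: np.ndarray, order: int = 1,
    cval: float | None = None,
) -> np.ndarray:
    """Rotate a volume about the grid centre: out(x) = in(R^-1 (x - c) + c)."""
    coords = grid.coordinates()
    center = _grid_center(grid)
    src = (coords - center) @ rot + center  # rot is orthogonal: R^-1 = R^T; (x-c)R = R^T(x-c)
    idx = (src - np.asarray(grid.origin)) / np.asarray(grid.spacing)
    if cval is None:
        cval = float(values.min())
    return ndimage.map_coordinates(
        values, [idx[..., 0], idx[..., 1], idx[..., 2]],
        order=order, mode="constant", cval=cval,
    )


def rotate_field(field: DisplacementField, rot: np.ndarray) -> DisplacementField:
    """Rotate a displacement field: u'(x) = R u(R^-1 (x - c) + c)."""
    comps = [
        rotate_volume_values(field.vectors[..., k], field.grid, rot, cval=0.0)
        for k in range(3)
    ]
    u = np.stack(comps, axis=-1) @ rot.T
    return DisplacementField(field.grid, u)


def _crop(values: np.ndarray, start: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    sl = tuple(slice(s, s + n) for s, n in zip(start, shape))
    return values[sl].copy()


def augment(pair: PairSample, config: AugmentConfig, seed: int) -> PairSample:
    """Augment a pair deterministically; never changes its order label.

    Applies (in order): per-volume z-score normalisation, an identical
    random rotation and/or flips to fixed, moving and field (vector
    components co-rotated / sign-flipped), a shared centred crop, and
    patch erasing at the same location in both scans.
    """
    rng = np.random.default_rng(seed)
    grid = pair.fixed.grid
    fixed = pair.fixed.values
    moving = pair.moving.values
    vectors = pair.field.vectors
    if config.normalize:
        fixed = _zscore(fixed)
        moving = _zscore(moving)

    if config.rotate_prob > 0 and rng.uniform() < config.rotate_prob:
        axis = int(rng.integers(0, 3))
        angle = float(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
        rot = _rotation_matrix(angle, axis)
        fixed = rotate_volume_values(fixed, grid, rot)
        moving = rotate_volume_values(moving, grid, rot)
        vectors = rotate_field(DisplacementField(grid, vectors), rot).vectors

    flip_axes = [ax for ax in range(3)
                 if config.flip_prob > 0 and rng.uniform() < config.flip_prob]
    fixed = _flip(fixed, flip_axes)
    moving = _flip(moving, flip_axes)
    vectors = _flip_field(vectors, flip_axes)

    if config.crop_shape is not None:
        shape = np.asarray(grid.shape)
        crop = np.asarray(config.crop_shape)
        if np.any(crop > shape):
            raise ValueError(f"crop {config.crop_shape} larger than volume {grid.shape}")
        start = (shape - crop) // 2
        fixed = _crop(fixed, start, config.crop_shape)
        moving = _crop(moving, start, config.crop_shape)
        sl = tuple(slice(s, s + n) for s, n in zip(start, config.crop_shape))
        vectors = vectors[sl].copy()
        origin = np.asarray(grid.origin) + start * np.asarray(grid.spacing)
        grid = ImageGrid(tuple(int(c) for c in crop), grid.spacing, tuple(origin))

    if config.erase_prob > 0 and rng.uniform() < config.erase_prob:
        size = [max(1, int(config.erase_fraction * s)) for s in grid.shape]
        start = [int(rng.integers(0, s - sz + 1)) for s, sz in zip(grid.shape, size)]
        sl = tuple(slice(st, st + sz) for st, sz in zip(start, size))
        fixed = fixed.copy()
        moving = moving.copy()
        fixed[sl] = 0.0
        moving[sl] = 0.0

    return replace(
        pair,
        fixed=ScalarVolume(grid, fixed),
        moving=ScalarVolume(grid, moving),
        field=DisplacementField(grid, vectors),
    )
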
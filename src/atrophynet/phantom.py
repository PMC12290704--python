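"""Synthetic longitudinal cohorts with analytic ground-truth deformations.

Each phantom subject carries two ellipsoidal structures on a common grid:
a bright "tissue" region that loses volume linearly in time (fractional
loss r_j per year, subject-specific) and a darker "fluid" region that
gains volume at a coupled rate, emulating gray-matter atrophy and
ventricular expansion.  For every ordered scan pair the generator provides
the exact displacement field that maps the fixed-time geometry onto the
moving-time geometry — a uniform scaling about each region's centre,
blended smoothly to the identity outside a support shell — together with
binary ground-truth shrink/expand masks on the fixed grid.

Time-independent ("nonsystematic") confounds — small random smooth warps
and stripe/patch intensity artifacts, drawn independently of acquisition
time — can be layered onto the rendered scans; they never alter the
ground-truth masks, fields or rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .deformation import warp_scalar
from .grids import DisplacementField, ImageGrid, ScalarVolume

__all__ = [
    "Ellipsoid",
    "ConfoundConfig",
    "PhantomSpec",
    "PhantomSubject",
    "LongitudinalCohort",
    "generate_cohort",
    "add_nonsystematic_confound",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in physical mm."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("ellipsoid radii must be positive")

    def elliptic_radius(self, coords: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """rho(x): 1 on the (scaled) surface, <1 inside."""
        d = (coords - np.asarray(self.center)) / (np.asarray(self.radii) * scale)
        return np.sqrt((d**2).sum(axis=-1))

    def volume(self, scale: float = 1.0) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(np.asarray(self.radii) * scale))


@dataclass(frozen=True)
class ConfoundConfig:
    """Time-independent perturbations applied to rendered scans.

    warp_amplitude : peak displacement (mm) of a random smooth warp.
    warp_scale     : smoothness of that warp (Gaussian sigma, mm).
    artifact_probability : chance that a scan receives intensity artifacts.
    stripe_amplitude : stripe contrast as a fraction of the tissue intensity.
    patch_fraction : linear size of an erased/overwritten patch, as a
        fraction of the grid extent.
    """

    warp_amplitude: float = 0.0
    warp_scale: float = 8.0
    artifact_probability: float = 0.0
    stripe_amplitude: float = 0.5
    patch_fraction: float = 0.25

    @property
    def enabled(self) -> bool:
        return self.warp_amplitude > 0 or self.artifact_probability > 0

    @classmethod
    def severe(cls) -> "ConfoundConfig":
        """Settings harsh enough to fail SSIM-based registration QC."""
        return cls(
            warp_amplitude=5.0,
            warp_scale=6.0,
            artifact_probability=1.0,
            stripe_amplitude=1.2,
            patch_fraction=0.45,
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of the synthetic longitudinal cohort.

    Defaults emulate desk-scale versions of a multi-visit aging cohort:
    2-4 scans per subject over up to ~6 years, annual fractional tissue
    loss r_j drawn from 0.5%-8%/yr spanning control-to-impaired regimes.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_region: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((32.0, 24.0, 24.0), (8.0, 8.0, 7.0))
    )
    fluid_region: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((10.5, 24.0, 24.0), (4.0, 4.0, 3.5))
    )
    intensity_tissue: float = 1.0
    intensity_fluid: float = 0.3
    intensity_background: float = 0.0
    noise_sigma: float = 0.05  # fraction of tissue intensity
    texture_amplitude: float = 0.2  # subject-specific stationary background texture
    texture_scale: float = 3.0  # mm, texture correlation length
    rate_range: tuple[float, float] = (0.005, 0.08)  # fraction / year
    fluid_coupling: float = 1.0  # rho: fluid gains rho * r_j per year
    n_timepoints: tuple[int, int] = (3, 4)  # inclusive range per subject
    interval_range: tuple[float, float] = (0.5, 2.0)  # years between visits
    support_factor: float = 1.4  # deformation blends to identity by rho = this
    edge_width: float = 0.7  # mm, softness of rendered region boundaries
    center_jitter: float = 1.5  # mm, per-subject translation (template warp known)
    confounds: ConfoundConfig = field(default_factory=ConfoundConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints[0] < 2:
            raise ValueError("subjects need at least 2 timepoints")
        if not (0 <= self.rate_range[0] <= self.rate_range[1] < 1):
            raise ValueError("rate_range must satisfy 0 <= lo <= hi < 1")
        if self.interval_range[0] <= 0:
            raise ValueError("intervals must be positive")
        max_span = (self.n_timepoints[1] - 1) * self.interval_range[1]
        if self.rate_range[1] * max_span >= 1.0:
            raise ValueError(
                "rate_range and interval_range imply non-positive tissue volume "
                f"(max loss {self.rate_range[1] * max_span:.2f} of baseline)"
            )
        # Support shells (plus jitter) must stay disjoint so the two region
        # deformations superpose exactly.
        c1 = np.asarray(self.tissue_region.center)
        c2 = np.asarray(self.fluid_region.center)
        # fluid can grow by up to (1 + rho * r * span)^(1/3)
        growth = (1 + self.fluid_coupling * self.rate_range[1] * max_span) ** (1 / 3)
        reach = self.support_factor * (
            max(self.tissue_region.radii) + growth * max(self.fluid_region.radii)
        )
        if np.linalg.norm(c1 - c2) < reach + 2 * self.center_jitter:
            raise ValueError("tissue and fluid support shells overlap")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(self.grid_shape, self.spacing)


def _blend_weight(rho: np.ndarray, support_factor: float) -> np.ndarray:
    """1 inside the region (rho<=1), smoothstep to 0 at rho=support_factor."""
    s = np.clip((rho - 1.0) / (support_factor - 1.0), 0.0, 1.0)
    return 1.0 - (3.0 * s**2 - 2.0 * s**3)


@dataclass
class PhantomSubject:
    subject_id: str
    rate: float  # true fractional tissue loss per year
    age: float  # baseline age, years
    offset: np.ndarray  # mm translation from template geometry
    times: list[float]  # years from baseline, times[0] == 0
    scans: list[ScalarVolume]

    def n_timepoints(self) -> int:
        return len(self.times)


class LongitudinalCohort:
    """Subjects x timepoints with analytic ground truth.

    Ground-truth fields and masks are computed on demand from the stored
    geometry so that arbitrarily many ordered pairs can be queried without
    storing a quadratic number of dense fields.
    """

    def __init__(self, spec: PhantomSpec, subjects: list[PhantomSubject]):
        self.spec = spec
        self.subjects = subjects

    @property
    def grid(self) -> ImageGrid:
        return self.spec.grid

    # -- geometry helpers ------------------------------------------------
    def _region_scale(self, subject: PhantomSubject, t: float, which: str) -> float:
        if which == "tissue":
            frac = 1.0 - subject.rate * t
        elif which == "fluid":
            frac = 1.0 + self.spec.fluid_coupling * subject.rate * t
        else:
            raise ValueError(which)
        if frac <= 0:
            raise ValueError(f"non-positive volume fraction at t={t}")
        return frac ** (1.0 / 3.0)

    def _region(self, which: str) -> Ellipsoid:
        return self.spec.tissue_region if which == "tissue" else self.spec.fluid_region

    def true_tissue_volume(self, j: int, i: int) -> float:
        """Analytic tissue volume (mm^3) of subject j at timepoint index i."""
        s = self.subjects[j]
        return self.spec.tissue_region.volume(self._region_scale(s, s.times[i], "tissue"))

    def true_fluid_volume(self, j: int, i: int) -> float:
        s = self.subjects[j]
        return self.spec.fluid_region.volume(self._region_scale(s, s.times[i], "fluid"))

    def truth_masks(self, j: int, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Binary (shrink, expand) masks of subject j at timepoint index i."""
        s = self.subjects[j]
        coords = self.grid.coordinates() - s.offset
        shrink = (
            self.spec.tissue_region.elliptic_radius(
                coords, self._region_scale(s, s.times[i], "tissue")
            )
            <= 1.0
        )
        expand = (
            self.spec.fluid_region.elliptic_radius(
                coords, self._region_scale(s, s.times[i], "fluid")
            )
            <= 1.0
        )
        return shrink.astype(np.float64), expand.astype(np.float64)

    def truth_field(self, j: int, i1: int, i2: int) -> DisplacementField:
        """Exact displacement field with timepoint i1 fixed, i2 moving."""
        s = self.subjects[j]
        t1, t2 = s.times[i1], s.times[i2]
        coords = self.grid.coordinates() - s.offset
        u = np.zeros_like(coords)
        for which in ("tissue", "fluid"):
            region = self._region(which)
            scale1 = self._region_scale(s, t1, which)
            scale2 = self._region_scale(s, t2, which)
            lam = scale2 / scale1
            rho = region.elliptic_radius(coords, scale1)
            w = _blend_weight(rho, self.spec.support_factor)
            u += (lam - 1.0) * (coords - np.asarray(region.center)) * w[..., None]
        return DisplacementField(self.grid, u)

    def template_warp(self, j: int) -> DisplacementField:
        """Warp psi mapping template coordinates to subject j's space.

        Phantom subjects differ from the template geometry by a rigid
        translation, so psi is a constant field; sampling a subject-space
        map at x + u(x) brings it into template space.
        """
        s = self.subjects[j]
        u = np.broadcast_to(s.offset, (*self.grid.shape, 3)).copy()
        return DisplacementField(self.grid, u)

    def template_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Baseline (shrink, expand) masks of the un-jittered template."""
        coords = self.grid.coordinates()
        shrink = self.spec.tissue_region.elliptic_radius(coords) <= 1.0
        expand = self.spec.fluid_region.elliptic_radius(coords) <= 1.0
        return shrink.astype(np.float64), expand.astype(np.float64)

    def template_expansion_region(self) -> np.ndarray:
        """All template voxels where the ground-truth field expands.

        Besides the fluid structure itself this includes the compensatory
        shell around the shrinking tissue: the truth field blends to the
        identity across that shell, so the volume lost inside the tissue
        reappears there as an equal, time-linked expansion.
        """
        coords = self.grid.coordinates()
        rho_t = self.spec.tissue_region.elliptic_radius(coords)
        shell = (rho_t > 1.0) & (rho_t <= self.spec.support_factor)
        fluid = self.spec.fluid_region.elliptic_radius(coords) <= 1.0
        return (shell | fluid).astype(np.float64)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for j, s in enumerate(self.subjects):
            for i, t in enumerate(s.times):
                rows.append(
                    {
                        "subject": s.subject_id,
                        "subject_index": j,
                        "timepoint": i,
                        "years_from_baseline": t,
                        "age_at_baseline": s.age,
                        "true_rate_per_year": s.rate,
                    }
                )
        return pd.DataFrame(rows)


def _subject_texture(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Stationary anatomy-like texture, fixed across a subject's timepoints.

    Real scan pairs share fine structure everywhere, which is what keeps
    the SSIM of well-registered pairs in the 0.7-0.9 band; without it a
    noise-only background drags SSIM below the QC threshold even for
    perfectly aligned scans.
    """
    if spec.texture_amplitude <= 0:
        return np.zeros(spec.grid_shape)
    sigma = [spec.texture_scale / s for s in spec.spacing]
    tex = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma)
    std = tex.std()
    if std > 0:
        tex *= spec.texture_amplitude * spec.intensity_tissue / std
    return tex


def _render_scan(
    spec: PhantomSpec,
    offset: np.ndarray,
    tissue_scale: float,
    fluid_scale: float,
    texture: np.ndarray,
    rng: np.random.Generator,
) -> ScalarVolume:
    coords = spec.grid.coordinates() - offset
    values = np.full(spec.grid_shape, spec.intensity_background, dtype=np.float64)
    values = values + texture
    for region, scale, level in (
        (spec.tissue_region, tissue_scale, spec.intensity_tissue),
        (spec.fluid_region, fluid_scale, spec.intensity_fluid),
    ):
        rho = region.elliptic_radius(coords, scale)
        # approximate signed distance (mm) to the scaled surface
        dist = (rho - 1.0) * min(region.radii) * scale
        indicator = 1.0 / (1.0 + np.exp(np.clip(dist / spec.edge_width, -40, 40)))
        values += (level - spec.intensity_background) * indicator
    if spec.noise_sigma > 0:
        values = values + rng.normal(
            0.0, spec.noise_sigma * spec.intensity_tissue, size=values.shape
        )
    return ScalarVolume(spec.grid, values)


def generate_cohort(
    spec: PhantomSpec, n_subjects: int, seed: int | None = None
) -> LongitudinalCohort:
    """Generate a deterministic synthetic cohort.

    Tissue volume at elapsed time t equals baseline * (1 - r_j * t); fluid
    volume equals baseline * (1 + rho * r_j * t).  Identical spec + seed
    give a bitwise identical cohort.
    """
    if seed is None:
        seed = spec.seed
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)
    cohort = LongitudinalCohort(spec, [])
    for j in range(n_subjects):
        rng = np.random.default_rng(subject_seeds[j])
        rate = float(rng.uniform(*spec.rate_range))
        age = float(rng.uniform(65.0, 85.0))
        offset = rng.uniform(-spec.center_jitter, spec.center_jitter, size=3)
        n_t = int(rng.integers(spec.n_timepoints[0], spec.n_timepoints[1] + 1))
        intervals = rng.uniform(*spec.interval_range, size=n_t - 1)
        times = [0.0] + list(np.cumsum(intervals))
        texture = _subject_texture(spec, rng)
        subject = PhantomSubject(
            subject_id=f"sub{j:03d}", rate=rate, age=age, offset=offset,
            times=[float(t) for t in times], scans=[],
        )
        cohort.subjects.append(subject)
        for i, t in enumerate(times):
            tissue_scale = (1.0 - rate * t) ** (1.0 / 3.0)
            fluid_scale = (1.0 + spec.fluid_coupling * rate * t) ** (1.0 / 3.0)
            scan = _render_scan(spec, offset, tissue_scale, fluid_scale, texture, rng)
            if spec.confounds.enabled:
                confound_seed = int(rng.integers(0, 2**31 - 1))
                scan = add_nonsystematic_confound(scan, spec.confounds, confound_seed)
            subject.scans.append(scan)
    return cohort


def _random_smooth_field(
    grid: ImageGrid, amplitude: float, scale_mm: float, rng: np.random.Generator
) -> DisplacementField:
    sigma_vox = [scale_mm / s for s in grid.spacing]
    u = rng.standard_normal((*grid.shape, 3))
    for c in range(3):
        u[..., c] = ndimage.gaussian_filter(u[..., c], sigma=sigma_vox)
    peak = np.abs(u).max()
    if peak > 0:
        u *= amplitude / peak
    return DisplacementField(grid, u)


def add_nonsystematic_confound(
    scan: ScalarVolume, config: ConfoundConfig, seed: int
) -> ScalarVolume:
    """Apply time-independent perturbations to a scan (deterministic per seed).

    A no-op when the config disables all confounds.  The ground truth of the
    cohort (masks, fields, rates) is never touched: confounds model head
    motion, artifacts and other nuisance structure, not anatomy.
    """
    if not config.enabled:
        return scan
    rng = np.random.default_rng(seed)
    values = scan.values
    if config.warp_amplitude > 0:
        warp = _random_smooth_field(
            scan.grid, config.warp_amplitude, config.warp_scale, rng
        )
        values = warp_scalar(values, scan.grid, warp, order=1, cval=values.min())
    if config.artifact_probability > 0 and rng.uniform() < config.artifact_probability:
        shape = scan.grid.shape
        axis = int(rng.integers(0, 3))
        period = float(rng.uniform(3.0, 8.0))
        phase = float(rng.uniform(0, 2 * np.pi))
        idx = np.arange(shape[axis], dtype=np.float64)
        stripes = config.stripe_amplitude * np.sin(2 * np.pi * idx / period + phase)
        shape_bcast = [1, 1, 1]
        shape_bcast[axis] = shape[axis]
        values = values + stripes.reshape(shape_bcast)
        if config.patch_fraction > 0:
            size = [max(1, int(config.patch_fraction * s)) for s in shape]
            start = [int(rng.integers(0, s - sz + 1)) for s, sz in zip(shape, size)]
            sl = tuple(slice(st, st + sz) for st, sz in zip(start, size))
            values = values.copy()
            values[sl] = float(rng.uniform(values.min(), values.max()))
    return ScalarVolume(scan.grid, values)
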
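"""Attention-weighted volume change and per-subject atrophy rates.

Sign convention: the pooled change a_pooled = a_shr - a_exp is negative
under atrophy when scans are presented in forward temporal order (the
shrink region loses volume, the expand region gains).  Annualised rates
carry the same sign, so more negative means faster atrophy.  Note that
some conventions in the literature report atrophy as a positive loss
fraction; flip the sign of a_pooled (and the AUC score orientation in
:mod:`atrophynet.evaluation`) to switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deformation import region_volumes
from .grids import AttentionMaps, DisplacementField, _require_same_grid

__all__ = ["PairChange", "pair_change", "annualized_rate", "age_adjust"]


@dataclass(frozen=True)
class PairChange:
    """Deformation-induced volume change of one ordered scan pair.

    a_shr, a_exp
        Moving-minus-fixed volume (mm^3) of the shrink / expand region.
    a_pooled
        a_shr - a_exp (mm^3); negative under forward-time atrophy.
    v_base
        Fixed-image volume (mm^3) of shrink + expand regions; the
        normaliser for fractional change.
    interval
        Signed t2 - t1 in years.
    fixed_id
        Optional identifier of the fixed scan, used to verify that
        multi-pair rate fits share a common baseline anchor.
    """

    a_shr: float
    a_exp: float
    a_pooled: float
    v_base: float
    interval: float
    fixed_id: object = None

    def __post_init__(self) -> None:
        if abs(self.a_pooled - (self.a_shr - self.a_exp)) > 1e-9 * max(
            1.0, abs(self.a_shr), abs(self.a_exp)
        ):
            raise ValueError("a_pooled must equal a_shr - a_exp")
        if self.v_base < 0:
            raise ValueError("v_base must be nonnegative")


def pair_change(
    att: AttentionMaps,
    field: DisplacementField,
    interval: float,
    fixed_id: object = None,
) -> PairChange:
    """Volume changes induced by ``field`` on the attention regions.

    For a well-trained model on forward-time pairs (interval > 0) one
    expects a_shr < 0, a_exp > 0 and hence a_pooled < 0.
    """
    _require_same_grid(att.grid, field.grid, "pair_change")
    v_shr_fixed, v_shr_moving = region_volumes(att.shrink, field, grid=att.grid)
    v_exp_fixed, v_exp_moving = region_volumes(att.expand, field, grid=att.grid)
    a_shr = v_shr_moving - v_shr_fixed
    a_exp = v_exp_moving - v_exp_fixed
    return PairChange(
        a_shr=a_shr,
        a_exp=a_exp,
        a_pooled=a_shr - a_exp,
        v_base=v_shr_fixed + v_exp_fixed,
        interval=float(interval),
        fixed_id=fixed_id,
    )


def annualized_rate(
    changes: list[PairChange], fit_intercept: bool = True
) -> float:
    """Per-year fractional volume-change rate from baseline-anchored pairs.

    With a single pair the rate is (a_pooled / v_base) / interval.  With
    several pairs — all sharing the subject's baseline scan as the fixed
    image — an ordinary least-squares line of a_pooled against interval is
    fit (free intercept by default) and its slope is divided by the v_base
    of the shortest-interval (closest-to-baseline) pair.
    """
    if not changes:
        raise ValueError("need at least one pair change")
    if any(c.interval <= 0 for c in changes):
        raise ValueError("intervals must be positive for rate estimation")
    anchors = {c.fixed_id for c in changes if c.fixed_id is not None}
    if len(anchors) > 1:
        raise ValueError(
            f"pairs are anchored at different fixed scans: {sorted(map(str, anchors))}"
        )
    if len(changes) == 1:
        c = changes[0]
        if c.v_base == 0:
            raise ValueError("zero baseline volume")
        return float(c.a_pooled / c.v_base / c.interval)
    intervals = np.array([c.interval for c in changes])
    pooled = np.array([c.a_pooled for c in changes])
    if fit_intercept:
        design = np.column_stack([intervals, np.ones_like(intervals)])
    else:
        design = intervals[:, None]
    coef, *_ = np.linalg.lstsq(design, pooled, rcond=None)
    slope = float(coef[0])
    v_base = changes[int(np.argmin(intervals))].v_base
    if v_base == 0:
        raise ValueError("zero baseline volume")
    return slope / v_base


def age_adjust(
    rates: np.ndarray, ages: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Residualise rates against age using a reference-group linear fit.

    Parameters
    ----------
    rates, ages
        Per-subject values (same length).
    reference
        Boolean mask or index array selecting the reference subjects
        (typically the unimpaired control group) used to fit rate ~ age.

    Returns
    -------
    Adjusted rates (rate minus the age-predicted rate) for all subjects.
    """
    rates = np.asarray(rates, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if rates.shape != ages.shape:
        raise ValueError("rates and ages must have the same shape")
    ref_rates = rates[reference]
    ref_ages = ages[reference]
    if ref_rates.size < 3:
        raise ValueError("reference group must have at least 3 subjects")
    if np.ptp(ref_ages) == 0:
        raise ValueError("reference group ages are constant; cannot fit age model")
    slope, intercept = np.polyfit(ref_ages, ref_rates, deg=1)
    return rates - (slope * ages + intercept)
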
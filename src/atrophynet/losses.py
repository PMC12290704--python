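"""Temporal self-supervision losses.

Two losses drive the attention model, both consuming only the scalar
attention-weighted volume changes:

* the scan-temporal-order (STO) loss — a two-class cross-entropy asking
  whether a pair of scans was presented in correct or reversed
  chronological order, encoded so that negative shrink change and positive
  expand change are favoured under forward time;
* the relative-interscan-interval (RISI) loss — a four-class cross-entropy
  over the ratio of the magnitudes of change in two nested scan pairs,
  binned into ratio ranges [0, 0.5], (0.5, 1], (1, 2], (2, inf).  The bin
  probabilities are built from products of sigmoids over the half-planes
  bounding each ratio cone in the (a1, a2) plane, which makes the
  classification differentiable; the raw cone products are renormalised to
  sum to one before the cross-entropy.

Volume changes are expected in normalised units (change divided by the
baseline attention-region volume); the sharpness parameter ``alpha``
(default 50) then puts typical percent-level annual changes in the sigmoid
transition region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RISIBins",
    "LossWeights",
    "sto_loss",
    "risi_category_probs",
    "risi_loss",
    "ratio_bin",
    "total_loss",
]

_LN_CLIP = 1e-300


@dataclass(frozen=True)
class RISIBins:
    """Ratio-bin boundaries and sigmoid sharpness for the RISI loss."""

    boundaries: tuple[float, float, float] = (0.5, 1.0, 2.0)
    alpha: float = 50.0

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (0 < b[0] < b[1] < b[2]):
            raise ValueError("boundaries must be strictly increasing and positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def n_categories(self) -> int:
        return len(self.boundaries) + 1


@dataclass(frozen=True)
class LossWeights:
    w_sto: float = 1.0
    w_risi: float = 1.0

    def __post_init__(self) -> None:
        if self.w_sto < 0 or self.w_risi < 0:
            raise ValueError("loss weights must be nonnegative")


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _softplus(x: float) -> float:
    return float(np.logaddexp(0.0, x))


def sto_loss(
    a_shr: float, a_exp: float, y: int, alpha: float = 50.0, grad: bool = False
):
    """Scan-temporal-order cross-entropy for one pair.

    The shrink change enters with logits [-a, a] and the expand change with
    logits [a, -a] (alpha-scaled), so for the forward-order label y = +1 the
    loss is minimised by a_shr < 0 and a_exp > 0.  At a_shr = a_exp = 0 the
    loss equals 2 ln 2; it is symmetric under (a, y) -> (-a, -y).

    With ``grad=True`` returns ``(loss, dloss_da_shr, dloss_da_exp)``.
    """
    if y not in (-1, 1):
        raise ValueError(f"order label must be +1 or -1, got {y!r}")
    l_shr = _softplus(2.0 * alpha * y * a_shr)
    l_exp = _softplus(-2.0 * alpha * y * a_exp)
    loss = l_shr + l_exp
    if not grad:
        return loss
    d_shr = 2.0 * alpha * y * float(_sigmoid(2.0 * alpha * y * a_shr))
    d_exp = -2.0 * alpha * y * float(_sigmoid(-2.0 * alpha * y * a_exp))
    return loss, d_shr, d_exp


def _cone_forms(bins: RISIBins) -> list[list[tuple[float, float]]]:
    """Half-plane coefficient pairs (c1, c2) per category.

    Each category's wedge is the intersection of two half-planes
    {c1*a1 + c2*a2 > 0}; the boundary line at ratio c is scaled as the
    sharper of (a1 - c*a2) and (a1/c - a2) so that for the default bins the
    forms are the integer-coefficient ones (2a1 +/- a2, a1 +/- a2,
    a1 +/- 2a2).
    """

    def line(c: float) -> tuple[float, float]:
        # coefficients of f = a1 - c*a2, rescaled when c < 1
        return (1.0 / c, -1.0) if c < 1 else (1.0, -c)

    b0, b1, b2 = bins.boundaries
    l0, l1, l2 = line(b0), line(b1), line(b2)
    return [
        # ratio <= b0: cone around the a2 axis
        [(-l0[0], -l0[1]), (l0[0], -l0[1])],
        # b0 <= ratio <= b1
        [l0, (-l1[0], -l1[1])],
        # b1 <= ratio <= b2
        [l1, (-l2[0], -l2[1])],
        # ratio >= b2: cone around the a1 axis
        [l2, (l2[0], -l2[1])],
    ]


def risi_category_probs(
    a1: float, a2: float, bins: RISIBins | None = None, grad: bool = False
):
    """Soft assignment of |a1|/|a2| to the four ratio categories.

    For each category the probability is the maximum over the four sign
    orientations of (a1, a2) of the product of boundary sigmoids; the
    resulting vector is renormalised to sum to 1.  Continuous in (a1, a2),
    invariant under the simultaneous flip (a1, a2) -> (-a1, -a2), and equal
    to hard ratio binning in the alpha -> infinity limit.

    With ``grad=True`` returns ``(probs, dprobs_da1, dprobs_da2)`` where the
    gradient is taken through the active orientation of each max.
    """
    bins = bins or RISIBins()
    alpha = bins.alpha
    forms = _cone_forms(bins)
    n = len(forms)
    raw = np.empty(n)
    draw1 = np.empty(n)
    draw2 = np.empty(n)
    for k, cat in enumerate(forms):
        best, best_d1, best_d2 = -1.0, 0.0, 0.0
        for s1 in (1.0, -1.0):
            for s2 in (1.0, -1.0):
                p = 1.0
                d1 = d2 = 0.0
                for c1, c2 in cat:
                    f = c1 * s1 * a1 + c2 * s2 * a2
                    sig = float(_sigmoid(alpha * f))
                    p *= sig
                    d1 += (1.0 - sig) * alpha * c1 * s1
                    d2 += (1.0 - sig) * alpha * c2 * s2
                if p > best:
                    best, best_d1, best_d2 = p, p * d1, p * d2
        raw[k] = best
        draw1[k] = best_d1
        draw2[k] = best_d2
    total = raw.sum()
    probs = raw / total
    if not grad:
        return probs
    # quotient rule through the renormalisation
    dprobs1 = (draw1 - probs * draw1.sum()) / total
    dprobs2 = (draw2 - probs * draw2.sum()) / total
    return probs, dprobs1, dprobs2


def ratio_bin(true_ratio: float, bins: RISIBins | None = None) -> int:
    """Hard bin of an interval ratio; boundaries go to the lower bin."""
    bins = bins or RISIBins()
    if not np.isfinite(true_ratio) or true_ratio <= 0:
        raise ValueError(f"interval ratio must be positive and finite, got {true_ratio}")
    return int(np.searchsorted(np.asarray(bins.boundaries), true_ratio, side="left"))


def risi_loss(
    a1_shr: float,
    a2_shr: float,
    a1_exp: float,
    a2_exp: float,
    true_ratio: float,
    bins: RISIBins | None = None,
    grad: bool = False,
):
    """Relative-interscan-interval cross-entropy, summed over region types.

    ``true_ratio`` is |t2 - t1| / |t4 - t3|; its bin is the cross-entropy
    target for both the shrink-change pair (a1_shr, a2_shr) and the
    expand-change pair (a1_exp, a2_exp).

    With ``grad=True`` returns ``(loss, (d_a1_shr, d_a2_shr, d_a1_exp,
    d_a2_exp))``.
    """
    bins = bins or RISIBins()
    target = ratio_bin(true_ratio, bins)
    loss = 0.0
    grads = []
    for a1, a2 in ((a1_shr, a2_shr), (a1_exp, a2_exp)):
        if grad:
            probs, d1, d2 = risi_category_probs(a1, a2, bins, grad=True)
        else:
            probs = risi_category_probs(a1, a2, bins)
        p_t = max(float(probs[target]), _LN_CLIP)
        loss += -np.log(p_t)
        if grad:
            grads.extend([-d1[target] / p_t, -d2[target] / p_t])
    if not grad:
        return float(loss)
    return float(loss), tuple(grads)


def total_loss(
    sto_branch1: float,
    sto_branch2: float,
    risi: float,
    weights: LossWeights | None = None,
) -> float:
    """Weighted training objective for one pair-of-pairs sample.

    The two branch STO losses (each already the shrink + expand sum for its
    pair) are summed and weighted against the single RISI term.
    """
    weights = weights or LossWeights()
    value = weights.w_sto * (sto_branch1 + sto_branch2) + weights.w_risi * risi
    if not np.isfinite(value):
        raise FloatingPointError("non-finite training loss")
    return float(value)
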
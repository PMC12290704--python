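"""Temporal-inference accuracy, group statistics and attention heatmaps.

Under the adopted sign convention a_pooled is negative for forward-time
atrophy, so the continuous score fed to ROC analysis is -a_pooled against
the label "pair presented in true order"; a user flipping the sign
convention flips only this score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .deformation import warp_scalar
from .grids import AttentionMaps, DisplacementField, ImageGrid

__all__ = [
    "EvalRecord",
    "Heatmap",
    "sto_accuracy",
    "risi_accuracy",
    "auc",
    "group_difference",
    "aggregate_heatmap",
]


@dataclass(frozen=True)
class EvalRecord:
    """One ordered scan pair's temporal-order trial."""

    subject: str
    i1: int
    i2: int
    a_pooled: float
    interval: float  # signed true interval, years

    @property
    def correct(self) -> bool:
        """Sign of the atrophy score matches the sign of the true interval.

        Zero pooled change never matches (counted incorrect).
        """
        return bool(np.sign(-self.a_pooled) == np.sign(self.interval)) and (
            self.a_pooled != 0
        )


def sto_accuracy(
    records: list[EvalRecord], groups: dict[str, str] | None = None
) -> dict[str, float | None]:
    """Fraction of pairs whose change sign matches the true temporal order.

    Both orderings of a scan pair count as separate trials.  Returns a dict
    with key "overall" plus one key per group when a subject -> group
    mapping is given; a group without records maps to None.
    """
    if not records:
        raise ValueError("no evaluation records")
    out: dict[str, float | None] = {
        "overall": float(np.mean([r.correct for r in records]))
    }
    if groups is not None:
        for name in sorted(set(groups.values())):
            sub = [r.correct for r in records if groups.get(r.subject) == name]
            out[name] = float(np.mean(sub)) if sub else None
    return out


def risi_accuracy(pairs_of_changes: list[tuple[float, float]]) -> float:
    """Fraction of nested pair-of-pairs ranked correctly by |a_pooled|.

    Each item is (a_pooled of the shorter-interval pair, a_pooled of the
    longer-interval pair); correct when the longer pair's magnitude is
    strictly greater.  Ties count as failures.
    """
    if not pairs_of_changes:
        raise ValueError("no quadruple records")
    correct = [abs(a_long) > abs(a_short) for a_short, a_long in pairs_of_changes]
    return float(np.mean(correct))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def group_difference(
    rates: np.ndarray,
    labels: np.ndarray,
    reference_group: str,
    exact_max_n: int = 25,
) -> dict[str, dict[str, float]]:
    """One-sided rank-sum tests of each group against the reference.

    The alternative is that the comparison group shows greater atrophy,
    i.e. more negative adjusted rates than the reference.  Uses the exact
    Mann-Whitney null when the combined sample is small (<= ``exact_max_n``
    and tie-free), otherwise the normal approximation with tie correction.
    Also reports the AUC of -rate for separating each group from the
    reference.
    """
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray(labels)
    ref = rates[labels == reference_group]
    if ref.size == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    out: dict[str, dict[str, float]] = {}
    for name in sorted(set(labels.tolist())):
        if name == reference_group:
            continue
        comp = rates[labels == name]
        if comp.size == 0:
            raise ValueError(f"comparison group {name!r} is empty")
        n_total = comp.size + ref.size
        has_ties = np.unique(np.concatenate([comp, ref])).size < n_total
        method = "exact" if (n_total <= exact_max_n and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(comp, ref, alternative="less", method=method)
        scores = np.concatenate([-comp, -ref])
        lab = np.concatenate([np.ones(comp.size), np.zeros(ref.size)])
        out[str(name)] = {
            "p": float(res.pvalue),
            "auc": auc(scores, lab),
            "n": int(comp.size),
        }
    return out


@dataclass
class Heatmap:
    """Per-voxel identification frequency in a common template space."""

    grid: ImageGrid
    shrink_freq: np.ndarray
    expand_freq: np.ndarray
    coverage: np.ndarray  # per-voxel denominator (number of contributing pairs)


def aggregate_heatmap(
    items: list[tuple[AttentionMaps, DisplacementField | None]],
    template_grid: ImageGrid,
    threshold: float = 0.5,
) -> Heatmap:
    """Average warped near-binary attention masks into a template heatmap.

    Each item is a fixed-image attention map plus the warp psi from
    template coordinates to that image's space; items without a warp are
    skipped with a warning.  Per voxel, the numerator accumulates the
    warped binarised shrink (resp. expand) indicator and the denominator
    the warped coverage mask, so peripheral template voxels seen by fewer
    pairs are normalised by their own coverage and frequencies stay in
    [0, 1]; voxels never covered report frequency 0.
    """
    num_shr = np.zeros(template_grid.shape)
    num_exp = np.zeros(template_grid.shape)
    denom = np.zeros(template_grid.shape)
    used = 0
    for att, warp in items:
        if warp is None:
            warnings.warn("attention map without a template warp; skipped")
            continue
        shrink = (att.shrink >= threshold).astype(np.float64)
        expand = (att.expand >= threshold).astype(np.float64)
        ones = np.ones(att.grid.shape)
        num_shr += warp_scalar(shrink, att.grid, warp, order=1, cval=0.0)
        num_exp += warp_scalar(expand, att.grid, warp, order=1, cval=0.0)
        denom += warp_scalar(ones, att.grid, warp, order=1, cval=0.0)
        used += 1
    if used == 0:
        raise ValueError("no usable (attention, warp) items")
    with np.errstate(invalid="ignore", divide="ignore"):
        shr = np.where(denom > 1e-9, num_shr / np.maximum(denom, 1e-9), 0.0)
        exp = np.where(denom > 1e-9, num_exp / np.maximum(denom, 1e-9), 0.0)
    return Heatmap(template_grid, np.clip(shr, 0, 1), np.clip(exp, 0, 1), denom)
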
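"""End-to-end convenience layer: train on a cohort, evaluate held-out subjects.

This stitches the modules together the way a study would run them:
generate (or load) a longitudinal cohort, assemble nested pair-of-pairs,
train the attention network, then sweep every ordered test pair through
the model to produce temporal-order records, interval-ranking records,
per-subject annualised rates and a template-space heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attention import AttentionNet
from .evaluation import EvalRecord, Heatmap, aggregate_heatmap, risi_accuracy, sto_accuracy
from .grids import AttentionMaps
from .morphometry import PairChange, annualized_rate, pair_change
from .phantom import LongitudinalCohort
from .sampling import enumerate_quadruples

__all__ = ["CohortEvaluation", "evaluate_cohort", "heatmap_enrichment"]


@dataclass
class CohortEvaluation:
    """Everything measured on a set of evaluation subjects."""

    pairs: pd.DataFrame  # one row per ordered pair, both directions
    risi_pairs: list[tuple[float, float]]  # (a_pooled short, a_pooled long)
    rates: pd.DataFrame  # per subject: estimated and true rate, age
    heatmap: Heatmap

    def sto_records(
        self, min_rate: float = 0.0, min_interval: float = 0.0
    ) -> list[EvalRecord]:
        df = self.pairs
        sel = (df.true_rate >= min_rate) & (df.interval.abs() >= min_interval)
        return [
            EvalRecord(r.subject, int(r.i1), int(r.i2), r.a_pooled, r.interval)
            for r in df[sel].itertuples()
        ]

    def sto_accuracy(self, min_rate: float = 0.0, min_interval: float = 0.0) -> float:
        return sto_accuracy(self.sto_records(min_rate, min_interval))["overall"]

    def risi_accuracy(self) -> float:
        return risi_accuracy(self.risi_pairs)

    def rate_spearman(self) -> float:
        """Spearman correlation between estimated atrophy (positive = loss,
        i.e. the negated annualised rate) and the true simulated rate."""
        from scipy.stats import spearmanr

        rho, _ = spearmanr(-self.rates.estimated_rate, self.rates.true_rate)
        return float(rho)


def evaluate_cohort(
    net: AttentionNet,
    cohort: LongitudinalCohort,
    subject_indices: list[int],
) -> CohortEvaluation:
    """Run the trained model over every ordered pair of the given subjects."""
    rows = []
    risi_pairs: list[tuple[float, float]] = []
    rate_rows = []
    heat_items: list[tuple[AttentionMaps, object]] = []
    for j in subject_indices:
        s = cohort.subjects[j]
        n = len(s.times)
        pooled: dict[tuple[int, int], float] = {}
        baseline_changes: list[PairChange] = []
        for i1 in range(n):
            for i2 in range(n):
                if i1 == i2:
                    continue
                field = cohort.truth_field(j, i1, i2)
                att = net.forward(s.scans[i1], s.scans[i2])
                pc = pair_change(att, field, s.times[i2] - s.times[i1], fixed_id=i1)
                pooled[(i1, i2)] = pc.a_pooled
                rows.append(
                    {
                        "subject": s.subject_id,
                        "subject_index": j,
                        "i1": i1,
                        "i2": i2,
                        "interval": pc.interval,
                        "a_pooled": pc.a_pooled,
                        "a_shr": pc.a_shr,
                        "a_exp": pc.a_exp,
                        "v_base": pc.v_base,
                        "true_rate": s.rate,
                    }
                )
                if i1 == 0 and i2 > 0:
                    baseline_changes.append(pc)
                    heat_items.append((att, cohort.template_warp(j)))
        seen = set()
        for (a, b, c, d) in enumerate_quadruples(s.times):
            key = (min(a, b), max(a, b), min(c, d), max(c, d))
            if key in seen:
                continue
            seen.add(key)
            risi_pairs.append((pooled[key[:2]], pooled[key[2:]]))
        rate_rows.append(
            {
                "subject": s.subject_id,
                "subject_index": j,
                "estimated_rate": annualized_rate(baseline_changes),
                "true_rate": s.rate,
                "age": s.age,
            }
        )
    heatmap = aggregate_heatmap(heat_items, cohort.grid)
    return CohortEvaluation(
        pairs=pd.DataFrame(rows),
        risi_pairs=risi_pairs,
        rates=pd.DataFrame(rate_rows),
        heatmap=heatmap,
    )


def heatmap_enrichment(
    heatmap: Heatmap, region_mask: np.ndarray, which: str = "shrink"
) -> float:
    """Mean identification frequency inside a region over the mean outside.

    Only voxels with nonzero coverage enter either mean; a zero outside
    mean is floored at 1e-6 so the enrichment stays finite.
    """
    freq = heatmap.shrink_freq if which == "shrink" else heatmap.expand_freq
    covered = heatmap.coverage > 1e-9
    inside = (region_mask > 0.5) & covered
    outside = (region_mask <= 0.5) & covered
    if not inside.any() or not outside.any():
        raise ValueError("region mask does not split the covered template")
    mean_in = float(freq[inside].mean())
    mean_out = float(freq[outside].mean())
    return mean_in / max(mean_out, 1e-6)
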
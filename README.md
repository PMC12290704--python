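# atrophynet

Attention-weighted deformation-based morphometry for longitudinal brain MRI.

## The problem

Deformation-based morphometry (DBM) measures structural change between two
scans of the same person by deformably registering them and applying the
resulting displacement field to a region of interest. Its weakness is that
*any* measured deformation — head motion, MRI artifacts, hydration shifts —
is booked as "change", even though only changes that are systematic in time
reflect neurodegeneration. `atrophynet` implements a trainable attention
model that learns, with no anatomical labels at all, **where** a fixed
deformation field carries genuinely time-linked change, and turns that into
an interpretable atrophy-rate biomarker.

Given a co-registered scan pair (fixed at time t1, moving at t2) and a dense
displacement field Φ(x) = x + u(x), a 3D U-Net emits three near-binary
attention maps — shrinkage S_SHR, expansion S_EXP, background — sharpened by
a temperature SoftMax (τ = 100). The deformation-induced volume change of a
region is computed through the field's Jacobian:

    V₁ = ∫ S(x) dx,   V₂ = ∫ S(x) |det ∇Φ(x)| dx,   A = V₂ − V₁

and the pooled change A_pooled = A_SHR − A_EXP (negative under forward-time
atrophy) is the per-pair progression measure. The network is trained purely
by temporal self-supervision:

* **STO (scan temporal order)** — a cross-entropy on the sign of A_SHR and
  A_EXP: was the pair presented in correct or reversed chronological order?
* **RISI (relative interscan interval)** — for two nested scan pairs of one
  subject, a four-class cross-entropy on the ratio of their change
  magnitudes (bins [0, 0.5], (0.5, 1], (1, 2], (2, ∞)), built from products
  of sigmoids over the ratio cones in the (A₁, A₂) plane.

Because nonsystematic confounds are independent of time, regions dominated
by them are useless for predicting temporal order and are pushed into the
background channel; normalising changes by the attended baseline volume
additionally penalises attention spent where the field carries no change.

Per subject, annualised atrophy rate is the slope of A_pooled against the
interscan interval over baseline-anchored pairs, divided by the baseline
attention volume; group contrasts use age-adjusted rates with one-sided
rank-sum tests and AUC.

A synthetic longitudinal-phantom generator stands in for clinical data:
ellipsoidal "tissue" (shrinking at a subject-specific rate r_j, linear in
time) and "fluid" (expanding) regions with analytic ground-truth
displacement fields, shared anatomy-like texture, noise, and optional
time-independent confounds (random warps, stripe/patch artifacts) for
exercising the SSIM < 0.6 quality-control path.

## Worked example

```python
from atrophynet.benchmark import end_to_end_recovery

metrics, ev, net = end_to_end_recovery(seed=0)
print({k: round(v, 3) for k, v in metrics.items()})
```

This generates a 60-subject phantom cohort (48³ voxels, 3–4 timepoints,
rates 0.5–8 %/yr), trains on 40 subjects (3 epochs, ~8 minutes on one CPU)
and evaluates the 20 held-out subjects. The run above prints:

```
{"sto_accuracy": 1.0, "sto_accuracy_all": 1.0, "risi_accuracy": 1.0,
 "rate_spearman": 0.988, "heatmap_shrink_enrichment": 1869.814,
 "heatmap_expand_enrichment": 128.073, "final_training_loss": 1.299}
```

Read: every held-out scan pair is temporally ordered correctly (both
presentation directions counted separately), every nested interval pair is
ranked correctly by change magnitude, recovered annualised rates track the
simulated rates with Spearman ρ ≈ 0.99, and the shrink heatmap is ~1900×
more frequent inside the true atrophying region than outside it (the
expand heatmap ~130× inside the region where the ground-truth field
expands; see `docs/methods.md` on why expansion attention prefers the
peritissue expansion shell over the distant fluid structure).

A thin CLI wraps the same library calls:

```bash
atrophynet simulate --n-subjects 10 --seed 0 --out cohort/
atrophynet train --n-subjects 40 --seed 0 --out run/
atrophynet evaluate --checkpoint run/checkpoint.npz --n-subjects 20 --seed 1 --out eval/
atrophynet infer --checkpoint run/checkpoint.npz --fixed f.nii.gz \
    --moving m.nii.gz --field phi.nii.gz --interval 1.5 --out pairA
```

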
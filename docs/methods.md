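# Methods

## Model

`atrophynet` treats longitudinal change measurement as a two-stage problem.
Registration is taken as given: each ordered scan pair (fixed at time t1,
moving at t2) arrives with a dense displacement field Φ(x) = x + u(x), in
physical mm, mapping fixed-image to moving-image coordinates, and Φ stays
fixed throughout. The trainable part is *where to look*: a 3D U-Net maps the
stacked (fixed, moving) intensities to three per-voxel logits, and a SoftMax
with temperature τ converts them to near-binary shrinkage / expansion /
background maps. Reversing a pair's presentation order is treated as a
separate sample with its own independently registered field, not the inverse
field — the attention network sees the images in the presented order and may
respond differently.

Volume change is read off the field through its Jacobian. For a soft region
s(x) on the fixed grid,

    v_fixed  = Σ_x s(x) · voxel_volume
    v_moving = Σ_x s(x) · |det ∇Φ(x)| · voxel_volume

where the second line is the change-of-variables form of "the volume the
region occupies after deformation". We use it instead of numerically
inverting Φ; the two are identical for diffeomorphic fields, and the
absolute value guards the rare negative determinants of noisy fields.
The per-pair measures are a_shr = v_moving − v_fixed of the shrink map,
a_exp likewise for expand, and the pooled change a_pooled = a_shr − a_exp.
Under forward time and real atrophy, a_shr < 0 and a_exp > 0, so a_pooled
is negative. (Some authors report atrophy with the opposite sign; every
sign-sensitive consumer in this package — order correctness, the ROC score
−a_pooled — is documented against this one convention.)

### Losses

Training is purely self-supervised by time:

* **Scan temporal order (STO).** Cross-entropy on two-logit pairs
  [−a_shr, a_shr] and [a_exp, −a_exp] against the order label
  y = sign(t2 − t1). At a_shr = a_exp = 0 the loss is exactly 2 ln 2; it is
  invariant under (a, y) → (−a, −y).
* **Relative interscan interval (RISI).** Two nested pairs of one subject
  (the shorter unordered interval contained in the longer, at most one
  shared endpoint) are pushed through two branches sharing the single
  weight store. The magnitude ratio of their changes is classified into
  four bins of |Δt12|/|Δt34| — [0, 0.5], (0.5, 1], (1, 2], (2, ∞) — via a
  differentiable construction: in the (a1, a2) plane each bin is a union of
  cones bounded by lines through the origin (2a1 ± a2, a1 ± a2, a1 ± 2a2),
  a bin's score is the maximum over the four sign orientations of the
  product of boundary sigmoids σ_α, and the four scores are renormalised to
  a simplex before the cross-entropy. The raw cone products do not sum to
  one by themselves, so the renormalisation is required for a proper
  distribution; in the α → ∞ limit the argmax equals exact ratio binning
  everywhere. A boundary ratio is assigned to the lower bin.

Both losses consume *fractional* changes: a_shr and a_exp are divided by
v_base = v_fixed(shr) + v_fixed(exp) (plus a 1 mm³ guard against an empty
attention map) before the sigmoids. This serves two purposes. Numerically,
raw mm³ values would saturate σ_α; fractionally, a sharpness of α = 50 puts
percent-level annual changes in the responsive range (a 2% vs 8% change
pair sits well inside the sharp-assignment regime). Behaviourally, it makes
attention expensive: covering voxels whose Jacobian carries no change
dilutes the fractional signal and *raises* the loss, which is what drives
the maps toward compact informative regions rather than everything-is-
shrinkage solutions.

The total objective per quadruple is w_sto·(STO₁ + STO₂) + w_risi·RISI with
default weights (1, 1). Setting w_risi = 0 gives the order-only ablation.

### Numerical implementation

No deep-learning framework is used: the U-Net and its training loop are
plain numpy with explicit backward passes. Convolutions (3³ and 1³ kernels,
stride 1, same padding) are im2col + BLAS matmuls; the input gradient of a
stride-1 convolution is itself a convolution with the flipped,
channel-transposed kernel, so no scatter-adds appear anywhere. Encoder
levels use one conv → instance-norm → leaky-ReLU block each with 2× average
pooling between levels; decoding uses nearest-neighbour 2× upsampling, skip
concatenation, a 1×1 projection block to collapse channels, then a 3³
block. Nearest upsampling (rather than trilinear) was chosen because its
adjoint is a trivial block sum and the following 3³ convolution provides
the smoothing; instance norm because batches are single volumes. The output
head is zero-initialised: an untrained net emits uniform class
probabilities, keeping the τ = 100 SoftMax unsaturated so gradients flow
from the first step (with a randomly initialised head, τ-scaled logits
saturate immediately and learning stalls). Default architecture is depth 3,
base width 8 (≈ 60k parameters), float32; shapes not divisible by the
pooling factor are zero-padded and cropped back at inference.

Jacobians use central differences in the interior, one-sided at borders,
scaled by the physical spacing. Voxel index i maps to physical
x = origin + i · spacing; fields are stored and consumed in mm,
fixed → moving. SSIM uses the canonical parameters (Gaussian window
σ = 1.5 voxels, K1 = 0.01, K2 = 0.03) with the dynamic range taken as the
pair's joint max − joint min, and pairs below 0.6 are rejected by QC.

### Optimisation

Adam on the shared weight store. The conservative full-scale defaults are
40 epochs at learning rate 1e-5; the phantom experiments in this package
run a desk-scale schedule (3 epochs, lr 1e-3, 2 quadruples per subject per
epoch, batches of 2 quadruples accumulated before each step), which is
where the 48³ task converges in a few hundred updates. Augmentation applies
the identical spatial transform to fixed image, moving image and field
(flip: spatial flip plus sign flip of the flipped vector component;
rotation: resampling plus rotation of the vectors; patch erasing at a
shared location; per-volume z-scoring always). Augmentation never alters
the order label or interval ratio. Branch roles of a quadruple are swapped
with probability ½ during sampling so that RISI target bins on both sides
of ratio 1 are exercised (enumeration canonically emits the nested pair
first). Training aborts with a diagnostic on non-finite loss.

## Downstream measures

Per-subject annualised rate: for one pair, (a_pooled / v_base) / Δt; for
several baseline-anchored pairs, the OLS slope of a_pooled against Δt
(free intercept by default — an intercept-free fit is a switch, since the
choice is genuinely open) divided by the v_base of the closest-to-baseline
pair. Pairs anchored at different fixed scans are rejected rather than
pooled. Age adjustment residualises rate against age using a reference-
group linear fit. Group contrasts use the one-sided Mann–Whitney/Wilcoxon
rank-sum test (alternative: more negative rates in the comparison group),
exact for small tie-free samples (combined n ≤ 25) and the tie-corrected
normal approximation otherwise, plus the AUC of −rate.

Heatmaps: each test pair's fixed-image attention maps are binarised at 0.5
(they are near-binary by construction), pulled into template space through
the known per-subject warp, and averaged voxel-wise with an explicit
coverage denominator, so template voxels seen by fewer pairs cannot exceed
frequency 1. Only fixed-image maps (not both registration directions)
enter the aggregate.

## The phantom: what it emulates, and what it does not

Each synthetic subject carries a bright "tissue" ellipsoid losing volume
linearly at a subject-specific rate r_j (drawn from 0.5–8 %/yr, spanning
healthy-to-impaired regimes) and a darker "fluid" ellipsoid gaining volume
at a coupled rate, on a 48³ grid at 1 mm spacing; 2–4 visits (default 3–4)
at 0.5–2-year spacings; a per-subject rigid jitter (±1.5 mm) whose inverse
is the known template warp; a subject-specific smooth background texture
shared across that subject's visits (real scan pairs share fine anatomy
everywhere — without this, SSIM of perfectly aligned pairs sits far below
the QC band, with it they score ≈ 0.8); and 5% Gaussian noise per scan.
Linear-in-time volume change is a deliberate simplification, defensible at
annual rates of a few percent. Ground-truth pair fields are uniform
scalings about each region's centre, exact inside the region and blended
smoothly to the identity across a support shell (scaled elliptic radius 1
to 1.4); the two regions' supports are verified disjoint at spec
validation, so the superposition is still exact per region. Optional
time-independent confounds (random smooth warps, sinusoidal stripes,
overwritten patches) perturb rendered scans only — never masks, fields or
rates — and a "severe" preset reliably lands below the SSIM 0.6 threshold
to exercise the rejection path.

Because the field is identity outside each support shell, the volume a
tissue region loses reappears exactly in its blend shell. The trained
expansion attention therefore concentrates on that peritissue shell rather
than the small distant fluid structure — a correct reading of the training
signal (the shell's time-linked expansion is several times larger than the
fluid's), and an analogue of expansion attention hugging the CSF interfaces
adjacent to atrophying tissue. Evaluation accordingly scores expansion
enrichment against all voxels where the truth field expands (fluid plus
shells); shrinkage enrichment is scored against the tissue region alone.

What the phantom does *not* emulate: MRI physics (bias fields, k-space
artifacts, partial-volume spectra beyond a soft rendered edge), anatomical
shape variability, nonrigid inter-subject differences (the template warp is
a translation), registration error in the supplied fields (they are exact),
or scanner upgrades and other *systematic* non-biological change. Passing
the end-to-end tests therefore demonstrates that the machinery — losses,
backprop through the volume operators, rate estimation, heatmap
aggregation — recovers known ground truth under realistic noise and
time-independent confounds; it does not certify performance on clinical
data, where registration error and anatomy dominate. A hook for externally
computed fields (any NIfTI vector field in mm) exists precisely so a real
registration backbone can be substituted without code change.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| τ (SoftMax temperature) | 100 | — | near-binary maps; gap 0.06 → winner ≥ 0.995 |
| α (sigmoid sharpness) | 50 | per unit fractional change | percent-level annual changes land in the transition region |
| RISI bin edges | 0.5, 1, 2 | ratio | four-way interval-ratio classification |
| loss weights (w_sto, w_risi) | 1, 1 | — | equal weighting; (1, 0) is the ablation |
| SSIM threshold | 0.6 | — | below it pairs are treated as misregistered |
| U-Net depth / width | 3 / 8 | levels / channels | smallest net that solves the 48³ task; both free |
| learning rate / epochs | 1e-5 / 40 (desk: 1e-3 / 3) | — | conservative full-scale vs. phantom scale |
| v_base guard ε | 1.0 | mm³ | keeps fractional changes finite for empty maps |
| rate_range | 0.005–0.08 | /yr | control-to-impaired regimes |
| interval windows (group analysis) | 180–400, 400–800 | days | one- and two-year follow-up scenarios |

## Known limitations

* The numpy U-Net is single-sample and CPU-bound; it is sized for desk-
  scale volumes (≈ 0.5 s per 48³ forward+backward) and would need a GPU
  framework for full-resolution clinical cohorts.
* The cone construction for the middle RISI bins uses wedge pairs under a
  four-orientation max; between wedges of *different* categories the soft
  probabilities are exchangeable only up to the sigmoid overlap, which is
  why accuracy guarantees exclude a 10% margin around bin edges.
* Rank-sum p-values switch from exact to asymptotic at combined n = 25;
  at that boundary p-values can shift in the third decimal.
* The heatmap uses only fixed-image attention maps; aggregating both
  registration directions would roughly double the sample at the cost of
  mixing the two attention conventions.
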
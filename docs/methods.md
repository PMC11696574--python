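# Methods

This note records what `mskseg` computes, the modelling assumptions behind
each stage, the default parameters and why they were chosen, and the known
limits of the approach. It is written for a reader who wants to audit the
numbers the package produces.

## Pipeline overview

`mskseg` segments paired (left/right) musculoskeletal structures in CT,
quantifies how *sure* the model is about each structure, and uses that
uncertainty to detect segmentation failures without ground truth:

1. **Segmentation** — a 2D Bayesian U-Net labels each axial slice with
   side-agnostic structure classes.
2. **Uncertainty** — Monte-Carlo dropout sampling (MCDS): T stochastic
   forward passes are fused into one segmentation plus a voxel-wise
   uncertainty map; per-structure uncertainty is the mean over the
   structure's predicted voxels.
3. **Side resolution** — each bilateral class is split into left/right
   instances by connected-component analysis, falling back to a
   distance-transform watershed when the sides touch.
4. **Biomarkers** — volume, height-normalized volume, mean HU and
   fat/composite/lean composition per structure instance.
5. **Evaluation** — Dice (DC), average surface distance (ASD), absolute
   volume error (AVE), absolute intensity error (AIE), concordance (CCC,
   Pearson), and an adaptive paired test with Bonferroni correction.
6. **Failure detection** — robust Dice outlier thresholds, a
   DC–uncertainty regression, inverted uncertainty cut-offs, and AUROC.

All volumes use the axis order `(z, y, x)` with the patient's left at +x.

## Segmentation model

The network is a U-Net operating on 2D axial slices (a volume is processed
slice by slice and re-stacked). Each encoder level is two blocks of
3×3 same-padding convolution → batch normalization → ReLU, followed by an
elementwise dropout layer; levels are connected by 2×2 max pooling. Each
decoder level is a 2×2 stride-2 up-convolution concatenated with the
matching encoder feature map, followed by one conv–BN–ReLU block. A 1×1
convolution and softmax yield per-pixel class probabilities. Inputs whose
in-plane size is not divisible by 2^(levels−1) are zero-padded internally
and the logits cropped back.

The implementation is pure NumPy with hand-written backpropagation
(im2col + GEMM convolutions, Adam optimizer). This keeps the package free
of deep-learning framework dependencies and fully deterministic given a
seed; the cost is speed, which bounds the problem sizes below.

*Why "Bayesian":* keeping dropout active at test time makes each forward
pass a sample from an approximate posterior over networks; the spread of
those samples estimates model (epistemic) uncertainty.

**Defaults** (`ModelConfig`): 5 encoder levels (6 supported), base width 64
channels doubling per level, dropout rate 0.2, batch norm on, HU window
(−150, 350) mapped linearly to [0, 1]. The window brackets the soft-tissue
range where muscle (≈30–80 HU), fat (≈−100 HU) and contrast boundaries
live; dropout 0.2 is large enough to give a usable sample spread at T=10
without crippling accuracy. The experiment-scale default
(`ExperimentConfig`) shrinks the base width to 8 channels so a full study
trains in minutes on one CPU; the architecture is otherwise identical.

Training samples random axial slices (batch 3), with cross-entropy loss by
default (soft-Dice and combined losses are available), optional left-right
flip augmentation, and optional class weights.

## MC-dropout sampling and uncertainty

`mcds_predict` draws T samples (default 10); sample t uses an RNG stream
derived from `(seed, t)`, so the first T′ samples of a longer run are
bit-identical to a T′-sample run. The fused label is the argmax of the
mean class probabilities.

**Voxel uncertainty (default): mean per-class variance.** For each voxel,
the sample variance of each class's probability is averaged over classes.
The alternative — variance of only the fused (argmax) class — is available
via `per_class_variance=False`, but measured markedly worse on the phantom
study: with fused-class variance the case-level failure AUROC dropped to
≈0.6 and the DC–uncertainty correlation became unstable across seeds,
because confident-but-wrong voxels can have low variance in the winning
channel while the inter-class competition shows up in the losing channels.
The per-class mean restores AUROC ≈1.0 and a strong negative correlation,
so it is the default.

An entropy mode (−Σ p ln p, nats, from a single deterministic pass) is
provided for comparison; it measures the *softness* of one prediction, not
the spread across samples.

**Structure uncertainty** is the mean voxel uncertainty over the
structure's *predicted* voxels. A structure with no predicted voxels gets
NaN, never zero — absence is itself a failure signal, and downstream
screening flags such cases as failed.

**Sample count.** Accuracy plateaus quickly: in the frozen study the mean
Dice of clean test cases changes by less than 0.001 between T=10 and T=20
(see `results/acceptance.json`), so T=10 is the default.

## Side resolution

Bilateral structures are trained as one class; `split_sides` recovers
instances. With ≥2 connected components (6-connectivity by default) the
two largest become left/right by centroid x; smaller satellites merge into
the nearer instance unless below an explicit minimum size. A single
component — the sides touching, as hemi-pelvises do at the pubic
symphysis — is split by watershed on the negated Euclidean distance
transform, seeded with the deepest point on each side of the component's
centroid sagittal plane; a midsagittal cut is the last resort. Every split
records provenance (component count, method, warnings), and voxels are
conserved exactly except for explicitly dropped satellites.

## Biomarkers

Volume is voxel count × voxel volume (cc). Height-normalized volume
divides by height^e with e=2 by default (cc/m², the body-composition
convention analogous to BMI); e=1 (cc/m) is supported and the unit string
is always emitted so the convention is never implicit. Mean HU is the
unweighted mean of raw HU inside the label. Density composition uses the
standard bands: fat < −30 HU, lean muscle > 30 HU, muscle/fat composite in
[−30, 30] (boundaries inclusive to composite). A deterministic
color/opacity transfer table with breakpoints at exactly ±30 HU supports
volume rendering of muscle density.

## Evaluation metrics

- **DC** = 2|A∩B|/(|A|+|B|); both-empty is defined as 1 with a warning.
- **ASD**: boundary voxels are face-adjacent erosion residues; distances
  use the anisotropic voxel spacing; the symmetric mean is weighted by
  boundary size. Empty masks raise — there is no meaningful surface.
- **AVE** = 100·|V_pred − V_gt|/V_gt (%); **AIE** = |HU_pred − HU_gt|.
- **CCC** is Lin's coefficient with population moments; degenerate series
  raise rather than return 0/0.
- **compare_groups**: Shapiro-Wilk on both groups (and the paired
  differences) chooses paired t-test vs Wilcoxon signed-rank (rank-sum
  when unpaired); the significance level is α/n_comparisons (Bonferroni).
  Under 2000 null simulations the realized type-I error is ≈0.055,
  consistent with the nominal 0.05 (the Shapiro gate adds slight
  anti-conservatism; see `tests/test_acceptance.py`).

## Failure detection

On an annotated cohort the Dice distribution defines robust outlier
thresholds DC\* = median(DC) + 1.4826·k·MAD(DC) with k=−2 ("inaccurate")
and k=−3 ("failed"); 1.4826 rescales MAD to an SD equivalent under
normality. AUROC of uncertainty for detecting DC < DC\* is the exact
normalized Mann-Whitney U statistic (ties credit 0.5); it is `None` when a
class is empty, never a fabricated number. An OLS line DC = a + b·u
(b must be negative) inverted at DC\* gives uncertainty cut-offs
u\* = (DC\*−a)/b that screen *unannotated* cases: mean structure
uncertainty above u\* flags the case, and any missing structure flags it
failed outright.

**Case-level aggregation.** The headline AUROC is computed per case (mean
DC vs mean uncertainty over the case's structures) in addition to the
per-record level. Averaging cancels per-structure noise and matches how a
screening decision is actually made — per scan, not per structure. In the
frozen study the case-level AUROC is 1.0 on all three seeds while the
record level is 0.87–0.99.

## The phantom, and what it can and cannot show

Real training data cannot ship with the package, so all end-to-end claims
are made on a synthetic phantom: mirror-placed ellipsoid pairs plus a
midline structure with Gaussian HU distributions (defaults 60/45/−100/300
HU over a 0 HU background, noise SD 20), exact left-right symmetry, an
optional cross-midline bridge, and a corruption operator that blends
structure voxels toward the background distribution (level 0 = identity,
1 = indistinguishable) as a severity surrogate for disease/domain shift.

The frozen study (`ExperimentConfig`) trains on 15 phantoms with
corruption 0.0–0.5 — a training database that itself contains
mild-to-moderate "disease" — and tests on 25 phantoms of which 10 are
corrupted at 0.7–0.9, i.e. beyond anything seen in training. Grid
16×64×64 at (3.0, 1.5, 1.5) mm, 800 iterations, T=10. These sizes are this
package's choice, picked so the full three-seed study runs in ≈8 minutes
on one CPU while leaving clear headroom on every acceptance threshold.

Limits: ellipsoids have none of the thin, interdigitated geometry of real
muscles; HU distributions are stationary Gaussians (no bias fields, beam
hardening, metal artifacts); corruption is spatially uniform; cohorts are
small. Absolute accuracy numbers therefore do not transfer to clinical
CT — what the phantom establishes is the *internal consistency* of the
pipeline: metrics match oracles, uncertainty tracks induced degradation,
and the failure-detection machinery recovers exactly the cases that were
degraded.

## Reproducibility

Every stochastic component takes an explicit seed (NumPy `SeedSequence`
streams); phantoms are pure functions of their spec, training of its
config and data, and MCDS of `(seed, sample_index)`. The acceptance script
(`python scripts/acceptance.py --seed 1 --out results/acceptance.json`)
re-runs the full study and rewrites every headline number.
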
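# Methods

## Scope and model

`datgen` implements early-to-delayed [18F]-FP-CIT PET translation as a
conditional GAN and everything required to evaluate it on synthetic data:
phantom simulation, preprocessing, training/inference, striatal
quantification, and evaluation statistics. Scanner acquisition and
reconstruction, automated VOI segmentation, image registration, and human
visual reading are out of scope; atlases are supplied inputs and phantom
volumes are generated aligned.

## Phantom

The phantom is a voxelized head on a 64×64×48 grid of 2 mm isotropic voxels
(axial index 0 = most superior slice): a large brain ellipsoid (cortex), a
posterior occipital ellipsoid (the reference region), and per-hemisphere
ellipsoids for caudate (CA), anterior putamen (AP), posterior putamen (PP)
and ventral striatum (VS). The right hemisphere is the exact mirror of the
left, so symmetry properties are exact by construction; subregions are
painted with fixed precedence so label codes are disjoint.

### Time-activity curves

Region SUV over time follows minimal functional forms that reproduce the
qualitative kinetics of the tracer — a declining reference and a
rising-to-plateau striatum whose contrast over the reference grows with
time:

* occipital: `A·exp(−t/τ) + B` with A = 3, τ = 60 min, B = 0.5;
* cortex: 0.95 × occipital;
* striatum: `1.1 × occipital(t) + S·(1 − exp(−t/τ_s))·f`, S = 4.5
  (VS: 3.8), τ_s = 60 min.

No quantitative FP-CIT TAC parameters are published for these time points,
so the defaults were fixed once to give a normal delayed putaminal SUVR of
about 7.7 (painted value; partial-volume blur lowers the measured value) —
inside the intended 6–8 band so the SUVR-10 cap is engaged occasionally but
not saturated — and an early-phase striatal SUVR near 2 that exceeds the
reference. Every phantom-based claim in the test suite is therefore
*relative* (orderings, correlations, recovery), never an absolute SUV.

### Degeneration patterns

DP multiplies the specific-binding term by `f = 1 − severity·g_region` with
gradient weights g = 0.90 (PP), 0.70 (AP), 0.35 (CA), 0.20 (VS), giving the
posterior-putamen-dominant, ventrodorsally graded loss pattern; the
perfusion term is left intact, so early frames carry an attenuated copy of
the disease signal — exactly the information the translation model must
exploit. Asymmetry shifts severity by ±a/2 between hemispheres. The non-DP
pattern instead draws 1–3 random (subregion, hemisphere) lesions with a
uniform factor in [0.3, 0.7] and no gradient. Cohort severities: normal 0,
DP uniform on [0.4, 0.9] with asymmetry on [0, 0.3].

### Noise and resolution

Volumes are blurred with a 6 mm FWHM Gaussian (a typical post-filtered
clinical resolution) and receive additive Gaussian noise (default
SD 0.1 SUV) after the blur; reconstructed PET noise is approximately
Gaussian at this stage and no count-domain model is claimed. All randomness
flows from a single per-study seed; per-subject seeds in cohorts derive
deterministically from the base seed.

### What the phantom does not emulate

Piecewise-constant region interiors, no anatomical texture, no motion, no
scatter/randoms, no projection-domain physics, perfectly aligned dual-phase
volumes, and a shared atlas geometry across subjects. Consequently the
translation task is easier than on patient data: passing tests show the
pipeline is wired correctly and preserves the quantitative disease signal
under blur and noise, not that clinical-grade synthesis accuracy has been
reached.

## Preprocessing

* Delayed volumes are divided by the occipital-VOI mean (SUVR), clipped at
  SUVR 10 and mapped linearly to [−1, 1] (`x/5 − 1`); the inverse map is
  exact on the valid range.
* Early frames are min-max scaled to [−1, 1]. The scaling scope is a config
  option; the default is one (min, max) per subject across all five frames,
  which preserves inter-frame kinetic contrast (per-frame scaling would
  erase it). The (min, max) pairs are retained so inference can invert
  exactly.
* The analysis slab spans a fixed field of view downward from the skull
  vertex (topmost slice whose maximum exceeds 5% of the volume maximum — a
  proxy for scanner FOV placement), minus the top 3 and bottom 2 slices. At
  2 mm spacing the clinical 150 mm FOV gives 75 − 3 − 2 = 70 slices; for the
  96 mm-tall phantom grid the packaged default is a 90 mm FOV (40 slices),
  tolerant of the vertex landing a few slices below the grid top.
* Each scaled frame is expanded to three resolution channels: original plus
  4 mm and 8 mm FWHM Gaussian-smoothed copies (σ = FWHM/(2√(2 ln 2))/voxel).
  Smoothing is applied after scaling with nearest-edge extension, so outputs
  remain convex combinations of in-range values and stay within [−1, 1].
* A training sample stacks 5 consecutive axial slices × 5 frames × 3 scales
  = 75 channels (slice-major, then frame, then scale) against the central
  delayed slice; a slab of n slices yields n − 4 samples, with no padding at
  training time. A config switch sums the five 2-min frames into a single
  10-min early image (15 channels) for the single-early-image reading of the
  design.

## Network and training

Because no deep-learning framework ships with the package's runtime
dependencies, the network engine is a small numpy implementation
(`datgen.nn`): 4×4 convolutions and transposed convolutions (im2col/GEMM),
instance normalization, LeakyReLU, tanh, inverted dropout, and Adam.
Analytic gradients of every layer — and of the full generator and
discriminator — are verified against central finite differences in the test
suite (with a small step, since LeakyReLU kinks and instance-norm curvature
dominate the difference at larger steps).

Generator: depth-4 U-Net for 64×64 slices (bottleneck 4×4), channel
multipliers 1/2/4/8 capped at 8×, instance norm omitted on the first encoder
layer, dropout rate 0.5 at decoder levels whose feature maps are smaller
than 64×64, tanh output. Dropout is disabled at inference so volumetric
generation is a deterministic function of the input. Discriminator: 3-layer
patch classifier on the 76-channel (condition + slice) stack, scored with
binary cross-entropy on logits; a least-squares variant is available by
flag. Adversarial-loss details, Adam β₁ = 0.5, stride-2 down/up-sampling and
the per-level filter counts are conventional conditional-GAN choices.

Training alternates one discriminator and one generator update per sample
(batch size 1), with the discriminator loss halved across its real/fake
terms. Augmentation applies one random rotation (±10°), shear (±5°) and
scale (0.95–1.05) identically to all 75 input channels and the target.
Weight init N(0, 0.02²), float32 throughout. With a fixed seed and
single-threaded BLAS, training is bit-reproducible; histories record mean
L1, adversarial, total and discriminator losses per epoch.

Inference slides the generator along the axial axis, replicate-padding the
slice axis by two on each end so every slab slice gets a prediction, then
inverse-scales tanh outputs to SUVR in (0, 10).

## Quantification

SNBR = (mean_region − mean_occipital)/mean_occipital. This is the standard definition
used in striatal DAT quantification. Whole striatum and
putamen are computed over union masks (not averages of subregion SNBRs);
bilateral values are the mean of hemispheres, which is the primary reported
value (per-hemisphere values are retained). ISRs are ratios of bilateral
SNBRs — CA/P, PP/AP, CA/VS ("C" read as caudate), P/VS — with non-positive
denominators flagged undefined rather than dropped. On noise-free phantoms
the recovered reduction factors are biased toward unity by partial-volume
blur; tests therefore assert orderings and monotonicity, not painted values.

## Statistics

* PSNR = 10 log₁₀(Max²/MSE) with Max the real (reference) volume maximum;
  flagged infinite at MSE 0, undefined for an all-zero reference.
* SSIM: the standard Wang et al. form, per axial slice with an 11×11 Gaussian
  window (σ 1.5), K1 = 0.01, K2 = 0.03, averaged over slices; the window
  shrinks to fit very small test slices.
* ROC-AUC: tie-aware Mann–Whitney rank form; callers negate markers that
  decrease with disease. AUC comparison: paired permutation test swapping
  real/generated scores within subject with probability ½,
  p = (1 + #{Δ* ≥ Δ})/(B + 1).
* Diagnostic metrics use Wilson score 95% CIs — this choice was validated by
  recomputing published example intervals exactly before adoption. Zero
  denominators flag the metric undefined.
* McNemar: exact binomial two-sided test on the discordant counts (paired
  samples here are small); p = 1 when there is no discordance.
* Fleiss' kappa with the large-sample H0 standard error (Fleiss 1971);
  Cohen's kappa with SE ≈ √(p_o(1−p_o)/(N(1−p_e)²)). Both SEs are
  approximations adequate for the z-comparison of two kappas,
  z = (κ₁−κ₂)/√(SE₁²+SE₂²).

## Problem sizes and numerical choices

The packaged recovery experiment uses 30 subjects (15 normal / 15 DP),
64×64×48 grids, training samples taken at slice stride 2 (18 per subject),
generator base filters 8, and 10 epochs — a deliberately small configuration
chosen so the full simulate→train→generate→quantify loop runs in minutes on
one CPU while still exercising every stage at full fidelity. At this scale
the generated posterior-putamen SNBR reproduces ground truth with Pearson
r ≈ 0.999 and separates DP from normal with AUC 1.0 (the task is nearly
voxelwise-linear on the phantom; see the phantom-limitations note above for
why patient data would be harder). Tolerances: scaling round-trips asserted
to float32 precision; symmetry checks to 1e-5; rank/counting oracles to
1e-12; Monte-Carlo agreement to 3 standard errors.

## Known limitations

* The numpy engine is single-image (batch 1) and CPU-only by design.
* The phantom's piecewise-constant anatomy understates the difficulty of
  the clinical task; reported recovery numbers are not clinical claims.
* Kappa standard errors use large-sample approximations.
* No registration: volumes must share a grid.
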
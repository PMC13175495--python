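# datgen

Early-to-delayed [18F]-FP-CIT PET translation on a synthetic dual-phase
kinetic brain phantom: a 2.5D conditional GAN, striatal binding-ratio
quantification, and the statistical machinery to evaluate generated against
real delayed-phase images.

## The problem

[18F]-FP-CIT binds the dopamine transporter (DAT) on striatal nerve
terminals. Clinically, a *delayed-phase* image at 180 min post-injection is
what shows DAT binding — and hence the posterior-putamen-dominant,
ventrodorsally graded binding loss of degenerative parkinsonism (DP) — but
keeping movement-disorder patients in the department for three hours is a
real burden. The *early phase* (30–40 min p.i., five 2-min frames) is
perfusion-dominant yet already carries attenuated binding information.

`datgen` implements an image-to-image translation model that maps the early
frames to the delayed image, plus everything needed to exercise and judge it
without patient data:

* **phantom** — a synthetic dual-phase study generator: a voxelized head with
  occipital reference and striatal subregions (caudate CA, anterior/posterior
  putamen AP/PP, ventral striatum VS, per hemisphere), region time-activity
  curves (occipital `A·exp(−t/τ)+B`, striatum perfusion + saturating specific
  binding `S(1−e^{−t/τ_s})·f`), DP/non-DP degeneration patterns, resolution
  blur and noise.
* **preprocess** — occipital-SUVR normalization with the cap at SUVR 10
  mapped linearly to [−1, 1]; per-subject min-max scaling of early frames;
  15 cm slab selection from the skull vertex (top 3 / bottom 2 slices
  dropped); multi-scale channels (original, 4 mm, 8 mm FWHM smoothed); 2.5D
  sample assembly (5 slices × 5 frames × 3 scales = 75 channels → 1 central
  delayed slice).
* **gan** — U-Net generator (stride-2 encoder/decoder, skip connections,
  instance norm, LeakyReLU 0.2, tanh output, dropout 0.5 below 64×64) and a
  patch discriminator, trained with
  `L_total = λ_GAN·L_GAN + λ_L1·L_L1` (λ_GAN = 1, λ_L1 = 100), Adam
  (lr 2·10⁻⁴, β₁ 0.5), batch size 1, rotation/shear/scale augmentation, and
  sliding-window volumetric inference. The network engine (convolutions,
  backprop, Adam) is implemented in numpy within the package.
* **quant** — SNBR = (mean_region − mean_occipital)/mean_occipital per
  subregion and hemisphere, whole-striatum and putamen over union masks, and
  the four inter-subregional ratios CA/P, PP/AP, CA/VS, P/VS.
* **stats** — PSNR/SSIM/RMSE, Pearson r, Mann–Whitney ROC-AUC with a paired
  permutation test for AUC differences, confusion-matrix diagnostics with
  Wilson 95% CIs, exact McNemar, Fleiss' and Cohen's kappa with z-tests.

## Worked example

```python
import numpy as np
from datgen import phantom, preprocess, gan, quant, stats

studies = phantom.simulate_cohort(4, 4, 0, base_seed=11)
pcfg = preprocess.PreprocessConfig.for_phantom()
samples = [s for st in studies
           for s in preprocess.make_training_samples(st, pcfg)[::2]]
model = gan.train(samples, gan.GeneratorConfig(base_filters=8),
                  tcfg=gan.TrainConfig(epochs=10, seed=1))

real, gen, labels = [], [], []
for st in studies:
    prep = preprocess.prepare_study(st, pcfg)
    vol = gan.generate_volume(model, prep)          # SUVR volume in (0, 10)
    atlas = phantom.RegionAtlas(st.atlas.labels[prep.slab], st.atlas.voxel_mm)
    suvr = preprocess.normalize_suvr(st.delayed,
                                     st.atlas.mask("occipital"))[prep.slab]
    real.append(quant.snbr_table(suvr, atlas).bilateral("PP"))
    gen.append(quant.snbr_table(vol, atlas).bilateral("PP"))
    labels.append(st.meta.subject_class == "DP")

print("PP SNBR real     ", np.round(real, 2))
print("PP SNBR generated", np.round(gen, 2))
print("Pearson r =", round(stats.pearson_r(real, gen), 3))
print("AUC (generated) =", stats.roc_auc([-v for v in gen], labels))
```

On the full 30-subject experiment (15 normal / 15 DP, seed 1, 10 epochs)
this pipeline prints per-epoch L1 falling from 0.101 to 0.016, ground-truth
posterior-putamen SNBRs around 4.2 for normal subjects versus 1.0–2.7 for
DP, generated SNBRs tracking them with Pearson r = 0.999, and ROC-AUC 1.0
for DP-vs-normal from the generated volumes — i.e. the translation preserves
the quantitative disease signal the phantom encodes.

The same workflow is scriptable from the shell:

```bash
datgen simulate --out cohort/ --seed 1 --n-normal 15 --n-dp 15
datgen train --data cohort/ --out model/ --seed 1
datgen generate --model model/ --early cohort/sub-000 --out gen000.nii.gz
datgen quantify --volume gen000.nii.gz --atlas cohort/sub-000/atlas.nii.gz --out snbr.csv
datgen evaluate --real cohort/ --generated gen/ --out report/
```

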
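# Methods

## Measurement model

The quantities of interest describe the neuromelanin-rich SNc in an axial
NM-MRI slab. All grids are indexed `(x, y, z)` with slice `z = 0` the most
inferior; default voxel size 0.35 × 0.35 × 3 mm with 7 slices.

**Consensus ROI.** Two raters each delineate the SNc per hemisphere. The
working ROI is the voxelwise mean of the two binary masks thresholded
inclusively at 0.5 — i.e. the union for two raters, the common dialect of
mask-averaging command-line tools. The alternative (intersection) is one
argument away (`consensus_threshold > 0.5`); which binarization the original
protocol used is not documented, so the tool exposes both.

**Slice selection.** Measurements use the three most-inferior slices of the
most-inferior contiguous run (length ≥ 3) of non-empty consensus slices.
Isolated stray slices below that run are treated as segmentation noise,
consistent with a protocol that requires contiguous contours.

**CNR.** Per selected slice, `(Sig_SNc − Sig_BND) / STD_BND` with `Sig` the
ROI mean intensities and `STD_BND` the *sample* (n−1) standard deviation of
the background ROI (tegmentum/peduncle band); the slice values are averaged,
not pooled — literal to the defining formula. CNR is invariant under affine
intensity rescaling and dimensionless.

**Volume and C_vol.** Volume is the consensus voxel count on the selected
slices times the voxel volume (mm³). `C_vol = volume[mm³] / TIV[mL]`; the
mm³/mL convention is fixed by the magnitudes involved (≈ 394 mm³ / 1460 mL ≈
0.27). Left and right hemispheres are measured separately and averaged; all
configured volume targets are on that per-hemisphere averaged scale.

**Regional measures.** The whole-SNc consensus is intersected with three
disjoint territory templates (dorsolateral sensorimotor, ventral associative,
dorsomedial limbic). Regional CNR reuses the whole-SNc slice set; slices where
an intersection is empty are skipped with a warning and a fully empty region
is recorded as missing. In synthetic space the templates partition the whole
grid, so regional volumes always sum exactly to the whole-SNc volume —
registration to a population template, which breaks that additivity in real
data, is deliberately out of scope.

**Reliability.** Dice `2|A∩B|/(|A|+|B|)` (two empty masks count as 1, with a
warning) and ICC(2,1) — two-way random effects, absolute agreement, single
measurement, computed from the two-way ANOVA mean squares. Absolute agreement
is the convention for test–retest of a single rater; it penalises constant
offsets, which a consistency ICC would forgive. With one simulated session
per rater, the pipeline's reliability table reports the inter-rater grid
(Dice, ICC for volume and CNR).

## Synthetic cohort

The generator emulates the study conditions rather than radiological realism:
no bias fields, partial-volume effects or MR physics.

- **Background**: homoscedastic Gaussian, N(100, 10²) by default, so the CNR
  estimator is analytically checkable; the background ROI is a fixed
  rectangular band ventral to the SNc (≥ 50 voxels per slice on every slice).
- **SNc geometry**: per hemisphere and slice, a half-ellipse footprint dorsal
  to the band, midline-centred bilaterally, occupying slices 2–4 of 7. Truth
  masks are built by ranking candidate voxels by elliptical distance, so any
  requested voxel count yields a compact, simply connected footprint.
- **Raters**: a rater mask is the super-level set `{d + A·η > 0}` of the
  truth's signed in-plane distance `d` plus a smooth Gaussian random field
  `η` (SD 1, correlation length ≈ 2 mm). The amplitude `A` is bisected per
  draw so the realized Dice against the truth matches the target (0.81 by
  default, the reported inter-rater overlap); each slice then keeps its
  largest component with holes filled, preserving simply connected contours.
- **Group distributions**: per-subject contrast and volume targets are drawn
  from the configured group normals (defaults: CNR 1.51±0.19 / 1.38±0.19 /
  1.32±0.13; volume 394.2±57.4 / 359.4±62.6 / 324.6±60.8 mm³ for HC /
  carriers / PD), truncated to positive values. TIV ~ N(1460, 130²) mL shared
  across groups (1460 mL is the value implied by C_vol ≈ 0.27 at 394 mm³;
  130 mL is a typical adult between-subject SD). Age and sex follow the
  demographic defaults; 8/15 of carriers are G2385R, the rest R1628P.
  Contrast and volume are drawn independently within subject (no
  cross-measure covariance is modelled, and none is reported to emulate).

### Measurement-referenced calibration

The configured group means are *measured* quantities — what the pipeline
reports after rater consensus — not properties of the hidden truth. A union
consensus of two raters at Dice 0.81 is systematically larger than either
rater's mask and dilutes contrast with non-SNc voxels, so placing the target
volume and contrast directly in the truth would bias the measured values by
10–25%. The cohort generator therefore calibrates each phantom to the
measurement scale:

- **Volume**: the true-mask voxel count is bisected (with the rater noise
  fields held fixed) until the realized consensus voxel count matches the
  subject's volume target; the residual is a few voxels (≪ 1%).
- **Contrast**: after the masks are fixed, the contrast actually placed in
  the truth is the target divided by the consensus *purity* (the slice-mean
  fraction of consensus voxels that are truly SNc), making the expected
  measured CNR equal to the target exactly.

`generate_phantom` itself stays literal — it places exactly the requested
true volume (to the nearest voxel) and contrast — so ground-truth-based
experiments remain possible; the calibration lives in `generate_cohort`.
Empirically the pipeline recovers the configured HC mean CNR to within ~0.01
and the mean volume to within ~0.5% at n = 200. Two geometric consequences
are worth knowing: the *true* masks are smaller than the measured volumes
(the union consensus makes up the difference), and the realized inter-rater
Dice is ≈ 0.70 — with a union consensus it is geometrically impossible to
hold per-rater-vs-truth Dice, inter-rater Dice and consensus-neutrality at
0.81 simultaneously, and the per-rater calibration plus measurement-scale
convergence are the properties the validation relies on.

### Clinical scores

Within each group, scores are conditional-Gaussian draws given the
(standardized) imaging measures: for targets `r` (score vs each measure) and
measure correlation `Σ`, the score's latent value is `Z Σ⁻¹ r + √(1 − rᵀΣ⁻¹r)·ε`,
scaled to the group's score mean/SD. Scores are conditionally independent
given the measures, and infeasible joint targets (negative conditional
variance) raise an error naming the offending pair. Inside `generate_cohort`,
`Σ` is the *structural* population matrix (volume–C_vol correlation implied by
the configured coefficients of variation, CNR independent) rather than the
small-sample empirical matrix, which at n = 15 is noisy enough to make valid
targets spuriously infeasible. Scores stay continuous by default — rounding
and clipping attenuate Pearson correlations — so UPDRS-like scores can be
negative when the group SD exceeds the mean; the `integerize_scores` flag
(off by default) rounds and clips for display realism at the cost of
correlation fidelity.

## Inference

- ANOVA/t/χ² delegate to scipy; ANCOVA builds the design explicitly
  (HC-reference group indicators, sex coded M=1) and tests the group term by
  the 2-df partial F of full vs reduced OLS fits, with covariate-adjusted
  means evaluated at the sample covariate means.
- Post-hoc pairwise tests are pooled-variance Student t-tests, *gated*: they
  run only when the omnibus p < α and are reported missing otherwise
  (Fisher's LSD when gated on the omnibus). No correction is applied across
  measures.
- ROC AUC uses midrank Mann–Whitney with a direction convention: lower
  measure ⇒ disease-positive, so effective markers score above 0.5.
- Permutation FWE: one family per (group, measure) = the clinical scores
  tested against that measure. The measure's subject order is permuted
  (default 10,000 draws; exhaustive enumeration available for tiny n), each
  permutation records the family max |r|, and p = (1 + #{max ≥ |r_obs|}) /
  (n_perm + 1), so p ≥ 1/(n_perm+1) and p is monotone in |r|. Pairs with
  fewer than 5 complete cases (3 in exact mode) or zero variance are missing.
- Trend band: p ∈ (0.05, 0.09] is flagged `#`, significant p < 0.05 as `*`.

## Numerical and reproducibility choices

- One master seed; per-subject streams come from counter-based
  `SeedSequence(seed, spawn_key=(i,))` splitting, so cohorts are reproducible
  under subsetting and the whole pipeline (NIfTI files included) is
  bit-identical across re-runs of one configuration.
- Masks are uint8 0/1 NIfTI-1; images float32. Mask loading binarizes at 0.5
  but treats values in (0.25, 0.75) as a dialect error rather than rounding
  silently. Geometry mismatches are errors, never resampling.
- Hemisphere split: grid x-midplane (synthetic space is midline-centred); an
  odd-grid midline column goes to the left hemisphere and is logged. Real
  data would pass an explicit midline.
- Degenerate inputs error loudly: empty ROI or zero background SD on a
  selected slice, no 3-slice contiguous run, non-positive TIV, zero
  between-subject variance in ICC, overlapping templates (with overlap count).

## What passing tests do and do not show

The validation demonstrates that the measurement rules, reliability
statistics and inferential battery are implemented correctly (against hand
calculations, closed forms, enumeration and reference implementations), that
the estimators are calibrated (parameter recovery on phantoms; null rejection
rates in [0.03, 0.07] at α = 0.05), and that the full pipeline is
deterministic. It does not demonstrate performance on real NM-MRI: the
phantoms have Gaussian noise, idealized geometry, identity registration and a
fixed background ROI, so segmentation difficulty, registration error, bias
fields and template mismatch are all outside what these tests can certify.

## Problem sizes

Default validation scales were chosen to keep the whole suite at a few
minutes on one CPU: 200 subjects for estimator-calibration runs, 500
repetitions for correlation recovery, 1000 simulations for type-I
calibration, 100 draws for rater-Dice calibration, and a 17-subject cohort
for end-to-end determinism checks.
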
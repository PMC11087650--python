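# nigraquant

Quantification of substantia nigra pars compacta (SNc) degeneration from
neuromelanin-sensitive MRI (NM-MRI), exercised end-to-end on calibrated
synthetic midbrain phantoms.

NM-MRI shows the neuromelanin-rich SNc as a hyperintense band in a thin axial
slab (0.35 × 0.35 mm in-plane, 3 mm slices). In Parkinson's disease (PD) the
SNc loses both size and contrast, and the same degeneration begins silently in
at-risk groups such as asymptomatic LRRK2 mutation carriers. `nigraquant`
implements the measurement and inference chain used to quantify that loss, for
researchers who want a tested, reproducible reference implementation and a
synthetic test bed with known ground truth:

- **Measurement.** From an NM-MRI volume, two raters' SNc masks (left/right), a
  background mask and regional territory templates, it computes per hemisphere
  and left–right averaged:
  - volume `V = N_voxels × v_voxel` over the three lowest contiguous slices of
    the visible SNc on the raters' consensus (mean) ROI,
  - TIV-corrected volume `C_vol = V [mm³] / TIV [mL]`,
  - contrast-to-noise ratio
    `CNR = mean_over_slices{ (Sig_SNc − Sig_BND) / STD_BND }`,
  - the same measures inside the sensorimotor (dorsolateral), associative
    (ventral) and limbic (dorsomedial) nigral territories via template
    intersection,
  - rater reliability: Dice overlap and ICC(2,1).
- **Inference.** One-way ANOVA and χ² for demographics; ANCOVA
  (`measure ~ group + age + sex`, 2-df partial F) for imaging measures;
  gated post-hoc Student t-tests; percent changes; ROC AUC; Pearson
  correlations with max-statistic permutation control of the family-wise
  error rate; mutation-subtype (G2385R vs R1628P) t-tests.
- **Synthesis.** A phantom generator that emulates the three-group study
  design (30 HC / 15 LRRK2 / 22 PD by default): Gaussian background,
  half-ellipse SNc footprints with group-specific contrast and volume
  distributions, level-set simulated raters calibrated to a target Dice
  (0.81), and clinical scores (MDS-UPDRS etc.) drawn with configurable
  score–measure correlations. The generator is calibrated on the measurement
  scale, so the values the pipeline reports converge to the configured group
  targets (see `docs/methods.md`).

## Worked example

```python
import pandas as pd
from nigraquant import CohortConfig, generate_cohort

cfg = CohortConfig(n_hc=10, n_lrrk2=8, n_pd=10, seed=0)
cohort = generate_cohort(cfg)
rows = [
    {"group": sd.record.group,
     "volume_mm3": sd.measures.volume_mm3.mean,
     "c_vol": sd.measures.c_vol.mean,
     "cnr": sd.measures.cnr.mean}
    for sd in cohort.data
]
print(pd.DataFrame(rows).groupby("group").mean().round(3))
```

prints

```
       volume_mm3  c_vol    cnr
group
HC        380.840  0.257  1.554
LRRK2     338.031  0.220  1.426
PD        327.222  0.228  1.298
```

Each row is the group mean of the left–right averaged whole-SNc measures that
the pipeline extracted from the phantoms via rater-consensus masks: healthy
controls sit near the configured population values (394.2 mm³, CNR 1.51),
carriers are intermediate, PD lowest — the expected ordering of progressive
nigral degeneration, with small-sample scatter at these group sizes.

The same thing from the shell, with all report tables:

```bash
nigraquant run --seed 0 --out run/
# run/reports/: table1_demographics.csv  table2_measures.csv
#               table3_correlations.csv  roc.csv  reliability.csv
#               mutation_ttest.csv       + measures.csv, manifest.json
```

Stages are individually invocable (`nigraquant synth|measure|analyze`), write
plain NIfTI-1 + CSV, and are bit-reproducible for a fixed seed.

## Layout

```
src/nigraquant/
  imaging_io.py        NIfTI I/O, geometry contract (VolumeImage, RoiMask)
  roi_model.py         consensus mask, slice selection, hemispheres, regions
  nm_metrics.py        CNR, volume, C_vol, Dice, ICC, per-subject measures
  synthetic_cohort.py  phantom/rater/score generators, CohortConfig
  group_stats.py       ANOVA, ANCOVA, t-tests, ROC, permutation FWE
  pipeline.py          on-disk layout, stages, report tables, manifest
  cli.py               `nigraquant` and `synth-cohort` entry points
docs/methods.md        model, calibration and design notes
```
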
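# dyadkin

Kinematic and postural feature analysis of dyadic point-light interactions.

`dyadkin` implements a complete analysis chain for two-person motion-capture
scenes (2 agents x 15 markers x 3-D at 100 Hz):

- **scene_io** — scene data model; canonical tabular CSV format, JSON
  manifests and a thin C3D adapter (optional `ezc3d` dependency); linear
  interpolation of short marker gaps.
- **synthetic_scenes** — seeded generator of dyadic scenes from per-emotion
  motion archetypes (speed, vertical bounce, approach schedule, mutual
  orientation, posture openness, motion-energy ratio, speed synchrony) plus
  a simulated-rater model (confusion matrix + valence noise).
- **intra_features** — 8 per-scene intrapersonal scalars: velocity (VEL),
  acceleration (ACC), vertical movement (VM), bounding-box volume and its SD
  (VOL, VOL_STD), left/right symmetry (SM), limb angles (LA), limb
  contraction (LC).
- **inter_features** — 12 interpersonal scalars: interpersonal distance and
  SD (IPD, IPD_STD), personal space (PS), interpersonal orientation and its
  balance (IPO, IPO_BAL), distance correlations (DC_VEL/ACC/VOL/LC),
  synchrony (SYNC_VEL/ACC), motion-energy balance (ME_BAL).
- **group_stats** — one-way emotion ANOVA with eta-squared and
  Bonferroni-corrected post hoc tests (Fisher-Z for correlation features);
  recognition-vs-chance t tests.
- **emotion_classifier** — bagged CART trees (M1 = intrapersonal,
  M2 = interpersonal, M3 = all 20 predictors), balanced
  leave-one-scene-per-category cross-validation, predictor importance.
- **rsa_pipeline** — representational similarity analysis: model / feature /
  behavioural / combination RDMs, Kendall tau-A and Pearson comparisons,
  permutation and signed-rank significance with Holm and FDR correction,
  two-bound noise ceiling, classical MDS.
- **pipeline** — one-seed reproducible orchestration of all stages.

## CLI

```sh
dyadkin simulate --out scenes/ --seed 1            # scenes + ratings
dyadkin features --scenes scenes/ --out features.csv
dyadkin anova    --features features.csv --out anova.csv
dyadkin classify --features features.csv --model M3 --out report.json
dyadkin rsa      --features features.csv --ratings scenes/ratings.csv --out rsa/
dyadkin run      --config run.yaml                 # full pipeline
```

A full run writes `scenes/`, `features.csv`, `anova.csv`, `recognition.csv`,
`classify/*.json`, `rsa/*` and a `summary.json` with the headline numbers,
plus a `run.log` and the resolved `config.yaml`. Re-running a saved config
with the same seed reproduces every CSV bit-exactly.

## Notes on conventions

- Coordinates are millimetres; x, y horizontal, z vertical (up-positive).
  Volumes are reported in m^3.
- Balance indices use `1 - |difference| / sum`, so 1 = perfectly balanced.
- Kendall's tau-A counts ties in the denominator only; an RDM with tied
  entries therefore correlates with itself below 1, and noise-ceiling
  bounds inherit that property.
- The bounding-box volume is axis-aligned by definition and hence not
  invariant under rotations of the whole scene; all other features are
  rigid-motion invariant.
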
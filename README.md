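# penumbra

Analysis toolkit for myelin-sensitive and comparison white-matter metrics in
lesioned brains: lesion mask geometry and frequency mapping, spatially matched
covariate-adjusted difference scores, distance-gradient ("penumbra") inference
around white-matter hyperintensities, voxelwise FDR group mapping, and ridge
regression cognition models with effective-degrees-of-freedom inference — plus
a seeded synthetic cohort generator so the whole pipeline is testable without
any imaging data.

## Layout

| module                | contents |
| --------------------- | -------- |
| `penumbra.volume`     | `VolumeMap`, `MaskSet`, `SubjectRecord` containers |
| `penumbra.masks`      | WM probability thresholding + mm erosion, NAWM derivation, EDT-based penumbra rings, lesion frequency maps |
| `penumbra.scores`     | control-group reference atlas, spatially matched ROI difference scores, covariate adjustment |
| `penumbra.stats`      | one/two-sample t tests, Cohen's d + CI, Pearson tests, ridge regression with `edf = n − tr(2H − HH′)` and t-based p-values, partial R², GCV penalty selection, BH-FDR, voxelwise group GLM with cluster extent filtering |
| `penumbra.cognition`  | normative stratification of timed test scores, Box-Cox processing-speed compound |
| `penumbra.simulate`   | seeded synthetic cohorts: periventricular lesions grown to a target volume fraction, boundary-distance exponential metric deficits, coupled cognition outcome, normative table generator |
| `penumbra.pipeline`   | stage functions + `run_pipeline` report bundle (TSV tables, NIfTI maps, JSON manifest) |
| `penumbra.cli`        | `penumbra` command with per-stage subcommands |

## CLI

All subcommands share one YAML config plus flag overrides
(`--config`, `--seed`, `--outdir`, `--input-dir`):

```sh
penumbra simulate  --config config.yaml --outdir cohort/   # write NIfTI volumes + cohort.tsv
penumbra all       --config config.yaml --outdir out/      # full pipeline
penumbra penumbra  --config config.yaml --outdir out/      # ring gradient table only
penumbra ridge     --config config.yaml --outdir out/      # ridge cognition models
penumbra report    cohort/cohort.tsv                       # demographics table
```

Example config:

```yaml
simulation:
  grid_shape: [48, 56, 48]
  voxel_size_mm: [2.0, 2.0, 2.0]
  n_case: 60
  n_control: 20
  seed: 1
ring_step_mm: 2.0
ring_max_mm: 10.0
alpha: 0.05
extent_k: 10
ridge_lambda: auto
run_voxelwise: true
```

With `mode: load` / `--input-dir`, the pipeline instead reads per-subject
NIfTI maps (`chi_neg`, `chi_pos`, `md`, `rd`, `fw`) and masks (`wm`, `wmh`,
`lacunes`, optional `brain`) from one directory per subject plus a
`cohort.tsv` (id, group, age, sex, education, cognition).

Outputs: `difference_scores.tsv` (long format), `penumbra_table.tsv`
(t, df, p, d, 95% CI per ring per metric), `correlations.tsv`,
`ridge_<roi>.tsv` (scaled estimate, SE, t, effective df, p, partial R²),
`clusters.tsv` + t-statistic NIfTI maps, per-group lesion frequency maps, and
`manifest.json` echoing config + seed so every number is recomputable.

## Notes

- Difference scores compare a subject's ROI mean to the control-group
  voxelwise-mean map averaged over the *same* subject-specific ROI; negative
  means below the control average. The diamagnetic susceptibility metric is
  analyzed as a magnitude, so a myelin deficit yields a negative score.
- Penumbra rings are half-open 2 mm distance bins from the lesion boundary
  (Euclidean distance transform with physical spacing); on a 2 mm grid the
  innermost ring is empty by construction — use a finer grid when the 0–2 mm
  shell matters.
- Ridge inference: predictors standardized, outcome centered, penalty chosen
  by deterministic GCV minimization (or fixed via config); p-values come from
  a Student t distribution with the effective residual degrees of freedom.
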
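# alertfmri

A tested, reusable pipeline for task-fMRI analysis of phasic alertness and
self-reported fatigue: from event-related task design and synthetic BOLD
cohorts, through voxelwise GLM with percent-signal-change (PSC) extraction
on a systematic cubic-grid ROI atlas, to network-level Spearman correlation
of brain signal with MFI-20 fatigue scores under a two-main-test Bonferroni
scheme with conditionally corrected follow-ups.

## What's inside

| Module | Role |
| --- | --- |
| `alertfmri.taskdesign` | Cue / cue+stimulus event schedules (randomized runs enveloped by rest blocks), canonical double-gamma HRF, design matrices with unit-peak task columns and a 128-s discrete-cosine high-pass basis |
| `alertfmri.bold_synth` | Synthetic 4D BOLD cohorts: planted positive (CEN-like) and negative (DMN-like) cue responses, AR(1) noise, slow drift, Gaussian-copula coupling between DMN amplitude and MFI total, ellipsoidal tumor masks, behavior logs |
| `alertfmri.glm` | Voxelwise OLS, beta → PSC transform, 3D Gaussian smoothing, one-sample group t-maps |
| `alertfmri.roigrid` | 15-mm cubic-grid parcellation (≤ 125 voxels of 3 mm per ROI), threshold-based hotspot selection with the contralateral mirror rule, CEN/DMN allocation by PSC sign, tumor-overlap statistics |
| `alertfmri.mfi` | MFI-20 scoring (five 4-item domains + total in 20..100; key is configuration, a published key ships as YAML), task accuracy and reaction time |
| `alertfmri.stats_report` | Spearman correlation (average ranks, t-approximation or seeded permutation), the conditional Bonferroni battery, CSV/JSON report bundle |
| `alertfmri.pipeline` | End-to-end orchestration (`fit_first_level`, `analyze_cohort`) |

Known limitation: first-level fits are plain OLS without prewhitening, so
temporal autocorrelation inflates single-subject standard errors; group
inference uses only between-subject variance and is unaffected.

## CLI

```bash
alertfmri simulate design --seed 1 --out events.tsv
alertfmri simulate cohort --config cohort.yaml --seed 1 --out cohort/
alertfmri fit --bold sub-001_bold.nii.gz --events events.tsv \
              --mask sub-001_mask.nii.gz --tr 2.0 --fwhm 12 --out firstlevel/
alertfmri roi build --mask mask.nii.gz --out atlas/
alertfmri mfi score --in responses.csv --out scores.csv
alertfmri correlate --signals network_psc.csv --scores scores.csv --out report/
```

Events are BIDS-style TSV (`onset`, `duration`, `trial_type`, `run`);
images are NIfTI-1; questionnaires and reports are CSV.

## Library quick start

```python
from alertfmri import bold_synth, taskdesign
from alertfmri.pipeline import analyze_cohort

design = taskdesign.generate_task_design(seed=1)
grid = bold_synth.plant_networks(bold_synth.default_grid())
spec = bold_synth.CohortSpec(n_subjects=63, planted_rho=0.47, seed=1)
cohort = bold_synth.synthesize_cohort(spec, design, grid)
result = analyze_cohort(cohort, design, grid, t_threshold=4.0,
                        smoothing_fwhm_mm=12.0)
print(result.report.main_results["DMN"])   # e.g. r(61) = 0.45, p < 0.001
```

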
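# afconn — asymmetric functional connectivity analysis

`afconn` quantifies hemispheric asymmetry in resting-state fMRI functional
connectivity at the level of ROI pairs, for researchers studying language
lateralization, handedness, and other lateralized brain functions.

The core idea: with a parcellation of 38 left/right homologue ROI pairs
(76 ROIs), a subject's Fisher-z connectivity matrix **Z** is compared to the
same matrix with every region swapped for its contralateral homologue (the
*mirror matrix* **M** = **P**ᵀ**ZP**, with **P** the mirror permutation).
The difference **D** = **Z** − **M** contains every independent asymmetry
value twice, so it is condensed to a P×P matrix whose lower triangle holds
within-hemisphere asymmetries z(Lᵢ,Lⱼ) − z(Rᵢ,Rⱼ) and whose upper triangle
holds between-hemisphere asymmetries z(Lᵢ,Rⱼ) − z(Rᵢ,Lⱼ); homotopic
connections are mirror-invariant (zero asymmetry by construction) and are
excluded, leaving P(P−1) = 1406 non-redundant values.

On top of this the package provides:

- **Symmetry index** — ICC(2,1) between a group connectivity matrix and its
  mirror (homotopic entries excluded); 100·ICC² is the percentage of
  connectivity variance that is hemispherically symmetric.
- **AFC-score** — the slope β of the simple regression
  y = α + βx + ε of a subject's 1406-entry asymmetry vector (y) on the
  group-mean vector (x): how strongly the subject expresses the
  group-typical asymmetry pattern.
- **Entrywise statistics** — one-sample and paired t tests per asymmetry
  entry, Bonferroni corrected over the 1406 values (2850 for full
  connectivity matrices).
- **PCA of asymmetry** — principal components of subject asymmetry vectors
  (entries as variables, subjects as observations), scaled so each
  component's subject scores have RMS 1, with cross-session component
  matching and ICC(2,1) reliability of re-fitted day-wise scores.
- **Language-task lateralization** — a GLM with a story-vs-math boxcar
  convolved with a canonical double-gamma HRF, run-intercept and cosine
  high-pass regressors (~0.005 Hz cutoff); left-minus-right betas per
  homologue pair give a 38-element lateralization vector, scored against the
  group mean (LTL-score).
- **Behavioral screening** — Pearson r for continuous and one-way ANOVA F
  for categorical covariates, Bonferroni corrected, with the critical
  correlation threshold computed from the t transform.
- **Synthetic cohorts** — a generator producing multi-day/multi-run ROI
  timeseries from mirror-symmetric network backbones with injected
  antisymmetric patterns, subject-specific loadings, day jitter, and linked
  behavioral variables — so the entire pipeline is testable with known
  ground truth.

## Worked example

```python
import numpy as np
import afconn
from afconn.synthetic import CohortSpec, language_pattern, simulate_rs_cohort

atlas = afconn.default_atlas()            # 76 ROIs, 38 homologue pairs
spec = CohortSpec(
    n_subjects=20, volumes_per_run=400,
    asymmetry_patterns=[(language_pattern(atlas), 1.0, 0.3)],
    day_jitter_sd=0.15, seed=7,
)
subjects, truth = simulate_rs_cohort(spec, atlas)
results = afconn.AFCModel.from_timeseries(subjects, atlas).fit(n_components=3)
print(results.summary())
r = np.corrcoef(results.afc_scores, truth["loading_0"])[0, 1]
print(f"corr(AFC-score, injected loading) = {r:.3f}")
```

prints

```
Asymmetric functional connectivity — fit summary
====================================================
subjects: 20    pairs: 38    asymmetry entries: 1406
group symmetry: ICC(2,1) = 0.976  (95.3% symmetric)
entries significant after Bonferroni (alpha=0.05): 42 / 1406
AFC-score: mean 1.000, sd 0.245
AFC-score day1/day2 reliability: ICC(2,1) = 0.683 (95% CI [0.365, 0.860])
components (% variance): 10.77, 6.86, 6.43
component reliability (ICC / similarity day1-day2):
  comp 0: ICC 0.89, r12 0.34, r1 0.81, r2 0.75
  comp 1: ICC 0.93, r12 0.06, r1 0.36, r2 0.45
  comp 2: ICC 0.92, r12 0.06, r1 0.53, r2 0.30
corr(AFC-score, injected loading) = 0.940
```

Reading the output: the simulated group connectivity is ~95% symmetric
(ICC 0.976 between original and mirrored matrices); 42 of the 1406
asymmetry entries survive Bonferroni correction (the injected language-like
pattern); AFC-scores cluster around 1 (the injected mean loading) with
between-subject spread; day-split scores are moderately reliable because
the generator adds day-level loading jitter; and the first principal
component carries the injected pattern, tracked by individual scores that
correlate 0.94 with the true loadings.

A command-line interface mirrors the library
(`afconn simulate | connect | asym | score | pca | task-glm | screen | icc | run-all`);
`afconn run-all --config config.yaml` runs the whole pipeline from a subject
manifest and writes TSV/JSON outputs.

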
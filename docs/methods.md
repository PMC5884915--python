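# Methods

## The asymmetry model

Resting-state functional connectivity is summarized per subject as a
Fisher-z correlation matrix over 76 ROIs (38 left/right homologue pairs;
default atlas: the 34 Desikan-Killiany cortical parcels plus
Cerebellum-Cortex, Hippocampus, Amygdala and VentralDC per hemisphere,
ordered left block then right block with pairs aligned). Each run's ROI-mean
traces are normalized to percent signal change about the run mean, all ROI
pairs are Pearson-correlated, and correlations are mapped through atanh.
The z scale is approximately variance-stabilizing (sampling variance
≈ 1/(T−3) per run, independent of r), which is what makes averaging across
runs and differencing across hemispheres well behaved. No global-signal
regression is applied: a globally shared signal is mirror-symmetric unless
it is expressed asymmetrically, in which case it is signal, not confound.

Runs are combined by averaging z matrices entrywise with equal weights
(robust to run-level mean/variance shifts); concatenating normalized runs
before correlating is available behind `concatenate=True`. Day-level
matrices average only that day's runs.

The mirror matrix conjugates z by the permutation that swaps every region
with its homologue; the asymmetry (original minus mirrored) is condensed to
a P×P matrix — lower triangle z(Lᵢ,Lⱼ) − z(Rᵢ,Rⱼ) (within-hemisphere), upper
triangle z(Lᵢ,Rⱼ) − z(Rᵢ,Lⱼ) (between-hemisphere), positive = left-favoring.
Homotopic entries are identically zero and excluded. The canonical vector
order is lower triangle row-major, then upper triangle row-major; it is
fixed so that templates, PCA coefficients and scores are bit-compatible
across runs.

Identities the implementation maintains exactly: mirroring is an involution;
a mirror-symmetric matrix has zero asymmetry; the asymmetry of a mirrored
matrix is the negated asymmetry; the asymmetry vector has P(P−1) entries
(1406 at P=38).

## Scores, reliability, screening

The AFC-score is the slope of OLS (with intercept) of a subject's asymmetry
vector on the group-mean vector. The template includes the scored subject
by default — at cohort sizes in the hundreds the inclusion bias is O(1/n) —
with a leave-one-out option for bias-sensitive small-n use. The same
routine scores task lateralization vectors (length 38).

Reliability uses ICC(2,1) — two-way random effects, absolute agreement,
single measures — computed from the ANOVA decomposition
(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n), with F-based confidence
intervals via Satterthwaite degrees of freedom. Absolute agreement is the
right variant here because a constant offset between sessions is a real
disagreement for trait-like scores.

The symmetry index applies ICC(2,1) to the 2812 unique heterotopic entries
of a group matrix paired with their mirrored counterparts (homotopic entries
excluded — they agree by construction and would inflate the estimate);
100·ICC² is reported as the percentage of symmetric variance. Because each
heterotopic value appears once as original and once as mirrored partner,
the paired vectors are permutations of each other; the ICC measures how
much of the across-entry variance is preserved under mirroring.

Behavioral screening: Pearson r (continuous) or one-way ANOVA F
(categorical), pairwise deletion of missing values with per-variable n,
Bonferroni at α/m with m the number of variables actually tested.
The critical correlation is r* = t*/√(t*² + n − 2) with t* the two-tailed
t critical value at α/m and df = n − 2; at n = 423, m = 735, α = 0.05 this
gives 0.192, consistent with per-variable missingness nudging published
thresholds slightly upward.

## Principal components

PCA runs on the subjects × entries matrix, mean-centered per entry but not
standardized: all entries share units (Δz), and per-entry standardization
would inflate noisy low-variance entries. Components are rescaled so each
score column has RMS 1 (coefficients rescaled reciprocally, so the
reconstruction grand_mean + scores·coefficients is preserved to machine
precision when all components are kept). Component signs are arbitrary;
matching across sessions therefore maximizes |Pearson r| between
coefficient vectors and reports the sign separately. Between-session
reliability re-scores subjects by regressing day-wise asymmetry vectors on
the combined-session component coefficients (one simple regression per
component — a joint multiple-regression option exists behind a flag) and
takes ICC(2,1) of the day-1/day-2 scores. Per-day PCAs are centered on
their own day means.

## Task GLM

The design has one task regressor — story blocks +1, math blocks −1,
sampled at TR and convolved run-wise with a canonical double-gamma HRF
(gamma-pdf peak at 6 s, undershoot peak at 16 s, undershoot ratio 1/6,
unit-peak normalized) — plus a run-intercept-difference column (±0.5), four
cosines with 0.5/1/1.5/2 cycles over the concatenated two-run duration
(together a high-pass filter; at 2 × 316 volumes and TR 0.72 s the highest
cosine sits at ≈ 0.0044 Hz), and a global intercept. Cosines are not
orthogonalized against the task regressor: shared variance is legitimately
absorbed by neither or both, and OLS handles it. With run means scaled to
100, betas are in percent-signal-change units; at ROI level, fitting
ROI-mean traces is algebraically identical to averaging voxelwise OLS betas
over the ROI. The lateralization vector is left-minus-right beta per pair;
an empty event list yields a zero task column, which the design tolerates
(the remaining columns must be full rank).

## Synthetic cohorts

The generator produces what the analysis assumes and nothing more:

- a mirror-symmetric block correlation backbone (networks identically
  distributed across hemispheres; default five contiguous pair blocks,
  within-network r = 0.5, between 0.1), projected to the nearest
  correlation matrix by one pass of eigenvalue clipping at 1e−6 plus
  diagonal renormalization — adequate for small perturbations, and cheap;
- antisymmetric-under-mirroring perturbation patterns applied on the z
  scale (left counterparts +loading·pattern/2, right −loading·pattern/2),
  mapped back through tanh and re-projected, so the analytic asymmetry of
  the target matrix is loading·pattern up to projection tolerance.
  A perturbation that drives the pre-projection matrix indefinite beyond
  tolerance (minimum eigenvalue < −0.01) raises instead of silently
  distorting;
- per-subject pattern loadings drawn from configurable normals, day-level
  loading jitter, and white measurement noise on top of the unit-variance
  network signal; runs are zero-mean Gaussian draws rescaled to BOLD-like
  units (baseline 1000, signal sd ~10);
- behavioral variables as slope·loading + noise.

Default geometry matches a long two-day acquisition: 2 days × 2 runs ×
1200 volumes at TR 0.72 s. The bundled named patterns place a left-favoring
within-hemisphere block on language-area pairs plus a between-hemisphere
block linking default-mode pairs to language homologues, and a disjoint
(hence orthogonal) limbic pattern; their amplitude default is 0.2 Δz, in
the range of reported group-level connectivity asymmetries, with loading
means/sds of (1.0, 0.3) and (0.0, 0.15) and day jitter sd 0.15 in the
validation experiments. With these settings the simulated group
connectivity is ≈95% symmetric — the regime the method targets.

Timeseries are temporally white by default, so sample correlations are
unbiased and their variance follows the 1/(T−3) law; an AR(1) option exists
to stress-test that assumption. The generator does not emulate physiological
noise, motion, susceptibility/phase-encode artifacts, spatial smoothness, or
non-Gaussian BOLD features — passing recovery tests therefore demonstrates
correctness of the estimators under the model's assumptions, not robustness
to real-data artifacts.

## Validation experiments and problem sizes

`afconn.experiments` runs three self-contained experiments, used by both the
test suite and `scripts/acceptance.py`:

- resting-state recovery at the full geometry (100 subjects, 2 days ×
  2 runs × 1200 volumes): correlation of AFC-scores with true loadings, of
  the group-mean asymmetry with the injected pattern, best |corr| of each
  injected pattern with the three leading components, day-split score
  ICC against the analytic variance ratio σ_b²/(σ_b² + σ_day²), and the
  group symmetry index. Sampling at this size takes a few seconds, so no
  scale reduction is needed;
- task recovery: one simulated language session (2 × 316 volumes) with
  injected lateral amplitudes N(0.5, 0.5) at SNR 1;
- type-I control: 200 null cohorts (8 pairs, 10 subjects, 1 run × 120
  volumes) through the Bonferroni-corrected entrywise tests, reporting the
  fraction of cohorts with any significant entry. Direct Monte Carlo shows
  the per-entry t level is essentially exact, so the familywise rate sits
  at its nominal bound; the test suite accordingly judges the 200-trial
  binomial estimate against the exact binomial 99.5% upper quantile of a
  rate-0.05 process, which flags genuine loss of control but not sampling
  noise.

## Numerical choices and edge cases

- Correlations with |r| ≥ 1 − 1e−12 between distinct ROIs abort with a
  degenerate-correlation error (duplicated traces), as do zero-variance
  traces and zero-mean columns in percent-signal-change scaling.
- Matrix diagonals are stored as NaN masks, never numbers, so
  self-connections cannot leak into vectorized statistics.
- Zero-variance asymmetry entries in group tests get NaN t and p, reported
  rather than dropped, and are never flagged significant.
- ICC CI bounds are NaN when MSE = 0 (degenerate perfect agreement is
  reported as ICC 1 with a point CI).
- All cohort randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical cohorts.

## Known limitations

The condensed-matrix construction requires a strict homologue pairing; ROIs
without a contralateral partner only pass through as fixed points of the
mirror permutation and contribute no asymmetry entries. Volumetric ROI
extraction assumes labels already resliced to the functional grid.
Windowed/dynamic asymmetry, graph metrics, partial correlations and
voxelwise maps are out of scope. Reported day-split reliabilities use half
the data per session and are therefore low-end estimates of full-session
reliability.
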
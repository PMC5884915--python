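"""Self-contained validation experiments on simulated cohorts.

These run the full pipeline on generated data with known ground truth and
report recovery metrics: how faithfully subject scores track injected
loadings, how well the group-mean asymmetry and the PCA components recover
the injected patterns, the test-retest reliability of day-split scores
against the analytic variance ratio, task-lateralization recovery, and the
familywise type-I error of the Bonferroni-corrected entrywise tests on null
cohorts.  Used by the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .asymmetry import AFCMatrix, afc_from_vector, entrywise_tests
from .atlas import default_atlas
from .model import AFCModel
from .scores import fit_score
from .synthetic import (
    CohortSpec,
    language_pattern,
    limbic_pattern,
    make_base_covariance,
    simulate_rs_cohort,
    simulate_task_session,
)
from .task_glm import build_design, fit_glm, lateralization_vector

__all__ = ["rs_recovery_experiment", "task_recovery_experiment", "type_one_error_experiment"]

# study-condition defaults for the simulated cohort: loading spread and
# day-to-day jitter of the language pattern, plus a second (limbic) pattern
LANGUAGE_LOADING = (1.0, 0.3)
LIMBIC_LOADING = (0.0, 0.15)
DAY_JITTER_SD = 0.15
NOISE_SD = 0.5


def rs_recovery_experiment(
    seed: int,
    n_subjects: int = 100,
    volumes_per_run: int = 1200,
    runs_per_day: int = 2,
) -> dict:
    """Full resting-state pipeline on a two-pattern cohort with ground truth.

    Returns a dict with: corr(AFC-score, true language loading), corr of the
    group-mean asymmetry with the injected mean pattern, best |corr| of each
    injected pattern with the three leading PCA components, ICC(2,1) of
    day-split scores with its analytic expectation
    sigma_b^2 / (sigma_b^2 + sigma_day^2), and the group symmetry index.
    """
    atlas = default_atlas()
    lang = language_pattern(atlas)
    limb = limbic_pattern(atlas)
    spec = CohortSpec(
        n_subjects=n_subjects,
        volumes_per_run=volumes_per_run,
        runs_per_day=runs_per_day,
        days=2,
        asymmetry_patterns=[
            (lang, *LANGUAGE_LOADING),
            (limb, *LIMBIC_LOADING),
        ],
        day_jitter_sd=DAY_JITTER_SD,
        noise_sd=NOISE_SD,
        behavioral_links=[(0, 1.0, 0.3)],
        seed=seed,
    )
    subjects, truth = simulate_rs_cohort(spec, atlas)
    model = AFCModel.from_timeseries(subjects, atlas)
    res = model.fit(n_components=3)

    lang_vec = AFCMatrix(condensed=lang.copy()).vector
    limb_vec = AFCMatrix(condensed=limb.copy()).vector
    loadings = truth["loading_0"].to_numpy()

    def best_component_corr(target):
        return max(
            abs(np.corrcoef(target, c)[0, 1]) for c in res.components.coefficients
        )

    sd_b = LANGUAGE_LOADING[1]
    analytic_icc = sd_b**2 / (sd_b**2 + DAY_JITTER_SD**2)
    behav_r = float(np.corrcoef(res.afc_scores, truth["behavior_0"])[0, 1])
    return {
        "score_loading_corr": float(np.corrcoef(res.afc_scores, loadings)[0, 1]),
        "group_pattern_corr": float(np.corrcoef(res.group_mean.vector, lang_vec)[0, 1]),
        "pca_language_corr": float(best_component_corr(lang_vec)),
        "pca_limbic_corr": float(best_component_corr(limb_vec)),
        "day_score_icc": float(res.score_reliability.icc),
        "day_score_icc_analytic": float(analytic_icc),
        "symmetry_icc": float(res.symmetry_icc),
        "symmetry_percent": float(res.symmetry_percent),
        "behavior_corr": behav_r,
        "n_subjects": n_subjects,
    }


def task_recovery_experiment(seed: int, noise_sd: float = 1.0) -> dict:
    """Task-session lateralization recovery at the configured noise level.

    Injected left-minus-right amplitudes are drawn from N(0.5, 0.5); with
    ``noise_sd`` equal to the 1%-signal-change base response amplitude the
    signal-to-noise ratio is 1.
    """
    atlas = default_atlas()
    rng = np.random.default_rng(seed)
    lateral = rng.normal(0.5, 0.5, size=atlas.n_pairs)
    events, y = simulate_task_session(
        atlas, lateral, volumes_per_run=316, tr=0.72,
        noise_sd=noise_sd, base_amplitude=1.0, seed=seed,
    )
    design = build_design(events, (316, 316), 0.72)
    recovered = lateralization_vector(fit_glm(design, y), atlas)
    # score the recovered vector against the injected template
    ltl_score = fit_score(recovered, lateral).beta
    return {
        "lateralization_corr": float(np.corrcoef(recovered, lateral)[0, 1]),
        "ltl_score_vs_truth": float(ltl_score),
        "n_pairs": atlas.n_pairs,
    }


def type_one_error_experiment(
    seed: int,
    repetitions: int = 200,
    n_subjects: int = 10,
    n_pairs: int = 8,
    volumes_per_run: int = 120,
) -> dict:
    """Familywise type-I error of Bonferroni entrywise tests on null cohorts.

    Each repetition simulates a cohort with zero injected asymmetry and runs
    the one-sample entrywise t tests with Bonferroni correction over all
    P(P-1) asymmetry entries; the reported fraction is the share of
    repetitions with at least one significant entry, which Bonferroni bounds
    at the 0.05 familywise level.
    """
    atlas = _make_small_atlas(n_pairs)
    blocks = [list(range(n_pairs // 2)), list(range(n_pairs // 2, n_pairs))]
    base = make_base_covariance(atlas, network_blocks=blocks)
    rng = np.random.default_rng(seed)
    n_false = 0
    for rep in range(repetitions):
        spec = CohortSpec(
            n_subjects=n_subjects,
            volumes_per_run=volumes_per_run,
            runs_per_day=1,
            days=1,
            base_correlation=base,
            noise_sd=0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        subjects, _ = simulate_rs_cohort(spec, atlas)
        model = AFCModel.from_timeseries(subjects, atlas)
        mats = [afc_from_vector(v, n_pairs) for v in model.afc_vectors]
        table = entrywise_tests(mats, alpha=0.05)
        if table["significant"].any():
            n_false += 1
    return {
        "false_positive_fraction": n_false / repetitions,
        "repetitions": repetitions,
        "entries_per_test": n_pairs * (n_pairs - 1),
    }


def _make_small_atlas(n_pairs: int):
    from .atlas import ROIAtlas

    names, hemis, pids = [], [], []
    for side, hemi in (("L", "left"), ("R", "right")):
        for p in range(n_pairs):
            names.append(f"{side}-roi{p + 1}")
            hemis.append(hemi)
            pids.append(p + 1)
    return ROIAtlas(names=tuple(names), hemispheres=tuple(hemis), pair_ids=tuple(pids))
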
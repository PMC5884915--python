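"""Synthetic resting-state and task cohorts with known asymmetry ground truth.

The generator emulates the statistical structure the analysis assumes: a
mirror-symmetric block-correlation backbone (networks distributed identically
across hemispheres), small antisymmetric-under-mirroring perturbation
patterns carried with subject-specific loadings, a two-day/multi-run session
structure with optional day-level loading jitter, white measurement noise,
and behavioral variables linearly linked to the loadings.  Default geometry
matches a long two-day acquisition: 2 days x 2 runs x 1200 volumes at
TR 0.72 s.

Timeseries are Gaussian without temporal autocorrelation, so sample
correlations are unbiased and their variance follows 1/(T-3) per run on the
Fisher-z scale; an AR(1) option exists to stress-test that assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ROIAtlas, RunTimeseries, SubjectTimeseries
from .task_glm import build_design

__all__ = [
    "CohortSpec",
    "nearest_correlation",
    "make_base_covariance",
    "inject_asymmetry",
    "language_pattern",
    "limbic_pattern",
    "random_pattern",
    "simulate_rs_cohort",
    "simulate_task_session",
]

_LANGUAGE_PAIRS = (
    "parstriangularis",
    "parsopercularis",
    "parsorbitalis",
    "middletemporal",
    "caudalmiddlefrontal",
    "bankssts",
    "superiorfrontal",
)
_DMN_PAIRS = ("supramarginal", "posteriorcingulate", "rostralmiddlefrontal")
_LIMBIC_PAIRS = ("Amygdala", "Hippocampus", "VentralDC", "Cerebellum-Cortex")


def nearest_correlation(matrix: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Single-pass eigenvalue clipping at ``eps`` followed by diagonal
    renormalization — adequate for the small perturbations used here.
    """
    m = np.asarray(matrix, dtype=float)
    m = (m + m.T) / 2
    w, v = np.linalg.eigh(m)
    w = np.clip(w, eps, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return (m + m.T) / 2


def make_base_covariance(
    atlas: ROIAtlas,
    network_blocks=None,
    within_r: float = 0.5,
    between_r: float = 0.1,
) -> np.ndarray:
    """Mirror-symmetric block-structured correlation backbone.

    ``network_blocks`` partitions pair indices (0-based) into networks;
    regions whose pairs share a network correlate at ``within_r``, all other
    region pairs at ``between_r``, identically in both hemispheres.  The
    default splits the pairs into five contiguous blocks.  The result is
    averaged with its mirror conjugate (a no-op for this construction) and
    projected to the nearest correlation matrix.
    """
    if not 0 <= between_r < within_r < 1:
        raise ValueError("need 0 <= between_r < within_r < 1")
    p = atlas.n_pairs
    if network_blocks is None:
        n_blocks = min(5, p)
        bounds = np.linspace(0, p, n_blocks + 1).astype(int)
        network_blocks = [list(range(bounds[i], bounds[i + 1])) for i in range(n_blocks)]
    block_of_pair = np.empty(p, dtype=int)
    seen = set()
    for b, pairs in enumerate(network_blocks):
        for q in pairs:
            block_of_pair[q] = b
            seen.add(q)
    if seen != set(range(p)):
        raise ValueError("network_blocks must partition all pair indices")
    block_of_roi = np.empty(atlas.n_rois, dtype=int)
    block_of_roi[atlas.left_indices] = block_of_pair
    block_of_roi[atlas.right_indices] = block_of_pair
    same = block_of_roi[:, None] == block_of_roi[None, :]
    corr = np.where(same, within_r, between_r)
    np.fill_diagonal(corr, 1.0)
    # symmetrize under mirroring, then enforce positive definiteness
    from .atlas import mirror_permutation

    perm = mirror_permutation(atlas)
    corr = (corr + corr[np.ix_(perm, perm)]) / 2
    return nearest_correlation(corr)


def _pattern_delta(pattern: np.ndarray, atlas: ROIAtlas) -> np.ndarray:
    """Expand a condensed pattern to a full-matrix z-space perturbation.

    The returned symmetric ROI x ROI matrix D satisfies: adding loading * D
    to the Fisher-z matrix changes the condensed asymmetry by exactly
    loading * pattern (left and right counterparts move by +/- half).
    """
    pattern = np.asarray(pattern, dtype=float)
    p = atlas.n_pairs
    if pattern.shape != (p, p):
        raise ValueError(f"pattern must be {p} x {p} condensed")
    li, ri = atlas.left_indices, atlas.right_indices
    delta = np.zeros((atlas.n_rois, atlas.n_rois))
    for i in range(p):
        for j in range(i):  # lower triangle: within-hemisphere
            v = pattern[i, j]
            if v and np.isfinite(v):
                delta[li[i], li[j]] = delta[li[j], li[i]] = v / 2
                delta[ri[i], ri[j]] = delta[ri[j], ri[i]] = -v / 2
        for j in range(i + 1, p):  # upper triangle: between-hemisphere
            v = pattern[i, j]
            if v and np.isfinite(v):
                delta[li[i], ri[j]] = delta[ri[j], li[i]] = v / 2
                delta[ri[i], li[j]] = delta[li[j], ri[i]] = -v / 2
    return delta


def inject_asymmetry(
    base: np.ndarray,
    pattern: np.ndarray,
    loading: float,
    atlas: ROIAtlas,
    eps: float = 1e-6,
) -> np.ndarray:
    """Perturb a symmetric base correlation matrix by a condensed pattern.

    The perturbation is applied on the Fisher-z scale (+loading*pattern/2 on
    left counterparts, -loading*pattern/2 on right), mapped back through
    tanh, and re-projected to the nearest correlation matrix, so the analytic
    condensed asymmetry of the result is loading * pattern up to the
    projection tolerance.
    """
    base = np.asarray(base, dtype=float)
    delta = _pattern_delta(pattern, atlas)
    off = ~np.eye(base.shape[0], dtype=bool)
    z = np.zeros_like(base)
    z[off] = np.arctanh(np.clip(base[off], -0.999999, 0.999999))
    z += loading * delta
    corr = np.tanh(z)
    np.fill_diagonal(corr, 1.0)
    min_eig = np.linalg.eigvalsh((corr + corr.T) / 2).min()
    if min_eig < -0.01:
        raise ValueError(
            f"loading {loading} breaks positive definiteness "
            f"(minimum eigenvalue {min_eig:.4f} before projection)"
        )
    return nearest_correlation(corr, eps=eps)


def _named_pattern(atlas: ROIAtlas, within_sets, between_sets, strength: float):
    """Condensed pattern with ``strength`` on the listed pair-set products."""
    p = atlas.n_pairs
    names = atlas.pair_names
    pattern = np.zeros((p, p))

    def idx(group):
        found = [i for i, n in enumerate(names) if n in group]
        if not found:
            raise ValueError(f"no atlas pairs match {sorted(group)}")
        return found

    for group, sign in within_sets:
        ids = idx(group)
        for a in ids:
            for b in ids:
                if a > b:
                    pattern[a, b] = sign * strength
    for (ga, gb), sign in between_sets:
        for a in idx(ga):
            for b in idx(gb):
                i, j = min(a, b), max(a, b)
                if i != j:
                    pattern[i, j] = sign * strength
    return pattern


def language_pattern(atlas: ROIAtlas, strength: float = 0.2) -> np.ndarray:
    """Left-favoring language asymmetry template.

    Stronger connectivity among left-hemisphere language areas than among
    their right homologues (within-hemisphere part), and stronger
    connectivity between left default-mode areas and right language
    homologues than the mirrored combination (between-hemisphere part).
    """
    return _named_pattern(
        atlas,
        within_sets=[(set(_LANGUAGE_PAIRS), +1)],
        between_sets=[((set(_DMN_PAIRS), set(_LANGUAGE_PAIRS)), +1)],
        strength=strength,
    )


def limbic_pattern(atlas: ROIAtlas, strength: float = 0.2) -> np.ndarray:
    """Limbic asymmetry template: weaker left-limbic coupling to all cortex.

    Disjoint in its nonzero entries from :func:`language_pattern`, hence
    orthogonal to it — useful as a second injected component.
    """
    p = atlas.n_pairs
    names = atlas.pair_names
    limbic = [i for i, n in enumerate(names) if n in set(_LIMBIC_PAIRS)]
    if not limbic:
        raise ValueError("atlas has no limbic pairs")
    other = [i for i in range(p) if i not in limbic]
    pattern = np.zeros((p, p))
    for a in limbic:
        for b in other:
            i, j = max(a, b), min(a, b)
            pattern[i, j] = -strength  # within-hemisphere
            pattern[j, i] = +strength  # between-hemisphere
    return pattern


def random_pattern(
    n_pairs: int,
    rng: np.random.Generator,
    rms: float = 0.05,
    orthogonal_to: np.ndarray | None = None,
) -> np.ndarray:
    """Dense random condensed pattern scaled to a target full-vector RMS."""
    pattern = rng.standard_normal((n_pairs, n_pairs))
    np.fill_diagonal(pattern, 0.0)
    if orthogonal_to is not None:
        o = np.asarray(orthogonal_to, float).copy()
        np.fill_diagonal(o, 0.0)
        denom = (o * o).sum()
        if denom > 0:
            pattern -= o * (pattern * o).sum() / denom
    off = ~np.eye(n_pairs, dtype=bool)
    pattern *= rms / np.sqrt((pattern[off] ** 2).mean())
    return pattern


@dataclass
class CohortSpec:
    """Study-condition parameters of a simulated resting-state cohort.

    Defaults follow the acquisition the analysis targets: two scanning days,
    two runs per day of 1200 volumes each at TR 0.72 s.  ``asymmetry_patterns``
    is a list of (condensed pattern, loading mean, loading sd) triples;
    ``behavioral_links`` a list of (pattern index, slope, noise sd) triples.
    ``noise_sd`` is white measurement noise relative to the unit-variance
    network signal.
    """

    n_subjects: int = 100
    runs_per_day: int = 2
    days: int = 2
    volumes_per_run: int = 1200
    tr_seconds: float = 0.72
    base_correlation: np.ndarray | None = None
    asymmetry_patterns: list = field(default_factory=list)
    day_jitter_sd: float = 0.0
    noise_sd: float = 0.5
    ar1_coefficient: float = 0.0
    behavioral_links: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.runs_per_day < 1 or self.days < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.volumes_per_run < 4:
            raise ValueError("need at least 4 volumes per run")
        if self.tr_seconds <= 0 or self.noise_sd < 0 or self.day_jitter_sd < 0:
            raise ValueError("invalid noise/timing parameters")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        for idx, _, _ in self.behavioral_links:
            if not 0 <= idx < len(self.asymmetry_patterns):
                raise ValueError(f"behavioral link references pattern {idx} that does not exist")


def _sample_run(rng, chol, n_t, noise_sd, ar1):
    n = chol.shape[0]
    w = rng.standard_normal((n_t, n))
    if ar1 > 0:
        for t in range(1, n_t):
            w[t] = ar1 * w[t - 1] + np.sqrt(1 - ar1**2) * w[t]
    x = w @ chol.T
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal((n_t, n))
    return x


def simulate_rs_cohort(spec: CohortSpec, atlas: ROIAtlas):
    """Generate a resting-state cohort with known asymmetry loadings.

    Per subject, pattern loadings are drawn from the configured normals; per
    day, day jitter is added; each run is sampled as a zero-mean multivariate
    normal with the subject-day target correlation plus white noise, then
    rescaled to plausible BOLD units (baseline 1000, signal sd ~10).
    Behavioral variables are slope * loading + noise.  Fully reproducible
    from ``spec.seed``.

    Returns
    -------
    (subjects, ground_truth)
        ``subjects`` is a list of :class:`SubjectTimeseries`; ``ground_truth``
        a DataFrame with one row per subject (loadings and behavioral values).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = (
        spec.base_correlation
        if spec.base_correlation is not None
        else make_base_covariance(atlas)
    )
    base = np.asarray(base, dtype=float)
    if base.shape != (atlas.n_rois, atlas.n_rois):
        raise ValueError("base correlation does not match the atlas")
    deltas = [_pattern_delta(pat, atlas) for pat, _, _ in spec.asymmetry_patterns]
    off = ~np.eye(atlas.n_rois, dtype=bool)
    base_z = np.zeros_like(base)
    base_z[off] = np.arctanh(np.clip(base[off], -0.999999, 0.999999))

    subjects = []
    truth_rows = []
    n_pat = len(spec.asymmetry_patterns)
    for s in range(spec.n_subjects):
        loadings = np.array(
            [rng.normal(mean, sd) for _, mean, sd in spec.asymmetry_patterns]
        )
        runs = []
        for day in range(1, spec.days + 1):
            day_loadings = loadings + rng.normal(0.0, spec.day_jitter_sd, size=n_pat)
            z = base_z.copy()
            for lam, d in zip(day_loadings, deltas):
                z += lam * d
            corr = np.tanh(z)
            np.fill_diagonal(corr, 1.0)
            corr = nearest_correlation(corr)
            chol = np.linalg.cholesky(corr)
            for r in range(spec.runs_per_day):
                x = _sample_run(
                    rng, chol, spec.volumes_per_run, spec.noise_sd, spec.ar1_coefficient
                )
                data = 1000.0 + 10.0 * x
                runs.append(
                    RunTimeseries(
                        data=data,
                        day=day,
                        run_index=r + 1,
                        phase_encode="LR" if r % 2 == 0 else "RL",
                        tr_seconds=spec.tr_seconds,
                    )
                )
        row = {"subject_id": f"sub-{s + 1:03d}"}
        for k, lam in enumerate(loadings):
            row[f"loading_{k}"] = lam
        for b, (idx, slope, noise) in enumerate(spec.behavioral_links):
            row[f"behavior_{b}"] = slope * loadings[idx] + rng.normal(0.0, noise)
        truth_rows.append(row)
        subjects.append(SubjectTimeseries(subject_id=row["subject_id"], runs=runs))
    return subjects, pd.DataFrame(truth_rows)


def simulate_task_session(
    atlas: ROIAtlas,
    lateral_amplitudes: np.ndarray,
    runs: int = 2,
    volumes_per_run: int = 316,
    tr: float = 0.72,
    noise_sd: float = 1.0,
    base_amplitude: float = 1.0,
    block_seconds: float = 30.0,
    seed: int = 0,
):
    """Simulate a block-design language session for one subject.

    Alternating story/math blocks of ``block_seconds`` over two runs; each
    ROI responds with amplitude base +/- lateral/2 (left/right member of its
    pair) in % signal change, plus Gaussian noise; run means are 100.

    Returns
    -------
    (events, roi_timeseries)
        ``events`` as (condition, onset_s, duration_s) triples over
        concatenated session time; ``roi_timeseries`` the (time x ROI) matrix.
    """
    lateral = np.asarray(lateral_amplitudes, dtype=float).ravel()
    if lateral.size != atlas.n_pairs:
        raise ValueError(f"need one lateral amplitude per pair ({atlas.n_pairs})")
    if runs != 2:
        raise ValueError("the task design uses exactly two runs")
    rng = np.random.default_rng(seed)
    run_lengths = (volumes_per_run, volumes_per_run)
    run_seconds = volumes_per_run * tr
    events = []
    for r in range(runs):
        t0 = r * run_seconds
        onset = 0.0
        k = 0
        while onset + block_seconds <= run_seconds + 1e-9:
            events.append(
                ("story" if k % 2 == 0 else "math", t0 + onset, block_seconds)
            )
            onset += block_seconds
            k += 1
    design = build_design(events, run_lengths, tr)
    task = design.column("story_vs_math")
    # demean the response per run so run means are exactly 100 without noise
    task = task.copy()
    start = 0
    for ln in run_lengths:
        task[start : start + ln] -= task[start : start + ln].mean()
        start += ln
    amps = np.empty(atlas.n_rois)
    amps[atlas.left_indices] = base_amplitude + lateral / 2
    amps[atlas.right_indices] = base_amplitude - lateral / 2
    y = 100.0 + task[:, None] * amps[None, :]
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(y.shape)
    # rescale each run to mean exactly 100, as the GLM expects
    start = 0
    for ln in run_lengths:
        seg = y[start : start + ln]
        y[start : start + ln] = 100.0 * seg / seg.mean(axis=0)
        start += ln
    return events, y
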
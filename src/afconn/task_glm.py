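"""Language-task GLM: design construction, OLS fit, lateralization vector.

The design has a single task factor — the story-versus-math boxcar (+1 story,
-1 math) convolved with a canonical double-gamma hemodynamic response — plus
a run-intercept-difference column, four low-frequency cosines (0.5, 1, 1.5
and 2 cycles over the concatenated two-run duration, together a high-pass
filter with a cutoff near 0.005 Hz at the session length used here), and a
global intercept.  Regional language activity is the story-vs-math
coefficient per ROI (% signal change units when the input run means are
scaled to 100); subtracting each right-hemisphere estimate from its left
homologue gives the 38-element lateralization vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import ROIAtlas

__all__ = [
    "TaskDesign",
    "double_gamma_hrf",
    "build_design",
    "scale_to_mean_100",
    "fit_glm",
    "lateralization_vector",
]

REGRESSOR_ROLES = (
    "story_vs_math",
    "run_intercept_diff",
    "cosine_0.5",
    "cosine_1",
    "cosine_1.5",
    "cosine_2",
    "global_intercept",
)


@dataclass
class TaskDesign:
    """Design matrix (time x regressor) with named columns."""

    matrix: np.ndarray
    roles: tuple
    tr_seconds: float
    run_lengths: tuple

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != sum(self.run_lengths):
            raise ValueError("design rows must equal the summed run lengths")
        if self.matrix.shape[1] != len(self.roles):
            raise ValueError("one role per design column required")
        # an all-zero task column (no events) is tolerated; the remaining
        # columns must be linearly independent
        nonzero = np.flatnonzero(np.any(self.matrix != 0, axis=0))
        if np.linalg.matrix_rank(self.matrix[:, nonzero]) < nonzero.size:
            raise ValueError("design matrix is rank deficient")

    def column(self, role: str) -> np.ndarray:
        return self.matrix[:, self.roles.index(role)]


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at TR.

    Response peak at 6 s, undershoot peak at 16 s, undershoot ratio 1/6;
    normalized to unit peak.
    """
    from scipy.stats import gamma

    t = np.arange(0, duration, tr)
    peak = gamma.pdf(t, a=6, scale=1.0)
    undershoot = gamma.pdf(t, a=16, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def build_design(
    events,
    run_lengths,
    tr: float,
) -> TaskDesign:
    """Build the language-task design from block timing.

    Parameters
    ----------
    events : iterable of (condition, onset_s, duration_s)
        ``condition`` is "story" or "math"; onsets are relative to the start
        of the concatenated session.  Blocks must lie within run bounds and
        story/math blocks must not overlap.
    run_lengths : lengths (volumes) of the two runs.
    tr : repetition time in seconds.
    """
    run_lengths = tuple(int(v) for v in run_lengths)
    if len(run_lengths) != 2:
        raise ValueError("the task design expects exactly two runs")
    n_total = sum(run_lengths)
    t_total = n_total * tr

    box = np.zeros(n_total)
    events = list(events)
    for cond, onset, dur in events:
        if cond not in ("story", "math"):
            raise ValueError(f"unknown condition {cond!r}")
        if onset < 0 or onset + dur > t_total + 1e-9:
            raise ValueError(f"event ({cond}, {onset}, {dur}) outside session bounds")
        i0 = int(np.ceil(onset / tr - 1e-9))
        i1 = int(np.ceil((onset + dur) / tr - 1e-9))
        sign = 1.0 if cond == "story" else -1.0
        seg = box[i0:i1]
        if np.any(seg * sign < 0):
            raise ValueError("overlapping story and math events")
        box[i0:i1] = sign

    # convolve run-wise: responses do not carry over run boundaries
    hrf = double_gamma_hrf(tr)
    task = np.zeros(n_total)
    start = 0
    for ln in run_lengths:
        task[start : start + ln] = np.convolve(box[start : start + ln], hrf)[:ln]
        start += ln

    run_diff = np.concatenate(
        [np.full(run_lengths[0], 0.5), np.full(run_lengths[1], -0.5)]
    )
    t = (np.arange(n_total) + 0.5) * tr
    cosines = [np.cos(2 * np.pi * c * t / t_total) for c in (0.5, 1.0, 1.5, 2.0)]
    intercept = np.ones(n_total)
    matrix = np.column_stack([task, run_diff, *cosines, intercept])
    return TaskDesign(
        matrix=matrix, roles=REGRESSOR_ROLES, tr_seconds=tr, run_lengths=run_lengths
    )


def scale_to_mean_100(run_data: np.ndarray) -> np.ndarray:
    """Scale each column so its temporal mean is 100 (% signal change units)."""
    run_data = np.asarray(run_data, dtype=float)
    mean = run_data.mean(axis=0)
    if np.any(mean == 0):
        raise ValueError("zero-mean trace; cannot scale to mean 100")
    return 100.0 * run_data / mean


def fit_glm(design: TaskDesign, roi_timeseries: np.ndarray) -> np.ndarray:
    """OLS fit of the design to every ROI; returns story-vs-math betas.

    ``roi_timeseries`` is the concatenated (time x ROI) matrix with run means
    scaled to 100, so betas are in % signal change units.
    """
    y = np.asarray(roi_timeseries, dtype=float)
    if y.shape[0] != design.matrix.shape[0]:
        raise ValueError(
            f"timeseries has {y.shape[0]} volumes, design has {design.matrix.shape[0]}"
        )
    betas, *_ = np.linalg.lstsq(design.matrix, y, rcond=None)
    return betas[design.roles.index("story_vs_math")]


def lateralization_vector(betas: np.ndarray, atlas: ROIAtlas) -> np.ndarray:
    """Left minus right homologue activity per pair (length = number of pairs).

    Positive entries mean stronger story-vs-math activity on the left; a high
    score of this vector against the group mean indicates strong left
    language lateralization.
    """
    betas = np.asarray(betas, dtype=float).ravel()
    if betas.size != atlas.n_rois:
        raise ValueError(f"got {betas.size} betas for a {atlas.n_rois}-ROI atlas")
    return betas[atlas.left_indices] - betas[atlas.right_indices]
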
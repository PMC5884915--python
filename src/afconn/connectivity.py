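"""Run normalization and Fisher-z connectivity matrices.

Each run's ROI-mean traces are converted to percent signal change, all ROI
pairs are Pearson-correlated, and the correlations are Fisher transformed
(atanh) so they can be averaged and differenced on an approximately
variance-stabilized scale.  Day- and session-level matrices are formed by
entrywise averaging of run-level z matrices; no global-signal regression is
applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import ROIAtlas, SubjectTimeseries

__all__ = [
    "ConnectivityMatrix",
    "percent_signal_change",
    "correlate_run",
    "combine_runs",
    "subject_connectivity",
    "DegenerateCorrelationError",
    "NormalizationError",
]

_DEGENERATE_TOL = 1e-12

LEVELS = ("run", "day1", "day2", "session")


class NormalizationError(ValueError):
    pass


class DegenerateCorrelationError(ValueError):
    pass


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Fisher-z matrix; the diagonal is masked (NaN).

    The diagonal is never a number so that self-connections cannot leak into
    vectorized statistics downstream.
    """

    z: np.ndarray
    level: str = "run"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != n:
            raise ValueError("z must be square")
        if self.level not in LEVELS:
            raise ValueError(f"invalid level {self.level!r}")
        np.fill_diagonal(self.z, np.nan)
        off = self.z[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal z values must be finite")
        if not np.allclose(self.z, self.z.T, equal_nan=True):
            raise ValueError("z must be symmetric")

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]

    def off_diagonal_mask(self) -> np.ndarray:
        return ~np.eye(self.n_rois, dtype=bool)

    def unique_entries(self) -> np.ndarray:
        """The n(n-1)/2 upper-triangular off-diagonal values (row-major)."""
        iu = np.triu_indices(self.n_rois, k=1)
        return self.z[iu]


def percent_signal_change(run_data: np.ndarray, roi_names=None) -> np.ndarray:
    """Normalize each column to percent change from its temporal mean.

    x -> 100 * (x - mean(x)) / mean(x); column means become 0.  Raises
    :class:`NormalizationError` for zero-mean columns (percent change from a
    zero baseline is undefined).
    """
    run_data = np.asarray(run_data, dtype=float)
    mean = run_data.mean(axis=0)
    bad = np.flatnonzero(mean == 0)
    if bad.size:
        names = [roi_names[i] for i in bad] if roi_names is not None else bad.tolist()
        raise NormalizationError(f"zero-mean trace(s), cannot normalize: {names}")
    return 100.0 * (run_data - mean) / mean


def correlate_run(
    run_data: np.ndarray, subject_id: str = "", roi_names=None
) -> ConnectivityMatrix:
    """Pearson-correlate all ROI pairs of one run and Fisher transform.

    z[i, j] = atanh(r(x_i, x_j)).  Correlations at |r| >= 1 - 1e-12 between
    distinct ROIs signal duplicated traces and raise
    :class:`DegenerateCorrelationError`.
    """
    run_data = np.asarray(run_data, dtype=float)
    if run_data.shape[0] < 3:
        raise ValueError("need at least 3 timepoints to correlate")
    sd = run_data.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [roi_names[i] for i in bad] if roi_names is not None else bad.tolist()
        raise DegenerateCorrelationError(f"constant trace(s): {names}")
    r = np.corrcoef(run_data, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    worst = np.abs(r[off]).max()
    if worst >= 1 - _DEGENERATE_TOL:
        i, j = np.unravel_index(np.argmax(np.abs(np.where(off, r, 0.0))), r.shape)
        a, b = (roi_names[i], roi_names[j]) if roi_names is not None else (i, j)
        raise DegenerateCorrelationError(
            f"|r| = {worst:.15f} between {a} and {b}: duplicated or collinear traces"
        )
    np.fill_diagonal(r, 0.0)  # diagonal is masked downstream; avoid atanh(1)
    z = np.arctanh(np.clip(r, -1.0, 1.0))
    return ConnectivityMatrix(z=z, level="run", subject_id=subject_id)


def combine_runs(run_matrices, level: str) -> ConnectivityMatrix:
    """Entrywise mean of Fisher-z matrices over the selected runs.

    ``level`` is recorded on the output ("day1", "day2" or "session"); the
    caller selects which run matrices belong to the level.
    """
    run_matrices = list(run_matrices)
    if not run_matrices:
        raise ValueError(f"empty run selection for level {level!r}")
    n = run_matrices[0].n_rois
    for m in run_matrices:
        if m.n_rois != n:
            raise ValueError("run matrices have mismatched sizes")
    stack = np.stack([m.z for m in run_matrices])
    return ConnectivityMatrix(
        z=stack.mean(axis=0), level=level, subject_id=run_matrices[0].subject_id
    )


def subject_connectivity(
    subject: SubjectTimeseries,
    atlas: ROIAtlas,
    levels=("session",),
    concatenate: bool = False,
) -> dict:
    """Per-subject connectivity at the requested levels.

    Runs are normalized to percent signal change individually, correlated,
    Fisher transformed, and averaged in z space (default).  With
    ``concatenate=True`` the normalized runs of a level are concatenated in
    time and correlated once instead.

    Returns a dict mapping level name to :class:`ConnectivityMatrix`.
    """
    subject.validate(atlas)
    names = list(atlas.names)

    def runs_for(level):
        if level == "day1":
            return [r for r in subject.runs if r.day == 1]
        if level == "day2":
            return [r for r in subject.runs if r.day == 2]
        return list(subject.runs)

    out = {}
    norm_cache = {}
    for level in levels:
        runs = runs_for(level)
        if not runs:
            raise ValueError(f"subject {subject.subject_id}: no runs for level {level!r}")
        normed = []
        for r in runs:
            key = id(r)
            if key not in norm_cache:
                norm_cache[key] = percent_signal_change(r.data, roi_names=names)
            normed.append(norm_cache[key])
        if concatenate:
            mat = correlate_run(
                np.vstack(normed), subject_id=subject.subject_id, roi_names=names
            )
            mat.level = level if level != "run" else "session"
            out[level] = mat
        else:
            run_mats = [
                correlate_run(d, subject_id=subject.subject_id, roi_names=names)
                for d in normed
            ]
            out[level] = combine_runs(run_mats, level if level in LEVELS else "session")
    return out
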
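"""Mirror matrices, the condensed asymmetry (AFC) matrix, and group statistics.

The asymmetry of a connectivity matrix is the difference between the matrix
and its left/right-mirrored counterpart.  With the atlas ordered as 38
homologue pairs this difference contains each independent value twice (with
opposite signs), so it is condensed into a P x P matrix:

* lower triangle (row i > column j): within-hemisphere asymmetry
  z(L_i, L_j) - z(R_i, R_j)
* upper triangle (i < j): between-hemisphere asymmetry
  z(L_i, R_j) - z(R_i, L_j)

Homotopic connections (a region with its own homologue) are invariant under
mirroring, so their asymmetry is identically zero; they sit on the condensed
diagonal and are excluded from the non-redundant vector, which therefore has
P(P-1) entries (1406 for the default 38-pair atlas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .atlas import ROIAtlas, mirror_permutation
from .connectivity import ConnectivityMatrix

__all__ = [
    "AFCMatrix",
    "mirror_matrix",
    "afc_matrix",
    "afc_from_vector",
    "group_mean_afc",
    "entrywise_tests",
    "paired_entrywise_tests",
    "symmetry_index",
]


@dataclass
class AFCMatrix:
    """Condensed pair x pair asymmetry matrix with a masked (NaN) diagonal."""

    condensed: np.ndarray
    subject_id: str = ""
    level: str = "session"

    def __post_init__(self) -> None:
        self.condensed = np.asarray(self.condensed, dtype=float)
        p = self.condensed.shape[0]
        if self.condensed.ndim != 2 or self.condensed.shape[1] != p:
            raise ValueError("condensed matrix must be square")
        np.fill_diagonal(self.condensed, np.nan)

    @property
    def n_pairs(self) -> int:
        return self.condensed.shape[0]

    @property
    def vector(self) -> np.ndarray:
        """The P(P-1) non-redundant values in canonical order.

        Lower triangle (within-hemisphere) row-major by pair index first, then
        the upper triangle (between-hemisphere) row-major.
        """
        p = self.n_pairs
        il = np.tril_indices(p, k=-1)
        iu = np.triu_indices(p, k=1)
        return np.concatenate([self.condensed[il], self.condensed[iu]])

    @classmethod
    def from_vector(cls, vector: np.ndarray, n_pairs: int, **kw) -> "AFCMatrix":
        return afc_from_vector(vector, n_pairs, **kw)


def afc_from_vector(vector: np.ndarray, n_pairs: int, **kw) -> AFCMatrix:
    """Rebuild a condensed matrix from a canonical-order vector."""
    vector = np.asarray(vector, dtype=float)
    p = n_pairs
    if vector.size != p * (p - 1):
        raise ValueError(f"vector length {vector.size} != P(P-1) = {p * (p - 1)}")
    half = p * (p - 1) // 2
    cond = np.full((p, p), np.nan)
    il = np.tril_indices(p, k=-1)
    iu = np.triu_indices(p, k=1)
    cond[il] = vector[:half]
    cond[iu] = vector[half:]
    return AFCMatrix(condensed=cond, **kw)


def mirror_matrix(z: ConnectivityMatrix, atlas: ROIAtlas) -> ConnectivityMatrix:
    """Connectivity of the same brain mirrored across the longitudinal fissure.

    Conjugates the matrix by the mirror permutation: M = P^T z P.  Applying
    the operation twice returns the original matrix exactly.
    """
    if z.n_rois != atlas.n_rois:
        raise ValueError(f"matrix has {z.n_rois} ROIs, atlas has {atlas.n_rois}")
    perm = mirror_permutation(atlas)
    return ConnectivityMatrix(
        z=z.z[np.ix_(perm, perm)], level=z.level, subject_id=z.subject_id
    )


def afc_matrix(z: ConnectivityMatrix, atlas: ROIAtlas) -> AFCMatrix:
    """Condensed asymmetry matrix of ``z`` (original minus mirrored).

    Positive values are left-favoring: stronger left-left than right-right
    connectivity (lower triangle), or stronger left_i-right_j than
    right_i-left_j connectivity (upper triangle).
    """
    if z.n_rois != atlas.n_rois:
        raise ValueError(f"matrix has {z.n_rois} ROIs, atlas has {atlas.n_rois}")
    li = atlas.left_indices
    ri = atlas.right_indices
    p = atlas.n_pairs
    zl = z.z
    cond = np.full((p, p), np.nan)
    # within-hemisphere: lower triangle, z(L_i,L_j) - z(R_i,R_j)
    within = zl[np.ix_(li, li)] - zl[np.ix_(ri, ri)]
    # between-hemisphere: upper triangle, z(L_i,R_j) - z(R_i,L_j)
    between = zl[np.ix_(li, ri)] - zl[np.ix_(ri, li)]
    il = np.tril_indices(p, k=-1)
    iu = np.triu_indices(p, k=1)
    cond[il] = within[il]
    cond[iu] = between[iu]
    return AFCMatrix(condensed=cond, subject_id=z.subject_id, level=z.level)


def group_mean_afc(subjects) -> AFCMatrix:
    """Entrywise mean of subject asymmetry matrices."""
    subjects = list(subjects)
    if not subjects:
        raise ValueError("empty subject list")
    p = subjects[0].n_pairs
    for s in subjects:
        if s.n_pairs != p:
            raise ValueError("subjects have mismatched atlas sizes")
    stack = np.stack([s.condensed for s in subjects])
    return AFCMatrix(condensed=stack.mean(axis=0), subject_id="group-mean")


def _t_table(values: np.ndarray, t: np.ndarray, pval: np.ndarray, alpha, m):
    import pandas as pd

    sig = pval < alpha / m
    return pd.DataFrame(
        {
            "mean": values,
            "t": t,
            "p_uncorrected": pval,
            "significant": sig,
        }
    )


def entrywise_tests(subjects, correction_m: int | None = None, alpha: float = 0.05):
    """One-sample two-tailed t test per asymmetry entry against zero.

    Bonferroni significance is flagged at alpha / correction_m, where
    ``correction_m`` defaults to the number of entries tested (P(P-1), i.e.
    1406 on the default atlas).  Entries with zero variance across subjects
    get NaN t and p (reported, never silently dropped).

    Returns a DataFrame with one row per canonical-vector entry.
    """
    subjects = list(subjects)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for entrywise t tests")
    data = np.stack([s.vector for s in subjects])  # subjects x entries
    n, m_entries = data.shape
    if correction_m is None:
        correction_m = m_entries
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    t = np.full(m_entries, np.nan)
    pval = np.full(m_entries, np.nan)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    pval[ok] = 2 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    return _t_table(mean, t, pval, alpha, correction_m)


def paired_entrywise_tests(
    subjects_a, subjects_b, correction_m: int | None = None, alpha: float = 0.05
):
    """Paired two-tailed t test per entry between two matched condition lists.

    Serves comparisons such as day 1 vs. day 2 or the two phase-encoding
    directions; operates on the entrywise differences.
    """
    subjects_a, subjects_b = list(subjects_a), list(subjects_b)
    if len(subjects_a) != len(subjects_b):
        raise ValueError("paired lists must have equal length")
    diffs = [
        AFCMatrix(condensed=a.condensed - b.condensed)
        for a, b in zip(subjects_a, subjects_b)
    ]
    return entrywise_tests(diffs, correction_m=correction_m, alpha=alpha)


def symmetry_index(group_z: ConnectivityMatrix, atlas: ROIAtlas):
    """Quantify how symmetric a (group-mean) connectivity matrix is.

    Computes ICC(2,1) between the unique off-diagonal Fisher-z values of the
    matrix and the corresponding values of its mirrored counterpart, with
    homotopic connections excluded (they are mirror-invariant and would
    inflate the agreement).  The percentage of connectivity variance that is
    symmetric is 100 * ICC^2.

    Returns
    -------
    (icc, percent_symmetric)
    """
    from .scores import icc_2_1

    mirrored = mirror_matrix(group_z, atlas)
    n = group_z.n_rois
    iu = np.triu_indices(n, k=1)
    # homotopic mask: (left member, right member) of the same pair
    homotopic = np.zeros((n, n), dtype=bool)
    li, ri = atlas.left_indices, atlas.right_indices
    homotopic[li, ri] = True
    homotopic[ri, li] = True
    keep = ~homotopic[iu]
    x = group_z.z[iu][keep]
    y = mirrored.z[iu][keep]
    res = icc_2_1(np.column_stack([x, y]))
    return res.icc, 100.0 * res.icc**2
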
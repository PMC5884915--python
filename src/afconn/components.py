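"""PCA of subject asymmetry vectors and cross-session component reliability.

Principal component analysis is run with the asymmetry-matrix entries as
variables and subjects as observations (covariance PCA on mean-centered
entries — entries share units of Delta-z, so no per-entry standardization).
Components are rescaled so that the root mean square of each component's
subject scores is 1, with coefficients rescaled reciprocally to preserve the
reconstruction.  Cross-session reliability re-scores subjects on per-day
asymmetry vectors by regressing them on the combined-session component
coefficients, then takes ICC(2,1) across days; component similarity is the
Pearson correlation between matched coefficient vectors (component signs are
arbitrary, so matching maximizes |r|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .scores import fit_score, icc_2_1

__all__ = [
    "ComponentModel",
    "pca_afc",
    "fit_component_scores",
    "match_components",
    "component_reliability",
]


@dataclass
class ComponentModel:
    """PCA decomposition of a subjects x entries asymmetry matrix.

    Attributes
    ----------
    coefficients : (components, entries) array
        Each row is a pattern of asymmetry; reshapeable to a condensed matrix.
    scores : (subjects, components) array
        Per-subject expression of each pattern; RMS of each column is 1.
    variance_explained : (components,) array, percent of total variance.
    grand_mean : (entries,) array, the per-entry mean removed before PCA.
    """

    coefficients: np.ndarray
    scores: np.ndarray
    variance_explained: np.ndarray
    grand_mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coefficients.shape[0]

    def reconstruct(self) -> np.ndarray:
        """grand_mean + scores @ coefficients (exact if all components kept)."""
        return self.grand_mean + self.scores @ self.coefficients


def pca_afc(subject_vectors: np.ndarray, n_components: int | None = None) -> ComponentModel:
    """Covariance PCA of subject asymmetry vectors with RMS-1 score scaling.

    Parameters
    ----------
    subject_vectors : (subjects, entries) array.
    n_components : number of leading components to keep (default: all
        min(subjects - 1, entries)).
    """
    x = np.asarray(subject_vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 entries")
    max_k = min(x.shape[0] - 1, x.shape[1])
    if n_components is None:
        n_components = max_k
    if n_components > max_k:
        raise ValueError(
            f"requested {n_components} components but at most {max_k} are defined"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    raw_scores = pca.fit_transform(x)  # subjects x k, mean-centered
    rms = np.sqrt((raw_scores**2).mean(axis=0))
    rms[rms == 0] = 1.0
    scores = raw_scores / rms
    coefficients = pca.components_ * rms[:, None]
    return ComponentModel(
        coefficients=coefficients,
        scores=scores,
        variance_explained=100.0 * pca.explained_variance_ratio_,
        grand_mean=pca.mean_,
    )


def fit_component_scores(component: np.ndarray, subject_afc: np.ndarray) -> float:
    """Score one subject on one component by simple regression.

    Slope of OLS (with intercept) of the subject's asymmetry vector on the
    component coefficient vector — one component at a time.
    """
    return fit_score(subject_afc, component).beta


def match_components(model_a: ComponentModel, model_b: ComponentModel) -> pd.DataFrame:
    """For each component of ``model_a``, its best match in ``model_b``.

    The match maximizes |Pearson r| between coefficient vectors; ``sign``
    records the sign of r (component signs are arbitrary).

    Returns a DataFrame with columns (index_a, index_b, r, sign).
    """
    if model_a.coefficients.shape[1] != model_b.coefficients.shape[1]:
        raise ValueError("models are defined over different entry sets")
    rows = []
    for ia, ca in enumerate(model_a.coefficients):
        best = None
        for ib, cb in enumerate(model_b.coefficients):
            r = float(np.corrcoef(ca, cb)[0, 1])
            if best is None or abs(r) > abs(best[1]):
                best = (ib, r)
        rows.append(
            {
                "index_a": ia,
                "index_b": best[0],
                "r": best[1],
                "sign": int(np.sign(best[1])) if best[1] != 0 else 1,
            }
        )
    return pd.DataFrame(rows)


def component_reliability(
    day1_afc: np.ndarray,
    day2_afc: np.ndarray,
    combined_model: ComponentModel,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Between-session reliability and similarity of the leading components.

    For each retained combined-session component: subjects are re-scored on
    their day-1-only and day-2-only asymmetry vectors by regression on the
    component coefficients, and ICC(2,1) of those scores across days is the
    between-session reliability.  Separate PCAs of each day are matched to
    the combined model to give coefficient similarities (day 1 vs. day 2, and
    each day vs. combined), reported as sign-aligned |r|-maximizing Pearson
    correlations.

    Returns a DataFrame with one row per component and columns
    (variance_explained, icc_between_sessions, similarity_12, similarity_1,
    similarity_2).
    """
    day1 = np.asarray(day1_afc, dtype=float)
    day2 = np.asarray(day2_afc, dtype=float)
    if day1.shape != day2.shape:
        raise ValueError("day 1 and day 2 must cover the same subjects and entries")
    k = n_components or combined_model.n_components
    k = min(k, combined_model.n_components)
    max_day_k = min(day1.shape[0] - 1, day1.shape[1])
    model1 = pca_afc(day1, n_components=min(k, max_day_k))
    model2 = pca_afc(day2, n_components=min(k, max_day_k))

    sub_a = ComponentModel(
        coefficients=combined_model.coefficients[:k],
        scores=combined_model.scores[:, :k],
        variance_explained=combined_model.variance_explained[:k],
        grand_mean=combined_model.grand_mean,
    )
    m1 = match_components(sub_a, model1)
    m2 = match_components(sub_a, model2)

    rows = []
    for c in range(k):
        comp = combined_model.coefficients[c]
        s1 = np.array([fit_component_scores(comp, v) for v in day1])
        s2 = np.array([fit_component_scores(comp, v) for v in day2])
        icc = icc_2_1(np.column_stack([s1, s2])).icc
        c1 = model1.coefficients[int(m1.loc[c, "index_b"])]
        c2 = model2.coefficients[int(m2.loc[c, "index_b"])]
        sim1 = float(m1.loc[c, "r"])
        sim2 = float(m2.loc[c, "r"])
        sim12 = float(np.corrcoef(c1, c2)[0, 1])
        # sign-align all similarities to the combined component
        sim12 *= np.sign(sim1) * np.sign(sim2) if sim1 and sim2 else 1.0
        rows.append(
            {
                "variance_explained": float(combined_model.variance_explained[c]),
                "icc_between_sessions": float(icc),
                "similarity_12": sim12,
                "similarity_1": abs(sim1),
                "similarity_2": abs(sim2),
            }
        )
    return pd.DataFrame(rows, index=pd.RangeIndex(k, name="component"))
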
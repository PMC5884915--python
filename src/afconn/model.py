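"""Model/results interface tying the analysis stages together.

:class:`AFCModel` is constructed from per-subject asymmetry data (directly
from vectors, or from raw ROI timeseries via :meth:`AFCModel.from_timeseries`)
and ``fit()`` produces an :class:`AFCResults` carrying the group-mean
asymmetry, entrywise significance tests, the symmetry index, per-subject
scores with test-retest reliability, the principal-component decomposition
with its cross-session reliability, and an optional behavioral screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import asymmetry as asym
from . import components as comp
from . import connectivity as conn
from . import scores as sc
from .asymmetry import AFCMatrix, afc_from_vector
from .atlas import ROIAtlas
from .connectivity import ConnectivityMatrix

__all__ = ["AFCModel", "AFCResults"]


class AFCModel:
    """Group asymmetry model over a cohort of subjects.

    Parameters
    ----------
    afc_vectors : (subjects, P(P-1)) array
        Session-level condensed asymmetry vectors in canonical order.
    atlas : the ROI atlas defining pairing and vector layout.
    day1_vectors, day2_vectors : optional per-day asymmetry vectors
        (same subjects, same order) enabling reliability analyses.
    group_z : optional group-mean Fisher-z connectivity matrix enabling the
        symmetry index.
    behavioral : optional DataFrame (one row per subject) screened against
        the fitted scores.
    """

    def __init__(
        self,
        afc_vectors: np.ndarray,
        atlas: ROIAtlas,
        day1_vectors: np.ndarray | None = None,
        day2_vectors: np.ndarray | None = None,
        subject_ids=None,
        group_z: ConnectivityMatrix | None = None,
        behavioral: pd.DataFrame | None = None,
    ):
        self.afc_vectors = np.asarray(afc_vectors, dtype=float)
        if self.afc_vectors.ndim != 2:
            raise ValueError("afc_vectors must be subjects x entries")
        p = atlas.n_pairs
        if self.afc_vectors.shape[1] != p * (p - 1):
            raise ValueError(
                f"entries ({self.afc_vectors.shape[1]}) != P(P-1) = {p * (p - 1)}"
            )
        self.atlas = atlas
        self.day1_vectors = None if day1_vectors is None else np.asarray(day1_vectors, float)
        self.day2_vectors = None if day2_vectors is None else np.asarray(day2_vectors, float)
        for v in (self.day1_vectors, self.day2_vectors):
            if v is not None and v.shape != self.afc_vectors.shape:
                raise ValueError("day vectors must match afc_vectors in shape")
        n = self.afc_vectors.shape[0]
        self.subject_ids = (
            list(subject_ids)
            if subject_ids is not None
            else [f"sub-{i + 1:03d}" for i in range(n)]
        )
        if len(self.subject_ids) != n:
            raise ValueError("one subject id per row required")
        self.group_z = group_z
        self.behavioral = behavioral

    # -- construction -----------------------------------------------------

    @classmethod
    def from_timeseries(
        cls,
        subjects,
        atlas: ROIAtlas,
        behavioral: pd.DataFrame | None = None,
        concatenate: bool = False,
    ) -> "AFCModel":
        """Build the model from raw per-subject run timeseries.

        Computes session/day1/day2 Fisher-z connectivity per subject,
        condenses each to asymmetry vectors, and accumulates the group-mean
        connectivity for the symmetry index.  Subjects whose runs span only
        one day contribute no day-level vectors.
        """
        subjects = list(subjects)
        if not subjects:
            raise ValueError("empty cohort")
        have_days = all(
            {r.day for r in s.runs} >= {1, 2} for s in subjects
        )
        levels = ("session", "day1", "day2") if have_days else ("session",)
        sess, d1, d2 = [], [], []
        ids = []
        z_sum = None
        for s in subjects:
            mats = conn.subject_connectivity(s, atlas, levels=levels, concatenate=concatenate)
            sess.append(asym.afc_matrix(mats["session"], atlas).vector)
            if have_days:
                d1.append(asym.afc_matrix(mats["day1"], atlas).vector)
                d2.append(asym.afc_matrix(mats["day2"], atlas).vector)
            ids.append(s.subject_id)
            z = mats["session"].z
            z_sum = z.copy() if z_sum is None else z_sum + z
        group_z = ConnectivityMatrix(
            z=z_sum / len(subjects), level="session", subject_id="group-mean"
        )
        return cls(
            np.array(sess),
            atlas,
            day1_vectors=np.array(d1) if have_days else None,
            day2_vectors=np.array(d2) if have_days else None,
            subject_ids=ids,
            group_z=group_z,
            behavioral=behavioral,
        )

    @property
    def n_subjects(self) -> int:
        return self.afc_vectors.shape[0]

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        n_components: int = 3,
        alpha: float = 0.05,
        leave_one_out: bool = False,
    ) -> "AFCResults":
        """Estimate group asymmetry, subject scores, components and reliability."""
        atlas = self.atlas
        p = atlas.n_pairs
        group_mean = asym.afc_from_vector(
            self.afc_vectors.mean(axis=0), p, subject_id="group-mean"
        )
        template = group_mean.vector
        afc_scores = sc.score_cohort(
            self.afc_vectors, None if leave_one_out else template,
            leave_one_out=leave_one_out,
        )
        entry_tests = None
        if self.n_subjects >= 3:
            mats = [afc_from_vector(v, p) for v in self.afc_vectors]
            entry_tests = asym.entrywise_tests(mats, alpha=alpha)

        symmetry_icc = symmetry_percent = None
        if self.group_z is not None:
            symmetry_icc, symmetry_percent = asym.symmetry_index(self.group_z, atlas)

        day_scores = score_icc = None
        if self.day1_vectors is not None and self.day2_vectors is not None:
            s1 = np.array([sc.fit_score(v, template).beta for v in self.day1_vectors])
            s2 = np.array([sc.fit_score(v, template).beta for v in self.day2_vectors])
            day_scores = np.column_stack([s1, s2])
            if self.n_subjects >= 2:
                score_icc = sc.icc_2_1(day_scores)

        k = min(n_components, max(self.n_subjects - 1, 1), self.afc_vectors.shape[1])
        component_model = comp.pca_afc(self.afc_vectors, n_components=k)
        reliability = None
        if (
            self.day1_vectors is not None
            and self.day2_vectors is not None
            and self.n_subjects >= 3
        ):
            reliability = comp.component_reliability(
                self.day1_vectors, self.day2_vectors, component_model
            )

        screen = None
        if self.behavioral is not None:
            screen = sc.behavioral_screen(afc_scores, self.behavioral, alpha=alpha)

        return AFCResults(
            model=self,
            group_mean=group_mean,
            afc_scores=afc_scores,
            day_scores=day_scores,
            score_reliability=score_icc,
            entrywise=entry_tests,
            symmetry_icc=symmetry_icc,
            symmetry_percent=symmetry_percent,
            components=component_model,
            component_reliability=reliability,
            behavioral_screen=screen,
            alpha=alpha,
        )


@dataclass
class AFCResults:
    """Fitted group asymmetry results.

    ``afc_scores`` are the per-subject template-regression slopes;
    ``symmetry_percent`` is 100 * ICC(2,1)^2 between the group connectivity
    and its mirrored counterpart; ``components`` carries the PCA of subject
    asymmetry vectors with RMS-1 score scaling.
    """

    model: AFCModel
    group_mean: AFCMatrix
    afc_scores: np.ndarray
    day_scores: np.ndarray | None
    score_reliability: sc.ICCResult | None
    entrywise: pd.DataFrame | None
    symmetry_icc: float | None
    symmetry_percent: float | None
    components: comp.ComponentModel
    component_reliability: pd.DataFrame | None
    behavioral_screen: pd.DataFrame | None
    alpha: float = 0.05

    def scores_frame(self) -> pd.DataFrame:
        d = {"subject_id": self.model.subject_ids, "afc_score": self.afc_scores}
        if self.day_scores is not None:
            d["afc_score_day1"] = self.day_scores[:, 0]
            d["afc_score_day2"] = self.day_scores[:, 1]
        return pd.DataFrame(d)

    def n_significant_entries(self) -> int:
        if self.entrywise is None:
            return 0
        return int(self.entrywise["significant"].sum())

    def summary(self) -> str:
        m = self.model
        p = m.atlas.n_pairs
        lines = [
            "Asymmetric functional connectivity — fit summary",
            "=" * 52,
            f"subjects: {m.n_subjects}    pairs: {p}    "
            f"asymmetry entries: {p * (p - 1)}",
        ]
        if self.symmetry_icc is not None:
            lines.append(
                f"group symmetry: ICC(2,1) = {self.symmetry_icc:.3f}  "
                f"({self.symmetry_percent:.1f}% symmetric)"
            )
        if self.entrywise is not None:
            lines.append(
                f"entries significant after Bonferroni (alpha={self.alpha}): "
                f"{self.n_significant_entries()} / {len(self.entrywise)}"
            )
        s = self.afc_scores
        lines.append(
            f"AFC-score: mean {s.mean():.3f}, sd {s.std(ddof=1):.3f}"
            if s.size > 1
            else f"AFC-score: {s[0]:.3f}"
        )
        if self.score_reliability is not None:
            r = self.score_reliability
            lines.append(
                f"AFC-score day1/day2 reliability: ICC(2,1) = {r.icc:.3f} "
                f"(95% CI [{r.ci_low:.3f}, {r.ci_high:.3f}])"
            )
        ve = self.components.variance_explained
        lines.append(
            "components (% variance): "
            + ", ".join(f"{v:.2f}" for v in ve)
        )
        if self.component_reliability is not None:
            lines.append("component reliability (ICC / similarity day1-day2):")
            for i, row in self.component_reliability.iterrows():
                lines.append(
                    f"  comp {i}: ICC {row.icc_between_sessions:.2f}, "
                    f"r12 {row.similarity_12:.2f}, r1 {row.similarity_1:.2f}, "
                    f"r2 {row.similarity_2:.2f}"
                )
        if self.behavioral_screen is not None and len(self.behavioral_screen):
            nsig = int(self.behavioral_screen["significant"].sum())
            lines.append(
                f"behavioral screen: {nsig} / {len(self.behavioral_screen)} "
                "variables significant after Bonferroni"
            )
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_afc(self, which: str = "group", component: int = 0, ax=None):
        """Heatmap of the group-mean (or one component's) condensed matrix."""
        import matplotlib.pyplot as plt

        if which == "group":
            mat = self.group_mean.condensed
            title = "group-mean asymmetry (Delta z)"
        elif which == "component":
            mat = afc_from_vector(
                self.components.coefficients[component], self.model.atlas.n_pairs
            ).condensed
            title = f"component {component} coefficients"
        else:
            raise ValueError("which must be 'group' or 'component'")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        lim = np.nanmax(np.abs(mat))
        im = ax.imshow(mat, cmap="RdBu_r", vmin=-lim, vmax=lim)
        ax.set_title(title)
        ax.set_xlabel("pair (x: within lower / between upper)")
        ax.set_ylabel("pair")
        ax.figure.colorbar(im, ax=ax, label="Delta z")
        return ax
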
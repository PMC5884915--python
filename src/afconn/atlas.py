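"""ROI atlas with left/right homologue pairing, timeseries containers and file I/O.

The atlas defines the canonical ROI order (left-hemisphere block first, then
the right-hemisphere block with pairs aligned by ``pair_id``) and, through the
pairing, the mirror permutation that swaps every region with its contralateral
homologue.  The bundled default atlas (``atlas_dk38.tsv``) holds the 34
Desikan-Killiany cortical parcels per hemisphere plus Cerebellum-Cortex,
Hippocampus, Amygdala and VentralDC, i.e. 76 ROIs forming 38 homologue pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROIAtlas",
    "RunTimeseries",
    "SubjectTimeseries",
    "load_atlas",
    "default_atlas",
    "mirror_permutation",
    "extract_roi_timeseries",
    "write_run",
    "read_run",
    "write_matrix",
    "read_matrix",
    "AtlasError",
]

HEMISPHERES = ("left", "right", "none")


class AtlasError(ValueError):
    """Schema or pairing violation in an ROI atlas definition."""


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered list of ROIs with hemisphere labels and homologue pairing.

    Attributes
    ----------
    names : tuple of str
        Unique ROI names in file (= matrix) order.
    hemispheres : tuple of str
        ``"left"``, ``"right"`` or ``"none"`` per ROI.
    pair_ids : tuple of int
        1-based homologue pair index; 0 for unpaired (``hemisphere="none"``) ROIs.
    label_values : tuple of int or None
        Integer labels used for volumetric extraction, if provided.
    """

    names: tuple
    hemispheres: tuple
    pair_ids: tuple
    label_values: tuple | None = None
    # filled in __post_init__
    _left_of_pair: np.ndarray = field(init=False, repr=False, compare=False)
    _right_of_pair: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = list(self.names)
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise AtlasError(f"duplicate ROI names: {dup}")
        for h in self.hemispheres:
            if h not in HEMISPHERES:
                raise AtlasError(f"invalid hemisphere label {h!r}")
        pair_ids = np.asarray(self.pair_ids, dtype=int)
        hemis = np.asarray(self.hemispheres)
        paired = pair_ids[hemis != "none"]
        if paired.size:
            pids = np.unique(paired)
            if pids.min() < 1 or not np.array_equal(pids, np.arange(1, pids.size + 1)):
                raise AtlasError("pair_ids must cover 1..P without gaps")
        n_pairs = int(paired.max()) if paired.size else 0
        left = np.full(n_pairs, -1, dtype=int)
        right = np.full(n_pairs, -1, dtype=int)
        for i, (h, p) in enumerate(zip(hemis, pair_ids)):
            if h == "none":
                continue
            side = left if h == "left" else right
            if side[p - 1] != -1:
                raise AtlasError(
                    f"pair {p} has two {h}-hemisphere members "
                    f"({self.names[side[p - 1]]!r}, {self.names[i]!r})"
                )
            side[p - 1] = i
        missing = [p + 1 for p in range(n_pairs) if left[p] == -1 or right[p] == -1]
        if missing:
            raise AtlasError(f"unpaired ROI(s): pair_id(s) {missing} lack a partner")
        object.__setattr__(self, "_left_of_pair", left)
        object.__setattr__(self, "_right_of_pair", right)

    @property
    def n_rois(self) -> int:
        return len(self.names)

    @property
    def n_pairs(self) -> int:
        return self._left_of_pair.size

    @property
    def left_indices(self) -> np.ndarray:
        """ROI index of the left member of pair p (0-based, ordered by pair_id)."""
        return self._left_of_pair.copy()

    @property
    def right_indices(self) -> np.ndarray:
        return self._right_of_pair.copy()

    @property
    def pair_names(self) -> list:
        """Display name per pair: the left member's name with side affixes stripped."""
        out = []
        for i in self._left_of_pair:
            n = self.names[i]
            for pre in ("ctx-lh-", "ctx-rh-", "Left-", "Right-", "lh-", "rh-"):
                if n.startswith(pre):
                    n = n[len(pre):]
                    break
            out.append(n)
        return out

    def to_frame(self) -> pd.DataFrame:
        d = {
            "name": list(self.names),
            "hemisphere": list(self.hemispheres),
            "pair_id": list(self.pair_ids),
        }
        if self.label_values is not None:
            d["label_value"] = list(self.label_values)
        return pd.DataFrame(d)


def load_atlas(path: str | Path) -> ROIAtlas:
    """Read an atlas TSV (columns: name, hemisphere, pair_id[, label_value])."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "hemisphere", "pair_id"}
    if not required.issubset(df.columns):
        raise AtlasError(f"atlas file missing columns {sorted(required - set(df.columns))}")
    labels = None
    if "label_value" in df.columns:
        labels = tuple(int(v) for v in df["label_value"])
    return ROIAtlas(
        names=tuple(df["name"].astype(str)),
        hemispheres=tuple(df["hemisphere"].astype(str)),
        pair_ids=tuple(int(v) for v in df["pair_id"]),
        label_values=labels,
    )


def default_atlas() -> ROIAtlas:
    """The bundled 76-ROI / 38-pair atlas."""
    with resources.as_file(resources.files("afconn.data") / "atlas_dk38.tsv") as p:
        return load_atlas(p)


def mirror_permutation(atlas: ROIAtlas) -> np.ndarray:
    """Permutation of ROI indices swapping each region with its homologue.

    Left/right partners exchange places; ``hemisphere="none"`` ROIs are fixed
    points.  The permutation is an involution (applying it twice is the
    identity), and on the default atlas it is fixed-point free (38
    transpositions).
    """
    perm = np.arange(atlas.n_rois)
    perm[atlas.left_indices] = atlas.right_indices
    perm[atlas.right_indices] = atlas.left_indices
    return perm


# ---------------------------------------------------------------------------
# timeseries containers


@dataclass
class RunTimeseries:
    """One run of ROI-mean signal: time x ROI matrix plus acquisition metadata."""

    data: np.ndarray
    day: int = 1
    run_index: int = 1
    phase_encode: str = "NA"
    tr_seconds: float = 0.72

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("run data must be a 2-D time x ROI matrix")
        if self.phase_encode not in ("LR", "RL", "NA"):
            raise ValueError(f"invalid phase_encode {self.phase_encode!r}")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")


@dataclass
class SubjectTimeseries:
    """All runs of one subject, validated against an atlas."""

    subject_id: str
    runs: list

    def validate(self, atlas: ROIAtlas) -> None:
        for r in self.runs:
            if r.data.shape[1] != atlas.n_rois:
                raise ValueError(
                    f"subject {self.subject_id}: run has {r.data.shape[1]} ROIs, "
                    f"atlas has {atlas.n_rois}"
                )
            sd = r.data.std(axis=0)
            flat = np.flatnonzero(sd == 0)
            if flat.size:
                names = [atlas.names[i] for i in flat]
                raise ValueError(
                    f"subject {self.subject_id}: constant (zero-variance) trace for ROI(s) {names}"
                )


# ---------------------------------------------------------------------------
# volumetric extraction


def extract_roi_timeseries(
    image: np.ndarray, labels: np.ndarray, atlas: ROIAtlas
) -> np.ndarray:
    """Mean voxel timeseries per atlas ROI from a 4-D image and a label volume.

    Parameters
    ----------
    image : 4-D array (x, y, z, t) or a nibabel spatial image.
    labels : 3-D integer array (or nibabel image) on the same grid.
    atlas : atlas whose ``label_values`` select the voxels of each ROI.

    Returns
    -------
    (t, n_rois) array; column j is the mean over voxels carrying ROI j's label.
    """
    if hasattr(image, "get_fdata"):
        image = image.get_fdata()
    if hasattr(labels, "get_fdata"):
        labels = np.asarray(labels.get_fdata()).astype(int)
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if image.ndim != 4:
        raise ValueError("image must be 4-D (x, y, z, t)")
    if labels.shape != image.shape[:3]:
        raise ValueError("label volume grid does not match the image grid")
    if atlas.label_values is None:
        raise AtlasError("atlas has no label_value column; cannot extract from volumes")
    present = set(np.unique(labels).tolist())
    absent = [v for v in atlas.label_values if v not in present]
    if absent:
        raise ValueError(f"label value(s) absent from label volume: {absent}")
    n_t = image.shape[3]
    out = np.empty((n_t, atlas.n_rois))
    flat = image.reshape(-1, n_t)
    lab_flat = labels.reshape(-1)
    for j, v in enumerate(atlas.label_values):
        out[:, j] = flat[lab_flat == v].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# file I/O: run TSV + JSON sidecar; matrices as TSV with ROI-name headers


def write_run(run: RunTimeseries, atlas: ROIAtlas, path: str | Path) -> None:
    """Write one run as TSV (rows = timepoints, columns = ROI names) + JSON sidecar."""
    path = Path(path)
    pd.DataFrame(run.data, columns=list(atlas.names)).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
    meta = {
        "day": run.day,
        "run_index": run.run_index,
        "phase_encode": run.phase_encode,
        "tr_seconds": run.tr_seconds,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_run(path: str | Path, atlas: ROIAtlas | None = None) -> RunTimeseries:
    """Read a run TSV written by :func:`write_run`, reordering columns to the atlas."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if atlas is not None:
        missing = [n for n in atlas.names if n not in df.columns]
        if missing:
            raise ValueError(f"run file {path} missing ROI column(s): {missing}")
        df = df[list(atlas.names)]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return RunTimeseries(
        data=df.to_numpy(dtype=float),
        day=int(meta.get("day", 1)),
        run_index=int(meta.get("run_index", 1)),
        phase_encode=str(meta.get("phase_encode", "NA")),
        tr_seconds=float(meta.get("tr_seconds", 0.72)),
    )


def write_matrix(matrix: np.ndarray, names: Sequence[str], path: str | Path) -> None:
    """Write a square named matrix as TSV with a header row and index column."""
    pd.DataFrame(matrix, index=list(names), columns=list(names)).to_csv(
        Path(path), sep="\t", float_format="%.10g"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)
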
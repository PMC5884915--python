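"""End-to-end orchestration: configuration, manifest validation, full runs.

A pipeline run reads an atlas and a subject manifest (subject id -> run TSV
files), computes per-subject connectivity and asymmetry, fits the group
model, and writes a reproducible bundle of TSV/JSON outputs.  All randomness
flows from the single configured seed; the run metadata records every
parameter used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_io
from .asymmetry import afc_from_vector
from .atlas import ROIAtlas, SubjectTimeseries, default_atlas, load_atlas
from .model import AFCModel

__all__ = ["PipelineConfig", "validate_manifest", "load_subject", "run_pipeline"]

log = logging.getLogger("afconn")


@dataclass
class PipelineConfig:
    """Validated configuration of a full analysis run."""

    manifest: dict = field(default_factory=dict)  # subject_id -> [run tsv paths]
    atlas_path: str | None = None  # None -> bundled default atlas
    behavioral_path: str | None = None  # TSV with subject_id column
    alpha: float = 0.05
    combine_mode: str = "average"  # or "concatenate"
    leave_one_out: bool = False
    n_components: int = 3
    similarity_threshold: float = 0.5
    output_dir: str = "afconn-out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def load_atlas(self) -> ROIAtlas:
        return load_atlas(self.atlas_path) if self.atlas_path else default_atlas()

    def validate(self) -> None:
        if self.combine_mode not in ("average", "concatenate"):
            raise ValueError(f"invalid combine_mode {self.combine_mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def validate_manifest(config: PipelineConfig) -> pd.DataFrame:
    """Check the manifest without running anything.

    Returns a report DataFrame (subject_id, issue, severity) where severity
    is "fatal" (missing files, ROI mismatches) or "warning" (run-count
    anomalies, reordered ROI columns).  An empty frame means a clean manifest.
    """
    atlas = config.load_atlas()
    issues = []
    counts = [len(v) for v in config.manifest.values()]
    typical = max(set(counts), key=counts.count) if counts else 0
    for sid, paths in config.manifest.items():
        if len(paths) != typical:
            issues.append((sid, f"{len(paths)} runs (cohort norm {typical})", "warning"))
        for p in paths:
            p = Path(p)
            if not p.exists():
                issues.append((sid, f"missing run file {p}", "fatal"))
                continue
            header = pd.read_csv(p, sep="\t", nrows=0)
            cols = list(header.columns)
            missing = [n for n in atlas.names if n not in cols]
            if missing:
                issues.append(
                    (sid, f"{p.name}: missing ROI column(s) {missing[:3]}...", "fatal")
                )
            elif cols != list(atlas.names):
                issues.append(
                    (sid, f"{p.name}: ROI columns reordered; will be reconciled by name",
                     "warning")
                )
    return pd.DataFrame(issues, columns=["subject_id", "issue", "severity"])


def load_subject(sid: str, paths, atlas: ROIAtlas) -> SubjectTimeseries:
    runs = [atlas_io.read_run(p, atlas) for p in paths]
    subject = SubjectTimeseries(subject_id=sid, runs=runs)
    subject.validate(atlas)
    return subject


def run_pipeline(config: PipelineConfig):
    """Run the full analysis and write the output bundle.

    Writes, under ``config.output_dir``: per-subject condensed asymmetry
    matrices, the group-mean asymmetry and connectivity, the entrywise test
    table, subject scores, component coefficients/scores/reliability, the
    behavioral screen (if configured) and run metadata.  Returns the fitted
    :class:`~afconn.model.AFCResults`.
    """
    config.validate()
    report = validate_manifest(config)
    fatal = report[report["severity"] == "fatal"]
    if len(fatal):
        first = fatal.iloc[0]
        raise RuntimeError(
            f"manifest validation failed ({len(fatal)} fatal issues; first: "
            f"subject {first.subject_id}: {first.issue})"
        )
    atlas = config.load_atlas()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    subjects = []
    for sid, paths in config.manifest.items():
        log.info("loading subject %s (%d runs)", sid, len(paths))
        subjects.append(load_subject(sid, paths, atlas))

    behavioral = None
    if config.behavioral_path:
        behavioral = pd.read_csv(config.behavioral_path, sep="\t")
        behavioral = behavioral.set_index("subject_id").loc[
            [s.subject_id for s in subjects]
        ].reset_index(drop=True)

    model = AFCModel.from_timeseries(
        subjects,
        atlas,
        behavioral=behavioral,
        concatenate=config.combine_mode == "concatenate",
    )
    results = model.fit(
        n_components=config.n_components,
        alpha=config.alpha,
        leave_one_out=config.leave_one_out,
    )

    pair_names = atlas.pair_names
    sub_dir = out / "subjects"
    sub_dir.mkdir(exist_ok=True)
    for sid, vec in zip(model.subject_ids, model.afc_vectors):
        atlas_io.write_matrix(
            afc_from_vector(vec, atlas.n_pairs).condensed,
            pair_names,
            sub_dir / f"{sid}_afc.tsv",
        )
    atlas_io.write_matrix(results.group_mean.condensed, pair_names, out / "group_afc.tsv")
    if model.group_z is not None:
        atlas_io.write_matrix(model.group_z.z, atlas.names, out / "group_connectivity.tsv")
    if results.entrywise is not None:
        results.entrywise.to_csv(out / "entrywise_tests.tsv", sep="\t", index_label="entry")
    results.scores_frame().to_csv(out / "scores.tsv", sep="\t", index=False)
    np.savetxt(out / "component_coefficients.tsv", results.components.coefficients,
               delimiter="\t")
    np.savetxt(out / "component_scores.tsv", results.components.scores, delimiter="\t")
    if results.component_reliability is not None:
        results.component_reliability.to_csv(
            out / "component_reliability.tsv", sep="\t", index_label="component"
        )
    if results.behavioral_screen is not None:
        results.behavioral_screen.to_csv(
            out / "behavioral_screen.tsv", sep="\t", index_label="variable"
        )
    meta = {
        "n_subjects": model.n_subjects,
        "n_pairs": atlas.n_pairs,
        "alpha": config.alpha,
        "combine_mode": config.combine_mode,
        "leave_one_out": config.leave_one_out,
        "n_components": config.n_components,
        "seed": config.seed,
        "symmetry_icc": results.symmetry_icc,
        "symmetry_percent": results.symmetry_percent,
        "score_reliability_icc": (
            results.score_reliability.icc if results.score_reliability else None
        ),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    (out / "summary.txt").write_text(results.summary() + "\n")
    return results
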
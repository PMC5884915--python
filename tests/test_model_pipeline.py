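import hashlib
import json

import matplotlib
import numpy as np
import pandas as pd
import pytest

matplotlib.use("Agg")

from click.testing import CliRunner

from afconn import atlas as atlas_io
from afconn.cli import main as cli_main
from afconn.model import AFCModel
from afconn.pipeline import PipelineConfig, run_pipeline, validate_manifest
from afconn.synthetic import CohortSpec, random_pattern, simulate_rs_cohort

from .conftest import make_atlas


@pytest.fixture(scope="module")
def cohort():
    atlas = make_atlas(4)
    rng = np.random.default_rng(42)
    pat = random_pattern(4, rng, rms=0.08)
    from afconn.synthetic import make_base_covariance

    base = make_base_covariance(atlas, network_blocks=[[0, 1], [2, 3]])
    spec = CohortSpec(
        n_subjects=8,
        base_correlation=base,
        volumes_per_run=120,
        runs_per_day=2,
        days=2,
        noise_sd=0.3,
        asymmetry_patterns=[(pat, 1.0, 0.3)],
        behavioral_links=[(0, 1.0, 0.3)],
        seed=99,
    )
    subjects, truth = simulate_rs_cohort(spec, atlas)
    return atlas, subjects, truth


class TestModel:
    def test_fit_produces_complete_results(self, cohort):
        atlas, subjects, truth = cohort
        behavioral = truth[["behavior_0"]]
        model = AFCModel.from_timeseries(subjects, atlas, behavioral=behavioral)
        res = model.fit(n_components=2)
        assert res.afc_scores.shape == (8,)
        assert res.symmetry_icc is not None and 0 < res.symmetry_icc <= 1
        assert res.day_scores.shape == (8, 2)
        assert res.score_reliability is not None
        assert res.components.n_components == 2
        assert res.component_reliability is not None
        assert res.behavioral_screen is not None
        assert "behavior_0" in res.behavioral_screen.index

    def test_template_scored_against_itself_is_one(self, cohort):
        atlas, subjects, _ = cohort
        model = AFCModel.from_timeseries(subjects, atlas)
        res = model.fit()
        from afconn.scores import fit_score

        template = res.group_mean.vector
        assert np.isclose(fit_score(template, template).beta, 1.0)

    def test_summary_mentions_key_quantities(self, cohort):
        atlas, subjects, _ = cohort
        res = AFCModel.from_timeseries(subjects, atlas).fit(n_components=2)
        text = res.summary()
        assert "symmetry" in text
        assert "AFC-score" in text
        assert "components" in text

    def test_scores_frame_columns(self, cohort):
        atlas, subjects, _ = cohort
        res = AFCModel.from_timeseries(subjects, atlas).fit()
        frame = res.scores_frame()
        assert list(frame.columns) == [
            "subject_id", "afc_score", "afc_score_day1", "afc_score_day2",
        ]

    def test_plot_returns_axes(self, cohort):
        atlas, subjects, _ = cohort
        res = AFCModel.from_timeseries(subjects, atlas).fit(n_components=2)
        ax = res.plot_afc("group")
        assert ax is not None
        ax2 = res.plot_afc("component", component=1)
        assert ax2 is not None

    def test_vector_shape_validation(self, cohort):
        atlas, _, _ = cohort
        with pytest.raises(ValueError, match="P"):
            AFCModel(np.zeros((3, 10)), atlas)


def write_cohort(tmp_path, atlas, subjects):
    manifest = {}
    for s in subjects:
        paths = []
        for i, run in enumerate(s.runs):
            p = tmp_path / f"{s.subject_id}_run{i}.tsv"
            atlas_io.write_run(run, atlas, p)
            paths.append(str(p))
        manifest[s.subject_id] = paths
    return manifest


class TestPipeline:
    def test_full_run_and_determinism(self, cohort, tmp_path):
        atlas, subjects, truth = cohort
        atlas_path = tmp_path / "atlas.tsv"
        atlas.to_frame().to_csv(atlas_path, sep="\t", index=False)
        manifest = write_cohort(tmp_path, atlas, subjects)
        beh_path = tmp_path / "behavior.tsv"
        truth[["subject_id", "behavior_0"]].to_csv(beh_path, sep="\t", index=False)
        config = PipelineConfig(
            manifest=manifest,
            atlas_path=str(atlas_path),
            behavioral_path=str(beh_path),
            n_components=2,
            output_dir=str(tmp_path / "out1"),
        )
        results = run_pipeline(config)
        out = tmp_path / "out1"
        for f in ["group_afc.tsv", "scores.tsv", "entrywise_tests.tsv",
                  "component_reliability.tsv", "behavioral_screen.tsv",
                  "run_metadata.json", "summary.txt"]:
            assert (out / f).exists(), f
        meta = json.loads((out / "run_metadata.json").read_text())
        assert meta["n_subjects"] == 8
        # rerun reproduces identical outputs
        config2 = PipelineConfig(
            manifest=manifest,
            atlas_path=str(atlas_path),
            behavioral_path=str(beh_path),
            n_components=2,
            output_dir=str(tmp_path / "out2"),
        )
        run_pipeline(config2)
        for f in ["group_afc.tsv", "scores.tsv"]:
            h1 = hashlib.sha256((out / f).read_bytes()).hexdigest()
            h2 = hashlib.sha256((tmp_path / "out2" / f).read_bytes()).hexdigest()
            assert h1 == h2
        assert results.symmetry_percent > 80

    def test_validate_manifest_flags_missing_file(self, cohort, tmp_path):
        atlas, subjects, _ = cohort
        atlas_path = tmp_path / "atlas.tsv"
        atlas.to_frame().to_csv(atlas_path, sep="\t", index=False)
        manifest = write_cohort(tmp_path, atlas, subjects[:2])
        manifest[subjects[0].subject_id].append(str(tmp_path / "nope.tsv"))
        config = PipelineConfig(manifest=manifest, atlas_path=str(atlas_path))
        report = validate_manifest(config)
        fatal = report[report["severity"] == "fatal"]
        assert len(fatal) == 1
        assert "nope.tsv" in fatal.iloc[0]["issue"]

    def test_validate_manifest_warns_on_reordered_columns(self, cohort, tmp_path):
        atlas, subjects, _ = cohort
        atlas_path = tmp_path / "atlas.tsv"
        atlas.to_frame().to_csv(atlas_path, sep="\t", index=False)
        manifest = write_cohort(tmp_path, atlas, subjects[:1])
        p = manifest[subjects[0].subject_id][0]
        df = pd.read_csv(p, sep="\t")
        df[list(df.columns[::-1])].to_csv(p, sep="\t", index=False)
        config = PipelineConfig(manifest=manifest, atlas_path=str(atlas_path))
        report = validate_manifest(config)
        warn = report[report["severity"] == "warning"]
        assert any("reordered" in s for s in warn["issue"])

    def test_clean_manifest_no_issues(self, cohort, tmp_path):
        atlas, subjects, _ = cohort
        atlas_path = tmp_path / "atlas.tsv"
        atlas.to_frame().to_csv(atlas_path, sep="\t", index=False)
        manifest = write_cohort(tmp_path, atlas, subjects)
        config = PipelineConfig(manifest=manifest, atlas_path=str(atlas_path))
        assert len(validate_manifest(config)) == 0


class TestCLI:
    def test_simulate_then_icc(self, tmp_path):
        runner = CliRunner()
        atlas = make_atlas(3)
        atlas_path = tmp_path / "atlas.tsv"
        atlas.to_frame().to_csv(atlas_path, sep="\t", index=False)
        out_dir = tmp_path / "sim"
        result = runner.invoke(
            cli_main,
            ["simulate", "--subjects", "3", "--volumes", "60", "--seed", "1",
             "--atlas", str(atlas_path), "--out", str(out_dir),
             "--language-loading-sd", "0"],
        )
        # the bundled language pattern needs the default atlas; small atlases
        # are rejected cleanly
        if result.exit_code != 0:
            assert "no atlas pairs match" in str(result.exception)
        ratings = tmp_path / "ratings.tsv"
        np.savetxt(ratings, np.array([[1.0, 1.1], [2.0, 2.1], [3.0, 2.9]]),
                   delimiter="\t")
        res2 = runner.invoke(cli_main, ["icc", str(ratings)])
        assert res2.exit_code == 0
        assert "ICC(2,1)" in res2.output

    def test_simulate_default_atlas_smoke(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "sim"
        result = runner.invoke(
            cli_main,
            ["simulate", "--subjects", "2", "--volumes", "50",
             "--runs-per-day", "1", "--seed", "2", "--out", str(out_dir)],
        )
        assert result.exit_code == 0, result.output
        assert (out_dir / "manifest.json").exists()
        assert (out_dir / "ground_truth.tsv").exists()
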
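"""Container round trips, pipeline idempotence, CLI smoke checks."""

import h5py
import numpy as np
import pytest
from click.testing import CliRunner

from emg_swn import CohortConfig, generate_cohort, read_container, write_container
from emg_swn.cli import main as cli_main
from emg_swn.container import ContainerError
from emg_swn.pipeline import (
    PipelineConfigError,
    load_config,
    result_digest,
    run_pipeline,
    validate_cohort,
    benchmark_latency,
)


@pytest.fixture(scope="module")
def roundtrip_cohort():
    return generate_cohort(CohortConfig(n_subjects=2, n_trials=10, seed=3))


def test_container_round_trip_is_lossless(roundtrip_cohort, tmp_path):
    path = tmp_path / "cohort.h5"
    write_container(path, roundtrip_cohort)
    back = read_container(path)
    assert back.config.to_dict() == roundtrip_cohort.config.to_dict()
    for s_a, s_b in zip(roundtrip_cohort.subjects, back.subjects):
        assert np.array_equal(s_a.profile.channel_gains, s_b.profile.channel_gains)
        assert s_a.profile.channel_roles == s_b.profile.channel_roles
        for t_a, t_b in zip(s_a.trials, s_b.trials):
            assert np.array_equal(t_a.emg.samples, t_b.emg.samples)
            assert t_a.emg.stage == t_b.emg.stage
            assert np.array_equal(t_a.motion.hand, t_b.motion.hand)
            assert np.array_equal(t_a.trajectory.theta_elb, t_b.trajectory.theta_elb)
            assert t_a.start_angle == t_b.start_angle


def test_file_without_manifest_is_rejected(tmp_path):
    path = tmp_path / "bogus.h5"
    with h5py.File(path, "w") as f:
        f.create_dataset("whatever", data=np.zeros(3))
    with pytest.raises(ContainerError, match="manifest"):
        read_container(path)


def test_unknown_stage_tag_names_the_trial(roundtrip_cohort, tmp_path):
    path = tmp_path / "cohort.h5"
    write_container(path, roundtrip_cohort)
    with h5py.File(path, "a") as f:
        f["subjects/s001/trials/t0002/emg"].attrs["stage"] = "mystery"
    with pytest.raises(ContainerError, match="s001/t0002"):
        read_container(path)


def test_validate_cohort_names_corrupted_trial(roundtrip_cohort):
    import copy

    bad = copy.deepcopy(roundtrip_cohort)
    bad.subjects[1].trials[4].emg.samples[0, 0] = np.inf
    with pytest.raises(ValueError, match="subject 1, trial 4"):
        validate_cohort(bad)


PIPE_CFG = {
    "seed": 4,
    "simulate": {"n_subjects": 2, "n_trials": 20},
    "normalization": {"methods": ["swn"], "l_norm_ms": [500]},
    "features": {"feature": "MAV", "l_feature_ms": [500]},
    "evaluate": {"model_types": ["OWN"]},
}


def test_pipeline_end_to_end_and_idempotent(tmp_path):
    out = tmp_path / "run"
    res1 = run_pipeline(PIPE_CFG, out)
    assert (out / "cohort_raw.h5").exists()
    assert (out / "cohort_preprocessed.h5").exists()
    assert (out / "results.csv").exists() and (out / "summary.csv").exists()
    assert set(res1["model_type"]) == {"OWN"}

    mtime = (out / "cohort_preprocessed.h5").stat().st_mtime
    res2 = run_pipeline(PIPE_CFG, out)  # second run: every stage is a no-op
    assert (out / "cohort_preprocessed.h5").stat().st_mtime == mtime
    assert result_digest(res1) == result_digest(res2)


def test_pipeline_deterministic_across_directories(tmp_path):
    r1 = run_pipeline(PIPE_CFG, tmp_path / "a")
    r2 = run_pipeline(PIPE_CFG, tmp_path / "b")
    assert result_digest(r1) == result_digest(r2)


def test_config_schema_errors_name_the_field(tmp_path):
    with pytest.raises(PipelineConfigError, match="exactly one"):
        load_config({"seed": 0})
    with pytest.raises(PipelineConfigError, match="normalization"):
        load_config({"simulate": {}, "normalization": {"bogus_field": 1}})
    with pytest.raises(PipelineConfigError, match="simulate"):
        run_pipeline({"simulate": {"no_such_parameter": 3}}, tmp_path / "x")


def test_latency_benchmark_reports_both_chains():
    out = benchmark_latency(duration_s=0.5)
    assert out["swn"] > out["none"] > 0
    assert 0 < out["normalization_share"] < 1


def test_cli_simulate_features_labels(tmp_path):
    runner = CliRunner()
    cfg = tmp_path / "cohort.yaml"
    cfg.write_text("n_subjects: 1\nn_trials: 10\nseed: 2\n")
    h5 = tmp_path / "c.h5"
    r = runner.invoke(cli_main, ["simulate", "--config", str(cfg), "--out", str(h5)])
    assert r.exit_code == 0, r.output
    pre = tmp_path / "p.h5"
    r = runner.invoke(cli_main, ["preprocess", str(h5), "--out", str(pre)])
    assert r.exit_code == 0, r.output
    feats = tmp_path / "f.csv"
    r = runner.invoke(cli_main, ["features", str(pre), "--feature", "MAV",
                                 "--window-ms", "500", "--out", str(feats)])
    assert r.exit_code == 0, r.output
    labs = tmp_path / "l.csv"
    r = runner.invoke(cli_main, ["labels", str(pre), "--out", str(labs)])
    assert r.exit_code == 0, r.output
    import pandas as pd

    f = pd.read_csv(feats)
    l = pd.read_csv(labs)
    assert len(f) == len(l) == 10 * 82
    assert set(l["target"]) <= {"rest", "flexion", "extension"}


def test_cli_normalize_refuses_zscore(tmp_path):
    runner = CliRunner()
    r = runner.invoke(cli_main, ["normalize", "--method", "zscore",
                                 "--out", "x.h5", "nonexistent.h5"])
    assert r.exit_code != 0
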
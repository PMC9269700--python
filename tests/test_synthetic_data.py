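"""Simulator contracts: trajectories, EMG structure, cohort determinism."""

import numpy as np
import pytest
from scipy.signal import periodogram

from emg_swn import CohortConfig, generate_cohort, generate_trajectory, synthesize_trial_emg
from emg_swn.synthetic_data import make_profiles, minimum_jerk


def test_trajectory_holds_endpoints_exactly(tiny_config):
    cfg = tiny_config
    traj = generate_trajectory(40.0, 100.0, cfg, seed=5)
    fs = cfg.fs_pos
    pre = int(cfg.pre_rest_s * fs)
    assert np.all(traj.theta_elb[: pre // 2] == 40.0)  # well before any onset
    assert traj.theta_elb[-1] == 100.0
    assert np.all(traj.theta_sld == traj.theta_sld[0])


def test_trajectory_velocity_zero_at_rest_and_endpoints(tiny_config):
    traj = generate_trajectory(40.0, 130.0, tiny_config, seed=7)
    v = traj.theta_dot_elb
    moving = np.abs(v) > 1e-9
    # zero velocity everywhere outside the movement: rest rule trivially met
    assert np.all(np.abs(v[~moving]) < 2.0)
    first, last = np.flatnonzero(moving)[[0, -1]]
    # velocity ramps continuously from/to zero at the movement edges
    assert abs(v[first]) < 5.0 and abs(v[last]) < 5.0


def test_trajectory_peak_velocity_matches_quintic_oracle(tiny_config):
    """Peak speed equals the dense-grid max of the minimum-jerk polynomial."""
    u = np.linspace(0, 1, 200001)
    peak_shape = np.max(np.gradient(minimum_jerk(u), u))  # ~1.875, computed not assumed
    traj = generate_trajectory(40.0, 130.0, tiny_config, seed=3)
    v = traj.theta_dot_elb
    moving = np.abs(v) > 1e-9
    duration = moving.sum() / traj.fs
    expected = peak_shape * 90.0 / duration
    assert np.max(np.abs(v)) == pytest.approx(expected, rel=0.02)


def test_pure_rest_trials_rejected_by_default(tiny_config):
    with pytest.raises(ValueError, match="rest"):
        generate_trajectory(40.0, 40.0, tiny_config, seed=0)
    import dataclasses

    allowing = dataclasses.replace(tiny_config, allow_rest_trials=True)
    traj = generate_trajectory(40.0, 40.0, allowing, seed=0)
    assert np.all(traj.theta_elb == 40.0)


def test_rest_segment_rms_equals_gain_times_floor(tiny_config):
    cfg = tiny_config
    profile = make_profiles(cfg, np.random.SeedSequence(1))[0]
    traj = generate_trajectory(40.0, 70.0, cfg, seed=2)
    emg = synthesize_trial_emg(traj, profile, cfg, seed=2)
    head = emg.samples[:, : int(1.5 * cfg.fs_emg)]  # pre-rest, clear of the lead
    rms = np.sqrt((head**2).mean(axis=1))
    assert rms == pytest.approx(profile.channel_gains * cfg.noise_floor, rel=0.08)


def test_movement_activates_the_agonist_group(tiny_config):
    cfg = tiny_config
    profile = make_profiles(cfg, np.random.SeedSequence(1))[0]
    gains = profile.channel_gains
    roles = np.asarray(profile.channel_roles)
    for start, end in ((40.0, 130.0), (130.0, 40.0)):
        traj = generate_trajectory(start, end, cfg, seed=4)
        emg = synthesize_trial_emg(traj, profile, cfg, seed=4)
        moving = np.repeat(np.abs(traj.theta_dot_elb) > 10.0, 4)[: emg.n_samples]
        rms = np.sqrt((emg.samples[:, moving] ** 2).mean(axis=1)) / gains  # gain-corrected
        flex = rms[roles == "flexor"].mean()
        ext = rms[roles == "extensor"].mean()
        if end > start:  # flexion
            assert flex > ext
        else:
            assert ext > flex


def test_carrier_power_confined_to_band(tiny_cohort):
    trial = tiny_cohort.subjects[0].trials[0]
    x = trial.emg.samples[:3].ravel()
    f, p = periodogram(x, fs=trial.emg.fs)
    outside = p[(f < 20.0) | (f > 450.0)].sum() / p.sum()
    assert outside < 0.05


def test_cohort_shape(tiny_cohort, tiny_config):
    assert tiny_cohort.n_subjects == tiny_config.n_subjects
    for subject in tiny_cohort.subjects:
        assert len(subject.trials) == tiny_config.n_trials
        trial = subject.trials[0]
        assert trial.emg.n_channels == tiny_config.n_channels
        n_expected = int(tiny_config.trial_duration_s * tiny_config.fs_emg)
        assert trial.emg.n_samples == n_expected
        assert trial.motion.n_samples == int(tiny_config.trial_duration_s * tiny_config.fs_pos)


def test_cohort_determinism(tiny_config, tiny_cohort):
    again = generate_cohort(tiny_config)
    a, b = tiny_cohort.subjects[1], again.subjects[1]
    assert np.array_equal(a.profile.channel_gains, b.profile.channel_gains)
    assert np.array_equal(a.trials[3].emg.samples, b.trials[3].emg.samples)
    assert np.array_equal(a.trials[3].motion.hand, b.trials[3].motion.hand)


def test_gain_spread_zero_gives_identical_gains():
    cfg = CohortConfig(n_subjects=3, n_trials=10, gain_spread=0.0, seed=1)
    profiles = make_profiles(cfg, np.random.SeedSequence(0))
    for p in profiles[1:]:
        assert np.array_equal(p.channel_gains, profiles[0].channel_gains)
        assert np.all(p.channel_gains == 1.0)


def _between_subject_distance(gain_spread: float) -> float:
    cfg = CohortConfig(
        n_subjects=3, n_trials=10, gain_spread=gain_spread,
        session_drift=0.0, trial_jitter=0.0, seed=9,
    )
    cohort = generate_cohort(cfg)
    rms = []
    for subject in cohort.subjects:
        trial_rms = [np.sqrt((t.emg.samples**2).mean(axis=1)) for t in subject.trials]
        rms.append(np.mean(trial_rms, axis=0))
    rms = np.asarray(rms)
    d = [np.linalg.norm(rms[i] - rms[j]) for i in range(3) for j in range(i + 1, 3)]
    return float(np.mean(d))


def test_heterogeneity_monotone_in_gain_spread():
    d0, d1, d2 = (_between_subject_distance(g) for g in (0.0, 0.4, 0.8))
    assert d0 < d1 < d2


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="divisible"):
        CohortConfig(n_trials=35)
    with pytest.raises(ValueError, match="180"):
        CohortConfig(n_trials=10, target_angles=(40.0, 200.0))
    with pytest.raises(ValueError, match="spread"):
        CohortConfig(n_trials=10, gain_spread=-0.1)
    with pytest.raises(ValueError, match="task"):
        CohortConfig(n_trials=10, movement_duration_s=(1.0, 3.0))
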
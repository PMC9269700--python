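"""Seeded multi-subject EMG + kinematics cohort simulator.

No public recordings exist for the single-joint elbow task this package
targets, so every downstream stage is exercised against synthetic cohorts
with the same organisation as the motivating experiment: trials of
pre-rest (2 s) / task (2.5 s) / post-rest (0.1 s), 12 point-to-point elbow
movements among 4 target angles, sessions of 36 trials (12 movements x 3),
12 EMG channels at 2000 Hz and marker positions at 500 Hz.

Generative model
----------------
* The elbow angle follows a minimum-jerk profile between target angles;
  the shoulder is held still. Marker tracks come from the package's own
  forward kinematics (plus optional measurement noise).
* EMG per channel is the sum of a band-limited (20-450 Hz) Gaussian
  baseline (instrument/postural noise at the channel's noise floor) and a
  band-limited *sparse-impulse* activity component — motor-unit action
  potentials arrive discretely, which makes active surface EMG
  heavy-tailed (leptokurtic) rather than Gaussian — scaled by a
  muscle-activation envelope with a small electromechanical lead. The
  neural drive is the rectified elbow angular velocity (flexor channels
  respond to positive velocity, extensor channels to negative) plus an
  antagonist braking component proportional to deceleration, the
  canonical triphasic agonist/antagonist pattern of point-to-point
  movements. The drive passes through asymmetric first-order activation
  dynamics (fast activation, slow deactivation), so envelopes rise
  quickly and relax slowly, as real muscle does. The neutral wrist
  channel stays at the noise floor.
* Amplitude heterogeneity, the phenomenon sliding-window normalization
  exists to remove, enters at three multiplicative levels, all log-normal:
  stable per-subject per-channel gains (``gain_spread``), per-session
  drift within a subject (``session_drift``, emulating electrode
  reapplication and impedance changes), and per-trial jitter
  (``trial_jitter``, emulating posture and fatigue fluctuation).
* Subjects also differ *structurally*: each channel's coupling to the
  flexion and extension drives varies per subject (``coupling_spread``,
  ``cross_talk`` — electrode placement over muscle bellies, individual
  muscle-use patterns). Unlike gains, no per-channel normalization can
  remove this, which is what keeps transferred (OTHER) models below
  within-subject (OWN) ones.

Everything is deterministic given ``(config, seed)``: randomness flows
from one ``numpy.random.SeedSequence`` split per subject/session/trial.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .kinematics import forward_kinematics
from .records import (
    Cohort,
    EmgRecording,
    JointTrajectory,
    MotionRecording,
    SubjectData,
    SubjectProfile,
    Trial,
)

#: Trials per session: 12 ordered target pairs, each repeated 3 times.
SESSION_SIZE = 36

#: Movements per session round (ordered pairs of the 4 targets).
N_MOVEMENTS = 12


@dataclass
class CohortConfig:
    """Study-design and effect-size parameters of the simulator.

    Durations are seconds, rates Hz, angles degrees, lengths metres. The
    three ``*_spread``/``*_drift``/``*_jitter`` fields are log-scale SDs of
    multiplicative amplitude factors (0 disables that source of
    heterogeneity). ``noise_floor`` is the resting-channel RMS in the
    simulator's arbitrary amplitude units; ``peak_activation`` is the
    envelope multiple of the noise floor reached at ``reference_velocity``.
    """

    n_subjects: int = 10
    n_channels: int = 12
    n_trials: int = 360
    fs_emg: float = 2000.0
    fs_pos: float = 500.0
    pre_rest_s: float = 2.0
    task_s: float = 2.5
    post_rest_s: float = 0.1
    target_angles: tuple[float, ...] = (40.0, 70.0, 100.0, 130.0)
    upper_arm_m: float = 0.30
    forearm_m: float = 0.26
    gain_spread: float = 0.4
    session_drift: float = 0.5
    trial_jitter: float = 0.3
    noise_floor: float = 0.01
    peak_activation: float = 4.0
    reference_velocity_deg_s: float = 100.0
    electromechanical_lead_s: float = 0.05
    tau_activation_s: float = 0.04
    tau_deactivation_s: float = 0.2
    co_activation: float = 0.5
    reference_accel_deg_s2: float = 400.0
    coupling_spread: float = 0.6
    cross_talk: float = 0.4
    firing_density: float = 0.1
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    n_flexor: int = 6
    n_extensor: int = 5
    movement_duration_s: tuple[float, float] = (0.8, 1.8)
    marker_noise_m: float = 0.0
    allow_rest_trials: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize sequence fields so configs round-trip through JSON/YAML
        self.target_angles = tuple(float(a) for a in self.target_angles)
        self.carrier_band_hz = tuple(float(f) for f in self.carrier_band_hz)
        self.movement_duration_s = tuple(float(d) for d in self.movement_duration_s)
        if self.n_trials % 10 != 0:
            raise ValueError("n_trials must be divisible by the block size 10")
        for name in ("pre_rest_s", "task_s", "post_rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not all(0.0 < a < 180.0 for a in self.target_angles):
            raise ValueError("target angles must lie in (0, 180) degrees")
        if len(self.target_angles) < 2 and not self.allow_rest_trials:
            raise ValueError("need at least 2 target angles for movements")
        if self.gain_spread < 0 or self.session_drift < 0 or self.trial_jitter < 0:
            raise ValueError("amplitude spreads must be non-negative")
        if self.n_flexor + self.n_extensor > self.n_channels:
            raise ValueError("flexor + extensor channels exceed n_channels")
        if self.n_flexor < 1 or self.n_extensor < 1:
            raise ValueError("need at least one flexor and one extensor channel")
        lo, hi = self.movement_duration_s
        if not (0.0 < lo <= hi <= self.task_s):
            raise ValueError("movement durations must fit inside the task period")
        if self.fs_emg <= 0 or self.fs_pos <= 0:
            raise ValueError("sampling rates must be positive")

    @property
    def trial_duration_s(self) -> float:
        return self.pre_rest_s + self.task_s + self.post_rest_s

    @property
    def channel_roles(self) -> tuple[str, ...]:
        roles = ["flexor"] * self.n_flexor + ["extensor"] * self.n_extensor
        roles += ["neutral"] * (self.n_channels - len(roles))
        return tuple(roles)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on u in [0, 1]."""
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def generate_trajectory(
    start_angle: float,
    end_angle: float,
    config: CohortConfig,
    seed,
) -> JointTrajectory:
    """Minimum-jerk elbow trajectory for one trial at ``fs_pos``.

    The elbow angle holds ``start_angle`` through pre-rest, moves along a
    minimum-jerk profile of random duration (uniform over
    ``movement_duration_s``) starting at a random delay into the task
    period, then holds ``end_angle``; the shoulder stays at 90 deg. Both
    endpoints have exactly zero velocity, so rest periods trivially satisfy
    the < 2 deg/s rest rule.
    """
    if start_angle == end_angle and not config.allow_rest_trials:
        raise ValueError("pure-rest trials (start == end) are disabled by default")
    for a in (start_angle, end_angle):
        if a not in config.target_angles:
            raise ValueError(f"angle {a} not in the configured target set")
    rng = _rng(seed)
    lo, hi = config.movement_duration_s
    duration = rng.uniform(lo, hi)
    margin = 0.05
    max_delay = max(config.task_s - duration - margin, margin)
    onset_delay = rng.uniform(margin, max_delay)

    fs = config.fs_pos
    n = int(round(config.trial_duration_s * fs))
    t = np.arange(n) / fs
    t0 = config.pre_rest_s + onset_delay
    u = np.clip((t - t0) / duration, 0.0, 1.0)
    theta_elb = start_angle + (end_angle - start_angle) * minimum_jerk(u)
    theta_sld = np.full(n, 90.0)
    return JointTrajectory(theta_sld=theta_sld, theta_elb=theta_elb, fs=fs)


def _activation_ode(drive: np.ndarray, fs: float, tau_act: float, tau_deact: float) -> np.ndarray:
    """Asymmetric first-order muscle-activation dynamics.

    da/dt = (u - a)/tau, with the fast time constant while the drive
    exceeds the activation (recruitment) and the slow one while it decays
    (calcium reuptake): envelopes rise quickly and relax slowly.
    """
    a = np.empty_like(drive)
    state = 0.0
    k_act = 1.0 - np.exp(-1.0 / (tau_act * fs))
    k_deact = 1.0 - np.exp(-1.0 / (tau_deact * fs))
    for i, u in enumerate(drive):
        state += (k_act if u > state else k_deact) * (u - state)
        a[i] = state
    return a


def _activation_drive(trajectory: JointTrajectory, config: CohortConfig) -> dict:
    """Flexion/extension activation envelopes from the velocity profile.

    Agonist drive is the rectified angular velocity; the antagonist fires
    in proportion to deceleration (the braking burst of the triphasic
    pattern). Both pass through the activation dynamics and are shifted
    earlier by the electromechanical lead. Channels mix the two drives
    through their subject-specific response couplings.
    """
    v = trajectory.theta_dot_elb
    fs = trajectory.fs
    acc = np.gradient(v) * fs
    agonist = {
        "flexion": np.clip(v, 0, None) / config.reference_velocity_deg_s,
        "extension": np.clip(-v, 0, None) / config.reference_velocity_deg_s,
    }
    braking = {
        # flexion (v > 0) decelerating (acc < 0) recruits the extension
        # musculature, and symmetrically for extension
        "extension": np.clip(-acc, 0, None) * (v > 0) / config.reference_accel_deg_s2,
        "flexion": np.clip(acc, 0, None) * (v < 0) / config.reference_accel_deg_s2,
    }
    lead = int(round(config.electromechanical_lead_s * fs))
    drives = {}
    for direction in ("flexion", "extension"):
        u = agonist[direction] + config.co_activation * braking[direction]
        a = _activation_ode(u, fs, config.tau_activation_s, config.tau_deactivation_s)
        if lead > 0:
            a = np.concatenate([a[lead:], np.full(lead, a[-1])])
        drives[direction] = a
    return drives


def _carrier_sos(config: CohortConfig) -> np.ndarray:
    lo, hi = config.carrier_band_hz
    return signal.butter(4, [lo, hi], btype="bandpass", fs=config.fs_emg, output="sos")


def synthesize_trial_emg(
    trajectory: JointTrajectory,
    profile: SubjectProfile,
    config: CohortConfig,
    seed,
    channel_scale: np.ndarray | None = None,
) -> EmgRecording:
    """Render one trial's raw EMG from its joint trajectory.

    Each channel is ``gain * scale * noise_floor * (baseline +
    (peak_activation - 1) * activation(t) * muap)`` where ``baseline`` is a
    unit-RMS band-limited Gaussian carrier, ``muap`` a unit-RMS
    band-limited sparse-impulse carrier (heavy-tailed, emulating discrete
    motor-unit firings), and ``activation`` the channel role's envelope.
    ``channel_scale`` carries session drift x trial jitter.
    """
    if trajectory.n_samples == 0:
        raise ValueError("zero-length trajectory")
    rng = _rng(seed)
    n_emg = int(round(trajectory.n_samples / trajectory.fs * config.fs_emg))
    upsample = int(round(config.fs_emg / trajectory.fs))
    if abs(upsample * trajectory.fs - config.fs_emg) > 1e-9:
        raise ValueError("fs_emg must be an integer multiple of the trajectory rate")

    drives = _activation_drive(trajectory, config)
    sos = _carrier_sos(config)
    # zero-phase filtering doubles the effective order, keeping >95% of the
    # carrier power inside the 20-450 Hz surface-EMG band
    baseline = signal.sosfiltfilt(sos, rng.standard_normal((config.n_channels, n_emg)), axis=1)
    baseline /= baseline.std(axis=1, keepdims=True)
    p = config.firing_density
    impulses = rng.standard_normal((config.n_channels, n_emg))
    impulses *= rng.random((config.n_channels, n_emg)) < p
    muap = signal.sosfiltfilt(sos, impulses / np.sqrt(p), axis=1)
    muap /= muap.std(axis=1, keepdims=True)

    scale = np.ones(config.n_channels) if channel_scale is None else np.asarray(channel_scale)
    samples = np.empty((config.n_channels, n_emg))
    for ch in range(config.n_channels):
        drive = (
            profile.flexion_response[ch] * drives["flexion"]
            + profile.extension_response[ch] * drives["extension"]
        )
        act = np.repeat((config.peak_activation - 1.0) * drive, upsample)[:n_emg]
        amp = config.noise_floor * profile.channel_gains[ch] * scale[ch]
        samples[ch] = amp * (baseline[ch] + act * muap[ch])
    return EmgRecording(samples=samples, fs=config.fs_emg, stage="raw", subject=profile.subject_id)


def _movement_pairs(config: CohortConfig) -> list[tuple[float, float]]:
    return [
        (a, b)
        for a in config.target_angles
        for b in config.target_angles
        if a != b
    ]


def make_profiles(config: CohortConfig, seed_seq: np.random.SeedSequence) -> list[SubjectProfile]:
    """Draw per-subject channel gains and drive couplings.

    Gains are log-normal (median 1, log-SD ``gain_spread``): removable
    amplitude differences. Couplings give each channel a subject-specific
    response to the two drives — its own role's drive scaled by a
    log-normal factor (log-SD ``coupling_spread``) plus half-normal
    cross-talk (scale ``cross_talk``) from the antagonist drive; the
    neutral channel sees cross-talk only. Couplings change *which*
    channels speak for each movement, not just how loudly — structure no
    per-channel normalization can remove, which is what keeps transferred
    (OTHER) models below within-subject (OWN) ones.
    """
    rng = np.random.default_rng(seed_seq)
    n = config.n_channels
    profiles = []
    for s in range(config.n_subjects):
        gains = np.exp(config.gain_spread * rng.standard_normal(n))
        own = np.exp(config.coupling_spread * rng.standard_normal(n))
        cross_f = np.abs(rng.normal(0.0, config.cross_talk, n))
        cross_e = np.abs(rng.normal(0.0, config.cross_talk, n))
        roles = config.channel_roles
        flex = np.where([r == "flexor" for r in roles], own, cross_f)
        ext = np.where([r == "extensor" for r in roles], own, cross_e)
        neutral = np.array([r == "neutral" for r in roles])
        flex[neutral] = 0.5 * cross_f[neutral]
        ext[neutral] = 0.5 * cross_e[neutral]
        profiles.append(
            SubjectProfile(
                subject_id=s,
                channel_gains=gains,
                channel_roles=roles,
                l_upper=config.upper_arm_m,
                l_fore=config.forearm_m,
                flexion_response=flex,
                extension_response=ext,
            )
        )
    return profiles


def _trial_motion(
    trajectory: JointTrajectory,
    profile: SubjectProfile,
    config: CohortConfig,
    rng: np.random.Generator,
) -> MotionRecording:
    shoulder = np.zeros((2, trajectory.n_samples))
    elbow, hand = forward_kinematics(
        trajectory.theta_sld, trajectory.theta_elb, profile.l_upper, profile.l_fore
    )
    if config.marker_noise_m > 0:
        hand = hand + rng.normal(0, config.marker_noise_m, hand.shape)
        elbow = elbow + rng.normal(0, config.marker_noise_m, elbow.shape)
        shoulder = shoulder + rng.normal(0, config.marker_noise_m, shoulder.shape)
    return MotionRecording(
        hand=hand,
        elbow=elbow,
        shoulder=shoulder,
        fs=trajectory.fs,
        l_upper=profile.l_upper,
        l_fore=profile.l_fore,
    )


def generate_cohort(config: CohortConfig, preprocess: bool = False) -> Cohort:
    """Generate the full seeded cohort.

    Trials are organised into sessions of 36 (each a shuffled 3-fold
    repeat of the 12 movements; a trailing partial session repeats a
    shuffled movement list). With ``preprocess=True`` each trial's raw
    2000 Hz EMG is immediately passed through the causal preprocessing
    chain and only the 500 Hz result is kept, which bounds peak memory on
    large cohorts.
    """
    from .preprocessing import preprocess_emg  # local import avoids a cycle

    root = np.random.SeedSequence(config.seed)
    profile_seq, *subject_seqs = root.spawn(config.n_subjects + 1)
    profiles = make_profiles(config, profile_seq)
    pairs = _movement_pairs(config)

    subjects = []
    for s, profile in enumerate(profiles):
        srng = np.random.default_rng(subject_seqs[s])
        n_sessions = -(-config.n_trials // SESSION_SIZE)
        tasks: list[tuple[float, float]] = []
        session_of: list[int] = []
        for sess in range(n_sessions):
            order = np.repeat(np.arange(len(pairs)), 3)
            srng.shuffle(order)
            for k in order:
                tasks.append(pairs[k])
                session_of.append(sess)
        tasks = tasks[: config.n_trials]
        session_of = session_of[: config.n_trials]

        session_scales = np.exp(
            config.session_drift * srng.standard_normal((n_sessions, config.n_channels))
        )
        trials = []
        for i, (start, end) in enumerate(tasks):
            trial_scale = np.exp(
                config.trial_jitter * srng.standard_normal(config.n_channels)
            )
            scale = session_scales[session_of[i]] * trial_scale
            traj = generate_trajectory(start, end, config, srng)
            emg = synthesize_trial_emg(traj, profile, config, srng, channel_scale=scale)
            emg.trial = i
            emg.session = session_of[i]
            if preprocess:
                emg = preprocess_emg(emg)
            motion = _trial_motion(traj, profile, config, srng)
            trials.append(
                Trial(
                    emg=emg,
                    motion=motion,
                    trajectory=traj,
                    start_angle=start,
                    end_angle=end,
                    session=session_of[i],
                )
            )
        subjects.append(SubjectData(profile=profile, trials=trials))
    return Cohort(config=config, subjects=subjects)
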
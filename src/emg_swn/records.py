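"""Core data containers shared across the pipeline.

Arrays are plain numpy; each container carries its sampling rate so no stage
needs out-of-band timing information. EMG recordings move through a fixed
stage progression (``raw -> preprocessed -> normalized``) which downstream
operations check before running.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Motion classes, in the order used for integer label codes.
CLASSES: tuple[str, ...] = ("rest", "flexion", "extension")

REST, FLEXION, EXTENSION = 0, 1, 2

#: Valid EMG processing stages, in order.
STAGES: tuple[str, ...] = ("raw", "preprocessed", "normalized")


class StageError(ValueError):
    """An operation received a recording at the wrong processing stage."""


@dataclass
class EmgRecording:
    """Multi-channel surface EMG for one trial.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes in arbitrary units (the simulator uses ~mV-scale values).
    fs : float
        Sampling rate in Hz.
    stage : str
        One of ``raw``, ``preprocessed``, ``normalized``.
    """

    samples: np.ndarray
    fs: float
    stage: str = "raw"
    channel_labels: tuple[str, ...] | None = None
    subject: int | None = None
    trial: int | None = None
    session: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"expected a {stage!r} recording, got {self.stage!r} "
                f"(subject={self.subject}, trial={self.trial})"
            )

    def advanced(self, samples: np.ndarray, fs: float, stage: str) -> "EmgRecording":
        """Return a copy carrying new samples at the next processing stage."""
        if STAGES.index(stage) != STAGES.index(self.stage) + 1:
            raise StageError(f"invalid stage transition {self.stage!r} -> {stage!r}")
        return replace(self, samples=samples, fs=fs, stage=stage)


@dataclass
class JointTrajectory:
    """Shoulder/elbow joint angles (degrees) sampled at ``fs`` Hz.

    ``theta_dot_elb`` is the forward-difference elbow angular velocity in
    deg/s, with the final sample replicated from its predecessor so all
    series share one length.
    """

    theta_sld: np.ndarray
    theta_elb: np.ndarray
    fs: float
    theta_dot_elb: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta_sld = np.asarray(self.theta_sld, dtype=float)
        self.theta_elb = np.asarray(self.theta_elb, dtype=float)
        if self.theta_sld.shape != self.theta_elb.shape:
            raise ValueError("shoulder and elbow angle series must share a shape")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (np.isfinite(self.theta_sld).all() and np.isfinite(self.theta_elb).all()):
            raise ValueError("angles contain non-finite values")
        if self.theta_dot_elb is None and self.theta_elb.size >= 2:
            self.theta_dot_elb = forward_difference_velocity(self.theta_elb, self.fs)

    @property
    def n_samples(self) -> int:
        return self.theta_elb.size


def forward_difference_velocity(theta: np.ndarray, fs: float) -> np.ndarray:
    """Forward-difference angular velocity, last sample replicated.

    ``v[t] = (theta[t+1] - theta[t]) * fs`` for t < N-1; ``v[N-1] = v[N-2]``.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size < 2:
        raise ValueError("need at least 2 angle samples for a velocity")
    v = np.empty_like(theta)
    v[:-1] = np.diff(theta) * fs
    v[-1] = v[-2]
    return v


@dataclass
class MotionRecording:
    """Planar marker positions (metres) for hand/elbow/shoulder at ``fs`` Hz.

    Each marker array has shape (2, n_samples) holding (x, y). Limb lengths
    are the upper arm (shoulder-elbow) and forearm (elbow-hand) in metres.
    """

    hand: np.ndarray
    elbow: np.ndarray
    shoulder: np.ndarray
    fs: float
    l_upper: float
    l_fore: float

    def __post_init__(self) -> None:
        for name in ("hand", "elbow", "shoulder"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[0] != 2:
                raise ValueError(f"{name} positions must have shape (2, n)")
            setattr(self, name, arr)
        if self.hand.shape != self.shoulder.shape:
            raise ValueError("marker series must share a length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.l_upper <= 0 or self.l_fore <= 0:
            raise ValueError("limb lengths must be positive")

    @property
    def n_samples(self) -> int:
        return self.hand.shape[1]


@dataclass
class FeatureMatrix:
    """Per-timestep features at the decimated (20 Hz) rate.

    ``values`` has one row per retained timestep and one column per
    channel x feature component; ``columns`` names them. ``labels`` holds
    integer codes into :data:`CLASSES` aligned row-for-row, and
    ``sample_index`` records the 500 Hz sample index each row was computed
    at (the newest sample of its trailing window).
    """

    values: np.ndarray
    columns: tuple[str, ...]
    labels: np.ndarray | None = None
    sample_index: np.ndarray | None = None
    subject: int | None = None
    trial: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column names do not match the value width")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("labels must align row-for-row with values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


@dataclass
class SubjectProfile:
    """Per-subject simulator parameters.

    ``channel_gains`` are multiplicative amplitude factors — the stable
    between-subject amplitude differences that normalization can remove.
    ``flexion_response``/``extension_response`` are each channel's coupling
    to the flexion and extension drives — the *structural* between-subject
    differences (electrode placement, individual muscle use) that no
    per-channel normalization removes. ``channel_roles`` tags each channel
    ``flexor``/``extensor``/``neutral``.
    """

    subject_id: int
    channel_gains: np.ndarray
    channel_roles: tuple[str, ...]
    l_upper: float
    l_fore: float
    flexion_response: np.ndarray | None = None
    extension_response: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if np.any(self.channel_gains <= 0):
            raise ValueError("channel gains must be positive")
        if len(self.channel_roles) != self.channel_gains.size:
            raise ValueError("one role per channel required")
        roles = set(self.channel_roles)
        if "flexor" not in roles or "extensor" not in roles:
            raise ValueError("need at least one flexor and one extensor channel")
        n = self.channel_gains.size
        if self.flexion_response is None:
            self.flexion_response = np.array(
                [1.0 if r == "flexor" else 0.0 for r in self.channel_roles]
            )
        if self.extension_response is None:
            self.extension_response = np.array(
                [1.0 if r == "extensor" else 0.0 for r in self.channel_roles]
            )
        self.flexion_response = np.asarray(self.flexion_response, dtype=float)
        self.extension_response = np.asarray(self.extension_response, dtype=float)
        if self.flexion_response.shape != (n,) or self.extension_response.shape != (n,):
            raise ValueError("response couplings must have one entry per channel")
        if np.any(self.flexion_response < 0) or np.any(self.extension_response < 0):
            raise ValueError("response couplings must be non-negative")


@dataclass
class Trial:
    """One trial's aligned streams plus generating ground truth."""

    emg: EmgRecording
    motion: MotionRecording
    trajectory: JointTrajectory | None = None
    start_angle: float | None = None
    end_angle: float | None = None
    session: int | None = None


@dataclass
class SubjectData:
    profile: SubjectProfile
    trials: list[Trial] = field(default_factory=list)


@dataclass
class Cohort:
    """A multi-subject synthetic dataset plus the config that produced it."""

    config: "object"
    subjects: list[SubjectData] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def labels_to_names(codes: np.ndarray) -> np.ndarray:
    return np.asarray(CLASSES, dtype=object)[np.asarray(codes, dtype=int)]


def names_to_labels(names: Sequence[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(CLASSES)}
    return np.array([lut[str(n)] for n in names], dtype=np.int8)
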
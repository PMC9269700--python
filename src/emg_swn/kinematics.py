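"""Two-link planar arm kinematics and motion-target encoding.

Marker positions (hand/elbow/shoulder, metres) are smoothed with a
zero-phase low-pass filter, converted to shoulder/elbow joint angles by
closed-form inverse kinematics of a two-link planar arm, differentiated to
elbow angular velocity, and coded into rest/flexion/extension targets with
a +/-2 deg/s dead band. Forward kinematics is the exact inverse used both
by the simulator (to render marker tracks from a generated trajectory) and
by the round-trip tests.

Angle convention
----------------
``theta_sld`` is the shoulder elevation of the upper arm from the +x axis
(counter-clockwise, degrees). ``theta_elb`` is the interior flexion of the
forearm relative to the upper-arm direction: 0 deg is a fully extended arm
and increasing ``theta_elb`` flexes the elbow (the forearm rotates
counter-clockwise from the upper-arm axis, the branch implied by the
closed-form inverse below). Increasing elbow angle is coded as flexion.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .records import (
    EXTENSION,
    FLEXION,
    REST,
    JointTrajectory,
    MotionRecording,
    forward_difference_velocity,
)

#: Dead-band threshold on elbow angular velocity, deg/s. At or above codes
#: flexion, at or below the negative codes extension, strictly inside rest.
VELOCITY_THRESHOLD_DEG_S = 2.0

#: Zero-phase position smoother: 2nd-order Butterworth low-pass, 20 Hz.
POSITION_FILTER_ORDER = 2
POSITION_FILTER_CUTOFF_HZ = 20.0


def smooth_positions(motion: MotionRecording) -> MotionRecording:
    """Zero-phase low-pass filter every marker coordinate.

    Forward-backward (``sosfiltfilt``) filtering leaves no phase lag, so
    velocities derived from the smoothed angles stay aligned with the EMG.
    """
    sos = signal.butter(
        POSITION_FILTER_ORDER,
        POSITION_FILTER_CUTOFF_HZ,
        btype="low",
        fs=motion.fs,
        output="sos",
    )
    padlen = 3 * (2 * sos.shape[0] + 1)  # sosfiltfilt default edge padding
    if motion.n_samples <= padlen:
        raise ValueError(
            f"recording too short to smooth: {motion.n_samples} samples "
            f"<= filter warm-up {padlen}"
        )
    out = {}
    for name in ("hand", "elbow", "shoulder"):
        out[name] = signal.sosfiltfilt(sos, getattr(motion, name), axis=1)
    return MotionRecording(
        hand=out["hand"],
        elbow=out["elbow"],
        shoulder=out["shoulder"],
        fs=motion.fs,
        l_upper=motion.l_upper,
        l_fore=motion.l_fore,
    )


def inverse_kinematics(motion: MotionRecording) -> JointTrajectory:
    """Hand/shoulder positions -> shoulder and elbow joint angles (degrees).

    Closed-form two-link solution: with a = y_hand - y_sld, b = x_hand -
    x_sld, c = (a^2+b^2+L_sld^2-L_elb^2)/(2 L_sld), d = (a^2+b^2-L_sld^2+
    L_elb^2)/(2 L_elb),

        theta_sld = atan2d(a, b) - atan2d(sqrt(a^2+b^2-c^2), c)
        theta_elb = atan2d(sqrt(a^2+b^2-c^2), c) + atan2d(sqrt(a^2+b^2-d^2), d)

    choosing the elbow-down branch consistent with
    :func:`forward_kinematics`. Only hand and shoulder markers enter the
    solution; the measured elbow marker is carried as metadata.
    """
    ls, le = motion.l_upper, motion.l_fore
    a = motion.hand[1] - motion.shoulder[1]
    b = motion.hand[0] - motion.shoulder[0]
    r2 = a * a + b * b
    r = np.sqrt(r2)
    outer = ls + le
    inner = abs(ls - le)
    tol = 1e-9 * outer
    bad = (r > outer + tol) | (r < inner - tol)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"hand position unreachable at sample {idx}: "
            f"|hand-shoulder|={r[bad][0]:.6f} m outside [{inner:.6f}, {outer:.6f}]"
        )
    c = (r2 + ls * ls - le * le) / (2.0 * ls)
    d = (r2 - ls * ls + le * le) / (2.0 * le)
    # Round-off can push the radicand a hair negative at full extension.
    root_c = np.sqrt(np.clip(r2 - c * c, 0.0, None))
    root_d = np.sqrt(np.clip(r2 - d * d, 0.0, None))
    theta_sld = np.degrees(np.arctan2(a, b)) - np.degrees(np.arctan2(root_c, c))
    theta_elb = np.degrees(np.arctan2(root_c, c)) + np.degrees(np.arctan2(root_d, d))
    return JointTrajectory(theta_sld=theta_sld, theta_elb=theta_elb, fs=motion.fs)


def forward_kinematics(
    theta_sld: np.ndarray,
    theta_elb: np.ndarray,
    l_upper: float,
    l_fore: float,
    shoulder: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint angles (degrees) -> elbow and hand positions (metres).

    elbow = shoulder + L_sld (cos ts, sin ts);
    hand  = elbow + L_elb (cos(ts + te), sin(ts + te)).

    Returns ``(elbow, hand)`` arrays of shape (2, n). The convention is the
    exact inverse of :func:`inverse_kinematics` for theta_elb in [0, 180).
    """
    ts = np.radians(np.asarray(theta_sld, dtype=float))
    te = np.radians(np.asarray(theta_elb, dtype=float))
    if shoulder is None:
        shoulder = np.zeros((2,) + ts.shape)
    shoulder = np.asarray(shoulder, dtype=float)
    elbow = shoulder + l_upper * np.stack([np.cos(ts), np.sin(ts)])
    hand = elbow + l_fore * np.stack([np.cos(ts + te), np.sin(ts + te)])
    return elbow, hand


def encode_targets(trajectory: JointTrajectory) -> np.ndarray:
    """Code elbow angular velocity into integer motion targets at full rate.

    flexion if v >= +2.0 deg/s, extension if v <= -2.0 deg/s, rest
    otherwise; thresholds inclusive. Velocity is the forward difference
    scaled by fs, final sample replicated. Returns int8 codes aligned with
    the angle samples; decimation to the feature rate is done by indexing
    with the shared feature timestamps (see ``features.feature_sample_indices``).
    """
    if trajectory.n_samples < 2:
        raise ValueError("need at least 2 samples to encode targets")
    v = trajectory.theta_dot_elb
    if v is None:
        v = forward_difference_velocity(trajectory.theta_elb, trajectory.fs)
    labels = np.full(v.shape, REST, dtype=np.int8)
    labels[v >= VELOCITY_THRESHOLD_DEG_S] = FLEXION
    labels[v <= -VELOCITY_THRESHOLD_DEG_S] = EXTENSION
    return labels


def labels_from_motion(motion: MotionRecording) -> np.ndarray:
    """Full label pipeline: smooth -> IK -> velocity -> code. 500 Hz codes."""
    smoothed = smooth_positions(motion)
    traj = inverse_kinematics(smoothed)
    return encode_targets(traj)
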
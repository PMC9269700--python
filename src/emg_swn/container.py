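"""HDF5 cohort container.

There is no standard interchange format for multi-trial surface-EMG
experiments, so cohorts are stored in a small documented HDF5 schema::

    /  attrs: manifest (JSON: schema, version, config, seed, history)
    /subjects/s000  attrs: channel_gains, channel_roles, l_upper, l_fore
    /subjects/s000/trials/t0000
        emg        (n_channels, n_samples)  attrs: fs, stage
        positions  (3, 2, n_samples)        attrs: fs   [hand, elbow, shoulder]
        angles     (2, n_samples)           optional    [theta_sld, theta_elb]
        labels     (n_rows,)                optional 20 Hz int codes
        features   (n_rows, n_cols)         optional, attrs: columns
        attrs: session, start_angle, end_angle

Round trips are lossless: every array is stored verbatim with its
sampling rate, and the manifest echoes the generating config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .records import (
    Cohort,
    EmgRecording,
    JointTrajectory,
    MotionRecording,
    STAGES,
    SubjectData,
    SubjectProfile,
    Trial,
)
from .synthetic_data import CohortConfig

SCHEMA_VERSION = 1


class ContainerError(RuntimeError):
    """Malformed or incompatible cohort container."""


def config_hash(config: CohortConfig | dict) -> str:
    d = config.to_dict() if hasattr(config, "to_dict") else dict(config)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _manifest(cohort: Cohort, history: list[str]) -> str:
    return json.dumps(
        {
            "schema": "emg-swn-cohort",
            "schema_version": SCHEMA_VERSION,
            "software_version": __version__,
            "config": cohort.config.to_dict(),
            "config_hash": config_hash(cohort.config),
            "history": history,
        }
    )


def write_container(path, cohort: Cohort, history: list[str] | None = None) -> None:
    """Serialize a cohort (lossless)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = _manifest(cohort, history or [])
        for s, subject in enumerate(cohort.subjects):
            g = f.create_group(f"subjects/s{s:03d}")
            p = subject.profile
            g.attrs["subject_id"] = p.subject_id
            g.attrs["channel_gains"] = p.channel_gains
            g.attrs["channel_roles"] = [r.encode() for r in p.channel_roles]
            g.attrs["flexion_response"] = p.flexion_response
            g.attrs["extension_response"] = p.extension_response
            g.attrs["l_upper"] = p.l_upper
            g.attrs["l_fore"] = p.l_fore
            for i, trial in enumerate(subject.trials):
                t = g.create_group(f"trials/t{i:04d}")
                t.attrs["session"] = -1 if trial.session is None else trial.session
                t.attrs["start_angle"] = np.nan if trial.start_angle is None else trial.start_angle
                t.attrs["end_angle"] = np.nan if trial.end_angle is None else trial.end_angle
                d = t.create_dataset("emg", data=trial.emg.samples)
                d.attrs["fs"] = trial.emg.fs
                d.attrs["stage"] = trial.emg.stage
                m = trial.motion
                d = t.create_dataset(
                    "positions", data=np.stack([m.hand, m.elbow, m.shoulder])
                )
                d.attrs["fs"] = m.fs
                if trial.trajectory is not None:
                    d = t.create_dataset(
                        "angles",
                        data=np.stack(
                            [trial.trajectory.theta_sld, trial.trajectory.theta_elb]
                        ),
                    )
                    d.attrs["fs"] = trial.trajectory.fs


def read_manifest(path) -> dict:
    with h5py.File(path, "r") as f:
        if "manifest" not in f.attrs:
            raise ContainerError(f"{path}: missing manifest — not a cohort container")
        manifest = json.loads(f.attrs["manifest"])
    if manifest.get("schema") != "emg-swn-cohort":
        raise ContainerError(f"{path}: unknown schema {manifest.get('schema')!r}")
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ContainerError(
            f"{path}: unsupported schema version {manifest.get('schema_version')!r}"
        )
    return manifest


def read_container(path) -> Cohort:
    """Deserialize a cohort; validates manifest, stage tags and shapes."""
    manifest = read_manifest(path)
    config = CohortConfig(**manifest["config"])
    cohort = Cohort(config=config)
    with h5py.File(path, "r") as f:
        for sname in sorted(f["subjects"]):
            g = f[f"subjects/{sname}"]
            profile = SubjectProfile(
                subject_id=int(g.attrs["subject_id"]),
                channel_gains=np.asarray(g.attrs["channel_gains"]),
                channel_roles=tuple(
                    r.decode() if isinstance(r, bytes) else str(r)
                    for r in g.attrs["channel_roles"]
                ),
                l_upper=float(g.attrs["l_upper"]),
                l_fore=float(g.attrs["l_fore"]),
                flexion_response=np.asarray(g.attrs["flexion_response"]),
                extension_response=np.asarray(g.attrs["extension_response"]),
            )
            subject = SubjectData(profile=profile)
            for tname in sorted(g["trials"]):
                t = g[f"trials/{tname}"]
                stage = t["emg"].attrs["stage"]
                if stage not in STAGES:
                    raise ContainerError(
                        f"{path}: unknown stage tag {stage!r} in {sname}/{tname}"
                    )
                emg = EmgRecording(
                    samples=t["emg"][()],
                    fs=float(t["emg"].attrs["fs"]),
                    stage=str(stage),
                    subject=profile.subject_id,
                    trial=int(tname[1:]),
                    session=int(t.attrs["session"]),
                )
                pos = t["positions"][()]
                motion = MotionRecording(
                    hand=pos[0], elbow=pos[1], shoulder=pos[2],
                    fs=float(t["positions"].attrs["fs"]),
                    l_upper=profile.l_upper, l_fore=profile.l_fore,
                )
                traj = None
                if "angles" in t:
                    ang = t["angles"][()]
                    traj = JointTrajectory(
                        theta_sld=ang[0], theta_elb=ang[1],
                        fs=float(t["angles"].attrs["fs"]),
                    )
                start = float(t.attrs["start_angle"])
                end = float(t.attrs["end_angle"])
                subject.trials.append(
                    Trial(
                        emg=emg,
                        motion=motion,
                        trajectory=traj,
                        start_angle=None if np.isnan(start) else start,
                        end_angle=None if np.isnan(end) else end,
                        session=int(t.attrs["session"]),
                    )
                )
            cohort.subjects.append(subject)
    return cohort
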
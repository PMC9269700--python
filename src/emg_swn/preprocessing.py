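"""Causal EMG conditioning: low-pass, decimation, high-pass.

The chain mirrors a real-time acquisition front end: a 3rd-order
Butterworth low-pass at the post-decimation Nyquist (anti-alias), a
keep-every-4th decimation from 2000 to 500 Hz, and a 3rd-order Butterworth
high-pass at 30 Hz that removes offset and motion artifact. All filters
run forward-only (``sosfilt``), so the output at time t never depends on
later input — the property that makes the whole pipeline streamable.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .records import EmgRecording

TARGET_FS = 500.0
LOWPASS_ORDER = 3
LOWPASS_CUTOFF_HZ = 500.0
HIGHPASS_ORDER = 3
HIGHPASS_CUTOFF_HZ = 30.0

#: The nominal 500 Hz low-pass cutoff sits exactly at the decimated
#: Nyquist; the normalized digital cutoff is clamped just below 1 to keep
#: the design well-posed.
_NYQUIST_CLAMP = 0.999


def _lowpass_sos(fs: float) -> np.ndarray:
    wn = min(LOWPASS_CUTOFF_HZ / (fs / 2.0), _NYQUIST_CLAMP)
    return signal.butter(LOWPASS_ORDER, wn, btype="low", output="sos")


def preprocess_emg(rec: EmgRecording, target_fs: float = TARGET_FS) -> EmgRecording:
    """Low-pass, decimate to ``target_fs``, high-pass; causal throughout.

    The input rate must be an integer multiple of ``target_fs``; the
    decimation factor scales accordingly (4 for 2000 -> 500 Hz). Output
    length is ``floor(n / factor)`` and the result is tagged
    ``preprocessed``.
    """
    rec.require_stage("raw")
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"input rate {rec.fs} Hz is not an integer multiple of {target_fs} Hz"
        )
    factor = int(round(factor))

    warmup = 3 * (LOWPASS_ORDER + HIGHPASS_ORDER)
    if rec.n_samples < warmup * factor:
        warnings.warn(
            f"recording shorter than the filter warm-up ({rec.n_samples} samples); "
            "output will be transient-dominated",
            stacklevel=2,
        )

    x = np.asarray(rec.samples, dtype=float)
    if factor > 1:
        x = signal.sosfilt(_lowpass_sos(rec.fs), x, axis=1)
        x = x[:, ::factor]
    sos_hp = signal.butter(
        HIGHPASS_ORDER, HIGHPASS_CUTOFF_HZ, btype="high", fs=target_fs, output="sos"
    )
    x = signal.sosfilt(sos_hp, x, axis=1)
    return rec.advanced(samples=x, fs=target_fs, stage="preprocessed")
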
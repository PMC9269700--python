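"""Sliding-window EMG features and decimation to the classifier rate.

Five features are computed per channel over a trailing window of
``L_feature`` samples of the 500 Hz (normalized) stream:

* MAV  — mean absolute value,
* MWL  — mean waveform length: mean absolute first difference,
* DRMS — RMS of the first difference,
* STFT — time-averaged magnitude spectrogram (64-sample Hann window, 50%
  overlap) averaged inside three bands, 1-70 / 60-100 / 100-250 Hz (the
  low/mid overlap is intentional),
* SWT  — mean |cD3| of a level-3 stationary wavelet transform (db2),
  i.e. the ~31-62 Hz detail band.

``ALL`` concatenates the five (7 columns per channel). The feature stream
is evaluated only at timesteps that survive the longest-grid-window trim
(500 ms) — so the row count never depends on the window lengths chosen —
and then subsampled by stride 25 to 20 Hz. Features are already
window-smoothed, so plain stride decimation needs no extra anti-aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

from .normalization import LONGEST_WINDOW_MS
from .records import EmgRecording, FeatureMatrix

FEATURE_KINDS = ("MAV", "MWL", "DRMS", "STFT", "SWT", "ALL")

#: Decimated feature rate, Hz.
FEATURE_RATE_HZ = 20.0

_STFT_DEFAULT_BANDS = ((1.0, 70.0), (60.0, 100.0), (100.0, 250.0))
_BAND_NAMES = ("low", "mid", "hig")


@dataclass(frozen=True)
class FeatureSpec:
    """Feature choice plus window and transform parameters."""

    feature: str = "ALL"
    window_ms: float = 500.0
    stft_window_samples: int = 64
    stft_bands: tuple[tuple[float, float], ...] = _STFT_DEFAULT_BANDS
    swt_wavelet: str = "db2"
    swt_level: int = 3

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_KINDS:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")

    def window_samples(self, fs: float) -> int:
        n = int(round(self.window_ms * fs / 1000.0))
        if n < 2:
            raise ValueError("feature window must span at least 2 samples")
        return n

    @property
    def components_per_channel(self) -> int:
        return {"STFT": 3, "ALL": 7}.get(self.feature, 1)


# ---------------------------------------------------------------------------
# vectorized kernels on a (n_windows, L) matrix of trailing windows


def _mav(W: np.ndarray) -> np.ndarray:
    return np.abs(W).mean(axis=-1)


def _mwl(W: np.ndarray) -> np.ndarray:
    return np.abs(np.diff(W, axis=-1)).sum(axis=-1) / (W.shape[-1] - 1)


def _drms(W: np.ndarray) -> np.ndarray:
    d = np.diff(W, axis=-1)
    return np.sqrt((d * d).sum(axis=-1) / (W.shape[-1] - 1))


def _stft_bands(W: np.ndarray, fs: float, spec: FeatureSpec) -> np.ndarray:
    """(n_windows, 3) band-averaged mean magnitude spectra."""
    nper = spec.stft_window_samples
    if W.shape[-1] < nper:
        raise ValueError(
            f"STFT needs windows of >= {nper} samples, got {W.shape[-1]}"
        )
    for lo, hi in spec.stft_bands:
        if not (0 < lo <= hi <= fs / 2):
            raise ValueError(f"band ({lo}, {hi}) Hz outside (0, fs/2]")
    freqs, _, S = signal.spectrogram(
        W,
        fs=fs,
        window="hann",
        nperseg=nper,
        noverlap=nper // 2,
        detrend=False,
        mode="magnitude",
        axis=-1,
    )
    mean_spec = S.mean(axis=-1)  # (..., n_freqs)
    out = np.empty(W.shape[:-1] + (len(spec.stft_bands),))
    for i, (lo, hi) in enumerate(spec.stft_bands):
        mask = (freqs >= lo) & (freqs <= hi)  # bin centers, closed interval
        out[..., i] = mean_spec[..., mask].mean(axis=-1)
    return out


def _swt_cd(W: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """Mean |detail coefficients at the top level| per window."""
    L = W.shape[-1]
    block = 2 ** spec.swt_level
    if L < block:
        raise ValueError(f"SWT needs windows of >= {block} samples, got {L}")
    pad = (-L) % block
    if pad:
        W = np.pad(W, [(0, 0)] * (W.ndim - 1) + [(0, pad)], mode="symmetric")
    coeffs = pywt.swt(W, spec.swt_wavelet, level=spec.swt_level, axis=-1)
    cd_top = coeffs[0][1]  # first element is the deepest level (cD_level)
    return np.abs(cd_top[..., :L]).mean(axis=-1)


# ---------------------------------------------------------------------------
# public single-window operations (the verification primitives)


def time_domain_feature(window: np.ndarray, kind: str) -> float:
    """MAV / MWL / DRMS of one window."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    fn = {"MAV": _mav, "MWL": _mwl, "DRMS": _drms}.get(kind)
    if fn is None:
        raise ValueError(f"unknown time-domain feature {kind!r}")
    return float(fn(w[None, :])[0])


def stft_band_feature(
    window: np.ndarray, spec: FeatureSpec = FeatureSpec(feature="STFT"), fs: float = 500.0
) -> np.ndarray:
    """(low, mid, hig) band features of one window."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 1:
        raise ValueError("window must be 1-D")
    return _stft_bands(w[None, :], fs, spec)[0]


def swt_feature(window: np.ndarray, spec: FeatureSpec = FeatureSpec(feature="SWT")) -> float:
    """Mean |cD_level| of one window."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 1:
        raise ValueError("window must be 1-D")
    return float(_swt_cd(w[None, :], spec)[0])


# ---------------------------------------------------------------------------
# trial-level assembly


def feature_sample_indices(n_samples: int, fs: float) -> np.ndarray:
    """500 Hz sample indices of the retained feature timesteps.

    Trailing windows end at these indices. The first ``LONGEST_WINDOW_MS``
    of each trial is dropped regardless of the actual window lengths, and
    the remainder is subsampled to :data:`FEATURE_RATE_HZ`.
    """
    trim = int(round(LONGEST_WINDOW_MS * fs / 1000.0))
    stride = int(round(fs / FEATURE_RATE_HZ))
    if n_samples <= trim:
        raise ValueError(
            f"trial of {n_samples} samples is shorter than the "
            f"{LONGEST_WINDOW_MS} ms trim window"
        )
    return np.arange(trim, n_samples, stride)


def _trailing_windows(x: np.ndarray, ts: np.ndarray, L: int) -> np.ndarray:
    """(n_ts, L) matrix of windows x[t-L+1 .. t] for one channel."""
    idx = ts[:, None] + np.arange(-L + 1, 1)[None, :]
    return x[idx]


def assemble_features(rec: EmgRecording, spec: FeatureSpec) -> FeatureMatrix:
    """Evaluate the chosen feature over every retained timestep.

    Accepts a ``normalized`` or ``preprocessed`` recording at 500 Hz (the
    latter is the no-normalization path). Returns the 20 Hz
    :class:`FeatureMatrix` with named columns, feature blocks concatenated
    in the order MAV, MWL, DRMS, STFT(low,mid,hig), SWT.
    """
    if rec.stage not in ("normalized", "preprocessed"):
        raise ValueError(f"features need a conditioned recording, got {rec.stage!r}")
    fs = rec.fs
    L = spec.window_samples(fs)
    ts = feature_sample_indices(rec.n_samples, fs)

    kinds = ("MAV", "MWL", "DRMS", "STFT", "SWT") if spec.feature == "ALL" else (spec.feature,)
    wins = np.stack(
        [_trailing_windows(rec.samples[ch], ts, L) for ch in range(rec.n_channels)]
    )  # (ch, n_ts, L)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    for kind in kinds:
        if kind in ("MAV", "MWL", "DRMS"):
            vals = {"MAV": _mav, "MWL": _mwl, "DRMS": _drms}[kind](wins)  # (ch, n_ts)
            blocks.append(vals.transpose(1, 0))
            names += [f"ch{ch:02d}_{kind}" for ch in range(rec.n_channels)]
        elif kind == "STFT":
            vals = _stft_bands(wins, fs, spec)  # (ch, n_ts, 3)
            blocks.append(vals.transpose(1, 0, 2).reshape(len(ts), -1))
            names += [
                f"ch{ch:02d}_STFT_{b}"
                for ch in range(rec.n_channels)
                for b in _BAND_NAMES
            ]
        else:  # SWT
            vals = _swt_cd(wins, spec)
            blocks.append(vals.transpose(1, 0))
            names += [f"ch{ch:02d}_SWT" for ch in range(rec.n_channels)]

    values = np.concatenate(blocks, axis=1)
    return FeatureMatrix(
        values=values,
        columns=tuple(names),
        sample_index=ts,
        subject=rec.subject,
        trial=rec.trial,
    )
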
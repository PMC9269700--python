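"""Sliding-window normalization (SWN) and reference normalizations.

SWN is the package's core primitive: each channel is z-scored against the
mean and (population) standard deviation of its own trailing window of
``L_norm`` samples,

    y[t] = (x[t] - m[t]) / s[t],   m, s over x[(t - L_norm, t]]

so the output needs no pre-measured calibration reference, adapts to any
slow amplitude drift, and is exactly invariant to per-channel rescaling —
the mechanism behind calibration-free transfer of classifiers between
subjects. The streaming contract emits the newest sample of each window,
producing one normalized stream that any feature window can consume;
:func:`swn_window`, which re-normalizes a whole window, is kept as the
verification primitive.

Two baselines are provided: classical z-score against training-set
statistics (which *does* require a per-subject calibration reference) and
``none`` (identity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .records import EmgRecording

#: Window-length grid (ms) evaluated for both normalization and features.
WINDOW_GRID_MS: tuple[int, ...] = (100, 200, 300, 400, 500)

#: Longest grid window; trial starts are trimmed by this length for every
#: configuration so the row count never depends on the window choice.
LONGEST_WINDOW_MS: int = 500

NORMALIZATION_METHODS = ("swn", "zscore", "none")


@dataclass(frozen=True)
class NormalizationSpec:
    """Which normalization to run and with what window.

    ``window_ms`` is required for (and only meaningful to) SWN.
    ``zero_variance_policy`` controls constant windows: ``"zeros"`` emits
    zeros with a warning (streaming must not halt), ``"raise"`` errors.
    """

    method: str
    window_ms: float | None = None
    zero_variance_policy: str = "zeros"

    def __post_init__(self) -> None:
        if self.method not in NORMALIZATION_METHODS:
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.method == "swn":
            if self.window_ms is None:
                raise ValueError("SWN requires window_ms")
        elif self.window_ms is not None:
            raise ValueError(f"window_ms is only valid for SWN, not {self.method!r}")
        if self.zero_variance_policy not in ("zeros", "raise"):
            raise ValueError("zero_variance_policy must be 'zeros' or 'raise'")

    def window_samples(self, fs: float) -> int:
        n = int(round(self.window_ms * fs / 1000.0))
        if n < 2:
            raise ValueError(f"window of {self.window_ms} ms is < 2 samples at {fs} Hz")
        return n


@dataclass
class ZScoreStats:
    """Per-channel training mean/SD (population) for z-score normalization."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.std = np.atleast_1d(np.asarray(self.std, dtype=float))
        bad = np.flatnonzero(self.std <= 0)
        if bad.size:
            raise ValueError(f"zero-variance training channel(s): {bad.tolist()}")


def _handle_zero_variance(policy: str, where: str) -> None:
    if policy == "raise":
        raise ZeroDivisionError(f"zero-variance window in {where}")
    warnings.warn(
        f"zero-variance window in {where}; emitting zeros", stacklevel=3
    )


def swn_window(window: np.ndarray, zero_variance_policy: str = "zeros") -> np.ndarray:
    """Normalize one full window to mean 0, population SD 1.

    This is the per-window form of SWN: every sample of the window is
    transformed with the window's own statistics. The streaming pipeline
    uses only the last element of this result per step.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    m = np.mean(w)
    s = np.std(w)
    if s == 0:
        _handle_zero_variance(zero_variance_policy, "swn_window")
        return np.zeros_like(w)
    return (w - m) / s


def swn_stream(
    x: np.ndarray,
    window_samples: int,
    zero_variance_policy: str = "zeros",
) -> np.ndarray:
    """Streaming SWN of a (channels x time) array, per channel.

    For ``t >= window_samples - 1`` the output is exactly
    ``(x[t] - mean(win)) / std(win)`` over the trailing full window. The
    first ``window_samples - 1`` samples are warm-up: they are normalized
    against the expanding window seen so far (still causal and
    well-defined) and are discarded downstream by the longest-grid-window
    trim; the very first sample, whose window has no spread, follows the
    zero-variance policy.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    L = int(window_samples)
    if L < 2:
        raise ValueError("window must span at least 2 samples")
    if x.shape[1] <= L:
        raise ValueError(
            f"recording of {x.shape[1]} samples is not longer than the window ({L})"
        )
    y = np.empty_like(x)

    # warm-up: expanding causal window over the first L-1 samples
    head = x[:, : L - 1]
    n = np.arange(1, L, dtype=float)
    c1 = np.cumsum(head, axis=1)
    c2 = np.cumsum(head * head, axis=1)
    m_h = c1 / n
    var_h = np.clip(c2 / n - m_h * m_h, 0.0, None)
    s_h = np.sqrt(var_h)
    with np.errstate(invalid="ignore", divide="ignore"):
        y_h = (head - m_h) / s_h
    y[:, : L - 1] = np.where(s_h > 0, y_h, 0.0)

    # steady state: full trailing windows
    wins = sliding_window_view(x, L, axis=1)  # (ch, n - L + 1, L)
    m = wins.mean(axis=-1)
    s = wins.std(axis=-1)
    zero = s == 0
    if np.any(zero):
        _handle_zero_variance(zero_variance_policy, "swn_stream")
        s = np.where(zero, 1.0, s)
    tail = (x[:, L - 1 :] - m) / s
    y[:, L - 1 :] = np.where(zero, 0.0, tail)
    return y


def sliding_window_normalize(rec: EmgRecording, spec: NormalizationSpec) -> EmgRecording:
    """Apply streaming SWN to a preprocessed recording."""
    if spec.method != "swn":
        raise ValueError("spec.method must be 'swn'")
    rec.require_stage("preprocessed")
    L = spec.window_samples(rec.fs)
    y = swn_stream(rec.samples, L, spec.zero_variance_policy)
    return rec.advanced(samples=y, fs=rec.fs, stage="normalized")


def compute_zscore_stats(samples: np.ndarray) -> ZScoreStats:
    """Population mean/SD per channel of a (channels x time) training array."""
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[1] == 0:
        raise ValueError("empty training data")
    return ZScoreStats(mean=x.mean(axis=1), std=x.std(axis=1))


def apply_zscore(samples: np.ndarray, stats: ZScoreStats) -> np.ndarray:
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    return (x - stats.mean[:, None]) / stats.std[:, None]


def zscore_normalize(
    train: EmgRecording, test: EmgRecording
) -> tuple[EmgRecording, EmgRecording, ZScoreStats]:
    """Z-score both sets using *training* statistics only (per channel)."""
    train.require_stage("preprocessed")
    test.require_stage("preprocessed")
    stats = compute_zscore_stats(train.samples)
    train_n = train.advanced(
        samples=apply_zscore(train.samples, stats), fs=train.fs, stage="normalized"
    )
    test_n = test.advanced(
        samples=apply_zscore(test.samples, stats), fs=test.fs, stage="normalized"
    )
    return train_n, test_n, stats


def no_normalization(rec: EmgRecording) -> EmgRecording:
    """The identity baseline, advancing the stage tag only."""
    rec.require_stage("preprocessed")
    return rec.advanced(samples=np.asarray(rec.samples, dtype=float), fs=rec.fs,
                        stage="normalized")


def normalize(rec: EmgRecording, spec: NormalizationSpec,
              stats: ZScoreStats | None = None) -> EmgRecording:
    """Dispatch on ``spec.method`` (z-score requires precomputed stats)."""
    if spec.method == "swn":
        return sliding_window_normalize(rec, spec)
    if spec.method == "zscore":
        if stats is None:
            raise ValueError("z-score normalization needs training statistics")
        rec.require_stage("preprocessed")
        return rec.advanced(samples=apply_zscore(rec.samples, stats), fs=rec.fs,
                            stage="normalized")
    return no_normalization(rec)
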
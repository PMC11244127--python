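"""Moving-window covariance/correlation features and the phoneme stack.

The discriminative signal for mouth-motion work is the *co-modulation* of
band amplitudes: when the jaw or tongue moves, the EMG components and the
EEG gamma band surge together while the resting rhythms do not.  Band
signals at disjoint frequencies are nearly orthogonal sample-by-sample, so
second-moment statistics are computed on amplitude envelopes (analytic
signal magnitude) by default; a raw-signal mode is available.

The eight-trace stack per phoneme sample:

====  ==========================================================
6-1   low-frequency EMG component (<25 Hz)
6-2   high-frequency EMG component (>25 Hz)
6-3   combined alpha+beta EEG component (8–30 Hz)
6-4   gamma EEG component (30–100 Hz)
7-1   moving correlation of 6-1 and 6-2
7-2   moving correlation of 6-3 and 6-4
7-3   moving correlation of 6-1 and 6-3
7-4   moving correlation of 6-2 and 6-4
====  ==========================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .preprocess import PHONEME_BANDS, Recording, decompose

__all__ = [
    "WindowSpec",
    "FeatureTrace",
    "PhonemeSample",
    "envelope",
    "moving_covariance",
    "moving_correlation",
    "phoneme_feature_stack",
    "BAND_TRACE_IDS",
    "CORRELATION_TRACE_IDS",
    "CORRELATION_PAIRS",
]

logger = logging.getLogger(__name__)

BAND_TRACE_IDS = ("6-1", "6-2", "6-3", "6-4")
CORRELATION_TRACE_IDS = ("7-1", "7-2", "7-3", "7-4")
# correlation pairs in terms of band trace ids
CORRELATION_PAIRS = {
    "7-1": ("6-1", "6-2"),
    "7-2": ("6-3", "6-4"),
    "7-3": ("6-1", "6-3"),
    "7-4": ("6-2", "6-4"),
}
_BAND_FOR_TRACE = dict(zip(BAND_TRACE_IDS, PHONEME_BANDS))


@dataclass(frozen=True)
class WindowSpec:
    """A moving analysis window.

    ``length_ms`` is the window duration (default 500 ms, i.e. 2000 samples
    at a 4 kHz sampling rate).  ``stride_samples`` defaults to a quarter
    window for smooth traces.
    """

    length_ms: float = 500.0
    stride_samples: int | None = None

    def length_samples(self, rate: float) -> int:
        n = int(round(self.length_ms * rate / 1000.0))
        if n < 2:
            raise ValueError("window must span at least 2 samples")
        return n

    def stride(self, rate: float) -> int:
        if self.stride_samples is not None:
            if self.stride_samples < 1:
                raise ValueError("stride must be >= 1 sample")
            return self.stride_samples
        return max(self.length_samples(rate) // 4, 1)

    def n_windows(self, n_samples: int, rate: float) -> int:
        length = self.length_samples(rate)
        if n_samples < length:
            raise ValueError(
                f"signal ({n_samples} samples) shorter than window ({length})")
        return (n_samples - length) // self.stride(rate) + 1


@dataclass
class FeatureTrace:
    """A moving-window covariance or correlation series for one band pair."""

    values: np.ndarray
    kind: str  # "covariance" | "correlation"
    pair: tuple[str, str]
    window: WindowSpec
    rate: float
    n_degenerate_windows: int = 0

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PhonemeSample:
    """The eight-trace feature stack for one silent-phoneme recording."""

    traces: dict[str, np.ndarray]
    label: str
    subject: str
    rate: float
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = BAND_TRACE_IDS + CORRELATION_TRACE_IDS
        if tuple(self.traces) != expected:
            missing = set(expected) - set(self.traces)
            extra = set(self.traces) - set(expected)
            raise ValueError(f"phoneme sample must carry exactly the 8 traces "
                             f"{expected}; missing={missing} extra={extra}")
        band_lengths = {len(self.traces[t]) for t in BAND_TRACE_IDS}
        corr_lengths = {len(self.traces[t]) for t in CORRELATION_TRACE_IDS}
        if len(band_lengths) != 1 or len(corr_lengths) != 1:
            raise ValueError("trace lengths inconsistent within trace groups")

    def to_matrix(self, n_points: int | None = None,
                  standardize: bool = True) -> np.ndarray:
        """Stack the 8 traces as a (8, n_points) matrix for the classifiers.

        Correlation traces are short (one value per window); all traces are
        linearly resampled onto a common time axis — by default the band-trace
        length.  With ``standardize`` the four band traces are scaled by one
        shared RMS (preserving their relative amplitudes, which carry the
        band-activation signature of a phoneme); correlation traces are
        already dimensionless in [−1, 1] and are left untouched.
        """
        ref_len = n_points or len(self.traces[BAND_TRACE_IDS[0]])
        t_out = np.linspace(0.0, 1.0, ref_len)
        rows = []
        for tid in BAND_TRACE_IDS + CORRELATION_TRACE_IDS:
            v = np.asarray(self.traces[tid], dtype=np.float64)
            if tid in BAND_TRACE_IDS:
                # resampling an oscillatory carrier below its band frequency
                # would alias it; the amplitude envelope carries the
                # band-activation information and survives resampling
                v = envelope(v)
            if len(v) == ref_len:
                row = v.copy()
            else:
                row = np.interp(t_out, np.linspace(0.0, 1.0, len(v)), v)
            rows.append(row)
        mat = np.stack(rows)
        if standardize:
            band_rms = np.sqrt(np.mean(mat[: len(BAND_TRACE_IDS)] ** 2))
            if band_rms > 0:
                mat[: len(BAND_TRACE_IDS)] /= band_rms
        return mat


def envelope(x: np.ndarray) -> np.ndarray:
    """Amplitude envelope of a signal: magnitude of its analytic signal.

    For a pure tone A·sin(ωt) the interior of the envelope equals A.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        return x.copy()
    return np.abs(hilbert(x))


def _window_view(x: np.ndarray, length: int, stride: int) -> np.ndarray:
    wins = np.lib.stride_tricks.sliding_window_view(x, length)
    return wins[::stride]


def moving_covariance(x: np.ndarray, y: np.ndarray,
                      window: WindowSpec, rate: float) -> FeatureTrace:
    """Per-window sample covariance (denominator n−1) between two signals."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    length = window.length_samples(rate)
    if x.size < length:
        raise ValueError(f"signal length {x.size} < window length {length}")
    stride = window.stride(rate)
    xw = _window_view(x, length, stride)
    yw = _window_view(y, length, stride)
    xc = xw - xw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    cov = (xc * yc).sum(axis=1) / (length - 1)
    return FeatureTrace(values=cov, kind="covariance", pair=("x", "y"),
                        window=window, rate=rate)


def moving_correlation(x: np.ndarray, y: np.ndarray,
                       window: WindowSpec, rate: float) -> FeatureTrace:
    """Per-window Pearson correlation between two signals.

    Windows in which either input has zero variance are assigned the
    sentinel value 0 and counted in ``n_degenerate_windows`` (with a logged
    warning) rather than failing the whole trace.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    length = window.length_samples(rate)
    if x.size < length:
        raise ValueError(f"signal length {x.size} < window length {length}")
    stride = window.stride(rate)
    xw = _window_view(x, length, stride)
    yw = _window_view(y, length, stride)
    xc = xw - xw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc * xc).sum(axis=1))
    sy = np.sqrt((yc * yc).sum(axis=1))
    denom = sx * sy
    degenerate = denom == 0
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("moving_correlation: %d zero-variance window(s) set to 0",
                       n_deg)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    r = np.where(degenerate, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    return FeatureTrace(values=r, kind="correlation", pair=("x", "y"),
                        window=window, rate=rate,
                        n_degenerate_windows=n_deg)


def phoneme_feature_stack(recording: Recording,
                          window: WindowSpec | None = None,
                          use_envelope: bool = True) -> PhonemeSample:
    """Compute the eight-trace feature stack from a two-channel recording.

    Equivalent to ``decompose`` → ``envelope`` → ``moving_correlation`` on
    the four stated band pairs.  ``use_envelope=False`` computes the
    correlations on the raw band signals instead.
    """
    window = window or WindowSpec()
    bandset = decompose(recording, list(PHONEME_BANDS))
    traces: dict[str, np.ndarray] = {}
    env: dict[str, np.ndarray] = {}
    for tid in BAND_TRACE_IDS:
        sig = bandset[_BAND_FOR_TRACE[tid]]
        traces[tid] = sig
        env[tid] = envelope(sig) if use_envelope else sig
    for tid, (a, b) in CORRELATION_PAIRS.items():
        tr = moving_correlation(env[a], env[b], window, recording.sampling_rate)
        traces[tid] = tr.values
    label = recording.meta.get("label", "")
    subject = recording.meta.get("subject", "")
    return PhonemeSample(traces=traces, label=label, subject=subject,
                         rate=recording.sampling_rate,
                         sample_id=recording.meta.get("sample_id", ""),
                         meta=dict(recording.meta))
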
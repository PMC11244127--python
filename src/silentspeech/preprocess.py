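"""Signal containers, normalization and Butterworth band decomposition.

Mixed EEG-EMG recordings are decomposed into the conventional EEG rhythm
bands (alpha 8–12 Hz, beta 13–30 Hz, gamma 30–100 Hz, and the combined
alpha+beta 8–30 Hz) and into low-/high-frequency EMG components split at
25 Hz.  All filters are Butterworth, applied forward-backward (zero phase)
so band traces stay time-aligned with the raw signal — a requirement for
the moving-window covariance features computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "Annotation",
    "Recording",
    "BandDefinition",
    "BandSet",
    "CANONICAL_BANDS",
    "PHONEME_BANDS",
    "TONGUE_BANDS",
    "normalize_signal",
    "bandpass",
    "decompose",
    "default_filter_order",
]

default_filter_order = 4  # standard choice for EEG band filtering


@dataclass(frozen=True)
class Annotation:
    """An event marker: onset and duration in seconds plus a free-text label."""

    onset: float
    duration: float
    label: str = "event"


@dataclass
class Recording:
    """A multichannel biopotential recording.

    Parameters
    ----------
    channels : ndarray, shape (n_channels, n_samples)
        Microvolt-scale samples, one row per electrode.
    channel_roles : list of {"EEG", "EMG"}
        Physiological role of each channel.
    sampling_rate : float
        Samples per second (Hz).
    annotations : list of Annotation
        Movement / phoneme event markers.
    """

    channels: np.ndarray
    channel_roles: list[str]
    sampling_rate: float
    annotations: list[Annotation] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=np.float64))
        if self.channels.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_roles) != self.channels.shape[0]:
            raise ValueError("one role per channel required")
        dur = self.duration
        for ann in self.annotations:
            if ann.onset < 0 or ann.onset + ann.duration > dur + 1e-9:
                raise ValueError(
                    f"annotation {ann} falls outside the record [0, {dur:.3f}] s")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, role: str) -> np.ndarray:
        """Return the first channel with the given role."""
        for ch, r in zip(self.channels, self.channel_roles):
            if r == role:
                return ch
        raise KeyError(f"no channel with role {role!r} "
                       f"(available: {self.channel_roles})")


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band; ``low_hz``/``high_hz`` may be None for open edges."""

    name: str
    low_hz: float | None
    high_hz: float | None

    def __post_init__(self):
        if self.low_hz is not None and self.high_hz is not None \
                and not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low edge must be below high edge")
        if self.low_hz is None and self.high_hz is None:
            raise ValueError(f"band {self.name}: at least one edge required")

    def validate_rate(self, rate: float) -> None:
        nyq = rate / 2.0
        for edge in (self.low_hz, self.high_hz):
            if edge is not None and edge >= nyq:
                raise ValueError(
                    f"band {self.name}: edge {edge} Hz is at or above the "
                    f"Nyquist frequency {nyq} Hz")


def _emg_high(rate: float) -> BandDefinition:
    """EMG >25 Hz realized as a band up to 0.45·rate (below Nyquist)."""
    return BandDefinition("emg_high", 25.0, 0.45 * rate)


# Canonical band edges.  The "alpha" label is also used in the loose sense
# of "below 13 Hz" in parts of the tongue-motion analysis; the 8–12 Hz
# definition is the default and every edge can be overridden.
CANONICAL_BANDS: dict[str, BandDefinition] = {
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 100.0),
    "alpha_beta": BandDefinition("alpha_beta", 8.0, 30.0),
    "high_gamma": BandDefinition("high_gamma", 70.0, 120.0),
    "emg_low": BandDefinition("emg_low", 0.5, 25.0),
}

# role assignment for decompose(): which channel each named band filters
BAND_ROLES: dict[str, str] = {
    "alpha": "EEG", "beta": "EEG", "gamma": "EEG", "alpha_beta": "EEG",
    "high_gamma": "EEG", "emg_low": "EMG", "emg_high": "EMG",
}

# The four phoneme feature bands: EMG low/high split at 25 Hz plus the
# combined alpha+beta and the gamma EEG components.
PHONEME_BANDS = ("emg_low", "emg_high", "alpha_beta", "gamma")
# The three rhythm bands used for tongue-motion statistics.
TONGUE_BANDS = ("alpha", "beta", "gamma")


def band_by_name(name: str, rate: float) -> BandDefinition:
    if name == "emg_high":
        return _emg_high(rate)
    try:
        return CANONICAL_BANDS[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; known: "
                       f"{sorted(CANONICAL_BANDS) + ['emg_high']}") from None


@dataclass
class BandSet:
    """Named band-filtered derivatives of one recording."""

    source: Recording
    bands: dict[str, np.ndarray]
    filter_order: int = default_filter_order
    zero_phase: bool = True

    def __getitem__(self, name: str) -> np.ndarray:
        return self.bands[name]

    def __contains__(self, name: str) -> bool:
        return name in self.bands

    def names(self) -> list[str]:
        return list(self.bands)


def normalize_signal(x: np.ndarray, method: str = "zscore") -> np.ndarray:
    """Normalize a 1-D signal.

    ``zscore`` maps to mean 0 / population SD 1; ``minmax`` maps onto [0, 1].
    Raises on constant input (zero variance / zero range) and on signals
    shorter than two samples.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("normalize_signal expects a 1-D signal")
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    if method == "zscore":
        sd = x.std()
        if sd == 0:
            raise ValueError("zero-variance signal cannot be z-scored")
        return (x - x.mean()) / sd
    if method == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError("constant signal cannot be min-max scaled")
        return (x - lo) / (hi - lo)
    raise ValueError(f"unknown normalization method {method!r}")


def bandpass(x: np.ndarray, band: BandDefinition, rate: float,
             order: int = default_filter_order) -> np.ndarray:
    """Zero-phase Butterworth filtering of ``x`` into ``band``.

    Open-ended bands become high-pass (no upper edge) or low-pass (no lower
    edge) filters.  The forward-backward (``sosfiltfilt``) application keeps
    the output time-aligned with the input and squares the magnitude
    response, so the effective attenuation is twice the design order's.
    """
    x = np.asarray(x, dtype=np.float64)
    band.validate_rate(rate)
    nyq = rate / 2.0
    if band.low_hz is None:
        sos = sps.butter(order, band.high_hz / nyq, btype="lowpass", output="sos")
    elif band.high_hz is None:
        sos = sps.butter(order, band.low_hz / nyq, btype="highpass", output="sos")
    else:
        sos = sps.butter(order, [band.low_hz / nyq, band.high_hz / nyq],
                         btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, x)


def settling_length(band: BandDefinition, rate: float,
                    order: int = default_filter_order) -> int:
    """Edge-effect guard length in samples (≈ 3 periods of the low edge)."""
    low = band.low_hz if band.low_hz else band.high_hz
    return int(min(3.0 * rate / max(low, 1e-6), rate))


def decompose(recording: Recording,
              bands: list[BandDefinition] | list[str] | None = None,
              order: int = default_filter_order,
              normalize: str | None = "zscore",
              band_roles: dict[str, str] | None = None) -> BandSet:
    """Filter a recording into a set of named band traces.

    Each band is filtered from the channel matching its role (EEG rhythm
    bands from the EEG channel, EMG components from the EMG channel).
    Channels are z-score normalized before filtering by default.  An empty
    band list yields an empty BandSet.
    """
    roles = dict(BAND_ROLES)
    if band_roles:
        roles.update(band_roles)
    if bands is None:
        bands = list(PHONEME_BANDS)
    resolved: list[BandDefinition] = []
    for b in bands:
        resolved.append(band_by_name(b, recording.sampling_rate)
                        if isinstance(b, str) else b)

    normed: dict[str, np.ndarray] = {}

    def channel_for(band: BandDefinition) -> np.ndarray:
        role = roles.get(band.name)
        if role is None:
            raise KeyError(f"band {band.name!r} has no channel-role assignment; "
                           "pass band_roles={...}")
        if role not in recording.channel_roles:
            raise KeyError(f"band {band.name!r} needs a {role} channel but the "
                           f"recording has roles {recording.channel_roles}")
        if role not in normed:
            ch = recording.channel(role)
            normed[role] = normalize_signal(ch, normalize) if normalize else ch
        return normed[role]

    out: dict[str, np.ndarray] = {}
    for band in resolved:
        out[band.name] = bandpass(channel_for(band), band,
                                  recording.sampling_rate, order)
    return BandSet(source=recording, bands=out, filter_order=order)
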
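"""Synthetic EEG-EMG recordings and silent-phoneme datasets.

No public recordings exist for this kind of jaw/temple EEG-EMG setup, so
the generator emulates the statistical structure the real system exhibits:

* baseline signals are sums of band-limited Gaussian noise (alpha, beta,
  gamma on the EEG channel; <25 Hz and >25 Hz components on the EMG
  channel), so amplitude histograms are normal;
* during movement ("spike") events the gamma-band power rises (default
  4x over baseline), the EMG components burst, and the alpha and gamma
  amplitude envelopes — co-modulated at rest — decouple, reproducing the
  drop in alpha–gamma correlation during movement;
* phoneme samples (classes M, A, D; two subjects; ten samples each, 60 in
  total by default) differ by class-specific temporal envelopes on the
  EMG-low, EMG-high and gamma components, with per-sample jitter and
  per-subject gain/timing offsets so classes are separable but overlap.

Everything is a pure function of (config, seed): a single global seed fans
out to per-sample child seeds so any subset is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocess import Annotation, BandDefinition, Recording, band_by_name

__all__ = [
    "SynthConfig",
    "PhonemeSynthConfig",
    "ClassTemplate",
    "DEFAULT_TEMPLATES",
    "simulate_recording",
    "simulate_phoneme_dataset",
]

_EEG_BANDS = ("alpha", "beta", "gamma")
_EMG_BANDS = ("emg_low", "emg_high")

DEFAULT_PRE_POWERS = {
    "alpha": 1.0, "beta": 0.7, "gamma": 0.25, "emg_low": 0.5, "emg_high": 0.5,
}
DEFAULT_SPIKE_POWERS = {
    "alpha": 0.6, "beta": 0.7, "gamma": 1.0, "emg_low": 0.5, "emg_high": 0.5,
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for a tongue-motion style mixed EEG-EMG recording.

    ``band_powers_pre`` / ``band_powers_spike`` give per-band variances in
    (squared) signal units outside and inside movement events.  The default
    spike:pre gamma ratio is 4.  ``emg_burst_gain`` multiplies the EMG
    component amplitudes during events.  Events are ``event_duration`` (3 s
    by default) long, starting at ``event_times``.
    """

    sampling_rate: float = 4000.0
    duration: float = 40.0
    event_times: tuple[float, ...] = (5.0, 12.0, 19.0, 26.0, 33.0)
    event_duration: float = 3.0
    band_powers_pre: dict = field(default_factory=lambda: dict(DEFAULT_PRE_POWERS))
    band_powers_spike: dict = field(default_factory=lambda: dict(DEFAULT_SPIKE_POWERS))
    emg_burst_gain: float = 3.0
    noise_sd: float = 0.1
    modulation_depth: float = 0.4
    ramp_s: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, table in (("band_powers_pre", self.band_powers_pre),
                            ("band_powers_spike", self.band_powers_spike)):
            for band, var in table.items():
                if var < 0:
                    raise ValueError(f"{name}[{band!r}] must be >= 0")
        edges = [band_by_name(b, self.sampling_rate).high_hz
                 for b in set(self.band_powers_pre) | set(self.band_powers_spike)]
        top = max(e for e in edges if e is not None)
        if self.sampling_rate <= 2.0 * top:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz violates Nyquist for a "
                f"band edge at {top} Hz")
        intervals = sorted((t, t + self.event_duration) for t in self.event_times)
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise ValueError(
                    f"events overlap: [{a0}, {a1}) and [{b0}, {b1})")
        for a0, a1 in intervals:
            if a0 < 0 or a1 > self.duration:
                raise ValueError(f"event [{a0}, {a1}) outside [0, {self.duration}]")


def _band_noise(rng: np.random.Generator, band: BandDefinition, rate: float,
                n: int) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to one frequency band."""
    white = rng.standard_normal(n)
    nyq = rate / 2.0
    lo = band.low_hz / nyq if band.low_hz else None
    hi = band.high_hz / nyq if band.high_hz else None
    if lo and hi:
        sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos")
    elif hi:
        sos = sps.butter(4, hi, btype="lowpass", output="sos")
    else:
        sos = sps.butter(4, lo, btype="highpass", output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_modulation(rng: np.random.Generator, rate: float, n: int,
                     cutoff_hz: float = 2.0) -> np.ndarray:
    """Unit-variance slow (<~2 Hz) modulation series."""
    white = rng.standard_normal(n)
    sos = sps.butter(2, cutoff_hz / (rate / 2.0), btype="lowpass", output="sos")
    m = sps.sosfiltfilt(sos, white)
    sd = m.std()
    return m / sd if sd > 0 else m


def _event_blend(t: np.ndarray, events: list[tuple[float, float]],
                 ramp_s: float) -> np.ndarray:
    """0 outside events, 1 inside, cosine ramps of length ramp_s at edges."""
    s = np.zeros_like(t)
    for a, b in events:
        rise = np.clip((t - a) / max(ramp_s, 1e-9), 0.0, 1.0)
        fall = np.clip((b - t) / max(ramp_s, 1e-9), 0.0, 1.0)
        s = np.maximum(s, 0.5 * (1 - np.cos(np.pi * rise))
                       * 0.5 * (1 - np.cos(np.pi * fall)))
    return s


def simulate_recording(config: SynthConfig) -> Recording:
    """Generate a two-channel (EEG, EMG) recording with movement events.

    Outside events each band carries its ``band_powers_pre`` variance;
    inside events the EEG bands blend to ``band_powers_spike`` and the EMG
    components are multiplied by ``emg_burst_gain``.  At rest the alpha and
    gamma amplitude envelopes share a slow modulation; during events the
    gamma envelope switches to an independent modulation, so the alpha–gamma
    envelope correlation declines in spike epochs.  Identical seeds yield
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    rate = config.sampling_rate
    n = int(round(config.duration * rate))
    t = np.arange(n) / rate
    events = [(t0, t0 + config.event_duration) for t0 in config.event_times]
    blend = _event_blend(t, events, config.ramp_s)

    m_shared = _slow_modulation(rng, rate, n)
    m_indep = _slow_modulation(rng, rate, n)
    depth = config.modulation_depth

    def amp_mod(m: np.ndarray) -> np.ndarray:
        return np.clip(1.0 + depth * m, 0.05, None)

    eeg = np.zeros(n)
    for band_name in _EEG_BANDS:
        band = band_by_name(band_name, rate)
        carrier = _band_noise(rng, band, rate, n)
        sd_pre = np.sqrt(config.band_powers_pre.get(band_name, 0.0))
        sd_spk = np.sqrt(config.band_powers_spike.get(band_name, 0.0))
        level = sd_pre + (sd_spk - sd_pre) * blend
        if band_name == "gamma":
            mod = amp_mod((1 - blend) * m_shared + blend * m_indep)
        else:
            mod = amp_mod(m_shared)
        eeg += carrier * level * mod

    emg = np.zeros(n)
    burst = 1.0 + (config.emg_burst_gain - 1.0) * blend
    for band_name in _EMG_BANDS:
        band = band_by_name(band_name, rate)
        carrier = _band_noise(rng, band, rate, n)
        sd_pre = np.sqrt(config.band_powers_pre.get(band_name, 0.0))
        sd_spk = np.sqrt(config.band_powers_spike.get(band_name, sd_pre ** 2))
        level = sd_pre + (sd_spk - sd_pre) * blend
        emg += carrier * level * burst

    if config.noise_sd > 0:
        eeg = eeg + config.noise_sd * rng.standard_normal(n)
        emg = emg + config.noise_sd * rng.standard_normal(n)
    else:  # keep degenerate all-zero configs exactly zero
        rng.standard_normal(2 * n)

    annotations = [Annotation(onset=a, duration=b - a, label="movement")
                   for a, b in events]
    return Recording(
        channels=np.vstack([eeg, emg]),
        channel_roles=["EEG", "EMG"],
        sampling_rate=rate,
        annotations=annotations,
        meta={"generator": "simulate_recording", "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# phoneme dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassTemplate:
    """Per-class temporal signature: Gaussian activation bumps per band.

    ``bumps`` maps a band name to a list of ``(center, width, amplitude)``
    triples on the normalized time axis [0, 1] of a sample.  The band
    envelope is ``base + sum of bumps``; amplitudes are in units of the
    band's baseline SD.
    """

    name: str
    bumps: dict[str, tuple[tuple[float, float, float], ...]]
    base: float = 0.3


# Class signatures, loosely articulatory: M (bilabial, nasal) is a single
# broad low-frequency jaw/lip closure; A (open vowel) is a sustained broad
# opening with strong high-frequency EMG and gamma drive; D (alveolar stop)
# is a pair of short sharp bursts.  Magnitudes were fixed once so that the
# three classes are separable yet overlapping for the classifier study.
DEFAULT_TEMPLATES: dict[str, ClassTemplate] = {
    "M": ClassTemplate("M", {
        "emg_low": ((0.5, 0.14, 3.0),),
        "emg_high": ((0.5, 0.14, 0.6),),
        "gamma": ((0.5, 0.16, 1.2),),
    }),
    "A": ClassTemplate("A", {
        "emg_low": ((0.55, 0.26, 0.7),),
        "emg_high": ((0.55, 0.26, 2.4),),
        "gamma": ((0.55, 0.26, 2.2),),
    }),
    "D": ClassTemplate("D", {
        "emg_low": ((0.35, 0.055, 2.0), (0.65, 0.055, 2.0)),
        "emg_high": ((0.35, 0.055, 2.2), (0.65, 0.055, 2.2)),
        "gamma": ((0.35, 0.07, 1.8), (0.65, 0.07, 1.8)),
    }),
}


@dataclass(frozen=True)
class PhonemeSynthConfig:
    """Configuration for the synthetic silent-phoneme dataset.

    Defaults reproduce the study's dataset shape: 3 phonemes x 2 subjects
    x 10 samples = 60 recordings.  ``amp_jitter``/``time_jitter``/
    ``width_jitter`` control intra-class variability; ``subject_offset_scale``
    the inter-subject gain/timing offsets.
    """

    n_per_class_per_subject: int = 10
    classes: tuple[str, ...] = ("M", "A", "D")
    n_subjects: int = 2
    sampling_rate: float = 4000.0
    duration: float = 2.0
    templates: dict = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))
    band_powers: dict = field(default_factory=lambda: dict(DEFAULT_PRE_POWERS))
    amp_jitter: float = 0.45
    time_jitter: float = 0.10
    width_jitter: float = 0.30
    subject_offset_scale: float = 0.45
    noise_sd: float = 0.45
    modulation_depth: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class_per_subject < 1 or self.n_subjects < 1:
            raise ValueError("counts must be >= 1")
        for c in self.classes:
            if c not in self.templates:
                raise ValueError(f"class {c!r} has no template "
                                 f"(templates: {sorted(self.templates)})")
        if self.sampling_rate <= 2 * 100.0:
            raise ValueError("sampling rate must exceed twice the gamma band "
                             "upper edge (100 Hz)")

    @property
    def n_samples(self) -> int:
        return self.n_per_class_per_subject * len(self.classes) * self.n_subjects


def _phoneme_sample(child_seed: np.random.SeedSequence,
                    config: PhonemeSynthConfig, label: str, subject_idx: int,
                    subject_gains: dict[str, float], subject_shift: float,
                    sample_id: str) -> Recording:
    rng = np.random.default_rng(child_seed)
    rate = config.sampling_rate
    n = int(round(config.duration * rate))
    tau = np.arange(n) / n  # normalized time
    tpl = config.templates[label]

    def band_envelope(band: str) -> np.ndarray:
        env = np.full(n, tpl.base)
        for (c, w, a) in tpl.bumps.get(band, ()):
            c = c + rng.normal(0.0, config.time_jitter) + subject_shift
            w = w * np.exp(rng.normal(0.0, config.width_jitter))
            a = a * np.exp(rng.normal(0.0, config.amp_jitter)) \
                * subject_gains.get(band, 1.0)
            env = env + a * np.exp(-0.5 * ((tau - c) / w) ** 2)
        return env

    m_shared = _slow_modulation(rng, rate, n, cutoff_hz=3.0)

    def amp_mod() -> np.ndarray:
        return np.clip(1.0 + config.modulation_depth * m_shared, 0.05, None)

    channels = {"EEG": np.zeros(n), "EMG": np.zeros(n)}
    for band_name, role in (("alpha", "EEG"), ("beta", "EEG"),
                            ("gamma", "EEG"), ("emg_low", "EMG"),
                            ("emg_high", "EMG")):
        band = band_by_name(band_name, rate)
        carrier = _band_noise(rng, band, rate, n)
        sd = np.sqrt(config.band_powers.get(band_name, 0.0))
        env = band_envelope(band_name)
        channels[role] += carrier * sd * env * amp_mod()
    for role in channels:
        channels[role] += config.noise_sd * rng.standard_normal(n)

    annotations = [Annotation(onset=0.2 * config.duration,
                              duration=0.6 * config.duration,
                              label=f"phoneme:{label}")]
    return Recording(
        channels=np.vstack([channels["EEG"], channels["EMG"]]),
        channel_roles=["EEG", "EMG"],
        sampling_rate=rate,
        annotations=annotations,
        meta={"label": label, "subject": f"S{subject_idx + 1}",
              "sample_id": sample_id},
    )


def simulate_phoneme_dataset(config: PhonemeSynthConfig) -> list[Recording]:
    """Generate the labeled phoneme dataset (default 60 recordings).

    Samples are ordered by (subject, class, repetition); each gets its own
    child seed spawned from the global seed, so the collection is a pure
    function of (config, seed) and any subset regenerates identically.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    subj_ss, *sample_ss = root.spawn(1 + config.n_samples)
    subj_rng = np.random.default_rng(subj_ss)

    # per-subject multiplicative band gains and a small timing offset
    subject_params = []
    for _ in range(config.n_subjects):
        gains = {b: float(np.exp(subj_rng.normal(0.0, config.subject_offset_scale)))
                 for b in ("emg_low", "emg_high", "gamma", "alpha", "beta")}
        shift = float(subj_rng.normal(0.0, config.subject_offset_scale * 0.2))
        subject_params.append((gains, shift))

    recordings: list[Recording] = []
    k = 0
    for s in range(config.n_subjects):
        gains, shift = subject_params[s]
        for label in config.classes:
            for rep in range(config.n_per_class_per_subject):
                sid = f"S{s + 1}-{label}-{rep + 1:02d}"
                recordings.append(_phoneme_sample(
                    sample_ss[k], config, label, s, gains, shift, sid))
                k += 1
    return recordings
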
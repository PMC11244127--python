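"""Training-time data augmentation for feature-stack samples.

Two families of operations, applied in random order on every access to a
training sample (validation/test samples pass through untouched):

* whole-sample ops — random slope, x-shift (edge-replicated), y-shift,
  amplitude scaling;
* windowed ops — a moving window slides over the sample and, with a low
  per-window probability, applies one of: hanging datapoint (a held value,
  mimicking a brief recording dropout), Gaussian smoothing, noise addition,
  or downsampling (re-interpolated to keep the length stable).

Random cropping keeps a contiguous fraction of the sample, then linearly
re-interpolates to the original length so batch tensors stay rectangular.
Labels are never touched: augmentation operates on the signal array only.

All magnitudes are policy parameters; the defaults are deliberately mild
(a few percent of sample scale) since the operations model sensor drift,
noise intrusions and brief recording errors rather than new articulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "AugmentationPolicy",
    "GLOBAL_OPS",
    "WINDOWED_OPS",
    "apply_global_op",
    "apply_windowed_op",
    "random_crop",
    "augment",
]

GLOBAL_OPS = ("random_slope", "shift_x", "shift_y", "scale")
WINDOWED_OPS = ("hanging_datapoint", "gaussian_filter", "noise_addition",
                "downsample")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Magnitudes and probabilities for the augmentation suite.

    ``slope_mag``: max added slope over the full duration, as a fraction of
    the sample RMS.  ``shift_x_frac``: max translation as a fraction of the
    length.  ``shift_y_mag``: max vertical offset as a fraction of RMS.
    ``scale_range``: multiplicative amplitude range.  ``window_frac`` and
    ``window_p``: moving-window size (fraction of length) and per-window
    probability for the windowed ops.  ``noise_sd_frac``: added-noise SD as
    a fraction of RMS.  ``crop_range``: kept-fraction range for random
    cropping.  ``enabled=False`` or all-zero magnitudes give the identity.
    """

    enabled: bool = True
    slope_mag: float = 0.10
    shift_x_frac: float = 0.08
    shift_y_mag: float = 0.10
    scale_range: tuple[float, float] = (0.8, 1.25)
    window_frac: float = 0.1
    window_p: float = 0.05
    noise_sd_frac: float = 0.1
    gaussian_sigma: float = 2.0
    downsample_factor: int = 4
    crop_range: tuple[float, float] = (0.65, 1.0)
    crop_enabled: bool = True
    global_ops: tuple[str, ...] = GLOBAL_OPS
    windowed_ops: tuple[str, ...] = WINDOWED_OPS

    def __post_init__(self):
        if not 0.0 <= self.window_p <= 1.0:
            raise ValueError("window_p must be in [0, 1]")
        lo, hi = self.crop_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_range must satisfy 0 < lo <= hi <= 1")
        for op in self.global_ops:
            if op not in GLOBAL_OPS:
                raise ValueError(f"unknown global op {op!r}")
        for op in self.windowed_ops:
            if op not in WINDOWED_OPS:
                raise ValueError(f"unknown windowed op {op!r}")


def _rms(x: np.ndarray) -> float:
    r = float(np.sqrt(np.mean(x ** 2)))
    return r if r > 0 else 1.0


def apply_global_op(sample: np.ndarray, op: str, magnitude: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Apply one whole-sample operation; the label is untouched by design.

    ``magnitude`` is the op's drawn parameter: slope per full duration and
    y-offset in signal units, scale factor for ``scale``, and fractional
    translation for ``shift_x``.  Magnitude 0 (or scale 1) is the identity.
    """
    x = np.asarray(sample, dtype=np.float64)
    t = np.linspace(-0.5, 0.5, x.shape[-1])
    if op == "random_slope":
        return x + magnitude * t
    if op == "shift_y":
        return x + magnitude
    if op == "scale":
        return x * magnitude
    if op == "shift_x":
        shift = int(round(magnitude * x.shape[-1]))
        if shift == 0:
            return x.copy()
        out = np.roll(x, shift, axis=-1)
        if shift > 0:  # edge replication instead of wraparound
            out[..., :shift] = x[..., :1]
        else:
            out[..., shift:] = x[..., -1:]
        return out
    raise ValueError(f"unknown global op {op!r}")


def apply_windowed_op(sample: np.ndarray, op: str, window: int, p: float,
                      rng: np.random.Generator,
                      noise_sd: float = 0.1, gaussian_sigma: float = 2.0,
                      downsample_factor: int = 4) -> np.ndarray:
    """Slide a window over the sample, applying ``op`` with probability ``p``.

    Windows tile the time axis without overlap; untouched windows are
    bit-identical to the input.
    """
    x = np.asarray(sample, dtype=np.float64).copy()
    n = x.shape[-1]
    if window > n:
        raise ValueError(f"window {window} longer than sample {n}")
    if window < 2:
        raise ValueError("window must be >= 2 samples")
    for start in range(0, n - window + 1, window):
        if rng.random() >= p:
            continue
        seg = x[..., start:start + window]
        if op == "hanging_datapoint":
            hold_at = rng.integers(0, window)
            seg[..., hold_at:] = seg[..., hold_at:hold_at + 1]
        elif op == "gaussian_filter":
            x[..., start:start + window] = gaussian_filter1d(
                seg, sigma=gaussian_sigma, axis=-1, mode="nearest")
        elif op == "noise_addition":
            x[..., start:start + window] = seg + rng.normal(
                0.0, noise_sd, size=seg.shape)
        elif op == "downsample":
            idx = np.arange(0, window, downsample_factor)
            coarse = seg[..., idx]
            fine = np.arange(window)
            x[..., start:start + window] = np.apply_along_axis(
                lambda row: np.interp(fine, idx, row), -1, coarse)
        else:
            raise ValueError(f"unknown windowed op {op!r}")
    return x


def random_crop(sample: np.ndarray, crop_range: tuple[float, float],
                rng: np.random.Generator, min_length: int = 8,
                restore_length: bool = True) -> np.ndarray:
    """Keep a random contiguous fraction of the sample.

    The kept fraction is drawn uniformly from ``crop_range`` and the start
    offset uniformly over the valid positions.  With ``restore_length`` the
    crop is linearly re-interpolated back to the input length so downstream
    batch shapes stay fixed.
    """
    x = np.asarray(sample, dtype=np.float64)
    n = x.shape[-1]
    f = rng.uniform(*crop_range)
    keep = int(round(f * n))
    if keep < min_length:
        raise ValueError(f"crop of {keep} samples below the minimum "
                         f"{min_length}")
    start = int(rng.integers(0, n - keep + 1))
    cropped = x[..., start:start + keep]
    if not restore_length or keep == n:
        return cropped.copy()
    t_out = np.linspace(0.0, 1.0, n)
    t_in = np.linspace(0.0, 1.0, keep)
    return np.apply_along_axis(lambda row: np.interp(t_out, t_in, row),
                               -1, cropped)


def augment(sample: np.ndarray, policy: AugmentationPolicy,
            rng: np.random.Generator) -> np.ndarray:
    """Apply the full augmentation policy to one training sample.

    The enabled whole-sample and windowed operations are shuffled into a
    single random order and each is applied with its own random draw; a
    random crop follows.  Every call draws fresh randomness — the caller
    applies this to training samples only, on each access.
    """
    x = np.asarray(sample, dtype=np.float64)
    if not policy.enabled:
        return x.copy()
    rms = _rms(x)
    n = x.shape[-1]
    ops = list(policy.global_ops) + list(policy.windowed_ops)
    order = rng.permutation(len(ops))
    window = max(int(round(policy.window_frac * n)), 2)
    for i in order:
        op = ops[i]
        if op == "random_slope":
            x = apply_global_op(x, op, rng.uniform(-1, 1) * policy.slope_mag * rms, rng)
        elif op == "shift_x":
            x = apply_global_op(x, op, rng.uniform(-1, 1) * policy.shift_x_frac, rng)
        elif op == "shift_y":
            x = apply_global_op(x, op, rng.uniform(-1, 1) * policy.shift_y_mag * rms, rng)
        elif op == "scale":
            x = apply_global_op(x, op, rng.uniform(*policy.scale_range), rng)
        else:
            x = apply_windowed_op(
                x, op, window, policy.window_p, rng,
                noise_sd=policy.noise_sd_frac * rms,
                gaussian_sigma=policy.gaussian_sigma,
                downsample_factor=policy.downsample_factor)
    if policy.crop_enabled:
        x = random_crop(x, policy.crop_range, rng)
    return x
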
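"""Pre/spike epoch statistics on band correlations.

Tongue-motion detection rests on a simple contrast: in the ~2 s of repose
before a movement ("pre") the resting rhythms dominate and their amplitude
envelopes co-vary, while during the movement ("spike") gamma power surges
and the alpha–gamma correlation declines.  This module segments a recording
into pre/spike epochs around annotated events, computes per-epoch Pearson
correlations between band envelopes for chosen band pairs, and tests the
phase difference with a one-way ANOVA (F, p, and the F critical value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import envelope
from .preprocess import BandSet, Recording

__all__ = [
    "Epoch",
    "EpochSet",
    "CorrTable",
    "AnovaResult",
    "DEFAULT_PAIRS",
    "segment_epochs",
    "epoch_band_correlations",
    "one_way_anova",
    "f_critical",
    "compare_pre_spike",
]

DEFAULT_PAIRS = (("alpha", "gamma"), ("beta", "gamma"), ("alpha", "beta"))


@dataclass(frozen=True)
class Epoch:
    start: float
    end: float
    phase: str  # "pre" | "spike"
    repetition: int


@dataclass
class EpochSet:
    epochs: list[Epoch]
    rate: float

    def by_phase(self, phase: str) -> list[Epoch]:
        return [e for e in self.epochs if e.phase == phase]


@dataclass
class CorrTable:
    """Tidy per-(epoch, band-pair) correlation rows.

    Columns: repetition, phase, pair, r, flagged (zero-variance epochs are
    flagged and excluded from downstream tests).
    """

    rows: pd.DataFrame

    def valid(self) -> pd.DataFrame:
        return self.rows[~self.rows["flagged"]]


@dataclass(frozen=True)
class AnovaResult:
    f_value: float
    p_value: float
    df_between: int
    df_within: int
    f_critical: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def segment_epochs(recording: Recording, pre_s: float = 2.0,
                   spike_s: float | None = None) -> EpochSet:
    """Pair each annotated event with a pre epoch immediately before it.

    The pre epoch is ``[onset - pre_s, onset)`` and the spike epoch
    ``[onset, onset + spike_s)`` where ``spike_s`` defaults to each event's
    annotated duration (3 s in the standard protocol).  Events too close
    together (closer than pre_s + spike_s) or starting before ``pre_s`` are
    rejected with a message naming the offenders.
    """
    events = sorted(recording.annotations, key=lambda a: a.onset)
    if not events:
        raise ValueError("recording has no annotated events to segment")
    epochs: list[Epoch] = []
    problems: list[str] = []
    prev_end = 0.0
    for i, ev in enumerate(events):
        dur = spike_s if spike_s is not None else ev.duration
        pre_start = ev.onset - pre_s
        if pre_start < 0:
            problems.append(f"event {i} at t={ev.onset:.3f}s leaves no room "
                            f"for a {pre_s}s pre epoch")
            continue
        if pre_start < prev_end - 1e-9:
            problems.append(f"events {i - 1} and {i} closer than "
                            f"pre_s + spike_s = {pre_s + dur:.3f}s")
            continue
        epochs.append(Epoch(pre_start, ev.onset, "pre", i))
        epochs.append(Epoch(ev.onset, ev.onset + dur, "spike", i))
        prev_end = ev.onset + dur
    if problems:
        raise ValueError("epoch segmentation failed: " + "; ".join(problems))
    return EpochSet(epochs=epochs, rate=recording.sampling_rate)


def epoch_band_correlations(bandset: BandSet, epochs: EpochSet,
                            pairs=DEFAULT_PAIRS,
                            use_envelope: bool = True) -> CorrTable:
    """Pearson r between band (envelope) signals within each epoch.

    One row per (epoch, pair).  Epoch slices with zero variance in either
    band are flagged rather than raising.
    """
    rate = bandset.source.sampling_rate
    n = bandset.source.n_samples
    env: dict[str, np.ndarray] = {}

    def series(name: str) -> np.ndarray:
        if name not in env:
            sig = bandset[name]
            env[name] = envelope(sig) if use_envelope else sig
        return env[name]

    records = []
    for ep in epochs.epochs:
        i0 = int(round(ep.start * rate))
        i1 = min(int(round(ep.end * rate)), n)
        if i1 - i0 < 2:
            raise ValueError(f"epoch {ep} shorter than 2 samples")
        for (a, b) in pairs:
            xa = series(a)[i0:i1]
            xb = series(b)[i0:i1]
            flagged = xa.std() == 0 or xb.std() == 0
            r = 0.0 if flagged else float(np.corrcoef(xa, xb)[0, 1])
            records.append({"repetition": ep.repetition, "phase": ep.phase,
                            "pair": f"{a}-{b}", "r": np.clip(r, -1, 1),
                            "flagged": flagged})
    return CorrTable(rows=pd.DataFrame.from_records(
        records, columns=["repetition", "phase", "pair", "r", "flagged"]))


def one_way_anova(groups: list[np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """Classic one-way ANOVA: F = between-group MS / within-group MS.

    With all values identical the ratio is defined as F = 0, p = 1; with
    zero within-group variance but distinct means, F = inf, p = 0.
    """
    groups = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    fcrit = f_critical(alpha, df_b, df_w)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, df_b, df_w, fcrit, alpha)
        return AnovaResult(np.inf, 0.0, df_b, df_w, fcrit, alpha)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w, fcrit, alpha)


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-``alpha`` quantile of the F(df1, df2) distribution.

    f_critical(0.05, 1, 6) = 5.987, the threshold used with two groups of
    four repetitions each.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def compare_pre_spike(table: CorrTable, alpha: float = 0.05,
                      bonferroni: bool = False) -> pd.DataFrame:
    """Per band pair: mean r in pre vs spike, delta, and phase ANOVA.

    Returns a DataFrame with columns pair, mean_r_pre, mean_r_spike, delta
    (spike − pre), f_value, p_value, f_critical, significant.  Raises if a
    phase is missing.  ``bonferroni`` divides alpha by the number of pairs.
    """
    rows = table.valid()
    phases = set(rows["phase"])
    if not {"pre", "spike"} <= phases:
        raise ValueError(f"both phases required, table has {sorted(phases)}")
    pairs = rows["pair"].unique()
    eff_alpha = alpha / len(pairs) if bonferroni else alpha
    out = []
    for pair in pairs:
        sub = rows[rows["pair"] == pair]
        pre = sub[sub["phase"] == "pre"]["r"].to_numpy()
        spike = sub[sub["phase"] == "spike"]["r"].to_numpy()
        res = one_way_anova([pre, spike], alpha=eff_alpha)
        out.append({"pair": pair,
                    "mean_r_pre": pre.mean(), "mean_r_spike": spike.mean(),
                    "delta": spike.mean() - pre.mean(),
                    "f_value": res.f_value, "p_value": res.p_value,
                    "f_critical": res.f_critical,
                    "significant": res.significant})
    return pd.DataFrame(out)
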
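"""Cross-validation protocol and model comparison.

The study protocol holds out 10% of the samples (six of sixty) per
iteration and runs ten iterations so every sample is validated at least
once.  Folds are stratified (two samples per class per fold at n = 60);
when a class is one sample short of exact coverage, its first sample (in
shuffled order) is reused in the first and last iteration, and the reuse
is recorded in the plan.  The whole cross-validation is repeated (three
times by default) with reshuffling, and both the best repetition — the
study's headline convention — and the mean ± SD are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augment import AugmentationPolicy
from .features import WindowSpec, phoneme_feature_stack
from .models import (
    EmbeddingNetSpec,
    LSTMSpec,
    TrainConfig,
    select_references,
    train_few_shot,
    train_lstm,
)
from .preprocess import Recording

__all__ = [
    "CVPlan",
    "CVReport",
    "FewShotTrainer",
    "LSTMTrainer",
    "build_dataset",
    "make_cv_plan",
    "run_cv",
    "cross_validate",
    "compare_models",
    "subject_holdout_split",
    "fast_trainer",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(recordings: list[Recording],
                  window: WindowSpec | None = None,
                  n_points: int | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature stacks for a list of labeled recordings.

    Returns ``(x, y, ids)`` with ``x`` of shape (n_samples, 8, n_points).
    """
    samples = [phoneme_feature_stack(r, window) for r in recordings]
    mats = [s.to_matrix(n_points) for s in samples]
    x = np.stack(mats)
    y = np.array([s.label for s in samples])
    ids = np.array([s.sample_id or str(i) for i, s in enumerate(samples)])
    return x, y, ids


# ---------------------------------------------------------------------------
# cross-validation plan
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    n_samples: int
    fraction: float
    iterations: int
    folds: list  # list of np.ndarray of validation indices
    reused: list  # list of (index, [fold numbers]) for reused samples
    seed: int

    def validate_coverage(self) -> None:
        covered = set()
        for f in self.folds:
            covered.update(int(i) for i in f)
        if covered != set(range(self.n_samples)):
            missing = set(range(self.n_samples)) - covered
            raise AssertionError(f"plan does not cover indices {sorted(missing)}")


def make_cv_plan(n: int, fraction: float = 0.10, iterations: int = 10,
                 labels=None, seed: int = 0) -> CVPlan:
    """Build the validation folds for the 10%/10-iteration protocol.

    ``labels`` (optional) enables stratified folds: each fold draws a
    proportional quota from every class.  Classes cycle through a shuffled
    order; a class exactly one sample short of ``quota x iterations`` has
    its first shuffled sample reused in the first and last fold, mirroring
    the documented sample-reuse rule, and every reuse is recorded.
    """
    fold_size = int(round(fraction * n))
    if fold_size < 1:
        raise ValueError(f"fraction {fraction} of n={n} gives an empty fold")
    if fold_size * iterations < n:
        raise ValueError(
            f"{iterations} folds of {fold_size} cannot cover {n} samples")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if labels is None:
        groups = {None: rng.permutation(n)}
    else:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError("labels length must equal n")
        groups = {c: rng.permutation(np.flatnonzero(labels == c))
                  for c in sorted(set(labels))}

    # proportional per-fold quota per class (largest-remainder rounding)
    sizes = {c: len(v) for c, v in groups.items()}
    raw = {c: fold_size * sizes[c] / n for c in groups}
    quota = {c: int(np.floor(raw[c])) for c in groups}
    short = fold_size - sum(quota.values())
    for c in sorted(groups, key=lambda c: raw[c] - np.floor(raw[c]),
                    reverse=True)[:short]:
        quota[c] += 1
    for c, q in quota.items():
        if q * iterations < sizes[c]:
            raise ValueError(
                f"class {c!r}: {iterations} folds x quota {q} cannot cover "
                f"{sizes[c]} samples")

    folds: list[list[int]] = [[] for _ in range(iterations)]
    reuse_record: dict[int, list[int]] = {}
    for c, order in groups.items():
        pos = 0
        m = len(order)
        for fold_i in range(iterations):
            for _ in range(quota[c]):
                idx = int(order[pos % m])
                if pos >= m:
                    reuse_record.setdefault(idx, []).append(fold_i)
                folds[fold_i].append(idx)
                pos += 1
    reused = []
    for idx in reuse_record:
        first_folds = [fi for fi, f in enumerate(folds) if idx in f]
        reused.append((idx, sorted(set(first_folds))))
    plan = CVPlan(n_samples=n, fraction=fraction, iterations=iterations,
                  folds=[np.array(sorted(f), dtype=np.intp) for f in folds],
                  reused=reused, seed=seed)
    plan.validate_coverage()
    return plan


# ---------------------------------------------------------------------------
# trainers
# ---------------------------------------------------------------------------

@dataclass
class FewShotTrainer:
    """Builds and trains a fresh few-shot classifier for one fold."""

    spec: EmbeddingNetSpec = field(default_factory=EmbeddingNetSpec)
    config: TrainConfig = field(default_factory=TrainConfig)
    k: int = 3
    n_ref_trials: int = 4
    ref_short_epochs: int = 50
    policy: AugmentationPolicy | None = None
    tag: str = "fewshot"

    def fit(self, x_tr, y_tr, x_val, y_val, seed: int):
        refs = select_references(
            x_tr, y_tr, k=self.k, n_trials=self.n_ref_trials,
            config=self.config, spec=self.spec, seed=seed,
            short_epochs=self.ref_short_epochs)
        cfg = replace(self.config, seed=seed)
        clf, _ = train_few_shot(x_tr, y_tr, refs, cfg, x_val, y_val,
                                spec=self.spec, policy=self.policy)
        return clf


@dataclass
class LSTMTrainer:
    """Builds and trains a fresh LSTM baseline for one fold."""

    spec: LSTMSpec = field(default_factory=LSTMSpec)
    config: TrainConfig = field(default_factory=TrainConfig)
    policy: AugmentationPolicy | None = None
    tag: str = "lstm"

    def fit(self, x_tr, y_tr, x_val, y_val, seed: int):
        cfg = replace(self.config, seed=seed)
        clf, _ = train_lstm(x_tr, y_tr, cfg, x_val, y_val, spec=self.spec,
                            policy=self.policy)
        return clf


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Aggregated cross-validation result for one model."""

    model_tag: str
    class_order: tuple[str, ...]
    fold_accuracies: list
    confusion: np.ndarray  # rows = true class, cols = predicted
    misclassified_ids: list
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def pooled_accuracy(self) -> float:
        total = self.confusion.sum()
        return float(np.trace(self.confusion) / total) if total else 0.0

    def as_dict(self) -> dict:
        return {
            "model": self.model_tag,
            "pooled_accuracy": self.pooled_accuracy,
            "fold_accuracies": list(map(float, self.fold_accuracies)),
            "confusion": self.confusion.tolist(),
            "classes": list(self.class_order),
            "misclassified_ids": list(self.misclassified_ids),
            "seed": self.seed,
            **self.meta,
        }


def run_cv(x: np.ndarray, y, ids, trainer, plan: CVPlan,
           seed: int = 0) -> CVReport:
    """One pass of the cross-validation protocol.

    Per fold: the validation indices come from the plan, everything else is
    training; a fresh model is trained (augmentation, if the trainer has a
    policy, touches training samples only) and scored on the held-out fold.
    """
    y = np.asarray(y)
    ids = np.asarray(ids)
    if plan.n_samples != len(x):
        raise ValueError(f"plan is for n={plan.n_samples}, dataset has {len(x)}")
    order = tuple(sorted(set(y)))
    lut = {c: i for i, c in enumerate(order)}
    confusion = np.zeros((len(order), len(order)), dtype=np.intp)
    fold_accs = []
    missed: list[str] = []
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
                  for s in np.random.SeedSequence(seed).spawn(len(plan.folds))]
    for fold_i, val_idx in enumerate(plan.folds):
        mask = np.zeros(len(x), dtype=bool)
        mask[val_idx] = True
        x_tr, y_tr = x[~mask], y[~mask]
        x_val, y_val = x[val_idx], y[val_idx]
        model = trainer.fit(x_tr, y_tr, x_val, y_val, seed=fold_seeds[fold_i])
        pred, _ = model.predict(x_val)
        correct = pred == y_val
        fold_accs.append(float(correct.mean()))
        for yi, pi, ok, sid in zip(y_val, pred, correct, ids[val_idx]):
            confusion[lut[yi], lut[pi]] += 1
            if not ok:
                missed.append(str(sid))
        logger.info("fold %d/%d: accuracy %.3f", fold_i + 1,
                    len(plan.folds), fold_accs[-1])
    return CVReport(model_tag=getattr(trainer, "tag", "model"),
                    class_order=order, fold_accuracies=fold_accs,
                    confusion=confusion, misclassified_ids=missed, seed=seed)


def cross_validate(x: np.ndarray, y, ids, trainer,
                   fraction: float = 0.10, iterations: int = 10,
                   repetitions: int = 3, seed: int = 0,
                   ) -> tuple[CVReport, list[CVReport]]:
    """Repeat the whole CV with reshuffled folds; return (best, all).

    The best repetition by pooled accuracy matches the headline convention;
    the full list supports mean ± SD reporting.
    """
    rep_seeds = np.random.SeedSequence(seed).spawn(repetitions)
    reports = []
    for r in range(repetitions):
        s = int(rep_seeds[r].generate_state(1)[0] % (2 ** 31 - 1))
        plan = make_cv_plan(len(x), fraction, iterations, labels=y, seed=s)
        rep = run_cv(x, y, ids, trainer, plan, seed=s)
        rep.meta["repetition"] = r
        reports.append(rep)
        logger.info("repetition %d/%d: pooled accuracy %.3f", r + 1,
                    repetitions, rep.pooled_accuracy)
    best = max(reports, key=lambda r: r.pooled_accuracy)
    accs = [r.pooled_accuracy for r in reports]
    best.meta.update(mean_accuracy=float(np.mean(accs)),
                     sd_accuracy=float(np.std(accs)))
    return best, reports


def subject_holdout_split(subjects) -> dict:
    """Index splits for leave-one-subject-out evaluation.

    The standard protocol pools subjects; this split is provided for
    exploratory use.  Returns {held-out subject: (train_idx, test_idx)}.
    """
    subjects = np.asarray(subjects)
    out = {}
    for s in sorted(set(subjects)):
        test = np.flatnonzero(subjects == s)
        train = np.flatnonzero(subjects != s)
        if len(train) == 0:
            raise ValueError("need at least two subjects for a holdout split")
        out[s] = (train, test)
    return out


# ---------------------------------------------------------------------------
# fast (desk-scale) profile
# ---------------------------------------------------------------------------
#
# A compressed configuration for running the full model comparison on one
# CPU in minutes: smaller network widths, shorter input stacks, and a
# higher learning rate with proportionally fewer epochs than the full-size
# defaults (lr 1e-4 / patience 250).  Used by the reproduction script and
# the heavier tests; see docs/methods.md ("Problem sizes").

FAST_N_POINTS = 192
FAST_CNN_SPEC = EmbeddingNetSpec(adaptive_pool_out=64,
                                 channels=(8, 16, 16, 32, 32, 32))
FAST_LSTM_SPEC = LSTMSpec(hidden_size=64, seq_len=32)
FAST_CNN_SCHEDULE = dict(learning_rate=1e-3, batch_size=16, patience=40,
                         max_epochs=150)
FAST_LSTM_SCHEDULE = dict(learning_rate=1e-3, batch_size=16, patience=30,
                          max_epochs=100)
FAST_REF_SHORT_EPOCHS = 10


def fast_trainer(model: str, seed: int = 0):
    """A trainer under the fast profile: 'lstm', 'fewshot' or 'fewshot+aug'."""
    if model == "lstm":
        return LSTMTrainer(spec=FAST_LSTM_SPEC,
                           config=TrainConfig(seed=seed, **FAST_LSTM_SCHEDULE))
    cfg = TrainConfig(seed=seed, **FAST_CNN_SCHEDULE)
    if model == "fewshot":
        return FewShotTrainer(spec=FAST_CNN_SPEC, config=cfg,
                              ref_short_epochs=FAST_REF_SHORT_EPOCHS)
    if model == "fewshot+aug":
        return FewShotTrainer(spec=FAST_CNN_SPEC, config=cfg,
                              ref_short_epochs=FAST_REF_SHORT_EPOCHS,
                              policy=AugmentationPolicy(), tag="fewshot+aug")
    raise ValueError(f"unknown model {model!r}")


def compare_models(reports: list[CVReport]) -> pd.DataFrame:
    """Model-comparison table: one row per report, in the given order."""
    if not reports:
        raise ValueError("at least one report required")
    tags: list[str] = []
    rows = []
    for rep in reports:
        tag = rep.model_tag
        if tag in tags:
            k = sum(t.startswith(tag) for t in tags) + 1
            new_tag = f"{tag}-{k}"
            logger.warning("duplicate model tag %r renamed to %r", tag, new_tag)
            tag = new_tag
        tags.append(tag)
        rows.append({"model": tag,
                     "accuracy": rep.pooled_accuracy,
                     "mean_accuracy": rep.meta.get("mean_accuracy"),
                     "sd_accuracy": rep.meta.get("sd_accuracy")})
    return pd.DataFrame(rows)
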
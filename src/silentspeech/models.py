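"""Phoneme classifiers: few-shot contrastive 1D CNN and LSTM baseline.

The few-shot network maps a multichannel feature stack to a length-64
embedding through nine blocks: six convolutional body blocks (1-D
convolution, tanh, batch normalization, max pooling; the first block ends
in adaptive average pooling to a fixed length so the network is invariant
to input length) and a three-layer fully connected head.  Training pulls
samples toward same-class reference embeddings and pushes them from
other-class references using cosine similarity (contrastive loss):

    L = mean over positive pairs of (1 − cos)
      + mean over negative pairs of max(0, cos − margin),   margin = 0.

Classification compares a query embedding to k reference embeddings per
class (k = 3 shots by default) and takes the class with the highest mean
similarity.  Reference sets are drawn at random ``n_trials`` times (4 by
default), each short-trained, and the draw with the smallest training loss
is kept.

The baseline is a two-layer LSTM: the first layer emits a full sequence,
the second only its last step, followed by a fully connected layer to the
three class logits and a softmax.  Both models train with Adam (learning
rate 1e-4), batch size 16, and early stopping with a patience of 250
epochs; the checkpoint from the epoch with the lowest validation loss is
the returned model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._autograd import Adam, BatchNorm1d, Conv1d, Linear, Module, Parameter, Tensor
from .augment import AugmentationPolicy, augment

__all__ = [
    "EmbeddingNetSpec",
    "LSTMSpec",
    "TrainConfig",
    "ReferenceSet",
    "EmbeddingNet",
    "LSTMNet",
    "TrainHistory",
    "FewShotClassifier",
    "LSTMClassifier",
    "build_embedding_net",
    "cosine_similarity",
    "contrastive_loss",
    "select_references",
    "train_few_shot",
    "predict",
    "train_lstm",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# specs and configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddingNetSpec:
    """Architecture of the nine-block embedding network.

    Six body blocks (conv/tanh/batch-norm/max-pool; block 1 additionally
    adaptive-pools to ``adaptive_pool_out`` so any input length maps to the
    same tensor size) and three fully connected head blocks ending in a
    ``feature_dim``-long embedding.
    """

    in_channels: int = 8
    n_body_blocks: int = 6
    n_head_blocks: int = 3
    adaptive_pool_out: int = 1024
    feature_dim: int = 64
    kernels: tuple[int, ...] = (7, 7, 5, 5, 3, 3)
    channels: tuple[int, ...] = (8, 16, 32, 64, 64, 64)
    head_hidden: tuple[int, ...] = (256, 128)
    pool: int = 2
    min_input_length: int = 32

    def __post_init__(self):
        if self.n_body_blocks + self.n_head_blocks != 9:
            raise ValueError("the embedding network must have exactly 9 blocks "
                             f"(got {self.n_body_blocks} body + "
                             f"{self.n_head_blocks} head)")
        if len(self.kernels) != self.n_body_blocks \
                or len(self.channels) != self.n_body_blocks:
            raise ValueError("kernels/channels must list one entry per body block")
        if len(self.head_hidden) != self.n_head_blocks - 1:
            raise ValueError("head_hidden must list n_head_blocks - 1 widths")
        if self.adaptive_pool_out % self.pool ** (self.n_body_blocks - 1):
            raise ValueError("adaptive_pool_out must be divisible by "
                             "pool**(n_body_blocks-1)")

    @property
    def flat_dim(self) -> int:
        # length after block 1 is adaptive_pool_out; each later block pools
        length = self.adaptive_pool_out // self.pool ** (self.n_body_blocks - 1)
        return self.channels[-1] * length


@dataclass(frozen=True)
class LSTMSpec:
    """Two-layer LSTM: sequence layer, last-step layer, FC to class logits."""

    n_layers: int = 2
    hidden_size: int = 64
    n_classes: int = 3
    seq_len: int = 64  # input stacks are resampled to this many time steps

    def __post_init__(self):
        if self.n_layers != 2:
            raise ValueError("the baseline is defined as a two-layer LSTM")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by both models.

    Defaults are the study settings: Adam, learning rate 1e-4, batch size
    16, patience 250 epochs (training halts after that many epochs without
    a new best validation loss; the best-epoch checkpoint is restored).
    """

    learning_rate: float = 1e-4
    batch_size: int = 16
    patience: int = 250
    max_epochs: int = 5000
    margin: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class ReferenceSet:
    """k reference samples per class for the few-shot comparison."""

    k: int
    class_order: tuple[str, ...]
    indices: dict  # class -> list of dataset indices (bookkeeping)
    arrays: dict  # class -> ndarray (k, C, L)
    selection_seed: int = 0
    n_trials: int = 4

    def __post_init__(self):
        for c in self.class_order:
            if len(self.arrays[c]) != self.k:
                raise ValueError(f"class {c!r} must have exactly k={self.k} "
                                 "references")

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All references as one array plus their class indices."""
        arrs = [self.arrays[c] for c in self.class_order]
        labels = np.concatenate([
            np.full(len(a), i) for i, a in enumerate(arrs)])
        return np.concatenate(arrs, axis=0), labels

    def all_indices(self) -> set[int]:
        return {i for c in self.class_order for i in self.indices.get(c, [])}


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    stopped_epoch: int = 0

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch - 1]


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class EmbeddingNet(Module):
    """The nine-block 1-D convolutional embedding network."""

    def __init__(self, spec: EmbeddingNetSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.convs: list[Conv1d] = []
        self.norms: list[BatchNorm1d] = []
        c_prev = spec.in_channels
        for k, c in zip(spec.kernels, spec.channels):
            self.convs.append(Conv1d(c_prev, c, k, rng, padding="same"))
            self.norms.append(BatchNorm1d(c))
            c_prev = c
        widths = (spec.flat_dim,) + spec.head_hidden + (spec.feature_dim,)
        self.head: list[Linear] = [Linear(a, b, rng)
                                   for a, b in zip(widths, widths[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        """Map (N, C, L) inputs to (N, feature_dim) embeddings."""
        if x.shape[-1] < self.spec.min_input_length:
            raise ValueError(
                f"input length {x.shape[-1]} below the network minimum "
                f"{self.spec.min_input_length}")
        h = x
        for i, (conv, bn) in enumerate(zip(self.convs, self.norms)):
            h = bn(conv(h).tanh())
            h = h.maxpool1d(self.spec.pool)
            if i == 0:
                h = h.adaptive_avg_pool1d(self.spec.adaptive_pool_out)
        h = h.reshape(h.shape[0], -1)
        for j, lin in enumerate(self.head):
            h = lin(h)
            if j < len(self.head) - 1:
                h = h.tanh()
        return h

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode embeddings for a (N, C, L) or (C, L) array."""
        arr = np.asarray(x, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        was_training = self.training
        self.eval()
        out = self(Tensor(arr)).data
        self.train(was_training)
        return out


def build_embedding_net(spec: EmbeddingNetSpec | None = None,
                        seed: int = 0) -> EmbeddingNet:
    """Construct the embedding network with seeded parameter initialization."""
    spec = spec or EmbeddingNetSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return EmbeddingNet(spec, rng)


class _LSTMLayer(Module):
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(1.0 / n_hidden)
        self.w = Parameter(rng.uniform(-bound, bound, (n_in, 4 * n_hidden)))
        self.u = Parameter(rng.uniform(-bound, bound, (n_hidden, 4 * n_hidden)))
        self.b = Parameter(np.zeros(4 * n_hidden))
        self.n_hidden = n_hidden

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        """Run over a list of (N, F) step tensors; returns hidden states."""
        n = xs[0].shape[0]
        hsz = self.n_hidden
        h = Tensor(np.zeros((n, hsz)))
        c = Tensor(np.zeros((n, hsz)))
        out = []
        for x_t in xs:
            z = x_t @ self.w + h @ self.u + self.b
            i = z[:, 0 * hsz:1 * hsz].sigmoid()
            f = z[:, 1 * hsz:2 * hsz].sigmoid()
            g = z[:, 2 * hsz:3 * hsz].tanh()
            o = z[:, 3 * hsz:4 * hsz].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out.append(h)
        return out


class LSTMNet(Module):
    """Two-layer LSTM classifier head for the feature stacks."""

    def __init__(self, spec: LSTMSpec, in_features: int,
                 rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.layer1 = _LSTMLayer(in_features, spec.hidden_size, rng)
        self.layer2 = _LSTMLayer(spec.hidden_size, spec.hidden_size, rng)
        self.fc = Linear(spec.hidden_size, spec.n_classes, rng)

    def __call__(self, x: np.ndarray | Tensor) -> Tensor:
        """(N, C, L) feature stacks -> (N, n_classes) logits.

        The stack is resampled to ``spec.seq_len`` time steps; channels are
        the per-step features.  Layer 1 returns its full sequence, layer 2
        only the last step, and the fully connected layer maps that state
        to one logit per class.
        """
        arr = x.data if isinstance(x, Tensor) else np.asarray(x, np.float64)
        seq = _resample_steps(arr, self.spec.seq_len)  # (T, N, C)
        xs = [Tensor(seq[t]) for t in range(seq.shape[0])]
        hs = self.layer1(xs)
        last = self.layer2(hs)[-1]
        return self.fc(last)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        logits = self(np.atleast_3d(x)).data
        self.train(was_training)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def _resample_steps(arr: np.ndarray, seq_len: int) -> np.ndarray:
    """(N, C, L) -> (T, N, C) by linear resampling along time."""
    n, c, l = arr.shape
    if l == seq_len:
        seq = arr
    else:
        t_out = np.linspace(0.0, 1.0, seq_len)
        t_in = np.linspace(0.0, 1.0, l)
        seq = np.empty((n, c, seq_len))
        for i in range(n):
            for j in range(c):
                seq[i, j] = np.interp(t_out, t_in, arr[i, j])
    return np.ascontiguousarray(seq.transpose(2, 0, 1))


# ---------------------------------------------------------------------------
# similarity and loss
# ---------------------------------------------------------------------------

def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [−1, 1]."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _cosine_matrix(a: Tensor, b: Tensor, eps: float = 1e-12) -> Tensor:
    """Pairwise cosine similarities between rows of a (N,D) and b (M,D)."""
    an = a / (((a * a).sum(axis=1, keepdims=True)) + eps).sqrt()
    bn = b / (((b * b).sum(axis=1, keepdims=True)) + eps).sqrt()
    return an @ bn.swapaxes(0, 1)


def contrastive_loss(similarities: Tensor | np.ndarray,
                     match: np.ndarray, margin: float = 0.0) -> Tensor:
    """Cosine-similarity contrastive loss.

    ``similarities`` is the (query x reference) similarity matrix and
    ``match`` the boolean matrix of label agreement.  Positive pairs
    contribute ``1 − s`` (pulled toward similarity 1), negative pairs
    ``max(0, s − margin)`` (pushed below the margin); each term is averaged
    over its pairs.  The minimum 0 is attained when all positives sit at
    similarity 1 and all negatives at or below the margin.
    """
    sims = similarities if isinstance(similarities, Tensor) \
        else Tensor(np.asarray(similarities, dtype=np.float64))
    match = np.asarray(match, dtype=bool)
    if sims.data.size == 0:
        raise ValueError("contrastive loss needs at least one pair")
    if match.shape != sims.data.shape:
        raise ValueError("match matrix must have the similarity matrix shape")
    pos_idx = np.nonzero(match)
    neg_idx = np.nonzero(~match)
    terms = []
    if pos_idx[0].size:
        terms.append((1.0 - sims[pos_idx]).mean())
    else:
        logger.warning("contrastive loss batch has no positive pairs; "
                       "positive term skipped")
    if neg_idx[0].size:
        terms.append((sims[neg_idx] - margin).relu_floor(0.0).mean())
    else:
        logger.warning("contrastive loss batch has no negative pairs; "
                       "negative term skipped")
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _class_order(y) -> tuple[str, ...]:
    return tuple(sorted(set(y)))


def _encode(y, order: tuple[str, ...]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(order)}
    return np.array([lut[v] for v in y], dtype=np.intp)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield idx[i:i + batch_size]


def _augment_batch(xb: np.ndarray, policy: AugmentationPolicy | None,
                   rng: np.random.Generator) -> np.ndarray:
    if policy is None or not policy.enabled:
        return xb
    return np.stack([augment(x, policy, rng) for x in xb])


class _EarlyStopper:
    """Patience-based stopping on validation loss with best-state restore."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.best_state: list[np.ndarray] | None = None
        self.streak = 0

    def update(self, epoch: int, val_loss: float, model: Module) -> bool:
        """Record epoch; return True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.best_state = model.state_arrays()
            self.streak = 0
            return False
        self.streak += 1
        return self.streak >= self.patience

    def restore(self, model: Module) -> None:
        if self.best_state is not None:
            model.load_state_arrays(self.best_state)


def _fewshot_epoch_loss(net: EmbeddingNet, x: np.ndarray, y_enc: np.ndarray,
                        ref_x: np.ndarray, ref_y: np.ndarray,
                        margin: float) -> float:
    """Eval-mode contrastive loss of a sample set against the references."""
    was_training = net.training
    net.eval()
    emb = net(Tensor(np.concatenate([x, ref_x], axis=0)))
    q, r = emb[:len(x)], emb[len(x):]
    sims = _cosine_matrix(q, r)
    match = y_enc[:, None] == ref_y[None, :]
    loss = float(contrastive_loss(sims, match, margin).data)
    net.train(was_training)
    return loss


def train_few_shot(x: np.ndarray, y, refs: ReferenceSet, config: TrainConfig,
                   x_val: np.ndarray, y_val,
                   spec: EmbeddingNetSpec | None = None,
                   policy: AugmentationPolicy | None = None,
                   net: EmbeddingNet | None = None,
                   ) -> tuple["FewShotClassifier", TrainHistory]:
    """Train the few-shot embedding network with contrastive loss.

    ``x``/``y`` are the training stacks and labels; reference samples are
    excluded from the query set so no sample forms a positive pair with
    itself.  ``x_val``/``y_val`` must be disjoint from training and drive
    early stopping; the returned classifier carries the checkpoint from the
    epoch with the lowest validation loss.
    """
    if len(x) == 0 or len(x_val) == 0:
        raise ValueError("training and validation splits must be non-empty")
    order = refs.class_order
    y_enc = _encode(y, order)
    yv_enc = _encode(y_val, order)
    ref_x, ref_y = refs.stacked()

    ss = np.random.SeedSequence(config.seed)
    init_ss, loop_ss = ss.spawn(2)
    if net is None:
        net = EmbeddingNet(spec or EmbeddingNetSpec(),
                           np.random.default_rng(init_ss))
    rng = np.random.default_rng(loop_ss)

    # queries: training samples that are not references
    keep = np.array([i not in refs.all_indices() for i in range(len(x))])
    xq, yq = x[keep], y_enc[keep]
    if len(xq) == 0:
        raise ValueError("no query samples remain after removing references")

    opt = Adam(net.parameters(), lr=config.learning_rate)
    stopper = _EarlyStopper(config.patience)
    hist = TrainHistory()
    n_ref = len(ref_x)
    for epoch in range(1, config.max_epochs + 1):
        net.train()
        losses = []
        for bidx in _batches(len(xq), config.batch_size, rng):
            xb = _augment_batch(xq[bidx], policy, rng)
            emb = net(Tensor(np.concatenate([xb, ref_x], axis=0)))
            q_emb, r_emb = emb[:len(bidx)], emb[len(bidx):]
            sims = _cosine_matrix(q_emb, r_emb)
            match = yq[bidx][:, None] == ref_y[None, :]
            loss = contrastive_loss(sims, match, config.margin)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_loss = _fewshot_epoch_loss(net, x_val, yv_enc, ref_x, ref_y,
                                       config.margin)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(val_loss)
        if stopper.update(epoch, val_loss, net):
            hist.stopped_epoch = epoch
            break
    else:
        hist.stopped_epoch = config.max_epochs
    hist.best_epoch = stopper.best_epoch
    stopper.restore(net)
    return FewShotClassifier(net=net, refs=refs, class_order=order), hist


@dataclass
class FewShotClassifier:
    """A trained embedding network plus its reference set."""

    net: EmbeddingNet
    refs: ReferenceSet
    class_order: tuple[str, ...]
    score_mode: str = "mean"  # or "max"

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels and per-class scores for a (N, C, L) batch.

        The score for a class is the mean (or max) cosine similarity of the
        query embedding to that class's reference embeddings; ties break to
        the lowest class index.
        """
        arr = np.asarray(x, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        ref_x, ref_y = self.refs.stacked()
        emb = self.net.embed(np.concatenate([arr, ref_x], axis=0))
        q, r = emb[:len(arr)], emb[len(arr):]
        qn = q / np.maximum(np.linalg.norm(q, axis=1, keepdims=True), 1e-12)
        rn = r / np.maximum(np.linalg.norm(r, axis=1, keepdims=True), 1e-12)
        sims = qn @ rn.T  # (N, n_refs)
        scores = np.empty((len(arr), len(self.class_order)))
        for ci in range(len(self.class_order)):
            block = sims[:, ref_y == ci]
            scores[:, ci] = block.max(axis=1) if self.score_mode == "max" \
                else block.mean(axis=1)
        pred_idx = scores.argmax(axis=1)  # argmax ties -> lowest index
        labels = np.array([self.class_order[i] for i in pred_idx])
        return labels, scores


def predict(model: FewShotClassifier, refs: ReferenceSet,
            sample: np.ndarray) -> tuple[str, np.ndarray]:
    """Classify one sample against a reference set."""
    clf = replace(model, refs=refs)
    labels, scores = clf.predict(sample)
    return str(labels[0]), scores[0]


def select_references(x: np.ndarray, y, k: int = 3, n_trials: int = 4,
                      config: TrainConfig | None = None,
                      spec: EmbeddingNetSpec | None = None,
                      seed: int = 0, short_epochs: int = 50,
                      ) -> ReferenceSet:
    """Pick the reference set: best of ``n_trials`` random draws.

    Each trial draws k references per class, short-trains a fresh network
    for ``short_epochs`` epochs, and the draw with the smallest final
    training loss wins.  Fully reproducible given ``seed``.
    """
    config = config or TrainConfig()
    order = _class_order(y)
    y_arr = np.asarray(y)
    per_class = {c: np.flatnonzero(y_arr == c) for c in order}
    for c, idxs in per_class.items():
        if len(idxs) < k:
            raise ValueError(f"class {c!r} has only {len(idxs)} samples; "
                             f"k={k} references requested")
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.spawn(n_trials)
    best_loss = np.inf
    best_refs: ReferenceSet | None = None
    for t in range(n_trials):
        rng = np.random.default_rng(trial_seeds[t])
        indices = {c: sorted(rng.choice(per_class[c], size=k, replace=False))
                   for c in order}
        refs = ReferenceSet(
            k=k, class_order=order,
            indices={c: list(map(int, v)) for c, v in indices.items()},
            arrays={c: x[list(v)].copy() for c, v in indices.items()},
            selection_seed=seed, n_trials=n_trials)
        short_cfg = replace(config, max_epochs=short_epochs,
                            patience=max(short_epochs, 1),
                            seed=int(rng.integers(0, 2 ** 31 - 1)))
        _, hist = train_few_shot(x, y, refs, short_cfg, x, y, spec=spec)
        final_loss = hist.train_loss[-1]
        logger.debug("reference trial %d: final training loss %.4f",
                     t, final_loss)
        if final_loss < best_loss:
            best_loss = final_loss
            best_refs = refs
    assert best_refs is not None
    return best_refs


# ---------------------------------------------------------------------------
# LSTM baseline
# ---------------------------------------------------------------------------

def _cross_entropy(logits: Tensor, y_enc: np.ndarray) -> Tensor:
    """Softmax cross-entropy via the log-sum-exp trick."""
    m = Tensor(logits.data.max(axis=1, keepdims=True))
    lse = ((logits - m).exp().sum(axis=1, keepdims=True)).log() + m
    picked = logits[np.arange(len(y_enc)), y_enc]
    return (lse.reshape(-1) - picked).mean()


@dataclass
class LSTMClassifier:
    net: LSTMNet
    class_order: tuple[str, ...]

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels and softmax probabilities for a (N, C, L) batch."""
        arr = np.asarray(x, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        probs = self.net.predict_proba(arr)
        pred_idx = probs.argmax(axis=1)
        labels = np.array([self.class_order[i] for i in pred_idx])
        return labels, probs


def train_lstm(x: np.ndarray, y, config: TrainConfig,
               x_val: np.ndarray, y_val,
               spec: LSTMSpec | None = None,
               policy: AugmentationPolicy | None = None,
               ) -> tuple[LSTMClassifier, TrainHistory]:
    """Train the two-layer LSTM baseline with softmax cross-entropy.

    Same optimizer, batching, early stopping and best-epoch restore rules
    as the few-shot network.
    """
    if len(x) == 0 or len(x_val) == 0:
        raise ValueError("training and validation splits must be non-empty")
    spec = spec or LSTMSpec()
    order = _class_order(np.concatenate([np.asarray(y), np.asarray(y_val)]))
    if len(order) != spec.n_classes:
        spec = replace(spec, n_classes=len(order))
    y_enc = _encode(y, order)
    yv_enc = _encode(y_val, order)

    ss = np.random.SeedSequence(config.seed)
    init_ss, loop_ss = ss.spawn(2)
    net = LSTMNet(spec, in_features=x.shape[1],
                  rng=np.random.default_rng(init_ss))
    rng = np.random.default_rng(loop_ss)

    opt = Adam(net.parameters(), lr=config.learning_rate)
    stopper = _EarlyStopper(config.patience)
    hist = TrainHistory()
    for epoch in range(1, config.max_epochs + 1):
        net.train()
        losses = []
        for bidx in _batches(len(x), config.batch_size, rng):
            xb = _augment_batch(x[bidx], policy, rng)
            logits = net(xb)
            loss = _cross_entropy(logits, y_enc[bidx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        net.eval()
        val_loss = float(_cross_entropy(net(x_val), yv_enc).data)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(val_loss)
        if stopper.update(epoch, val_loss, net):
            hist.stopped_epoch = epoch
            break
    else:
        hist.stopped_epoch = config.max_epochs
    hist.best_epoch = stopper.best_epoch
    stopper.restore(net)
    net.eval()
    return LSTMClassifier(net=net, class_order=order), hist
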
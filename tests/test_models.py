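"""Few-shot network, contrastive loss, reference selection, LSTM baseline."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from silentspeech._autograd import Tensor
from silentspeech.models import (
    EmbeddingNetSpec,
    LSTMSpec,
    ReferenceSet,
    TrainConfig,
    _EarlyStopper,
    build_embedding_net,
    contrastive_loss,
    cosine_similarity,
    predict,
    select_references,
    train_few_shot,
    train_lstm,
)

TINY_SPEC = EmbeddingNetSpec(in_channels=2, adaptive_pool_out=32,
                             channels=(4, 4, 4, 8, 8, 8),
                             head_hidden=(16, 16), min_input_length=16)
FAST = TrainConfig(learning_rate=1e-2, batch_size=8, patience=50,
                   max_epochs=60, seed=0)


def toy_dataset(n_per_class=10, length=64, noise=0.05, seed=0):
    """Three well-separated classes of two-channel traces."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, length)
    protos = {
        "A": np.stack([np.exp(-((t - 0.3) / 0.1) ** 2), 0 * t + 0.2]),
        "B": np.stack([0 * t + 0.2, np.exp(-((t - 0.7) / 0.1) ** 2)]),
        "C": np.stack([np.sin(2 * np.pi * t) * 0.5 + 0.5,
                       np.cos(2 * np.pi * t) * 0.5 + 0.5]),
    }
    xs, ys = [], []
    for label, proto in protos.items():
        for _ in range(n_per_class):
            xs.append(proto + noise * rng.standard_normal(proto.shape))
            ys.append(label)
    return np.stack(xs), np.array(ys)


def make_refs(x, y, k=2):
    order = tuple(sorted(set(y)))
    idx = {c: list(np.flatnonzero(np.asarray(y) == c)[:k]) for c in order}
    return ReferenceSet(k=k, class_order=order, indices=idx,
                        arrays={c: x[v] for c, v in idx.items()})


class TestEmbeddingNet:
    def test_embedding_length_invariant_to_input_length(self):
        net = build_embedding_net(seed=0)
        for length in (3000, 12000):
            emb = net.embed(np.random.default_rng(1).standard_normal((1, 8, length)))
            assert emb.shape == (1, 64)

    def test_tiny_spec_invariance_across_doubling(self):
        net = build_embedding_net(TINY_SPEC, seed=0)
        for length in (64, 128):
            assert net.embed(np.zeros((2, 2, length))).shape == (2, 64)

    def test_eight_block_spec_rejected(self):
        with pytest.raises(ValueError, match="9 blocks"):
            EmbeddingNetSpec(n_body_blocks=5, kernels=(7, 7, 5, 5, 3),
                             channels=(8, 16, 32, 64, 64))

    def test_seeded_initialization_reproducible(self):
        a = build_embedding_net(TINY_SPEC, seed=9)
        b = build_embedding_net(TINY_SPEC, seed=9)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_input_below_minimum_rejected(self):
        net = build_embedding_net(TINY_SPEC, seed=0)
        with pytest.raises(ValueError, match="minimum"):
            net.embed(np.zeros((1, 2, 8)))


class TestCosineSimilarity:
    def test_identity_and_antipode(self, rng):
        u = rng.standard_normal(16)
        assert cosine_similarity(u, u) == pytest.approx(1.0)
        assert cosine_similarity(u, -u) == pytest.approx(-1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestContrastiveLoss:
    def test_documented_minimum_is_zero(self):
        sims = np.array([[1.0, -0.2], [1.0, 0.0]])
        match = np.array([[True, False], [True, False]])
        assert float(contrastive_loss(sims, match).data) == pytest.approx(0.0)

    def test_hand_toy_value(self):
        # one positive at 0.5, one negative at 0.5, margin 0:
        # (1 - 0.5) + max(0, 0.5) = 1.0
        sims = np.array([[0.5, 0.5]])
        match = np.array([[True, False]])
        assert float(contrastive_loss(sims, match).data) == pytest.approx(1.0)

    def test_loss_decreases_as_positive_similarity_rises(self):
        match = np.array([[True, False]])
        lo = float(contrastive_loss(np.array([[0.3, 0.1]]), match).data)
        hi = float(contrastive_loss(np.array([[0.8, 0.1]]), match).data)
        assert hi < lo

    def test_permutation_invariance_over_samples(self, rng):
        sims = rng.uniform(-1, 1, (6, 4))
        match = rng.random((6, 4)) > 0.5
        match[:, 0] = True
        match[:, 1] = False
        perm = rng.permutation(6)
        a = float(contrastive_loss(sims, match).data)
        b = float(contrastive_loss(sims[perm], match[perm]).data)
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(np.zeros((0, 0)), np.zeros((0, 0), dtype=bool))

    def test_margin_shifts_negative_term(self):
        sims = np.array([[1.0, 0.4]])
        match = np.array([[True, False]])
        assert float(contrastive_loss(sims, match, margin=0.5).data) == 0.0
        assert float(contrastive_loss(sims, match, margin=0.0).data) == \
            pytest.approx(0.4)


class TestReferenceSelection:
    def test_k_references_per_class(self):
        x, y = toy_dataset(n_per_class=5)
        refs = select_references(x, y, k=3, n_trials=2, config=FAST,
                                 spec=TINY_SPEC, seed=0, short_epochs=2)
        for c in refs.class_order:
            assert len(refs.arrays[c]) == 3
            assert len(refs.indices[c]) == 3

    def test_insufficient_class_size_names_class(self):
        x, y = toy_dataset(n_per_class=5)
        with pytest.raises(ValueError, match="'A'"):
            select_references(x, y, k=6, config=FAST, spec=TINY_SPEC)

    def test_same_seed_selects_same_indices(self):
        x, y = toy_dataset(n_per_class=5)
        kw = dict(k=2, n_trials=2, config=FAST, spec=TINY_SPEC,
                  seed=4, short_epochs=2)
        r1 = select_references(x, y, **kw)
        r2 = select_references(x, y, **kw)
        assert r1.indices == r2.indices


class TestEarlyStopping:
    def test_patience_one_stops_at_epoch_two(self):
        class Dummy:
            def state_arrays(self):
                return []

            def load_state_arrays(self, arrs):
                pass

        stopper = _EarlyStopper(patience=1)
        assert stopper.update(1, 1.0, Dummy()) is False
        assert stopper.update(2, 1.2, Dummy()) is True
        assert stopper.best_epoch == 1

    def test_improvement_resets_streak(self):
        class Dummy:
            def state_arrays(self):
                return []

        stopper = _EarlyStopper(patience=2)
        assert not stopper.update(1, 1.0, Dummy())
        assert not stopper.update(2, 1.5, Dummy())
        assert not stopper.update(3, 0.5, Dummy())
        assert not stopper.update(4, 0.6, Dummy())
        assert stopper.update(5, 0.7, Dummy())


class TestFewShotTraining:
    def test_converges_on_separable_toy_data(self):
        hits = 0
        for seed in range(3):
            x, y = toy_dataset(seed=seed)
            refs = make_refs(x, y, k=2)
            cfg = replace(FAST, seed=seed)
            clf, hist = train_few_shot(x, y, refs, cfg, x[:6], y[:6],
                                       spec=TINY_SPEC)
            pred, _ = clf.predict(x)
            if (pred == y).mean() == 1.0:
                hits += 1
        assert hits >= 2

    def test_identical_seeds_identical_histories(self):
        x, y = toy_dataset()
        refs = make_refs(x, y)
        cfg = replace(FAST, max_epochs=4)
        _, h1 = train_few_shot(x, y, refs, cfg, x[:6], y[:6], spec=TINY_SPEC)
        _, h2 = train_few_shot(x, y, refs, cfg, x[:6], y[:6], spec=TINY_SPEC)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_returns_best_epoch_checkpoint(self):
        x, y = toy_dataset()
        refs = make_refs(x, y)
        cfg = replace(FAST, max_epochs=10, patience=3)
        _, hist = train_few_shot(x, y, refs, cfg, x[:6], y[:6], spec=TINY_SPEC)
        assert hist.best_epoch >= 1
        assert hist.best_val_loss == min(hist.val_loss)

    def test_empty_split_rejected(self):
        x, y = toy_dataset()
        refs = make_refs(x, y)
        with pytest.raises(ValueError, match="non-empty"):
            train_few_shot(x, y, refs, FAST, x[:0], y[:0], spec=TINY_SPEC)


class TestPrediction:
    def test_scores_bounded_and_match_brute_force(self, rng):
        x, y = toy_dataset()
        refs = make_refs(x, y, k=2)
        cfg = replace(FAST, max_epochs=3)
        clf, _ = train_few_shot(x, y, refs, cfg, x[:6], y[:6], spec=TINY_SPEC)
        queries = x[rng.choice(len(x), 10, replace=False)]
        labels, scores = clf.predict(queries)
        assert np.all(scores >= -1.0) and np.all(scores <= 1.0)
        ref_x, ref_y = refs.stacked()
        emb_q = clf.net.embed(queries)
        emb_r = clf.net.embed(ref_x)
        for i in range(len(queries)):
            brute = []
            for ci, c in enumerate(refs.class_order):
                sims = [cosine_similarity(emb_q[i], emb_r[j])
                        for j in np.flatnonzero(ref_y == ci)]
                brute.append(np.mean(sims))
            assert np.allclose(scores[i], brute, atol=1e-9)
            assert labels[i] == refs.class_order[int(np.argmax(brute))]

    def test_query_identical_to_sole_reference_wins(self):
        x, y = toy_dataset()
        refs = make_refs(x, y, k=1)
        cfg = replace(FAST, max_epochs=2)
        clf, _ = train_few_shot(x, y, refs, cfg, x[:6], y[:6], spec=TINY_SPEC)
        sample = refs.arrays["B"][0]
        label, scores = predict(clf, refs, sample)
        assert label == "B"
        assert scores[list(refs.class_order).index("B")] == pytest.approx(1.0)


class TestLSTM:
    def test_softmax_outputs_sum_to_one(self):
        x, y = toy_dataset()
        cfg = replace(FAST, max_epochs=2)
        clf, _ = train_lstm(x, y, cfg, x[:6], y[:6],
                            spec=LSTMSpec(hidden_size=8, seq_len=16))
        _, probs = clf.predict(x[:5])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert probs.shape == (5, 3)

    def test_converges_on_separable_toy_data(self):
        hits = 0
        for seed in range(2):
            x, y = toy_dataset(seed=seed)
            cfg = replace(FAST, seed=seed, max_epochs=80)
            clf, _ = train_lstm(x, y, cfg, x[:6], y[:6],
                                spec=LSTMSpec(hidden_size=16, seq_len=16))
            pred, _ = clf.predict(x)
            if (pred == y).mean() >= 0.9:
                hits += 1
        assert hits >= 1

    def test_identical_seeds_identical_histories(self):
        x, y = toy_dataset()
        cfg = replace(FAST, max_epochs=3)
        spec = LSTMSpec(hidden_size=8, seq_len=16)
        _, h1 = train_lstm(x, y, cfg, x[:6], y[:6], spec=spec)
        _, h2 = train_lstm(x, y, cfg, x[:6], y[:6], spec=spec)
        assert h1.train_loss == h2.train_loss

    def test_two_layer_requirement_enforced(self):
        with pytest.raises(ValueError, match="two-layer"):
            LSTMSpec(n_layers=3)
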
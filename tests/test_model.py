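"""The NumPy LSTM classifier: construction, gradients, training, prediction."""

import numpy as np
import pytest

from acepep.datasets import LabeledDataset, PeptideRecord
from acepep.descriptors import EncodedPeptide, encode_many
from acepep.model import (
    LSTMClassifier,
    ModelConfig,
    _pad_batch,
    build_model,
    predict,
    train_classifier,
)

from conftest import tiny_lstm_config


class TestBuild:
    def test_input_width_follows_combination(self):
        net = build_model(ModelConfig(input_features=37))
        assert net.params["W0"].shape == (37, 4 * 128)
        assert net.params["W1"].shape == (128, 4 * 128)
        assert net.params["Wo"].shape == (128, 2)

    def test_one_hot_width_accepted(self):
        assert build_model(ModelConfig(input_features=20)).params["W0"].shape[0] == 20

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_features=0)
        with pytest.raises(ValueError):
            ModelConfig(input_features=5, hidden_size=0)

    def test_dropout_must_match_layer_count(self):
        with pytest.raises(ValueError, match="dropout"):
            ModelConfig(input_features=5, n_lstm_layers=3, dropout=(0.4, 0.4))

    def test_reference_defaults(self):
        cfg = ModelConfig(input_features=37)
        assert cfg.hidden_size == 128
        assert cfg.n_lstm_layers == 3
        assert cfg.dropout == (0.4, 0.4, 0.25)
        assert cfg.output_size == 2


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """Analytical BPTT gradients agree with central differences."""
        cfg = ModelConfig(
            input_features=3, hidden_size=5, n_lstm_layers=2, dropout=(0.0, 0.0), seed=0
        )
        net = LSTMClassifier(cfg)
        encs = [
            EncodedPeptide(rng.standard_normal((L, 3)), np.ones(L, bool), "X" * L)
            for L in (2, 4, 3)
        ]
        y = np.array([0, 1, 1])
        X, M = _pad_batch(encs)

        def loss():
            probs, *_ = net._forward(X, M, np.random.default_rng(0))
            return -np.log(probs[np.arange(3), y]).mean()

        out = net._forward(X, M, np.random.default_rng(0))
        grads = net._backward(X, M, y, *out)
        eps = 1e-6
        for k, P in net.params.items():
            for _ in range(10):
                idx = tuple(rng.integers(0, d) for d in P.shape) if P.ndim else ()
                orig = P[idx]
                P[idx] = orig + eps
                lp = loss()
                P[idx] = orig - eps
                lm = loss()
                P[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[k][idx]) < 1e-4 * max(1.0, abs(num)), k


class TestTraining:
    def test_learns_planted_rule(self, registry, planted_small):
        """A separable planted rule is learned to high training accuracy;
        a mean-pool logistic oracle confirms separability."""
        from sklearn.linear_model import LogisticRegression

        combo = registry.single("Z-scales")
        train = planted_small.subset("train")
        encs = encode_many(train.sequences(), combo, registry)
        pooled = np.stack([e.matrix.mean(axis=0) for e in encs])
        y = train.labels()
        oracle_acc = LogisticRegression(max_iter=500).fit(pooled, y).score(pooled, y)
        assert oracle_acc > 0.85  # the rule is separable for a linear model

        clf = train_classifier(train, combo, registry, tiny_lstm_config(5, seed=1), 1)
        probs = clf.predict_encoded(encs)
        acc = ((probs > 0.5).astype(int) == y).mean()
        assert acc >= 0.85

    def test_same_seed_reproduces_training(self, registry, planted_small):
        combo = registry.single("Z-scales")
        train = planted_small.subset("train")
        cfg = tiny_lstm_config(5, seed=3, max_epochs=8)
        a = train_classifier(train, combo, registry, cfg, 3)
        b = train_classifier(train, combo, registry, cfg, 3)
        assert a.training_log == b.training_log
        s = train.sequences()[:20]
        np.testing.assert_array_equal(
            predict(a, s, registry)[0], predict(b, s, registry)[0]
        )

    def test_single_class_rejected(self, registry):
        ds = LabeledDataset(
            [PeptideRecord(f"p{i}", "PLVKA", "positive") for i in range(10)]
        )
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(ds, registry.single("Z-scales"), registry,
                             tiny_lstm_config(5))

    def test_mismatched_feature_width_rejected(self, registry, planted_small):
        with pytest.raises(ValueError, match="features"):
            train_classifier(planted_small, registry.single("VHSE"), registry,
                             tiny_lstm_config(5))

    def test_can_overfit_random_labels(self, registry, rng):
        """Capacity check: the network memorises random labels on a small set."""
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = list({"".join(rng.choice(alphabet, size=rng.integers(3, 8)))
                     for _ in range(80)})[:64]
        labels = rng.integers(0, 2, size=len(seqs))
        recs = [
            PeptideRecord(f"r{i}", s, "positive" if l else "negative")
            for i, (s, l) in enumerate(zip(seqs, labels))
        ]
        ds = LabeledDataset(recs)
        cfg = tiny_lstm_config(
            5, seed=0, hidden_size=48, max_epochs=250, patience=250,
            dropout=(0.0, 0.0), learning_rate=3e-3, validation_fraction=0.0,
        )
        combo = registry.single("Z-scales")
        clf = train_classifier(ds, combo, registry, cfg, 0)
        encs = encode_many([r.sequence for r in recs], combo, registry)
        acc = ((clf.predict_encoded(encs) > 0.5).astype(int) == ds.labels()).mean()
        assert acc >= 0.9


class TestPrediction:
    def test_probabilities_in_unit_interval_and_deterministic(
        self, registry, planted_small
    ):
        combo = registry.single("Z-scales")
        clf = train_classifier(
            planted_small.subset("train"), combo, registry,
            tiny_lstm_config(5, seed=2, max_epochs=5), 2,
        )
        seqs = planted_small.subset("test").sequences()[:30]
        p1, _ = predict(clf, seqs, registry)
        p2, _ = predict(clf, seqs, registry)
        assert np.all((p1 >= 0) & (p1 <= 1))
        np.testing.assert_array_equal(p1, p2)

    def test_batching_does_not_leak_across_lengths(self, registry, planted_small):
        """Mixed-length batches give the same output as single-peptide calls."""
        combo = registry.single("Z-scales")
        clf = train_classifier(
            planted_small.subset("train"), combo, registry,
            tiny_lstm_config(5, seed=2, max_epochs=5), 2,
        )
        seqs = ["GG", "PLVKAYW", "LAF", "AAAAAAAAAAAA"]
        encs = encode_many(seqs, combo, registry)
        batched = clf.model.predict_proba(encs)
        single = np.array([clf.model.predict_proba([e])[0] for e in encs])
        np.testing.assert_allclose(batched, single, atol=1e-12)

    def test_unencodable_sequences_reported_not_fatal(self, registry, planted_small):
        combo = registry.single("Z-scales")
        clf = train_classifier(
            planted_small.subset("train"), combo, registry,
            tiny_lstm_config(5, seed=2, max_epochs=3), 2,
        )
        probs, errors = predict(clf, ["LAF", "LXF", "GG"], registry)
        assert set(errors) == {1}
        assert np.isnan(probs[1]) and not np.isnan(probs[[0, 2]]).any()

    def test_checkpoint_round_trip(self, registry, planted_small, tmp_path):
        from acepep.model import TrainedClassifier

        combo = registry.single("Z-scales")
        clf = train_classifier(
            planted_small.subset("train"), combo, registry,
            tiny_lstm_config(5, seed=2, max_epochs=3), 2,
        )
        clf.save(tmp_path / "model")
        back = TrainedClassifier.load(tmp_path / "model")
        seqs = planted_small.sequences()[:10]
        np.testing.assert_array_equal(
            predict(clf, seqs, registry)[0], predict(back, seqs, registry)[0]
        )
        assert back.combination.label == "Z-scales"
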
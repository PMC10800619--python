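"""Risk model: configuration contracts, truncation, evaluation metrics
against brute-force oracles, and the feature-ablation harness."""

from datetime import date as Date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrseq import risk
from ehrseq.embed import EmbeddingMatrix
from ehrseq.errors import AlignmentError, ConfigError
from ehrseq.tokens import TokenSequence, Vocabulary


def concordance_auc(scores, labels):
    """Brute-force pairwise concordance (ties count one half)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    num = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return num / (len(pos) * len(neg))


class TestEvaluate:
    def test_perfect_ranking(self):
        scores = {"a": 0.9, "b": 0.8, "c": 0.2, "d": 0.1}
        labels = {"a": 1, "b": 1, "c": 0, "d": 0}
        rep = risk.evaluate(scores, labels, ks=(0.5,))
        assert rep.roc_auc == 1.0
        assert rep.topk[0.5] == (1.0, 1.0)
        assert rep.incidence == 0.5

    def test_auc_matches_concordance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # forces ties
            labels = {f"p{i}": int(y[i]) for i in range(n)}
            scores = {f"p{i}": float(s[i]) for i in range(n)}
            rep = risk.evaluate(scores, labels, ks=())
            assert rep.roc_auc == pytest.approx(concordance_auc(s, y),
                                                abs=1e-12)

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(1)
        n = 10_000
        labels = {f"p{i}": int(i < n // 2) for i in range(n)}
        scores = {f"p{i}": float(rng.random()) for i in range(n)}
        rep = risk.evaluate(scores, labels, ks=())
        assert rep.roc_auc == pytest.approx(0.5, abs=0.02)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=20,
                    max_size=200))
    @settings(derandomize=True, max_examples=60)
    def test_recall_monotone_in_k(self, scores):
        rng = np.random.default_rng(len(scores))
        y = rng.integers(0, 2, size=len(scores))
        if y.sum() in (0, len(y)):
            y[0], y[1] = 0, 1
        labels = {f"p{i:04d}": int(y[i]) for i in range(len(scores))}
        smap = {f"p{i:04d}": scores[i] for i in range(len(scores))}
        rep = risk.evaluate(smap, labels)
        r1 = rep.topk[0.01][1]
        r5 = rep.topk[0.05][1]
        r10 = rep.topk[0.10][1]
        assert r1 <= r5 <= r10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            risk.evaluate({"a": 0.5, "b": 0.2}, {"a": 1, "b": 1})

    def test_missing_scores_rejected(self):
        with pytest.raises(ConfigError):
            risk.evaluate({"a": 0.5}, {"a": 1, "b": 0})


class TestTruncation:
    def test_short_sequence_unchanged(self):
        assert risk.truncate_tokens(["a", "b"], 10) == ["a", "b"]

    def test_keeps_most_recent_plus_demographics(self):
        toks = [f"c{i}" for i in range(5000)] + ["race_other",
                                                 "gender_female"]
        out = risk.truncate_tokens(toks, 3000)
        assert len(out) == 3000
        assert out[-2:] == ["race_other", "gender_female"]
        assert out[0] == "c2002"  # most recent 2998 body tokens kept

    def test_truncation_without_demographics(self):
        toks = [f"c{i}" for i in range(10)]
        assert risk.truncate_tokens(toks, 4) == ["c6", "c7", "c8", "c9"]


def _toy_sequences(n=120, seed=0, sentinel="sick"):
    rng = np.random.default_rng(seed)
    seqs, labels = [], {}
    for i in range(n):
        toks = [f"bg{rng.integers(0, 20)}" for _ in range(12)]
        if i % 2 == 0:
            toks[rng.integers(0, 12)] = sentinel
        seqs.append(TokenSequence(f"p{i:03d}", toks, Date(2018, 1, 1)))
        labels[f"p{i:03d}"] = int(i % 2 == 0)
    return seqs, labels


class TestTrainModel:
    def test_pretrained_mode_requires_embeddings(self):
        seqs, labels = _toy_sequences(20)
        cfg = risk.ModelConfig(embedding_mode="finetuned_pretrained", d=8)
        with pytest.raises(ConfigError):
            risk.train_model(seqs, labels, cfg)

    def test_dimension_mismatch_rejected(self):
        seqs, labels = _toy_sequences(20)
        emb = EmbeddingMatrix(Vocabulary(["sick"]),
                              np.zeros((3, 16), dtype=np.float32), 16, 5, 0)
        cfg = risk.ModelConfig(embedding_mode="frozen_pretrained", d=8)
        with pytest.raises(AlignmentError):
            risk.train_model(seqs, labels, cfg, embeddings=emb)

    def test_disjoint_vocabulary_rejected(self):
        seqs, labels = _toy_sequences(20)
        emb = EmbeddingMatrix(Vocabulary(["zzz"]),
                              np.zeros((3, 8), dtype=np.float32), 8, 5, 0)
        cfg = risk.ModelConfig(embedding_mode="frozen_pretrained", d=8)
        with pytest.raises(AlignmentError):
            risk.train_model(seqs, labels, cfg, embeddings=emb)

    def test_separable_task_and_deterministic_inference(self):
        seqs, labels = _toy_sequences(400)
        cfg = risk.ModelConfig(d=16, gru_hidden=8, epochs=8,
                               learning_rate=2e-3, seed=0)
        model = risk.train_model(seqs, labels, cfg)
        scores = risk.predict_risk(model, seqs)
        rep = risk.evaluate(scores, labels, ks=())
        assert rep.roc_auc >= 0.99
        again = risk.predict_risk(model, seqs)
        assert scores == again

    def test_unknown_embedding_mode(self):
        with pytest.raises(ConfigError):
            risk.ModelConfig(embedding_mode="nope")


class TestAblation:
    @staticmethod
    def _value_signal_corpus(n=160, seed=0):
        """Label depends only on a high observation-value bin; the bare
        observation code is uninformative."""
        rng = np.random.default_rng(seed)
        seqs, labels = [], {}
        code_domains = {"obs1": "observation", "d1": "diagnosis",
                        "m1": "medication"}
        for i in range(n):
            pos = i % 2 == 0
            toks = ["d1", "m1"]
            b = rng.integers(7, 10) if pos else rng.integers(0, 3)
            toks.append(f"obs1_{b}")
            toks.append(f"age_{rng.integers(40, 70)}")
            rng.shuffle(toks)
            seqs.append(TokenSequence(f"p{i:03d}", toks, Date(2018, 1, 1)))
            labels[f"p{i:03d}"] = int(pos)
        return seqs, labels, code_domains

    def test_observation_values_carry_the_planted_signal(self):
        seqs, labels, domains = self._value_signal_corpus()
        cfg = risk.ModelConfig(architecture="simple_maxpool", d=12,
                               epochs=6, seed=0)
        table = risk.run_feature_ablation(
            seqs, labels, domains, mode="individual",
            features=("observation_values", "age"), config=cfg, seed=0)
        assert list(table["scope"]) == ["baseline", "observation_values",
                                        "age"]
        assert table.loc[0, "delta"] == 0.0
        deltas = dict(zip(table["scope"], table["delta"]))
        assert deltas["observation_values"] == max(
            d for s, d in deltas.items() if s != "baseline")
        assert deltas["observation_values"] > 0.2

    def test_cumulative_mode_row_per_feature(self):
        seqs, labels, domains = self._value_signal_corpus(n=60)
        cfg = risk.ModelConfig(architecture="simple_maxpool", d=8,
                               epochs=2, seed=0)
        feats = ("observation_values", "age", "gender")
        table = risk.run_feature_ablation(seqs, labels, domains,
                                          mode="cumulative", features=feats,
                                          config=cfg, seed=0)
        assert list(table["scope"]) == ["baseline", *feats]

    def test_unknown_feature_rejected(self):
        seqs, labels, domains = self._value_signal_corpus(n=20)
        with pytest.raises(ConfigError):
            risk.run_feature_ablation(seqs, labels, domains,
                                      features=("nope",))

    def test_scope_filtering(self):
        domains = {"obs1": "observation", "d1": "diagnosis"}
        toks = ["d1", "obs1_7", "age_50", "race_other"]
        base = risk.filter_scope(toks, risk.BASELINE_SCOPE, domains)
        assert base == ["d1", "obs1"]   # value stripped to bare code
        withv = risk.filter_scope(
            toks, frozenset(risk.BASELINE_SCOPE | {"observation_values"}),
            domains)
        assert withv == ["d1", "obs1_7"]
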
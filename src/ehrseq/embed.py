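"""Skip-gram concept embeddings over patient token timelines.

Pre-training treats each patient's pre-cutoff token timeline as a sentence
and learns one vector per token with the skip-gram objective and negative
sampling (5 negatives drawn from the unigram distribution raised to 3/4,
dynamic window shrinkage as in the original word2vec).  Cosine-similarity
neighbor queries over the result are the standard qualitative check that
related clinical concepts — descendant diagnoses, adjacent ages, adjacent
value bins — land near each other.

Only history up to the label cutoff may enter pre-training; sequences
carrying a later cutoff raise a :class:`LeakageError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import LeakageError, UnknownTokenError
from .nn import scatter_add as _scatter_add
from .tokens import TokenSequence, Vocabulary, build_vocabulary

__all__ = [
    "EmbeddingMatrix",
    "NeighborList",
    "train_skipgram",
    "nearest_neighbors",
    "embedding_report",
    "save_word2vec",
    "load_word2vec",
]


@dataclass
class EmbeddingMatrix:
    vocabulary: Vocabulary
    vectors: np.ndarray          # (|V|, d) float32
    d: int
    window: int
    seed: int

    def vector(self, token: str) -> np.ndarray:
        if token not in self.vocabulary:
            raise UnknownTokenError(token)
        return self.vectors[self.vocabulary.id(token)]

    def aligned_to(self, vocab: Vocabulary, rng=None,
                   init_scale: float = 0.05) -> np.ndarray:
        """Embedding table reindexed to another vocabulary, for initializing
        a downstream model.

        Tokens missing from the trained matrix get small random vectors.
        Trained rows are rescaled so their mean norm matches the
        uniform(-init_scale, init_scale) initialization of the downstream
        layer: skip-gram vector norms are an order of magnitude larger, and
        initializing a recurrent layer at that scale saturates its gates.
        Rescaling preserves all cosine geometry."""
        rng = rng or np.random.default_rng(0)
        out = rng.uniform(-init_scale, init_scale,
                          size=(len(vocab), self.d)).astype(np.float32)
        trained = [t for t in vocab.index if t in self.vocabulary]
        if trained:
            rows = self.vectors[[self.vocabulary.id(t) for t in trained]]
            mean_norm = float(np.linalg.norm(rows, axis=1).mean())
            target = init_scale / np.sqrt(3.0) * np.sqrt(self.d)
            scale = target / mean_norm if mean_norm > 0 else 1.0
            for t, row in zip(trained, rows):
                out[vocab.index[t]] = row * scale
        out[0] = 0.0
        return out


@dataclass
class NeighborList:
    query: str
    neighbors: list[tuple[str, float]]   # similarity non-increasing


def _as_token_lists(sequences, max_cutoff: Date | None):
    out = []
    for s in sequences:
        if isinstance(s, TokenSequence):
            if max_cutoff is not None and s.cutoff_date > max_cutoff:
                raise LeakageError(
                    f"sequence for {s.patient_id} built with cutoff "
                    f"{s.cutoff_date} > pre-training cutoff {max_cutoff}"
                )
            out.append(s.tokens)
        else:
            out.append(list(s))
    return out


def train_skipgram(
    sequences: Iterable[TokenSequence | Sequence[str]],
    d: int = 128,
    window: int = 5,
    epochs: int = 5,
    min_count: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    seed: int = 0,
    max_cutoff: Date | None = None,
    subsample: float = 1e-3,
    batch_pairs: int = 2048,
) -> EmbeddingMatrix:
    """Train skip-gram vectors with negative sampling.

    Tokens below ``min_count`` are dropped from the corpus; very frequent
    tokens are stochastically subsampled (threshold ``subsample``, the
    word2vec convention), which curbs the dominance of near-universal
    tokens and keeps batched updates stable.  The context window is shrunk
    uniformly at random per center position, the learning rate decays
    linearly, and all sampling comes from one seeded generator, so a fixed
    seed reproduces the vectors.
    """
    corpus = _as_token_lists(sequences, max_cutoff)
    vocab = build_vocabulary(corpus, min_count=min_count)
    rng = np.random.default_rng(seed)
    V = len(vocab)
    W = ((rng.random((V, d)) - 0.5) / d).astype(np.float32)
    C = np.zeros((V, d), dtype=np.float32)

    # encode corpus, dropping rare (OOV) tokens; record sequence boundaries
    ids = []
    seq_of = []
    for si, toks in enumerate(corpus):
        enc = vocab.encode(toks)
        enc = enc[enc >= 2]
        ids.append(enc)
        seq_of.append(np.full(len(enc), si, dtype=np.int32))
    flat = np.concatenate(ids) if ids else np.array([], dtype=np.int32)
    seq_of = np.concatenate(seq_of) if seq_of else np.array([], dtype=np.int32)
    n_tok = len(flat)
    if n_tok == 0 or V <= 2:
        return EmbeddingMatrix(vocab, W, d, window, seed)

    # negative-sampling distribution: unigram^0.75 over real tokens
    counts = np.zeros(V)
    for tok, c in vocab.counts.items():
        counts[vocab.id(tok)] = c
    counts[:2] = 0.0
    p_neg = counts ** 0.75
    p_neg /= p_neg.sum()
    cdf = np.cumsum(p_neg)

    # frequent-token subsampling: keep probability per occurrence
    if subsample > 0:
        freq = counts / max(counts.sum(), 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            keep = (np.sqrt(freq / subsample) + 1) * subsample / freq
        keep = np.clip(np.nan_to_num(keep, nan=1.0, posinf=1.0), 0.0, 1.0)
        keep_tok = keep[flat]
        expected_kept = float(keep_tok.sum())
    else:
        keep_tok = None
        expected_kept = float(n_tok)

    total_updates = 0
    planned = epochs * expected_kept * (window + 1)  # lr decay schedule
    flat_full, seq_full = flat, seq_of
    for _epoch in range(epochs):
        if keep_tok is not None:
            mask = rng.random(len(flat_full)) < keep_tok
            flat, seq_of = flat_full[mask], seq_full[mask]
            n_tok = len(flat)
            if n_tok == 0:
                continue
        b = rng.integers(1, window + 1, size=n_tok)
        centers_parts, contexts_parts = [], []
        for off in range(1, window + 1):
            # left contexts at distance `off`
            m = (b >= off)
            m[:off] = False
            valid = m & (seq_of == np.roll(seq_of, off))
            idx = np.flatnonzero(valid)
            centers_parts.append(flat[idx])
            contexts_parts.append(flat[idx - off])
            # right contexts
            m = (b >= off)
            if off > 0:
                m[n_tok - off:] = False
            valid = m & (seq_of == np.roll(seq_of, -off))
            idx = np.flatnonzero(valid)
            centers_parts.append(flat[idx])
            contexts_parts.append(flat[idx + off])
        centers = np.concatenate(centers_parts)
        contexts = np.concatenate(contexts_parts)
        order = rng.permutation(len(centers))
        centers, contexts = centers[order], contexts[order]

        for start in range(0, len(centers), batch_pairs):
            c_b = centers[start:start + batch_pairs]
            o_b = contexts[start:start + batch_pairs]
            B = len(c_b)
            negs = np.searchsorted(
                cdf, rng.random((B, negative))).astype(np.int64)
            lr = max(min_alpha,
                     alpha * (1.0 - total_updates / max(planned, 1)))
            Vc = W[c_b]
            Uo = C[o_b]
            Un = C[negs]
            # logits clipped to +-8 (the word2vec MAX_EXP convention)
            z_pos = np.clip(np.einsum("bd,bd->b", Vc, Uo), -8.0, 8.0)
            z_neg = np.clip(np.einsum("bd,bkd->bk", Vc, Un), -8.0, 8.0)
            g_pos = (1.0 / (1.0 + np.exp(-z_pos)) - 1.0).astype(np.float32)
            g_neg = (1.0 / (1.0 + np.exp(-z_neg))).astype(np.float32)
            dVc = g_pos[:, None] * Uo + np.einsum("bk,bkd->bd", g_neg, Un)
            dUo = g_pos[:, None] * Vc
            dUn = g_neg[:, :, None] * Vc[:, None, :]
            _scatter_add(W, c_b, (-lr * dVc).astype(np.float32))
            out_rows = np.concatenate([o_b, negs.reshape(-1)])
            out_upds = np.concatenate(
                [(-lr * dUo).astype(np.float32),
                 (-lr * dUn.reshape(-1, d)).astype(np.float32)])
            _scatter_add(C, out_rows, out_upds)
            total_updates += B
    if not np.isfinite(W).all():
        raise FloatingPointError("non-finite embedding entries after training")
    return EmbeddingMatrix(vocab, W, d, window, seed)


def cosine_similarity(matrix: EmbeddingMatrix, a: str, b: str) -> float:
    va, vb = matrix.vector(a), matrix.vector(b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(va @ vb / (na * nb))


def nearest_neighbors(matrix: EmbeddingMatrix, token: str,
                      k: int = 8) -> NeighborList:
    """Exact top-k cosine neighbors over the full vocabulary (the query
    itself and the reserved indices excluded)."""
    q = matrix.vector(token)
    vecs = matrix.vectors
    norms = np.linalg.norm(vecs, axis=1)
    qn = np.linalg.norm(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = vecs @ q / np.where(norms * qn > 0, norms * qn, np.inf)
    sims[:2] = -np.inf
    sims[matrix.vocabulary.id(token)] = -np.inf
    k = min(k, (sims > -np.inf).sum())
    top = np.argpartition(-sims, k - 1)[:k] if k else np.array([], dtype=int)
    top = top[np.argsort(-sims[top], kind="stable")]
    return NeighborList(token, [(matrix.vocabulary.tokens[i], float(sims[i]))
                                for i in top])


def embedding_report(matrix: EmbeddingMatrix, probes: Sequence[str],
                     k: int = 8, render=None) -> dict[str, NeighborList]:
    """Neighbor lists for a set of probe tokens (missing probes are skipped
    with a warning); ``render`` optionally maps tokens to display labels."""
    import logging
    out: dict[str, NeighborList] = {}
    for probe in probes:
        if probe not in matrix.vocabulary:
            logging.getLogger(__name__).warning(
                "probe %r not in vocabulary; skipped", probe)
            continue
        nl = nearest_neighbors(matrix, probe, k)
        if render is not None:
            nl = NeighborList(probe, [(render(t), s)
                                      for t, s in nl.neighbors])
        out[probe] = nl
    return out


# ---------------------------------------------------------------------------
# word2vec text format


def save_word2vec(matrix: EmbeddingMatrix, path) -> None:
    """``|V| d`` header then one ``token v1 ... vd`` line per real token."""
    toks = matrix.vocabulary.tokens[2:]
    with open(path, "w") as fh:
        fh.write(f"{len(toks)} {matrix.d}\n")
        for t in toks:
            vec = matrix.vectors[matrix.vocabulary.id(t)]
            fh.write(t + " " + " ".join(f"{x:.8e}" for x in vec) + "\n")


def load_word2vec(path, window: int = 5, seed: int = 0) -> EmbeddingMatrix:
    path = Path(path)
    with open(path) as fh:
        n, d = map(int, fh.readline().split())
        toks, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            toks.append(parts[0])
            rows.append(np.array(parts[1:], dtype=np.float32))
    if len(toks) != n:
        raise ValueError(f"header declares {n} tokens, file has {len(toks)}")
    vocab = Vocabulary(toks)
    vecs = np.zeros((len(vocab), d), dtype=np.float32)
    for t, r in zip(toks, rows):
        vecs[vocab.id(t)] = r
    return EmbeddingMatrix(vocab, vecs, d, window, seed)
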
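"""Minimal numpy neural-network core for token-sequence classifiers.

Implements exactly the two architectures the toolkit needs:

* ``bigru_maxpool`` — embedding, one bidirectional GRU layer, global max
  pooling over the per-position outputs (padding masked out), and a sigmoid
  unit;
* ``simple_maxpool`` — embedding, global max pooling over the embedded
  tokens, and a sigmoid unit (the fast model used for feature-ablation
  screening).

Forward and backward passes are written out explicitly (no autograd).
Gradients are exact; a finite-difference check lives in the test suite.
Training uses Adam with mini-batches bucketed by sequence length and early
stopping on validation loss.  Parameters are float32; inference runs in
float64 so scores are batching-invariant to tight tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["NetParams", "SequenceNet", "TrainSettings"]


def scatter_add(target: np.ndarray, rows: np.ndarray,
                updates: np.ndarray) -> None:
    """``target[rows] += updates`` with duplicate-row accumulation.

    Equivalent to ``np.add.at`` but orders of magnitude faster: sort the
    row indices, segment-sum the updates with ``np.add.reduceat``, then add
    once per unique row."""
    if len(rows) == 0:
        return
    order = np.argsort(rows, kind="stable")
    r = np.asarray(rows)[order]
    u = updates[order]
    starts = np.r_[0, np.flatnonzero(np.diff(r)) + 1]
    sums = np.add.reduceat(u, starts, axis=0)
    target[r[starts]] += sums


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class TrainSettings:
    batch_size: int = 64
    epochs: int = 8
    learning_rate: float = 2e-3
    patience: int = 2
    val_fraction: float = 0.1
    seed: int = 0
    freeze_embedding: bool = False
    select_metric: str = "auc"   # early-stopping metric: "auc" or "loss"
    lr_decay_on_plateau: float = 1.0   # multiply lr per non-improving epoch
    verbose: bool = False


class NetParams(dict):
    """Named parameter arrays with dict access."""


def _init_gru(rng, d, h, scale=None):
    s = scale or (1.0 / np.sqrt(h))
    p = {}
    for gate in ("z", "r", "n"):
        p[f"W{gate}"] = rng.uniform(-s, s, size=(d, h)).astype(np.float32)
        p[f"U{gate}"] = rng.uniform(-s, s, size=(h, h)).astype(np.float32)
        p[f"b{gate}"] = np.zeros(h, dtype=np.float32)
    return p


class SequenceNet:
    """Sigmoid sequence classifier over integer token ids (0 = padding)."""

    def __init__(self, vocab_size: int, d: int = 128, hidden: int = 64,
                 architecture: str = "bigru_maxpool", seed: int = 0,
                 embedding_init: np.ndarray | None = None):
        if architecture not in ("bigru_maxpool", "simple_maxpool"):
            raise ValueError(f"unknown architecture {architecture!r}")
        self.architecture = architecture
        self.d = d
        self.hidden = hidden
        self.vocab_size = vocab_size
        rng = np.random.default_rng(seed)
        p = NetParams()
        if embedding_init is not None:
            if embedding_init.shape != (vocab_size, d):
                raise ValueError("embedding_init shape mismatch")
            p["E"] = embedding_init.astype(np.float32).copy()
        else:
            p["E"] = rng.uniform(-0.05, 0.05,
                                 size=(vocab_size, d)).astype(np.float32)
        if architecture == "bigru_maxpool":
            for dirn in ("f", "b"):
                for k, v in _init_gru(rng, d, hidden).items():
                    p[f"{dirn}_{k}"] = v
            pooled_dim = 2 * hidden
        else:
            pooled_dim = d
        p["w_out"] = rng.uniform(-0.05, 0.05,
                                 size=(pooled_dim,)).astype(np.float32)
        p["b_out"] = np.zeros(1, dtype=np.float32)
        self.params = p

    # -- batching ----------------------------------------------------------

    @staticmethod
    def pad_batch(seqs: Sequence[np.ndarray]):
        B = len(seqs)
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        T = max(1, int(lengths.max()) if B else 1)
        X = np.zeros((B, T), dtype=np.int64)
        for i, s in enumerate(seqs):
            X[i, : len(s)] = s
        return X, lengths

    @staticmethod
    def _reverse_within_length(X, lengths):
        B, T = X.shape
        Xr = np.zeros_like(X)
        for i in range(B):
            L = lengths[i]
            Xr[i, :L] = X[i, :L][::-1]
        return Xr

    # -- forward -----------------------------------------------------------

    def _gru_forward(self, params, prefix, Xe, dtype):
        """Xe: (B,T,d) embedded inputs.  Returns per-step hidden states
        (B,T,h) and a cache for backprop."""
        B, T, d = Xe.shape
        h = self.hidden
        Wz = params[f"{prefix}_Wz"].astype(dtype)
        Wr = params[f"{prefix}_Wr"].astype(dtype)
        Wn = params[f"{prefix}_Wn"].astype(dtype)
        Uz = params[f"{prefix}_Uz"].astype(dtype)
        Ur = params[f"{prefix}_Ur"].astype(dtype)
        Un = params[f"{prefix}_Un"].astype(dtype)
        bz = params[f"{prefix}_bz"].astype(dtype)
        br = params[f"{prefix}_br"].astype(dtype)
        bn = params[f"{prefix}_bn"].astype(dtype)
        # precompute input projections for all steps at once
        Xf = Xe.reshape(B * T, d)
        pz = (Xf @ Wz + bz).reshape(B, T, h)
        pr = (Xf @ Wr + br).reshape(B, T, h)
        pn = (Xf @ Wn + bn).reshape(B, T, h)
        H = np.empty((B, T, h), dtype=dtype)
        Z = np.empty_like(H)
        R = np.empty_like(H)
        Nc = np.empty_like(H)
        hprev = np.zeros((B, h), dtype=dtype)
        for t in range(T):
            z = _sigmoid(pz[:, t] + hprev @ Uz)
            r = _sigmoid(pr[:, t] + hprev @ Ur)
            n = np.tanh(pn[:, t] + (r * hprev) @ Un)
            hprev = (1.0 - z) * n + z * hprev
            H[:, t], Z[:, t], R[:, t], Nc[:, t] = hprev, z, r, n
        cache = (Xe, H, Z, R, Nc, (Wz, Wr, Wn, Uz, Ur, Un))
        return H, cache

    def _gru_backward(self, cache, dH, prefix, dtype):
        Xe, H, Z, R, Nc, (Wz, Wr, Wn, Uz, Ur, Un) = cache
        B, T, d = Xe.shape
        h = self.hidden
        g = {k: 0.0 for k in ("Wz", "Wr", "Wn", "Uz", "Ur", "Un",
                              "bz", "br", "bn")}
        dXe = np.zeros_like(Xe)
        dh = np.zeros((B, h), dtype=dtype)
        dz_all = np.empty((B, T, h), dtype=dtype)
        dr_all = np.empty((B, T, h), dtype=dtype)
        dn_all = np.empty((B, T, h), dtype=dtype)
        for t in range(T - 1, -1, -1):
            hp = H[:, t - 1] if t > 0 else np.zeros((B, h), dtype=dtype)
            z, r, n = Z[:, t], R[:, t], Nc[:, t]
            dh = dh + dH[:, t]
            dn = dh * (1.0 - z) * (1.0 - n * n)
            dz = dh * (hp - n) * z * (1.0 - z)
            dh_prev = dh * z
            drh = dn @ Un.T                    # grad wrt (r * hp)
            dr = drh * hp * r * (1.0 - r)
            dh_prev = dh_prev + drh * r
            dh_prev = dh_prev + dz @ Uz.T + dr @ Ur.T
            g["Uz"] = g["Uz"] + hp.T @ dz
            g["Ur"] = g["Ur"] + hp.T @ dr
            g["Un"] = g["Un"] + (r * hp).T @ dn
            dz_all[:, t], dr_all[:, t], dn_all[:, t] = dz, dr, dn
            dh = dh_prev
        Xf = Xe.reshape(B * T, d)
        g["Wz"] = Xf.T @ dz_all.reshape(B * T, h)
        g["Wr"] = Xf.T @ dr_all.reshape(B * T, h)
        g["Wn"] = Xf.T @ dn_all.reshape(B * T, h)
        g["bz"] = dz_all.sum(axis=(0, 1))
        g["br"] = dr_all.sum(axis=(0, 1))
        g["bn"] = dn_all.sum(axis=(0, 1))
        dXe += (dz_all.reshape(B * T, h) @ Wz.T
                + dr_all.reshape(B * T, h) @ Wr.T
                + dn_all.reshape(B * T, h) @ Wn.T).reshape(B, T, d)
        return dXe, {f"{prefix}_{k}": v for k, v in g.items()}

    def forward(self, X, lengths, dtype=np.float32, params=None,
                embedded: np.ndarray | None = None):
        """Scores for a padded batch.  Returns (probabilities, cache).

        ``embedded`` may supply the (B,T,d) embedded inputs directly (used
        by gradient-based attribution); otherwise they are looked up from
        the embedding table.
        """
        p = params or self.params
        B, T = X.shape
        E = p["E"].astype(dtype)
        Xe = E[X] if embedded is None else embedded.astype(dtype)
        mask = (np.arange(T)[None, :] < lengths[:, None])
        neg = np.finfo(dtype).min
        if self.architecture == "bigru_maxpool":
            Xr_idx = None
            Hf, cache_f = self._gru_forward(p, "f", Xe, dtype)
            # reverse each sequence within its length for the backward pass
            rev = self._reverse_index(lengths, T)
            Xe_r = np.take_along_axis(Xe, rev[:, :, None], axis=1)
            Hb, cache_b = self._gru_forward(p, "b", Xe_r, dtype)
            Hf_m = np.where(mask[:, :, None], Hf, neg)
            Hb_m = np.where(mask[:, :, None], Hb, neg)
            pool_f = Hf_m.max(axis=1)
            pool_b = Hb_m.max(axis=1)
            arg_f = Hf_m.argmax(axis=1)
            arg_b = Hb_m.argmax(axis=1)
            pooled = np.concatenate([pool_f, pool_b], axis=1)
            zero = ~mask.any(axis=1)
            if zero.any():
                pooled[zero] = 0.0
            cache = ("bigru", X, lengths, mask, Xe, rev, cache_f, cache_b,
                     arg_f, arg_b, zero)
            _ = Xr_idx
        else:
            Xe_m = np.where(mask[:, :, None], Xe, neg)
            pooled = Xe_m.max(axis=1)
            arg = Xe_m.argmax(axis=1)
            zero = ~mask.any(axis=1)
            if zero.any():
                pooled[zero] = 0.0
            cache = ("simple", X, lengths, mask, Xe, arg, zero)
        w = p["w_out"].astype(dtype)
        logit = pooled @ w + p["b_out"].astype(dtype)[0]
        prob = _sigmoid(logit)
        return prob, (cache, pooled, logit, w, dtype)

    @staticmethod
    def _reverse_index(lengths, T):
        B = len(lengths)
        idx = np.tile(np.arange(T), (B, 1))
        r = lengths[:, None] - 1 - idx
        return np.where(idx < lengths[:, None], r, idx)

    def backward(self, full_cache, dlogit, want_input_grad=False):
        """Gradients of a scalar loss with dlogit = dLoss/dlogit (B,).

        Returns (param_grads, dXe) where dXe is the gradient with respect to
        the embedded inputs (None unless requested or needed for E)."""
        cache, pooled, logit, w, dtype = full_cache
        grads = {}
        B = len(dlogit)
        grads["w_out"] = pooled.T @ dlogit
        grads["b_out"] = np.array([dlogit.sum()], dtype=dtype)
        dpooled = dlogit[:, None] * w[None, :]
        if cache[0] == "bigru":
            (_, X, lengths, mask, Xe, rev, cache_f, cache_b,
             arg_f, arg_b, zero) = cache
            h = self.hidden
            T = X.shape[1]
            dpooled = dpooled.copy()
            if zero.any():
                dpooled[zero] = 0.0
            dHf = np.zeros((B, T, h), dtype=dtype)
            dHb = np.zeros((B, T, h), dtype=dtype)
            bidx = np.arange(B)[:, None]
            hidx = np.arange(h)[None, :]
            np.add.at(dHf, (bidx, arg_f, hidx), dpooled[:, :h])
            np.add.at(dHb, (bidx, arg_b, hidx), dpooled[:, h:])
            dXe_f, gf = self._gru_backward(cache_f, dHf, "f", dtype)
            dXe_r, gb = self._gru_backward(cache_b, dHb, "b", dtype)
            grads.update(gf)
            grads.update(gb)
            # un-reverse the backward-direction input gradient
            dXe_b = np.zeros_like(dXe_r)
            np.put_along_axis(dXe_b, rev[:, :, None], dXe_r, axis=1)
            dXe = dXe_f + dXe_b
        else:
            _, X, lengths, mask, Xe, arg, zero = cache
            d = Xe.shape[2]
            dpooled = dpooled.copy()
            if zero.any():
                dpooled[zero] = 0.0
            dXe = np.zeros_like(Xe)
            bidx = np.arange(B)[:, None]
            didx = np.arange(d)[None, :]
            np.add.at(dXe, (bidx, arg, didx), dpooled)
        grads["_dXe"] = dXe
        grads["_X"] = cache[1]
        return grads

    # -- training ----------------------------------------------------------

    def fit(self, seqs: Sequence[np.ndarray], labels: np.ndarray,
            settings: TrainSettings,
            val_seqs: Sequence[np.ndarray] | None = None,
            val_labels: np.ndarray | None = None) -> dict:
        """Mini-batch Adam training with early stopping on validation loss.

        If no validation data is supplied, ``val_fraction`` of the training
        data is held out.  Returns a history dict."""
        rng = np.random.default_rng(settings.seed)
        labels = np.asarray(labels, dtype=np.float32)
        if val_seqs is None:
            n = len(seqs)
            order = rng.permutation(n)
            n_val = max(1, int(round(n * settings.val_fraction)))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            val_seqs = [seqs[i] for i in val_idx]
            val_labels = labels[val_idx]
            seqs = [seqs[i] for i in tr_idx]
            labels = labels[tr_idx]
        val_labels = np.asarray(val_labels, dtype=np.float32)

        m_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        lr_now = settings.learning_rate
        lengths = np.array([len(s) for s in seqs])
        history = {"train_loss": [], "val_loss": []}
        best_loss, best_params, bad = np.inf, None, 0

        # bucket by length to limit padding waste; shuffle bucket order
        base_order = np.argsort(lengths, kind="stable")
        n_batches = int(np.ceil(len(seqs) / settings.batch_size))
        for epoch in range(settings.epochs):
            batch_starts = rng.permutation(n_batches)
            total, seen = 0.0, 0
            for bi in batch_starts:
                sl = base_order[bi * settings.batch_size:
                                (bi + 1) * settings.batch_size]
                if len(sl) == 0:
                    continue
                X, ls = self.pad_batch([seqs[i] for i in sl])
                y = labels[sl]
                prob, cache = self.forward(X, ls)
                prob_c = np.clip(prob, 1e-7, 1.0 - 1e-7)
                loss = -np.mean(y * np.log(prob_c)
                                + (1 - y) * np.log(1 - prob_c))
                dlogit = (prob - y).astype(np.float32) / len(y)
                grads = self.backward(cache, dlogit)
                dXe, Xb = grads.pop("_dXe"), grads.pop("_X")
                if not settings.freeze_embedding:
                    dE = np.zeros_like(self.params["E"])
                    scatter_add(dE, Xb.ravel(),
                                dXe.reshape(-1, dXe.shape[2]))
                    dE[0] = 0.0  # padding row stays fixed
                    grads["E"] = dE
                step += 1
                lr_t = lr_now * \
                    np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step)
                for k, gk in grads.items():
                    gk = gk.astype(np.float32)
                    m_state[k] = beta1 * m_state[k] + (1 - beta1) * gk
                    v_state[k] = beta2 * v_state[k] + (1 - beta2) * gk * gk
                    self.params[k] -= lr_t * m_state[k] / \
                        (np.sqrt(v_state[k]) + eps)
                total += loss * len(y)
                seen += len(y)
            val_pred = self.predict(val_seqs)
            p = np.clip(val_pred, 1e-7, 1 - 1e-7)
            yv = np.asarray(val_labels, dtype=np.float64)
            val_loss = float(-np.mean(yv * np.log(p)
                                      + (1 - yv) * np.log(1 - p)))
            history["train_loss"].append(total / max(seen, 1))
            history["val_loss"].append(val_loss)
            if settings.select_metric == "auc" and 0 < yv.sum() < len(yv):
                from sklearn.metrics import roc_auc_score
                crit = -float(roc_auc_score(yv, val_pred))
            else:
                crit = val_loss
            history.setdefault("val_criterion", []).append(crit)
            if settings.verbose:
                print(f"epoch {epoch}: train {total / max(seen, 1):.4f} "
                      f"val {val_loss:.4f} crit {crit:.4f}")
            if crit < best_loss - 1e-5:
                best_loss = crit
                best_params = {k: v.copy() for k, v in self.params.items()}
                bad = 0
            else:
                bad += 1
                lr_now *= settings.lr_decay_on_plateau
                if bad > settings.patience:
                    break
        if best_params is not None:
            self.params = NetParams(best_params)
        return history

    def predict(self, seqs: Sequence[np.ndarray],
                batch_size: int = 256) -> np.ndarray:
        """Scores in [0,1]; float64 forward pass, batching-invariant."""
        out = np.empty(len(seqs), dtype=np.float64)
        order = np.argsort([len(s) for s in seqs], kind="stable")
        for i in range(0, len(seqs), batch_size):
            sl = order[i:i + batch_size]
            X, ls = self.pad_batch([seqs[j] for j in sl])
            prob, _ = self.forward(X, ls, dtype=np.float64)
            out[sl] = prob
        return out

    def loss(self, seqs, labels, batch_size: int = 256) -> float:
        p = np.clip(self.predict(seqs, batch_size), 1e-7, 1 - 1e-7)
        y = np.asarray(labels, dtype=np.float64)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    # -- gradients wrt embedded inputs (for attribution) -------------------

    def input_gradients(self, X, lengths, embedded, dtype=np.float64,
                        wrt: str = "prob"):
        """Gradient of the output with respect to the embedded inputs.

        ``wrt="prob"`` differentiates the sigmoid probability (the model
        score); ``wrt="logit"`` the pre-sigmoid logit.  Returns
        ``(output, dXe)`` for the batch."""
        prob, cache = self.forward(X, lengths, dtype=dtype, embedded=embedded)
        if wrt == "prob":
            dlogit = (prob * (1.0 - prob)).astype(dtype)
            out = prob
        else:
            dlogit = np.ones(len(X), dtype=dtype)
            out = cache[2]
        grads = self.backward(cache, dlogit)
        return out, grads["_dXe"]
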
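"""Minimal batched LSTM sequence labeller in numpy + numba.

Implements forward and backward passes (BPTT) for stacked, optionally
bidirectional LSTM layers followed by a per-timestep logistic output, trained
with Adam on masked binary cross-entropy. Written for small models (a few
layers, up to ~128 cells) on per-minute data, where a compiled deep-learning
framework is unnecessary; everything is deterministic given the seed. The
per-timestep recurrences are JIT-compiled with numba, the batched input
projections use BLAS.

Shapes: sequences are processed as padded batches ``x`` of shape ``(T, B, D)``
with a float mask ``(T, B)`` that is 1 on real timesteps and 0 on padding.
Masked steps pass hidden and cell state through unchanged and contribute
nothing to the loss or the gradients.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["LSTMNet"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its own length; padding stays in place."""
    T = x.shape[0]
    B = x.shape[1]
    t_idx = np.arange(T)[:, None]
    L = lengths[None, :]
    rev = np.where(t_idx < L, L - 1 - t_idx, t_idx)
    return x[rev, np.arange(B)[None, :]]


@njit(cache=False)
def _cell_forward_jit(xW, mask, Wh, b):
    T, B, H4 = xW.shape
    H = H4 // 4
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((T, B, H))
    I = np.empty((T, B, H))
    F = np.empty((T, B, H))
    G = np.empty((T, B, H))
    O = np.empty((T, B, H))
    TC = np.empty((T, B, H))
    Cprev = np.empty((T, B, H))
    Hprev = np.empty((T, B, H))
    for t in range(T):
        z = xW[t] + np.dot(h, Wh)
        for r in range(B):
            for k in range(H4):
                z[r, k] = z[r, k] + b[k]
        i = 1.0 / (1.0 + np.exp(-z[:, :H]))
        f = 1.0 / (1.0 + np.exp(-z[:, H:2 * H]))
        g = np.tanh(z[:, 2 * H:3 * H])
        o = 1.0 / (1.0 + np.exp(-z[:, 3 * H:]))
        I[t] = i
        F[t] = f
        G[t] = g
        O[t] = o
        Cprev[t] = c
        Hprev[t] = h
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        TC[t] = tc
        h_new = o * tc
        h_out = np.empty((B, H))
        c_out = np.empty((B, H))
        for r in range(B):
            m = mask[t, r]
            for k in range(H):
                h_out[r, k] = m * h_new[r, k] + (1.0 - m) * h[r, k]
                c_out[r, k] = m * c_new[r, k] + (1.0 - m) * c[r, k]
        h = h_out
        c = c_out
        Hs[t] = h
    return Hs, I, F, G, O, TC, Cprev, Hprev


@njit(cache=False)
def _cell_backward_jit(dHs, I, F, G, O, TC, Cprev, Hprev, x, mask, Wx, Wh):
    T, B, D = x.shape
    H = Wx.shape[1] // 4
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dx = np.empty_like(x)
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    dz = np.empty((B, 4 * H))
    for t in range(T - 1, -1, -1):
        dh_total = dh + dHs[t]
        for r in range(B):
            m = mask[t, r]
            for k in range(H):
                i = I[t, r, k]
                f = F[t, r, k]
                g = G[t, r, k]
                o = O[t, r, k]
                tc = TC[t, r, k]
                dh_new = dh_total[r, k] * m
                dc_new = dc[r, k] * m
                do = dh_new * tc
                dcn = dc_new + dh_new * o * (1.0 - tc * tc)
                df = dcn * Cprev[t, r, k]
                di = dcn * g
                dg = dcn * i
                dz[r, k] = di * i * (1.0 - i)
                dz[r, H + k] = df * f * (1.0 - f)
                dz[r, 2 * H + k] = dg * (1.0 - g * g)
                dz[r, 3 * H + k] = do * o * (1.0 - o)
                # stash passthrough pieces; completed after the matmuls
                dh[r, k] = dh_total[r, k] * (1.0 - m)
                dc[r, k] = dc[r, k] * (1.0 - m) + dcn * f
        xt = np.ascontiguousarray(x[t])
        hp = np.ascontiguousarray(Hprev[t])
        dWx += np.dot(xt.T, dz)
        dWh += np.dot(hp.T, dz)
        for k in range(4 * H):
            s = 0.0
            for r in range(B):
                s += dz[r, k]
            db[k] += s
        dx[t] = np.dot(dz, Wx.T)
        dh += np.dot(dz, Wh.T)
    return dx, dWx, dWh, db


class LSTMNet:
    """Stacked (bi)directional LSTM with a per-timestep logistic read-out."""

    def __init__(self, input_dim: int, hidden: int, n_layers: int,
                 bidirectional: bool, seed: int = 0):
        self.input_dim = input_dim
        self.hidden = hidden
        self.n_layers = n_layers
        self.bidirectional = bidirectional
        self.n_dir = 2 if bidirectional else 1
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        d_in = input_dim
        for layer in range(n_layers):
            for dirn in range(self.n_dir):
                k = 1.0 / np.sqrt(hidden)
                self.params[f"Wx{layer}_{dirn}"] = rng.uniform(
                    -k, k, size=(d_in, 4 * hidden))
                self.params[f"Wh{layer}_{dirn}"] = rng.uniform(
                    -k, k, size=(hidden, 4 * hidden))
                b = rng.uniform(-k, k, size=4 * hidden)
                b[hidden:2 * hidden] += 1.0  # forget-gate bias: remember by default
                self.params[f"b{layer}_{dirn}"] = b
            d_in = hidden * self.n_dir
        self.params["w_out"] = rng.uniform(-0.1, 0.1, size=d_in)
        self.params["b_out"] = np.zeros(1)
        # Adam state
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _cell_forward(self, x, mask, Wx, Wh, b):
        T, B, _ = x.shape
        xW = (x.reshape(T * B, -1) @ Wx).reshape(T, B, 4 * self.hidden)
        Hs, I, F, G, O, TC, Cprev, Hprev = _cell_forward_jit(
            np.ascontiguousarray(xW), mask, Wh, b)
        cache = {"I": I, "F": F, "G": G, "O": O, "TC": TC,
                 "Cprev": Cprev, "Hprev": Hprev}
        return Hs, cache

    def _cell_backward(self, dHs, cache, x, mask, Wx, Wh):
        return _cell_backward_jit(
            np.ascontiguousarray(dHs),
            cache["I"], cache["F"], cache["G"], cache["O"], cache["TC"],
            cache["Cprev"], cache["Hprev"],
            np.ascontiguousarray(x), mask, Wx, Wh)

    # --------------------------------------------------------------- network

    def forward(self, x, mask, lengths, need_cache: bool = False):
        """Per-timestep in-bed probabilities for a padded batch."""
        x = np.ascontiguousarray(x, dtype=np.float64)
        mask = np.ascontiguousarray(mask, dtype=np.float64)
        lengths = np.asarray(lengths, dtype=np.int64)
        caches = []
        inp = x
        for layer in range(self.n_layers):
            outs = []
            layer_cache = []
            for dirn in range(self.n_dir):
                xi = inp if dirn == 0 else _reverse_padded(inp, lengths)
                Hs, cache = self._cell_forward(
                    xi, mask,
                    self.params[f"Wx{layer}_{dirn}"],
                    self.params[f"Wh{layer}_{dirn}"],
                    self.params[f"b{layer}_{dirn}"],
                )
                if dirn == 1:
                    Hs = _reverse_padded(Hs, lengths)
                outs.append(Hs)
                layer_cache.append((cache, xi))
            inp = outs[0] if self.n_dir == 1 else np.concatenate(outs, axis=2)
            caches.append((layer_cache, inp))
        logits = inp @ self.params["w_out"] + self.params["b_out"][0]
        probs = _sigmoid(logits)
        if need_cache:
            return probs, (x, caches, inp, mask, lengths)
        return probs

    def backward(self, probs, targets, cache):
        """Gradients of masked mean BCE; returns (loss, grads dict)."""
        x, caches, top, mask, lengths = cache
        n_real = mask.sum()
        eps = 1e-12
        loss = -(
            mask * (targets * np.log(probs + eps)
                    + (1 - targets) * np.log(1 - probs + eps))
        ).sum() / n_real
        dlogit = (probs - targets) * mask / n_real  # (T, B)
        grads = {
            "w_out": np.einsum("tb,tbh->h", dlogit, top),
            "b_out": np.array([dlogit.sum()]),
        }
        d_inp = dlogit[:, :, None] * self.params["w_out"][None, None, :]
        for layer in range(self.n_layers - 1, -1, -1):
            layer_cache, _ = caches[layer]
            H = self.hidden
            dx_accum = None
            for dirn in range(self.n_dir):
                cell_cache, xi = layer_cache[dirn]
                dHs = d_inp[:, :, dirn * H:(dirn + 1) * H]
                if dirn == 1:
                    dHs = _reverse_padded(dHs, lengths)
                dx, dWx, dWh, db = self._cell_backward(
                    dHs, cell_cache, xi, mask,
                    self.params[f"Wx{layer}_{dirn}"],
                    self.params[f"Wh{layer}_{dirn}"],
                )
                if dirn == 1:
                    dx = _reverse_padded(dx, lengths)
                grads[f"Wx{layer}_{dirn}"] = dWx
                grads[f"Wh{layer}_{dirn}"] = dWh
                grads[f"b{layer}_{dirn}"] = db
                dx_accum = dx if dx_accum is None else dx_accum + dx
            d_inp = dx_accum
        return float(loss), grads

    def adam_step(self, grads, lr: float, beta1: float = 0.9,
                  beta2: float = 0.999, eps: float = 1e-8,
                  clip_norm: float = 5.0) -> None:
        gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        scale = min(1.0, clip_norm / (gnorm + 1e-12))
        self._t += 1
        bc1 = 1 - beta1 ** self._t
        bc2 = 1 - beta2 ** self._t
        for k, g in grads.items():
            g = g * scale
            self._m[k] = beta1 * self._m[k] + (1 - beta1) * g
            self._v[k] = beta2 * self._v[k] + (1 - beta2) * g * g
            self.params[k] -= lr * (self._m[k] / bc1) / (
                np.sqrt(self._v[k] / bc2) + eps)

    # ---------------------------------------------------------- persistence

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64).copy()
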
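"""Learning-to-rotate attention forecaster for residue time series.

The model is a small encoder-decoder transformer whose attention rotates each
query/key channel pair (treated as one complex plane) by a position-dependent
angle ``2*pi*omega*m + theta`` with per-plane frequency ``omega`` (cycles per
step, squashed to the Nyquist band [0, 0.5]) and phase ``theta`` (radians in
(-pi, pi]), both learned from the sequence content by a kernel-3 convolution.
Scores use the rotated softmax kernel ``exp(<Rq, Rk>/sqrt(d_h))``, which at
zero rotation reduces to standard scaled dot-product attention.

Two further ingredients:

* *Decoupled attention with global memory* — a learnable length-``c`` memory
  first attends to the key-value sequence (compressing it to ``c`` slots),
  then the queries attend to the compressed slots, so the number of score
  evaluations is ``N*c + c*L`` instead of ``N*L``.
* *Trend normalization* — instead of plain layer statistics, a per-channel
  least-squares line over positions (the slowly changing trend) is removed,
  the residual standardized, and the trend re-added with a learnable scale.

Training minimizes MSE plus smoothness/sparsity penalties on the learned
frequencies and phases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor, clip_grad_norm, concat

__all__ = [
    "RotationParams",
    "GlobalMemory",
    "QuatformerConfig",
    "AttentionOutput",
    "score_counter",
    "rotate_pairs",
    "lra_scores",
    "lra_attention",
    "decoupled_lra",
    "trend_normalize",
    "omega_regularizer",
    "theta_regularizer",
    "total_loss",
    "Quatformer",
]


class ScoreCounter:
    """Counts rotated-kernel score evaluations (query-key pairs scored)."""

    def __init__(self) -> None:
        self.count = 0

    def reset(self) -> None:
        self.count = 0

    def add(self, n: int) -> None:
        self.count += int(n)


#: module-level instrumentation; reset before a call to audit its complexity
score_counter = ScoreCounter()


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _is_grad(x) -> bool:
    return isinstance(x, Tensor) and x.requires_grad


@dataclass
class RotationParams:
    """Per-plane rotation frequencies and phases for one attention side.

    ``omega`` and ``theta`` are (P, N) (or batched (..., P, N)): P rotation
    planes (half the head width) by N positions.  ``omega`` is in cycles per
    step within [0, 0.5]; ``theta`` in radians.
    """

    omega: object  # ndarray or Tensor, shape (..., P, N)
    theta: object

    def __post_init__(self) -> None:
        ow, th = _data(self.omega), _data(self.theta)
        if ow.shape != th.shape:
            raise ValueError("omega and theta must share a shape")
        if ow.ndim < 2:
            raise ValueError("omega/theta must be at least 2-D: (P, N)")
        if np.any(ow < -1e-9) or np.any(ow > 0.5 + 1e-9):
            raise ValueError("omega must lie in the Nyquist band [0, 0.5]")

    @classmethod
    def zero(cls, P: int, N: int) -> "RotationParams":
        return cls(np.zeros((P, N)), np.zeros((P, N)))

    def angles(self, positions=None):
        """Rotation angle per plane/position: ``2*pi*omega*m + theta``."""
        N = _data(self.omega).shape[-1]
        if positions is None:
            positions = np.arange(N, dtype=float)
        pos = np.asarray(positions, dtype=float)
        return self.omega * (2.0 * np.pi * pos) + self.theta


@dataclass
class GlobalMemory:
    """A learnable length-``c`` sequence summarizing global temporal patterns."""

    slots: object  # (c, d) ndarray or Tensor

    def __post_init__(self) -> None:
        if _data(self.slots).ndim != 2 or _data(self.slots).shape[0] < 1:
            raise ValueError("memory slots must be a (c >= 1, d) matrix")

    @property
    def c(self) -> int:
        return _data(self.slots).shape[0]


@dataclass
class AttentionOutput:
    H: np.ndarray      # (N, d) query-side output
    M_prime: np.ndarray  # (c, d) compressed key-value summary


@dataclass
class QuatformerConfig:
    d_model: int = 32
    n_heads: int = 4
    enc_layers: int = 1
    dec_layers: int = 1
    memory_len: int = 8
    lambda1: float = 0.01
    lambda2: float = 0.01
    input_len: int = 7
    horizon: int = 1
    label_len: int = 3
    n_features: int = 3
    d_ff: int = 64
    epochs: int = 100
    learning_rate: float = 1e-2
    batch_size: int = 16
    patience: int = 10
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % (2 * self.n_heads) != 0:
            raise ValueError("d_model must be divisible by 2 * n_heads")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be non-negative")
        if self.memory_len < 1:
            raise ValueError("memory_len must be >= 1")
        if self.label_len > self.input_len:
            raise ValueError("label_len cannot exceed input_len")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


# ---------------------------------------------------------------------------
# functional core (ndarray in -> ndarray out; Tensors flow through untouched)
# ---------------------------------------------------------------------------


def _maybe_npy(out: Tensor, *inputs) -> object:
    return out if any(_is_grad(x) for x in inputs) else out.data


def rotate_pairs(vectors, angles):
    """Rotate channel pair ``p`` of position ``t`` by ``angles[..., p, t]``.

    ``vectors`` has shape (..., N, d_h) with even ``d_h = 2P``; pair ``p`` is
    the channel couple (2p, 2p+1) treated as a 2-vector.  Rotations are
    isometries: every position's Euclidean norm is preserved.
    """
    v = Tensor._lift(vectors)
    a = Tensor._lift(angles)
    d_h = v.shape[-1]
    if d_h % 2 != 0:
        raise ValueError("head width d_h must be even (2 channels per plane)")
    P = d_h // 2
    if _data(a).shape[-2] != P or _data(a).shape[-1] != v.shape[-2]:
        raise ValueError(
            f"angles must have shape (..., P={P}, N={v.shape[-2]}), "
            f"got {_data(a).shape}")
    ang = a.swapaxes(-1, -2)            # (..., N, P)
    xe = v[..., 0::2]                   # (..., N, P)
    xo = v[..., 1::2]
    ca, sa = ang.cos(), ang.sin()
    ye = xe * ca - xo * sa
    yo = xe * sa + xo * ca
    shp = tuple(v.shape[:-1])
    out = concat([ye.reshape(shp + (P, 1)), yo.reshape(shp + (P, 1))], axis=-1)
    out = out.reshape(shp + (d_h,))
    return _maybe_npy(out, vectors, angles)


def lra_scores(q, k, rp_q: RotationParams, rp_k: RotationParams):
    """Rotated softmax-kernel scores, shape (..., N, L), all entries > 0.

    ``score(m, n) = exp(<rot(q)_m, rot(k)_n> / sqrt(d_h))`` where the query
    rotation angle at plane p, position m is ``2*pi*omega_q[p,m]*m +
    theta_q[p,m]`` and likewise for keys at their own positions.
    """
    qt, kt = Tensor._lift(q), Tensor._lift(k)
    d_h = qt.shape[-1]
    if kt.shape[-1] != d_h:
        raise ValueError("query and key widths differ")
    if _data(rp_q.omega).shape[-2] != d_h // 2 or _data(rp_k.omega).shape[-2] != d_h // 2:
        raise ValueError("rotation plane count must equal d_h / 2")
    rq = Tensor._lift(rotate_pairs(qt, rp_q.angles()))
    rk = Tensor._lift(rotate_pairs(kt, rp_k.angles()))
    logits = (rq @ rk.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_h))
    out = logits.exp()
    N, L = qt.shape[-2], kt.shape[-2]
    multiplicity = int(np.prod(out.shape[:-2])) if out.ndim > 2 else 1
    score_counter.add(N * L * multiplicity)
    return _maybe_npy(out, q, k, rp_q.omega, rp_q.theta, rp_k.omega, rp_k.theta)


def lra_attention(q, k, v, rp_q: RotationParams | None = None,
                  rp_k: RotationParams | None = None):
    """Kernel-normalized learning-to-rotate attention output (..., N, d_v).

    Weights are the scores normalized per query row (each row sums to 1).
    With zero rotations this is exactly softmax scaled dot-product attention.
    """
    qt, kt, vt = Tensor._lift(q), Tensor._lift(k), Tensor._lift(v)
    if kt.shape[-2] == 0:
        raise ValueError("empty key sequence")
    if kt.shape[-2] != vt.shape[-2]:
        raise ValueError("keys and values must have the same length")
    P = qt.shape[-1] // 2
    rp_q = rp_q or RotationParams.zero(P, qt.shape[-2])
    rp_k = rp_k or RotationParams.zero(P, kt.shape[-2])
    s = Tensor._lift(lra_scores(qt, kt, rp_q, rp_k))
    w = s / s.sum(axis=-1, keepdims=True)
    out = w @ vt
    return _maybe_npy(out, q, k, v, rp_q.omega, rp_q.theta, rp_k.omega, rp_k.theta)


def decoupled_lra(queries, kv, memory: GlobalMemory,
                  rp_mem: RotationParams | None = None,
                  rp_kv: RotationParams | None = None,
                  rp_q: RotationParams | None = None,
                  rp_mprime: RotationParams | None = None) -> AttentionOutput:
    """Attend through a global memory: cost ``N*c + c*L`` score evaluations.

    Stage 1 compresses the key-value series of length L into the ``c`` memory
    slots (``M' = LRA(memory, kv, kv)``); stage 2 lets the N queries attend to
    the compressed slots (``H = LRA(queries, M', M')``).
    """
    if memory.c < 1:
        raise ValueError("memory length c must be >= 1")
    m_prime = lra_attention(memory.slots, kv, kv, rp_mem, rp_kv)
    h = lra_attention(queries, m_prime, m_prime, rp_q, rp_mprime)
    return AttentionOutput(H=h, M_prime=m_prime)


def _trend_projector(N: int) -> np.ndarray:
    """Hat matrix of the per-position straight-line fit (intercept + slope)."""
    t = np.arange(N, dtype=float)
    X = np.stack([np.ones(N), t], axis=1)
    return X @ np.linalg.solve(X.T @ X, X.T)


def trend_normalize(hidden, gamma=1.0, beta=0.0, rho=1.0, eps: float = 1e-5):
    """Normalize about the slowly changing (linear) temporal trend.

    Per channel, fit a least-squares line ``Tr`` over positions, then return
    ``gamma * (hidden - Tr) / (sd(hidden - Tr) + eps) + beta + rho * Tr``.
    The output's residual about ``rho * Tr`` has zero fitted slope.
    """
    h = Tensor._lift(hidden)
    N = h.shape[-2]
    if N < 2:
        raise ValueError("trend normalization needs at least 2 positions")
    proj = Tensor(_trend_projector(N))
    trend = proj @ h
    resid = h - trend
    sd = (resid * resid).mean(axis=-2, keepdims=True).sqrt()
    out = Tensor._lift(gamma) * resid / (sd + eps) + Tensor._lift(beta) \
        + Tensor._lift(rho) * trend
    return _maybe_npy(out, hidden, gamma, beta, rho)


def omega_regularizer(omega):
    """Mean squared step-to-step change of the frequencies (smoothness)."""
    ow = Tensor._lift(omega)
    if ow.ndim < 2:
        raise ValueError("omega must be (P, N)")
    P, N = ow.shape[-2], ow.shape[-1]
    if N < 2:
        raise ValueError("need N >= 2 for frequency differences")
    diff = ow[..., 1:] - ow[..., :-1]
    out = (diff * diff).sum() * (1.0 / (P * (N - 1) * int(np.prod(ow.shape[:-2]) or 1)))
    return _maybe_npy(out, omega)


def theta_regularizer(theta):
    """Mean absolute phase (sparsity)."""
    th = Tensor._lift(theta)
    if th.ndim < 2 or th.shape[-1] == 0 or th.shape[-2] == 0:
        raise ValueError("theta must be a non-empty (P, N) matrix")
    n = int(np.prod(th.shape))
    out = th.abs().sum() * (1.0 / n)
    return _maybe_npy(out, theta)


def total_loss(pred, target, all_omegas=(), all_thetas=(),
               lambda1: float = 0.01, lambda2: float = 0.01):
    """Training objective: MSE + lambda1 * L_omega + lambda2 * L_theta.

    The regularizers are averaged over every rotation-parameter instance
    (query- and key-side of every attention in every layer).
    """
    p, t = Tensor._lift(pred), Tensor._lift(target)
    if p.shape != t.shape:
        raise ValueError("pred and target must have the same shape")
    diff = p - t
    loss = (diff * diff).mean()
    if all_omegas and lambda1 > 0:
        l_om = omega_regularizer(all_omegas[0])
        for om in all_omegas[1:]:
            l_om = l_om + omega_regularizer(om)
        loss = loss + Tensor._lift(l_om) * (lambda1 / len(all_omegas))
    if all_thetas and lambda2 > 0:
        l_th = theta_regularizer(all_thetas[0])
        for th in all_thetas[1:]:
            l_th = l_th + theta_regularizer(th)
        loss = loss + Tensor._lift(l_th) * (lambda2 / len(all_thetas))
    return _maybe_npy(Tensor._lift(loss), pred, target, *all_omegas, *all_thetas)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def _linear_init(rng, fan_in: int, fan_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)),
                  requires_grad=True)


class _RotationLearner:
    """Kernel-3 convolution (replicate padding) emitting (omega, theta).

    Maps a (..., N, d_model) sequence to pre-activations for ``2 * P_total``
    channels; frequencies are squashed to [0, 0.5] by a sigmoid and phases to
    (-pi, pi) by ``pi * tanh``.
    """

    def __init__(self, rng, d_model: int):
        self.P_total = d_model // 2
        out_ch = 2 * self.P_total
        scale = 0.1  # small init -> near-zero rotations at start of training
        self.w = [Tensor(rng.normal(0, scale / np.sqrt(d_model),
                                    size=(d_model, out_ch)), requires_grad=True)
                  for _ in range(3)]
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [*self.w, self.b]

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (omega, theta) of shape (..., P_total, N)."""
        N = x.shape[-2]
        first = x[..., 0:1, :]
        last = x[..., N - 1:N, :]
        xpad = concat([first, x, last], axis=-2)
        pre = (xpad[..., 0:N, :] @ self.w[0]
               + xpad[..., 1:N + 1, :] @ self.w[1]
               + xpad[..., 2:N + 2, :] @ self.w[2]) + self.b
        omega = pre[..., :self.P_total].sigmoid() * 0.5
        theta = pre[..., self.P_total:].tanh() * np.pi
        return omega.swapaxes(-1, -2), theta.swapaxes(-1, -2)


class _TrendNorm:
    def __init__(self, d_model: int):
        self.gamma = Tensor(np.ones(d_model), requires_grad=True)
        self.beta = Tensor(np.zeros(d_model), requires_grad=True)
        self.rho = Tensor(np.ones(d_model), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta, self.rho]

    def __call__(self, x: Tensor) -> Tensor:
        return Tensor._lift(trend_normalize(x, self.gamma, self.beta, self.rho))


class _DecoupledLRABlock:
    """Multi-head decoupled learning-to-rotate attention (self or cross)."""

    def __init__(self, rng, cfg: QuatformerConfig):
        d = cfg.d_model
        self.cfg = cfg
        self.wq = _linear_init(rng, d, d)
        self.wk = _linear_init(rng, d, d)
        self.wv = _linear_init(rng, d, d)
        self.wo = _linear_init(rng, d, d)
        self.memory = GlobalMemory(
            Tensor(rng.normal(0, 0.5, size=(cfg.memory_len, d)),
                   requires_grad=True))
        self.rot_q = _RotationLearner(rng, d)
        self.rot_k = _RotationLearner(rng, d)
        self.rot_mem = _RotationLearner(rng, d)
        # the compressed summary M' is per-head (width d_head); one learner
        # shared across heads
        self.rot_mp = _RotationLearner(rng, cfg.d_head)

    def params(self) -> list[Tensor]:
        out = [self.wq, self.wk, self.wv, self.wo, self.memory.slots]
        for r in (self.rot_q, self.rot_k, self.rot_mem, self.rot_mp):
            out += r.params()
        return out

    @staticmethod
    def _head_fold(x: Tensor, n_heads: int, d_head: int) -> Tensor:
        """(B, N, d_model) -> (B, H, N, d_head)."""
        B, N = x.shape[0], x.shape[1]
        return x.reshape(B, N, n_heads, d_head).swapaxes(1, 2)

    def __call__(self, queries: Tensor, kv: Tensor,
                 collect: list | None = None) -> Tensor:
        cfg = self.cfg
        H, dh, P = cfg.n_heads, cfg.d_head, cfg.d_head // 2
        q = queries @ self.wq
        k = kv @ self.wk
        v = kv @ self.wv
        mem = self.memory.slots
        rp_q = self.rot_q(q)     # (B, P_total, N)
        rp_k = self.rot_k(k)
        rp_mem = self.rot_mem(mem)  # (P_total, c)
        if collect is not None:
            collect.append(rp_q)
            collect.append(rp_k)
            collect.append(rp_mem)
        B, N, L, c = q.shape[0], q.shape[1], k.shape[1], mem.shape[0]
        qh = self._head_fold(q, H, dh)              # (B, H, N, dh)
        kh = self._head_fold(k, H, dh)
        vh = self._head_fold(v, H, dh)
        memh = mem.reshape(c, H, dh).swapaxes(0, 1)  # (H, c, dh)
        hr = {  # plane h*P + p of the full set is plane p of head h
            "q": RotationParams(rp_q[0].reshape(B, H, P, N),
                                rp_q[1].reshape(B, H, P, N)),
            "k": RotationParams(rp_k[0].reshape(B, H, P, L),
                                rp_k[1].reshape(B, H, P, L)),
            "mem": RotationParams(rp_mem[0].reshape(H, P, c),
                                  rp_mem[1].reshape(H, P, c)),
        }
        # stage 1: compress the key-value series into the memory slots
        m_prime = Tensor._lift(lra_attention(memh, kh, vh, hr["mem"], hr["k"]))
        rp_mp = self.rot_mp(m_prime)                # (B, H, P, c)
        if collect is not None:
            collect.append(rp_mp)
        # stage 2: queries attend to the compressed slots
        out = Tensor._lift(lra_attention(
            qh, m_prime, m_prime, hr["q"], RotationParams(rp_mp[0], rp_mp[1])))
        merged = out.swapaxes(1, 2).reshape(B, N, H * dh)
        return merged @ self.wo


class _FeedForward:
    def __init__(self, rng, d_model: int, d_ff: int):
        self.w1 = _linear_init(rng, d_model, d_ff)
        self.b1 = Tensor(np.zeros(d_ff), requires_grad=True)
        self.w2 = _linear_init(rng, d_ff, d_model)
        self.b2 = Tensor(np.zeros(d_model), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        return ((x @ self.w1 + self.b1).relu()) @ self.w2 + self.b2


class _EncoderLayer:
    def __init__(self, rng, cfg: QuatformerConfig):
        self.attn = _DecoupledLRABlock(rng, cfg)
        self.ffn = _FeedForward(rng, cfg.d_model, cfg.d_ff)
        self.norm1 = _TrendNorm(cfg.d_model)
        self.norm2 = _TrendNorm(cfg.d_model)

    def params(self) -> list[Tensor]:
        return (self.attn.params() + self.ffn.params()
                + self.norm1.params() + self.norm2.params())

    def __call__(self, x: Tensor, collect: list) -> Tensor:
        x = self.norm1(x + self.attn(x, x, collect))
        return self.norm2(x + self.ffn(x))


class _DecoderLayer:
    def __init__(self, rng, cfg: QuatformerConfig):
        self.self_attn = _DecoupledLRABlock(rng, cfg)
        self.cross_attn = _DecoupledLRABlock(rng, cfg)
        self.ffn = _FeedForward(rng, cfg.d_model, cfg.d_ff)
        self.norm1 = _TrendNorm(cfg.d_model)
        self.norm2 = _TrendNorm(cfg.d_model)
        self.norm3 = _TrendNorm(cfg.d_model)

    def params(self) -> list[Tensor]:
        return (self.self_attn.params() + self.cross_attn.params()
                + self.ffn.params() + self.norm1.params()
                + self.norm2.params() + self.norm3.params())

    def __call__(self, y: Tensor, enc: Tensor, collect: list) -> Tensor:
        y = self.norm1(y + self.self_attn(y, y, collect))
        y = self.norm2(y + self.cross_attn(y, enc, collect))
        return self.norm3(y + self.ffn(y))


class Quatformer:
    """Encoder-decoder residue forecaster with learning-to-rotate attention.

    Inputs are windows of shape (input_len, F): standardized concentration
    plus scaled covariates (temperature, humidity).  The decoder consumes the
    last ``label_len`` observed steps plus ``horizon`` placeholder steps whose
    concentration channel is zero but whose covariates are known (storage
    conditions are constant per series); the output head reads the horizon
    positions.
    """

    def __init__(self, config: QuatformerConfig | None = None):
        self.config = config or QuatformerConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.embed_w = _linear_init(rng, cfg.n_features, cfg.d_model)
        self.embed_b = Tensor(np.zeros(cfg.d_model), requires_grad=True)
        self.pos_scale = 0.1
        self.enc_layers = [_EncoderLayer(rng, cfg) for _ in range(cfg.enc_layers)]
        self.dec_layers = [_DecoderLayer(rng, cfg) for _ in range(cfg.dec_layers)]
        self.head_w = _linear_init(rng, cfg.d_model, 1)
        self.head_b = Tensor(np.zeros(1), requires_grad=True)
        self.trained = False
        # standardization state (set by the training pipeline)
        self.conc_mean = 0.0
        self.conc_std = 1.0
        self.cov_mean = np.zeros(cfg.n_features - 1)
        self.cov_std = np.ones(cfg.n_features - 1)

    # -- parameters -------------------------------------------------------

    def params(self) -> list[Tensor]:
        out = [self.embed_w, self.embed_b, self.head_w, self.head_b]
        for layer in self.enc_layers + self.dec_layers:
            out += layer.params()
        return out

    def _embed(self, x: Tensor, offset: int = 0) -> Tensor:
        h = x @ self.embed_w + self.embed_b
        N = x.shape[-2]
        pos = np.arange(offset, offset + N, dtype=float)[:, None]
        freqs = np.arange(1, self.config.d_model + 1) / self.config.d_model
        pe = self.pos_scale * np.sin(pos * freqs * np.pi / self.config.input_len)
        return h + Tensor(pe)

    # -- forward ----------------------------------------------------------

    def forward(self, windows: np.ndarray,
                collect_rotations: list | None = None) -> Tensor:
        """Standardized forward pass.

        *windows*: (B, input_len, F) standardized.  Returns (B, horizon)
        standardized predictions.  Rotation-parameter pairs encountered along
        the way are appended to *collect_rotations* for the training loss.
        """
        cfg = self.config
        x = np.asarray(windows, dtype=float)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        if x.shape[1] != cfg.input_len or x.shape[2] != cfg.n_features:
            raise ValueError(
                f"expected windows of shape (B, {cfg.input_len}, "
                f"{cfg.n_features}), got {x.shape}")
        collect = collect_rotations if collect_rotations is not None else []
        enc_in = self._embed(Tensor(x))
        enc = enc_in
        for layer in self.enc_layers:
            enc = layer(enc, collect)
        # decoder input: last label_len steps + zero-concentration placeholders
        # carrying the (known, constant) covariates
        tail = x[:, cfg.input_len - cfg.label_len:, :]
        placeholder = np.repeat(x[:, -1:, :], cfg.horizon, axis=1).copy()
        placeholder[:, :, 0] = 0.0
        dec_in_np = np.concatenate([tail, placeholder], axis=1)
        dec = self._embed(Tensor(dec_in_np), offset=cfg.input_len - cfg.label_len)
        for layer in self.dec_layers:
            dec = layer(dec, enc, collect)
        out = dec @ self.head_w + self.head_b           # (B, L_dec, 1)
        pred = out[:, cfg.label_len:, 0]                # (B, horizon)
        if squeeze:
            pred = pred[0]
        return pred

    # -- public API -------------------------------------------------------

    def set_scaler(self, conc_mean: float, conc_std: float,
                   cov_mean: np.ndarray, cov_std: np.ndarray) -> None:
        self.conc_mean = float(conc_mean)
        self.conc_std = float(conc_std)
        self.cov_mean = np.asarray(cov_mean, dtype=float)
        self.cov_std = np.asarray(cov_std, dtype=float)

    def standardize(self, raw_window: np.ndarray) -> np.ndarray:
        w = np.asarray(raw_window, dtype=float).copy()
        w[..., 0] = (w[..., 0] - self.conc_mean) / self.conc_std
        w[..., 1:] = (w[..., 1:] - self.cov_mean) / self.cov_std
        return w

    def forecast(self, window: np.ndarray) -> np.ndarray:
        """Predict the next ``horizon`` residues (mg/kg) from a raw window.

        *window*: (input_len, F) raw — concentration in mg/kg and raw
        covariates.  Output is de-standardized back to mg/kg.
        """
        if not self.trained:
            warnings.warn("forecast from an untrained model: outputs are "
                          "defined but meaningless", stacklevel=2)
        w = np.asarray(window, dtype=float)
        if w.ndim != 2 or w.shape[1] != self.config.n_features:
            raise ValueError(
                f"window must be (input_len, {self.config.n_features})")
        pred = self.forward(self.standardize(w))
        return pred.data * self.conc_std + self.conc_mean

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Write a JSON checkpoint with an embedded config echo."""
        blob = {
            "config": asdict(self.config),
            "trained": self.trained,
            "scaler": {
                "conc_mean": self.conc_mean, "conc_std": self.conc_std,
                "cov_mean": self.cov_mean.tolist(),
                "cov_std": self.cov_std.tolist(),
            },
            "params": [p.data.tolist() for p in self.params()],
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path) -> "Quatformer":
        blob = json.loads(Path(path).read_text())
        model = cls(QuatformerConfig(**blob["config"]))
        for p, saved in zip(model.params(), blob["params"], strict=True):
            p.data = np.asarray(saved, dtype=float).reshape(p.data.shape)
        sc = blob["scaler"]
        model.set_scaler(sc["conc_mean"], sc["conc_std"],
                         np.asarray(sc["cov_mean"]), np.asarray(sc["cov_std"]))
        model.trained = blob["trained"]
        return model
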
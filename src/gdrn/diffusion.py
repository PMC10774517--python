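"""Denoising diffusion probabilistic model (DDPM) over brain networks.

Connectivity matrices are vectorized to their strictly upper triangle
(optionally after a Fisher z-transform, so Gaussian noising acts on an
unbounded scale) and modelled with a standard DDPM:

* forward process: ``q(x_t | x_0) = N(sqrt(abar_t) x_0, (1 - abar_t) I)``
  with ``alpha_t = 1 - beta_t`` and ``abar_t = prod_{s<=t} alpha_s``;
* reverse process: ``p(x_{t-1} | x_t) = N(mu_theta(x_t, t), beta_t I)`` with
  ``mu_theta = (x_t - beta_t / sqrt(1 - abar_t) * eps_theta(x_t, t)) / sqrt(alpha_t)``;
* training objective: the simplified noise-prediction loss
  ``E || eps - eps_theta(x_t, t) ||^2``.

One model is trained per exposure group (saline / low / high nicotine).
``eps_theta`` is a small fully connected residual network over the
upper-triangle vector with a sinusoidal time embedding, implemented directly
in numpy (forward, backprop and Adam), which is ample for these dense,
fixed-size inputs.

Besides unconditional sampling the module implements partial-noising
reconstruction: an observed network is noised forward to an intermediate
step ``t_noise`` and denoised back to step 0.  The discrepancy between the
reconstruction and the original measures how well the subject fits the
learned group distribution, and is the basis of classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .connectome import (
    ConnectivityMatrix,
    GROUPS,
    fisher_z,
    inverse_fisher_z,
    square_from_upper,
    vectorize_upper,
)

__all__ = [
    "DiffusionSchedule",
    "TrainConfig",
    "NoisePredictor",
    "make_schedule",
    "q_sample",
    "p_mean_variance",
    "simple_loss",
    "variational_bound",
    "train",
    "sample",
    "reconstruct",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Noise schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiffusionSchedule:
    """Noise schedule: beta_t, alpha_t = 1 - beta_t, abar_t = prod alpha_s.

    Steps are numbered 1..T; array index ``t - 1`` holds the step-``t`` value.
    """

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray

    def __post_init__(self) -> None:
        if self.T < 1 or len(self.beta) != self.T:
            raise ValueError("schedule length must equal T >= 1")
        if np.any(self.beta <= 0) or np.any(self.beta >= 1):
            raise ValueError("beta_t must lie in (0, 1)")
        if not np.allclose(self.alpha, 1.0 - self.beta):
            raise ValueError("alpha_t must equal 1 - beta_t")
        if not np.allclose(self.alpha_bar, np.cumprod(self.alpha), rtol=0, atol=1e-12):
            raise ValueError("alpha_bar must be the cumulative product of alpha")
        if np.any(np.diff(self.alpha_bar) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")


def make_schedule(
    T: int, beta_start: float = 1e-4, beta_end: float = 0.02, kind: str = "linear"
) -> DiffusionSchedule:
    """Build a noise schedule.

    ``linear`` interpolates beta from ``beta_start`` to ``beta_end``; ``cosine``
    follows the squared-cosine abar profile (endpoints are ignored beyond the
    validity check).
    """
    if not (0 < beta_start <= beta_end < 1):
        raise ValueError("require 0 < beta_start <= beta_end < 1")
    if T < 1:
        raise ValueError("T must be >= 1")
    if kind == "linear":
        beta = np.linspace(beta_start, beta_end, T)
    elif kind == "cosine":
        s = 0.008
        steps = np.arange(T + 1)
        abar = np.cos((steps / T + s) / (1 + s) * np.pi / 2) ** 2
        abar /= abar[0]
        beta = np.clip(1.0 - abar[1:] / abar[:-1], 1e-8, 0.999)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    alpha = 1.0 - beta
    return DiffusionSchedule(T, beta, alpha, np.cumprod(alpha))


# ---------------------------------------------------------------------------
# Training configuration
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Hyper-parameters for per-group DDPM training.

    Defaults follow common DDPM practice: Adam at learning rate 1e-3 for 1000
    epochs, a linear beta schedule from 1e-4 to 0.02.  ``transform`` selects
    the modelling scale: ``fisher_z`` (default; atanh of correlations, so the
    Gaussian noise model has unbounded support) or ``none`` (raw correlations).
    """

    learning_rate: float = 0.001
    epochs: int = 1000
    batch_size: int = 16
    T: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    schedule: str = "linear"
    hidden_width: int = 128
    time_embed_dim: int = 32
    transform: str = "fisher_z"
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.transform not in ("fisher_z", "none"):
            raise ValueError("transform must be 'fisher_z' or 'none'")
        if self.time_embed_dim % 2:
            raise ValueError("time_embed_dim must be even")

    def make_schedule(self) -> DiffusionSchedule:
        return make_schedule(self.T, self.beta_start, self.beta_end, self.schedule)


# ---------------------------------------------------------------------------
# Noise predictor (numpy MLP with sinusoidal time embedding)
# ---------------------------------------------------------------------------


def _silu(a: np.ndarray) -> np.ndarray:
    return a / (1.0 + np.exp(-a))


def _silu_grad(a: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-a))
    return s * (1.0 + a * (1.0 - s))


class NoisePredictor:
    """eps_theta(x_t, t): fully connected residual network, trained per group.

    Input and output dimension equal the upper-triangle length n(n-1)/2.
    The timestep enters through a sinusoidal embedding concatenated to x_t.

    The network is parameterized through a denoised-signal head: the MLP
    outputs f(x_t, t) (an estimate of x_0) and the noise prediction is
    recovered analytically as
    ``eps_theta = (x_t - sqrt(abar_t) f) / sqrt(1 - abar_t)``.
    This is an exact reparameterization of eps_theta — training still
    minimizes the noise-prediction MSE — but it removes the 1/sqrt(1-abar_t)
    steepness of the small-t noise map, which a plain MLP cannot represent
    accurately and which otherwise biases ancestral sampling.  The schedule
    implied by the model's own config is baked in at construction.
    """

    def __init__(
        self,
        dim: int,
        group: str,
        config: TrainConfig,
        region_indices: Sequence[int] | None = None,
        rng: np.random.Generator | None = None,
    ):
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        self.dim = int(dim)
        self.group = group
        self.config = config
        self.region_indices = list(region_indices) if region_indices is not None else None
        self.trained = False
        self.loss_history: list[float] = []
        H, E = config.hidden_width, config.time_embed_dim
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        d_in = self.dim + E
        self.params = {
            "W1": rng.standard_normal((d_in, H)) * np.sqrt(2.0 / d_in),
            "b1": np.zeros(H),
            "W2": rng.standard_normal((H, H)) * np.sqrt(2.0 / H),
            "b2": np.zeros(H),
            "W3": rng.standard_normal((H, self.dim)) * 1e-3,
            "b3": np.zeros(self.dim),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_step = 0
        self._alpha_bar = config.make_schedule().alpha_bar

    def _abar(self, t: np.ndarray) -> np.ndarray:
        t_idx = np.asarray(np.rint(t), dtype=int) - 1
        if np.any(t_idx < 0) or np.any(t_idx >= len(self._alpha_bar)):
            raise ValueError(f"t must lie in [1, T={len(self._alpha_bar)}]")
        return self._alpha_bar[t_idx]

    # -- forward ------------------------------------------------------------

    def _time_embedding(self, t: np.ndarray) -> np.ndarray:
        E = self.config.time_embed_dim
        half = E // 2
        freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
        ang = t[:, None] * freqs[None, :]
        return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)

    def _forward(self, x: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, dict]:
        p = self.params
        z = np.concatenate([x, self._time_embedding(t)], axis=1)
        a1 = z @ p["W1"] + p["b1"]
        h1 = _silu(a1)
        a2 = h1 @ p["W2"] + p["b2"]
        h2 = h1 + _silu(a2)
        out = h2 @ p["W3"] + p["b3"]
        return out, {"z": z, "a1": a1, "h1": h1, "a2": a2, "h2": h2}

    def predict(self, x: np.ndarray, t: int | np.ndarray) -> np.ndarray:
        """eps_theta for a single vector (1-D x) or a batch (2-D x)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        xb = x[None, :] if single else x
        if xb.shape[1] != self.dim:
            raise ValueError(f"input dimension {xb.shape[1]} != model dimension {self.dim}")
        tb = np.full(xb.shape[0], t, dtype=float) if np.isscalar(t) else np.asarray(t, float)
        f, _ = self._forward(xb, tb)
        ab = self._abar(tb)[:, None]
        out = (xb - np.sqrt(ab) * f) / np.sqrt(1.0 - ab)
        return out[0] if single else out

    # -- backward + Adam ----------------------------------------------------

    def _backward(self, g_out: np.ndarray, cache: dict) -> dict:
        p = self.params
        grads = {}
        grads["W3"] = cache["h2"].T @ g_out
        grads["b3"] = g_out.sum(axis=0)
        dh2 = g_out @ p["W3"].T
        da2 = dh2 * _silu_grad(cache["a2"])
        grads["W2"] = cache["h1"].T @ da2
        grads["b2"] = da2.sum(axis=0)
        dh1 = dh2 + da2 @ p["W2"].T
        da1 = dh1 * _silu_grad(cache["a1"])
        grads["W1"] = cache["z"].T @ da1
        grads["b1"] = da1.sum(axis=0)
        return grads

    def _adam_update(self, grads: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8) -> None:
        self._adam_step += 1
        k1 = 1.0 - b1 ** self._adam_step
        k2 = 1.0 - b2 ** self._adam_step
        for name, g in grads.items():
            m = self._adam_m[name] = b1 * self._adam_m[name] + (1 - b1) * g
            v = self._adam_v[name] = b2 * self._adam_v[name] + (1 - b2) * g * g
            self.params[name] -= lr * (m / k1) / (np.sqrt(v / k2) + eps)


# ---------------------------------------------------------------------------
# Forward process, reverse process, loss
# ---------------------------------------------------------------------------


def q_sample(
    x0: np.ndarray, t: int | np.ndarray, eps: np.ndarray, sched: DiffusionSchedule
) -> np.ndarray:
    """Sample x_t directly from the forward marginal:
    ``x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) eps``.

    ``x0`` may be a single vector or a batch; with a batch, ``t`` may give one
    step per row.
    """
    x0 = np.asarray(x0, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if x0.shape != eps.shape:
        raise ValueError("x0 and eps must have the same shape")
    t_arr = np.atleast_1d(np.asarray(t, dtype=int))
    if np.any(t_arr < 1) or np.any(t_arr > sched.T):
        raise ValueError(f"t must lie in [1, T={sched.T}]")
    abar = sched.alpha_bar[t_arr - 1]
    if x0.ndim == 2 and abar.size > 1:
        abar = abar[:, None]
    else:
        abar = abar.reshape(-1)[0]
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps


def p_mean_variance(
    model: NoisePredictor, x_t: np.ndarray, t: int, sched: DiffusionSchedule
) -> tuple[np.ndarray, float]:
    """Mean and (fixed) variance of the reverse kernel p(x_{t-1} | x_t).

    The variance is fixed to beta_t, matching the simplified-loss regime.
    """
    if t < 1 or t > sched.T:
        raise ValueError(f"t must lie in [1, T={sched.T}] (t=0 has no prior step)")
    beta_t = float(sched.beta[t - 1])
    alpha_t = float(sched.alpha[t - 1])
    abar_t = float(sched.alpha_bar[t - 1])
    eps_hat = model.predict(x_t, t)
    mean = (np.asarray(x_t, float) - beta_t / np.sqrt(1.0 - abar_t) * eps_hat) / np.sqrt(alpha_t)
    return mean, beta_t


def simple_loss(eps: np.ndarray, eps_hat: np.ndarray) -> float:
    """Simplified DDPM objective: mean squared error between true and
    predicted noise (mean over coordinates, and over the batch if 2-D)."""
    eps = np.asarray(eps, dtype=float)
    eps_hat = np.asarray(eps_hat, dtype=float)
    if eps.shape != eps_hat.shape:
        raise ValueError("eps and eps_hat must have the same shape")
    return float(np.mean((eps - eps_hat) ** 2))


# ---------------------------------------------------------------------------
# Transform helpers
# ---------------------------------------------------------------------------


def to_model_space(fc: ConnectivityMatrix, transform: str) -> np.ndarray:
    """Vectorize a connectivity matrix on the modelling scale."""
    if transform == "fisher_z":
        return vectorize_upper(fisher_z(fc))
    return vectorize_upper(fc)


def from_model_space(
    vec: np.ndarray,
    transform: str,
    region_indices: Sequence[int],
    subject_id: str = "",
    group: str = "saline",
) -> ConnectivityMatrix:
    """Inverse of :func:`to_model_space`; always yields a valid matrix
    (symmetric, unit diagonal, clipped to [-1, 1])."""
    mat = square_from_upper(vec, diagonal=0.0)
    if transform == "fisher_z":
        mat = inverse_fisher_z(mat)
    mat = np.clip(mat, -1.0, 1.0)
    np.fill_diagonal(mat, 1.0)
    return ConnectivityMatrix(mat, list(region_indices), subject_id, group)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train(dataset: Sequence[ConnectivityMatrix], config: TrainConfig) -> NoisePredictor:
    """Train a per-group noise predictor on a list of connectivity matrices.

    Each step draws a minibatch, a uniform timestep t in [1, T] per sample and
    standard-normal noise, forms x_t from the forward marginal and minimizes
    the simplified loss with Adam.  Fully deterministic for a fixed seed.

    ``loss_history`` holds one loss per epoch evaluated on a fixed
    (t, eps) set drawn once at the start, so successive entries are directly
    comparable (minibatch losses fluctuate strongly across epochs because the
    noise-prediction error varies by orders of magnitude over t).
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    groups = {fc.group for fc in dataset}
    if len(groups) > 1:
        raise ValueError(f"mixed groups in training dataset: {sorted(groups)}")
    sizes = {fc.n_regions for fc in dataset}
    if len(sizes) > 1:
        raise ValueError("all connectivity matrices must have the same size")
    group = dataset[0].group
    sched = config.make_schedule()
    X = np.stack([to_model_space(fc, config.transform) for fc in dataset])
    n, dim = X.shape

    rng = np.random.default_rng(config.seed)
    model = NoisePredictor(dim, group, config, dataset[0].region_indices, rng=rng)
    bs = min(config.batch_size, n)

    # fixed evaluation noise: one (t, eps) pair per training sample
    t_eval = rng.integers(1, sched.T + 1, size=n)
    eps_eval = rng.standard_normal(X.shape)
    x_t_eval = q_sample(X, t_eval, eps_eval, sched)

    for _ in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            xb = X[idx]
            t = rng.integers(1, sched.T + 1, size=len(idx))
            eps = rng.standard_normal(xb.shape)
            x_t = q_sample(xb, t, eps, sched)
            f, cache = model._forward(x_t, t.astype(float))
            ab = sched.alpha_bar[t - 1][:, None]
            eps_hat = (x_t - np.sqrt(ab) * f) / np.sqrt(1.0 - ab)
            g_eps = 2.0 * (eps_hat - eps) / eps_hat.size
            g_f = g_eps * (-np.sqrt(ab) / np.sqrt(1.0 - ab))
            grads = model._backward(g_f, cache)
            if config.grad_clip > 0:
                # noise-MSE gradients are heavy-tailed in t (weight up to
                # abar/(1-abar)); global norm clipping keeps Adam stable
                norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                if norm > config.grad_clip:
                    grads = {k: g * (config.grad_clip / norm) for k, g in grads.items()}
            model._adam_update(grads, config.learning_rate)
        model.loss_history.append(simple_loss(eps_eval, model.predict(x_t_eval, t_eval)))

    model.trained = True
    return model


# ---------------------------------------------------------------------------
# Sampling and reconstruction
# ---------------------------------------------------------------------------


def _reverse_chain(
    model: NoisePredictor,
    x: np.ndarray,
    t_start: int,
    sched: DiffusionSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """Run ancestral sampling from step t_start down to 0 (batched)."""
    for t in range(t_start, 0, -1):
        mean, var = p_mean_variance(model, x, t, sched)
        if t > 1:
            x = mean + np.sqrt(var) * rng.standard_normal(x.shape)
        else:
            x = mean
    return x


def sample(
    model: NoisePredictor, sched: DiffusionSchedule, n: int, seed: int
) -> list[ConnectivityMatrix]:
    """Draw n brain networks by ancestral sampling from pure noise.

    Deterministic for a fixed seed; every output satisfies the connectivity
    invariants (symmetrized, clipped, unit diagonal).
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, model.dim))
    x = _reverse_chain(model, x, sched.T, sched, rng)
    region_indices = model.region_indices or list(range(_n_from_dim(model.dim)))
    return [
        from_model_space(
            x[i], model.config.transform, region_indices, f"sample_{i:03d}", model.group
        )
        for i in range(n)
    ]


def _n_from_dim(dim: int) -> int:
    return int(round((1 + np.sqrt(1 + 8 * dim)) / 2))


def reconstruct(
    model: NoisePredictor,
    fc: ConnectivityMatrix,
    t_noise: int,
    sched: DiffusionSchedule,
    seed: int,
) -> ConnectivityMatrix:
    """Partial-noising reconstruction of one subject's network.

    Noises fc forward to step ``t_noise`` via the closed-form marginal, then
    denoises back to step 0 through the reverse chain.  ``t_noise = 0``
    returns the input unchanged.
    """
    if t_noise < 0 or t_noise > sched.T:
        raise ValueError(f"t_noise must lie in [0, T={sched.T}]")
    if t_noise == 0:
        return ConnectivityMatrix(
            fc.values.copy(), list(fc.region_indices), fc.subject_id, fc.group
        )
    x0 = to_model_space(fc, model.config.transform)
    if x0.shape[0] != model.dim:
        raise ValueError(f"matrix dimension {x0.shape[0]} != model dimension {model.dim}")
    rng = np.random.default_rng(seed)
    x_t = q_sample(x0, t_noise, rng.standard_normal(x0.shape), sched)
    x0_hat = _reverse_chain(model, x_t[None, :], t_noise, sched, rng)[0]
    return from_model_space(
        x0_hat, model.config.transform, fc.region_indices, fc.subject_id, fc.group
    )


# ---------------------------------------------------------------------------
# Variational bound (diagnostic)
# ---------------------------------------------------------------------------


def variational_bound(
    model: NoisePredictor,
    x0: ConnectivityMatrix | np.ndarray,
    sched: DiffusionSchedule,
    seed: int,
    n_mc: int = 10,
) -> float:
    """Monte-Carlo estimate of the negative variational lower bound (nats).

    Decomposes into the prior KL at step T, per-step KL terms between the
    forward posterior q(x_{t-1} | x_t, x_0) and the learned reverse kernel,
    and the step-1 reconstruction term.  Diagnostic only — training uses the
    simplified noise-prediction loss.
    """
    if isinstance(x0, ConnectivityMatrix):
        x0 = to_model_space(x0, model.config.transform)
    x0 = np.asarray(x0, dtype=float)
    D = x0.shape[0]
    rng = np.random.default_rng(seed)
    beta, alpha, abar = sched.beta, sched.alpha, sched.alpha_bar

    # prior term: KL(q(x_T | x_0) || N(0, I)), closed form
    aT = abar[-1]
    l_T = 0.5 * float(np.sum(aT * x0**2 + (1.0 - aT) - 1.0 - np.log(1.0 - aT)))

    total = l_T
    for t in range(2, sched.T + 1):
        bt, at = float(beta[t - 1]), float(alpha[t - 1])
        abar_t, abar_p = float(abar[t - 1]), float(abar[t - 2])
        tilde_beta = (1.0 - abar_p) / (1.0 - abar_t) * bt
        c0 = np.sqrt(abar_p) * bt / (1.0 - abar_t)
        ct = np.sqrt(at) * (1.0 - abar_p) / (1.0 - abar_t)
        kl = 0.0
        for _ in range(n_mc):
            x_t = q_sample(x0, t, rng.standard_normal(D), sched)
            mu_q = c0 * x0 + ct * x_t
            mu_p, var_p = p_mean_variance(model, x_t, t, sched)
            kl += 0.5 * (
                D * (np.log(var_p / tilde_beta) + tilde_beta / var_p - 1.0)
                + float(np.sum((mu_q - mu_p) ** 2)) / var_p
            )
        total += kl / n_mc

    # reconstruction term: E_q[-log p(x_0 | x_1)] with variance beta_1
    b1 = float(beta[0])
    rec = 0.0
    for _ in range(n_mc):
        x_1 = q_sample(x0, 1, rng.standard_normal(D), sched)
        mu_p, _ = p_mean_variance(model, x_1, 1, sched)
        rec += 0.5 * (D * np.log(2.0 * np.pi * b1) + float(np.sum((x0 - mu_p) ** 2)) / b1)
    total += rec / n_mc
    return float(total)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: NoisePredictor, sched: DiffusionSchedule, path: str | Path) -> None:
    """Write model parameters, schedule, config and group tag to one file."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "group": model.group,
        "dim": model.dim,
        "trained": model.trained,
        "region_indices": model.region_indices,
        "config": asdict(model.config),
        "loss_history": model.loss_history,
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    np.savez(path, meta=json.dumps(meta), beta=sched.beta, **arrays)


def load_checkpoint(path: str | Path) -> tuple[NoisePredictor, DiffusionSchedule]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {meta['format_version']}")
        config = TrainConfig(**meta["config"])
        model = NoisePredictor(meta["dim"], meta["group"], config, meta["region_indices"])
        for k in model.params:
            model.params[k] = data[f"param_{k}"]
        model.trained = bool(meta["trained"])
        model.loss_history = list(meta["loss_history"])
        beta = data["beta"]
        alpha = 1.0 - beta
        sched = DiffusionSchedule(len(beta), beta, alpha, np.cumprod(alpha))
    return model, sched
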
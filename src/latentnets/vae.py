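"""Recurrent variational autoencoder for univariate time series.

Architecture (all sizes configurable):

* **encoder** — an LSTM reads the series x_k one value per step; the hidden
  state at the last (unpadded) step is h_out.
* **encoder-to-latent** — two linear maps take h_out to a mean vector Zmu and a
  log-variance vector; Zsigma = exp(logvar / 2) guarantees positive standard
  deviations.
* **latent-to-decoder** — a linear map takes the reparameterized sample
  Z = Zmu + Zsigma * eps to the decoder's initial hidden state.
* **decoder** — an LSTM driven by a learnable input token (initialized at zero
  and trained by backpropagation) emits one hidden state per step; a linear
  output layer reconstructs the series.

The loss is the Gaussian-decoder negative ELBO: the sum of squared
reconstruction errors over the (unmasked) time steps, averaged over L
Monte-Carlo samples of Z, plus kl_scale * sum_m(mu^2 + sigma^2 - 1 -
log sigma^2) against a standard-normal prior; both terms are averaged over the
batch.  kl_scale = 0.5 gives the exact KL divergence.

Everything — forward pass, backpropagation through time, and the Adam update —
is implemented directly on numpy arrays, which keeps training exactly
reproducible from a single integer seed in single-threaded execution.
Variable-length batches are handled by zero-padding with a mask; padded steps
contribute nothing to the loss or the gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import LabeledDataset, TimeSeriesRecord

__all__ = [
    "VAEConfig",
    "LatentGaussianSet",
    "LossBreakdown",
    "TrainedVAE",
    "TrainingDiverged",
    "train",
    "encode",
    "reconstruct",
    "reparameterize",
    "kl_term",
    "vae_loss",
    "save_checkpoint",
    "load_checkpoint",
]

_CHECKPOINT_FORMAT = "latentnets-vae-1"


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class VAEConfig:
    latent_dim: int = 20
    hidden_units: int = 96
    n_recurrent_layers: int = 1
    learning_rate: float = 5e-4
    mc_samples: int = 1
    batch_size: int = 64
    max_epochs: int = 300
    patience: int = 20
    kl_scale: float = 0.5
    kl_warmup_epochs: int = 30
    grad_clip: float = 5.0
    normalize_input: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be at least 2 (a network needs >= 2 nodes)")
        for name in ("hidden_units", "n_recurrent_layers", "mc_samples", "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.kl_scale < 0:
            raise ValueError("kl_scale must be nonnegative")
        if self.kl_warmup_epochs < 0:
            raise ValueError("kl_warmup_epochs must be nonnegative")
        if self.grad_clip < 0:
            raise ValueError("grad_clip must be nonnegative (0 disables clipping)")


@dataclass(frozen=True)
class LatentGaussianSet:
    """Encoder output: M univariate Gaussians N(means[i], stds[i]^2)."""

    means: np.ndarray
    stds: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        mu = np.asarray(self.means, dtype=float)
        sd = np.asarray(self.stds, dtype=float)
        if mu.shape != sd.shape or mu.ndim != 1:
            raise ValueError("means and stds must be 1-d vectors of equal length")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sd))):
            raise ValueError("latent parameters must be finite")
        if np.any(sd <= 0):
            raise ValueError("stds must be strictly positive")
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "stds", sd)

    @property
    def M(self) -> int:
        return self.means.size


@dataclass(frozen=True)
class LossBreakdown:
    total: float
    reconstruction: float
    kl: float


# ---------------------------------------------------------------------------
# parameter initialization and the LSTM primitive
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _init_params(config: VAEConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Uniform(-k, k) init with k = 1/sqrt(H), the standard LSTM scaling."""
    H, M, R = config.hidden_units, config.latent_dim, config.n_recurrent_layers
    k = 1.0 / np.sqrt(H)
    u = lambda *shape: rng.uniform(-k, k, size=shape)
    p: dict[str, np.ndarray] = {}
    for layer in range(R):
        enc_in = 1 if layer == 0 else H
        dec_in = 1 if layer == 0 else H
        p[f"enc{layer}_Wx"] = u(4 * H, enc_in)
        p[f"enc{layer}_Wh"] = u(4 * H, H)
        p[f"enc{layer}_b"] = u(4 * H)
        p[f"dec{layer}_Wx"] = u(4 * H, dec_in)
        p[f"dec{layer}_Wh"] = u(4 * H, H)
        p[f"dec{layer}_b"] = u(4 * H)
    p["W_mu"] = u(M, H)
    p["b_mu"] = u(M)
    p["W_lv"] = u(M, H)
    p["b_lv"] = u(M)
    # latent-to-decoder map emits the full initial LSTM state (hidden + cell)
    p["W_z"] = u(2 * R * H, M)
    p["b_z"] = u(2 * R * H)
    p["W_out"] = u(1, H)
    p["b_out"] = u(1)
    p["dec_x0"] = np.zeros(1)  # learnable decoder input token, starts at zero
    return p


def _lstm_forward(X, h0, c0, Wx, Wh, b):
    """X: (B,T,I). Returns the hidden sequence (B,T,H) and caches for backward."""
    B, T, _ = X.shape
    H = Wh.shape[1]
    h, c = h0, c0
    Hseq = np.empty((B, T, H))
    cache = []
    for t in range(T):
        a = X[:, t] @ Wx.T + h @ Wh.T + b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache.append((X[:, t], h, c, i, f, g, o, c_new, tc))
        h, c = h_new, c_new
        Hseq[:, t] = h
    return Hseq, cache


def _lstm_backward(dHseq, cache, Wx, Wh, dh_final=None, dc_final=None):
    """BPTT. dHseq: (B,T,H) upstream grads on each hidden output.

    Returns (dX, dh0, dc0, dWx, dWh, db).
    """
    B, T, H = dHseq.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.empty((B, T, Wx.shape[1]))
    dh = np.zeros((B, H)) if dh_final is None else dh_final.copy()
    dc = np.zeros((B, H)) if dc_final is None else dc_final.copy()
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
        dh = dh + dHseq[:, t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc = dc * f
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dWx += da.T @ x_t
        dWh += da.T @ h_prev
        db += da.sum(axis=0)
        dX[:, t] = da @ Wx
        dh = da @ Wh
    return dX, dh, dc, dWx, dWh, db


# ---------------------------------------------------------------------------
# full model forward / backward on a padded batch
# ---------------------------------------------------------------------------


def _pad_batch(series_list: Sequence[np.ndarray]):
    lengths = np.array([len(s) for s in series_list], dtype=int)
    T = int(lengths.max())
    B = len(series_list)
    X = np.zeros((B, T))
    mask = np.zeros((B, T))
    for b, s in enumerate(series_list):
        X[b, : len(s)] = s
        mask[b, : len(s)] = 1.0
    return X, mask, lengths


def _forward(params, config, X, mask, lengths, eps_list, kl_scale=None):
    """Forward pass for one padded batch; eps_list has L arrays of shape (B,M).

    ``kl_scale`` overrides ``config.kl_scale`` during KL warm-up.
    """
    if kl_scale is None:
        kl_scale = config.kl_scale
    B, T = X.shape
    H, R = config.hidden_units, config.n_recurrent_layers
    zeros = np.zeros((B, H))
    ctx = {"X": X, "mask": mask, "lengths": lengths, "kl_scale": kl_scale}

    inp = X[:, :, None]
    ctx["enc"] = []
    for layer in range(R):
        Hseq, cache = _lstm_forward(
            inp, zeros, zeros,
            params[f"enc{layer}_Wx"], params[f"enc{layer}_Wh"], params[f"enc{layer}_b"],
        )
        ctx["enc"].append((Hseq, cache))
        inp = Hseq
    h_last = Hseq[np.arange(B), lengths - 1]
    ctx["h_last"] = h_last

    mu = h_last @ params["W_mu"].T + params["b_mu"]
    logvar = h_last @ params["W_lv"].T + params["b_lv"]
    logvar = np.clip(logvar, -15.0, 15.0)
    sigma = np.exp(0.5 * logvar)
    ctx.update(mu=mu, logvar=logvar, sigma=sigma)

    token = np.broadcast_to(params["dec_x0"], (B, T, 1))
    samples = []
    sq_sum = np.zeros(B)
    for eps in eps_list:
        z = mu + sigma * eps
        state0 = z @ params["W_z"].T + params["b_z"]  # (B, 2*R*H): h0s then c0s
        dec = []
        inp = token
        for layer in range(R):
            h0 = state0[:, layer * H : (layer + 1) * H]
            c0 = state0[:, (R + layer) * H : (R + layer + 1) * H]
            Hseq_d, cache_d = _lstm_forward(
                inp, h0, c0,
                params[f"dec{layer}_Wx"], params[f"dec{layer}_Wh"], params[f"dec{layer}_b"],
            )
            dec.append((Hseq_d, cache_d))
            inp = Hseq_d
        Y = (Hseq_d @ params["W_out"].T)[:, :, 0] + params["b_out"][0]
        err = (Y - X) * mask
        sq_sum += (err * err).sum(axis=1)
        samples.append({"eps": eps, "z": z, "dec": dec, "Y": Y, "err": err})
    ctx["samples"] = samples

    L = len(eps_list)
    if L > 0:  # encode-only passes carry no samples and no loss
        recon_per_series = sq_sum / L  # sum over time, mean over MC samples
        kl_per_series = kl_scale * np.sum(
            mu**2 + sigma**2 - 1.0 - logvar, axis=1
        )
        recon = float(recon_per_series.mean())
        kl = float(kl_per_series.mean())
        ctx["loss"] = LossBreakdown(total=recon + kl, reconstruction=recon, kl=kl)
    return ctx


def _backward(params, config, ctx):
    """Gradients of ctx['loss'].total with respect to every parameter."""
    X, mask, lengths = ctx["X"], ctx["mask"], ctx["lengths"]
    B, T = X.shape
    H, R = config.hidden_units, config.n_recurrent_layers
    L = len(ctx["samples"])
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    mu, sigma, logvar = ctx["mu"], ctx["sigma"], ctx["logvar"]
    kl_scale = ctx["kl_scale"]

    dmu = kl_scale * 2.0 * mu / B
    # d kl / d logvar with sigma^2 = exp(logvar): kl_scale*(exp(logvar) - 1)
    dlogvar = kl_scale * (np.exp(logvar) - 1.0) / B

    for s in ctx["samples"]:
        dY = 2.0 * s["err"] / (B * L)  # (B,T)
        grads["W_out"] += np.einsum("bt,bth->h", dY, s["dec"][-1][0])[None, :]
        grads["b_out"] += np.array([dY.sum()])
        dHseq = dY[:, :, None] * params["W_out"][0][None, None, :]
        dstate0 = np.empty((B, 2 * R * H))
        for layer in range(R - 1, -1, -1):
            _, cache_d = s["dec"][layer]
            dX_d, dh0, dc0, dWx, dWh, db = _lstm_backward(
                dHseq, cache_d, params[f"dec{layer}_Wx"], params[f"dec{layer}_Wh"]
            )
            grads[f"dec{layer}_Wx"] += dWx
            grads[f"dec{layer}_Wh"] += dWh
            grads[f"dec{layer}_b"] += db
            dstate0[:, layer * H : (layer + 1) * H] = dh0
            dstate0[:, (R + layer) * H : (R + layer + 1) * H] = dc0
            dHseq = dX_d
        grads["dec_x0"] += dX_d.sum(axis=(0, 1))
        dz = dstate0 @ params["W_z"]
        grads["W_z"] += dstate0.T @ s["z"]
        grads["b_z"] += dstate0.sum(axis=0)
        dmu = dmu + dz
        dlogvar = dlogvar + dz * s["eps"] * 0.5 * sigma

    h_last = ctx["h_last"]
    grads["W_mu"] += dmu.T @ h_last
    grads["b_mu"] += dmu.sum(axis=0)
    grads["W_lv"] += dlogvar.T @ h_last
    grads["b_lv"] += dlogvar.sum(axis=0)
    dh_last = dmu @ params["W_mu"] + dlogvar @ params["W_lv"]

    dHseq = np.zeros((B, T, H))
    dHseq[np.arange(B), lengths - 1] = dh_last
    for layer in range(R - 1, -1, -1):
        _, cache_e = ctx["enc"][layer]
        dX_e, _, _, dWx, dWh, db = _lstm_backward(
            dHseq, cache_e, params[f"enc{layer}_Wx"], params[f"enc{layer}_Wh"]
        )
        grads[f"enc{layer}_Wx"] += dWx
        grads[f"enc{layer}_Wh"] += dWh
        grads[f"enc{layer}_b"] += db
        dHseq = dX_e
    return grads


# ---------------------------------------------------------------------------
# model container, training, inference
# ---------------------------------------------------------------------------


@dataclass
class TrainedVAE:
    params: dict[str, np.ndarray]
    config: VAEConfig
    history: list[LossBreakdown] = field(default_factory=list)

    def normalize(self, values: np.ndarray) -> tuple[np.ndarray, float, float]:
        """Per-series z-score used at both training and encoding time."""
        v = np.asarray(values, dtype=float)
        if not self.config.normalize_input:
            return v, 0.0, 1.0
        m = float(v.mean())
        s = float(v.std())
        if s < 1e-8:
            s = 1.0
        return (v - m) / s, m, s


def _prepare(series: TimeSeriesRecord | np.ndarray) -> np.ndarray:
    v = series.values if isinstance(series, TimeSeriesRecord) else np.asarray(series, float)
    if v.size < 2:
        raise ValueError("series must have at least 2 points")
    return v


def encode(series: TimeSeriesRecord | np.ndarray, model: TrainedVAE) -> LatentGaussianSet:
    """Map one series to its M latent univariate Gaussians (deterministic)."""
    v = _prepare(series)
    v, _, _ = model.normalize(v)
    X, mask, lengths = _pad_batch([v])
    ctx = _forward(model.params, model.config, X, mask, lengths, eps_list=[])
    sid = series.id if isinstance(series, TimeSeriesRecord) else ""
    return LatentGaussianSet(means=ctx["mu"][0], stds=ctx["sigma"][0], source_id=sid)


def reparameterize(latent: LatentGaussianSet, rng: np.random.Generator) -> np.ndarray:
    """Z = Zmu + Zsigma * eps with eps ~ N(0, I)."""
    eps = rng.standard_normal(latent.M)
    return latent.means + latent.stds * eps


def kl_term(latent: LatentGaussianSet, kl_scale: float = 0.5) -> float:
    """kl_scale * sum_m(mu^2 + sigma^2 - 1 - log sigma^2); the KL divergence
    from N(mu, diag sigma^2) to N(0, I) when kl_scale = 0.5."""
    mu, sd = latent.means, latent.stds
    val = float(kl_scale * np.sum(mu**2 + sd**2 - 1.0 - np.log(sd**2)))
    return max(val, 0.0) if kl_scale >= 0 else val


def _batch_forward(model, batch, rng, kl_scale=None):
    cfg = model.config
    normed = [model.normalize(_prepare(r))[0] for r in batch]
    X, mask, lengths = _pad_batch(normed)
    eps_list = [rng.standard_normal((len(batch), cfg.latent_dim)) for _ in range(cfg.mc_samples)]
    return _forward(model.params, cfg, X, mask, lengths, eps_list, kl_scale=kl_scale)


def vae_loss(
    batch: Sequence[TimeSeriesRecord],
    model: TrainedVAE,
    rng: np.random.Generator,
    config: VAEConfig | None = None,
) -> LossBreakdown:
    """Loss of one batch without updating the model."""
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    ctx = _batch_forward(model, batch, rng)
    loss = ctx["loss"]
    if not np.isfinite(loss.total):
        ids = [getattr(r, "id", "?") for r in batch]
        raise TrainingDiverged(f"non-finite loss on batch {ids}")
    return loss


def train(dataset: LabeledDataset, config: VAEConfig) -> TrainedVAE:
    """Train the VAE on a labeled dataset; the labels are never read.

    One integer seed drives parameter initialization, batch shuffling, and the
    reparameterization draws.  Stops early when the epoch loss has not improved
    for ``config.patience`` epochs.

    The KL weight is annealed linearly from 0 to ``kl_scale`` over the first
    ``kl_warmup_epochs`` epochs (KL warm-up), the standard guard against
    posterior collapse in recurrent VAEs: the encoder is allowed to make the
    latents informative before the prior starts pulling them back.
    """
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, rng)
    model = TrainedVAE(params=params, config=config)
    records = list(dataset.records)
    K = len(records)
    bs = min(config.batch_size, K)

    opt_m = {k: np.zeros_like(v) for k, v in params.items()}
    opt_v = {k: np.zeros_like(v) for k, v in params.items()}
    step = 0
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8

    best = np.inf
    stale = 0
    for epoch in range(config.max_epochs):
        if config.kl_warmup_epochs > 0:
            w = config.kl_scale * min(1.0, (epoch + 1) / config.kl_warmup_epochs)
        else:
            w = config.kl_scale
        order = rng.permutation(K)
        tot = rec = kl = 0.0
        nb = 0
        for start in range(0, K, bs):
            batch = [records[i] for i in order[start : start + bs]]
            ctx = _batch_forward(model, batch, rng, kl_scale=w)
            loss = ctx["loss"]
            if not np.isfinite(loss.total):
                raise TrainingDiverged(
                    f"loss became non-finite at epoch {epoch}; try a lower "
                    "learning_rate or enable input normalization"
                )
            grads = _backward(params, config, ctx)
            if config.grad_clip > 0:  # global-norm clipping
                gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                if gnorm > config.grad_clip:
                    scale = config.grad_clip / gnorm
                    grads = {k: g * scale for k, g in grads.items()}
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k in params:
                g = grads[k]
                opt_m[k] = beta1 * opt_m[k] + (1 - beta1) * g
                opt_v[k] = beta2 * opt_v[k] + (1 - beta2) * g * g
                params[k] -= lr_t * opt_m[k] / (np.sqrt(opt_v[k]) + eps_adam)
            tot += loss.total
            rec += loss.reconstruction
            kl += loss.kl
            nb += 1
        epoch_loss = LossBreakdown(total=tot / nb, reconstruction=rec / nb, kl=kl / nb)
        model.history.append(epoch_loss)
        if epoch + 1 < config.kl_warmup_epochs:
            continue  # objective still changing during warm-up; no early stop
        if epoch_loss.total < best - 1e-6:
            best = epoch_loss.total
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return model


def reconstruct(
    series: TimeSeriesRecord | np.ndarray,
    model: TrainedVAE,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Decode one series back to its own length.

    With ``rng=None`` the latent mean is decoded (no sampling); otherwise one
    reparameterized draw is used.  Output is on the original scale (the
    per-series normalization, if enabled, is inverted).
    """
    v = _prepare(series)
    vn, m, s = model.normalize(v)
    X, mask, lengths = _pad_batch([vn])
    if rng is None:
        eps = np.zeros((1, model.config.latent_dim))
    else:
        eps = rng.standard_normal((1, model.config.latent_dim))
    ctx = _forward(model.params, model.config, X, mask, lengths, eps_list=[eps])
    Y = ctx["samples"][0]["Y"][0]
    return Y * s + m


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(model: TrainedVAE, path: str | Path) -> None:
    """Single-archive checkpoint: weights + JSON config + format version."""
    meta = {
        "format": _CHECKPOINT_FORMAT,
        "numpy": np.__version__,
        "config": asdict(model.config),
        "history": [asdict(h) for h in model.history],
    }
    np.savez(
        Path(path),
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.params,
    )


def load_checkpoint(path: str | Path) -> TrainedVAE:
    with np.load(Path(path)) as npz:
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        if meta.get("format") != _CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognized checkpoint format in {path}")
        params = {k: npz[k].copy() for k in npz.files if k != "__meta__"}
    config = VAEConfig(**meta["config"])
    history = [LossBreakdown(**h) for h in meta.get("history", [])]
    return TrainedVAE(params=params, config=config, history=history)
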
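"""Denoising diffusion probabilistic model for fibrosis-map synthesis.

The forward process gradually corrupts a map x0 with Gaussian noise over T
steps, q(x_t | x_{t-1}) = N(sqrt(1-beta_t) x_{t-1}, beta_t I), which has the
closed-form marginal x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps.  A U-Net is
trained to predict eps from (x_t, t) with an MSE loss; sampling runs the
learned reverse chain p(x_{t-1} | x_t) = N(mu_theta, sigma_t^2 I) with the
fixed variance sigma_t^2 = beta_t, starting from pure noise.

Maps are trained in a symmetric model range: IIR [0, 2] maps linearly to
[-1, 1]; samples are mapped back and clipped.

Defaults follow the original DDPM recipe (T = 1000 linear betas 1e-4..2e-2,
MSE + Adam 2.5e-5, 500 epochs); desk-scale runs override epochs/architecture
through :class:`DdpmTrainConfig`.
"""

from __future__ import annotations

import math
import zipfile
import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .maps import FibrosisMap

DEFAULT_T = 1000
DEFAULT_BETA_START = 1e-4
DEFAULT_BETA_END = 2e-2


@dataclass
class NoiseSchedule:
    """Variance schedule beta_1..beta_T with derived alpha / alpha-bar."""

    beta: np.ndarray
    alpha: np.ndarray = field(init=False)
    alpha_bar: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.beta.ndim != 1 or self.beta.size < 1:
            raise ValueError("beta must be a 1D sequence")
        if np.any(self.beta <= 0) or np.any(self.beta >= 1):
            raise ValueError("beta values must lie in (0, 1)")
        if np.any(np.diff(self.beta) < 0):
            raise ValueError("beta must be non-decreasing")
        self.alpha = 1.0 - self.beta
        self.alpha_bar = np.cumprod(self.alpha)

    @property
    def T(self) -> int:
        return self.beta.size

    @classmethod
    def linear(cls, T: int = DEFAULT_T, beta_start: float = DEFAULT_BETA_START,
               beta_end: float = DEFAULT_BETA_END) -> "NoiseSchedule":
        return cls(np.linspace(beta_start, beta_end, T))


@dataclass
class DdpmTrainConfig:
    """Training hyperparameters; the tuple of channel widths and attention
    levels define the U-Net (attention at the 2nd and 3rd resolution levels,
    one head each)."""

    epochs: int = 500
    learning_rate: float = 2.5e-5
    batch_size: int = 16
    seed: int = 0
    channels: tuple[int, ...] = (64, 128, 256)
    attention_levels: tuple[int, ...] = (1, 2)  # 0-based: 2nd and 3rd levels
    time_embed_dim: int = 64
    iir_range: tuple[float, float] = (0.0, 2.0)
    ema_decay: float = 0.995      # exponential moving average of weights
    lr_decay: float = 1.0         # multiplicative per-epoch decay

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")


def iir_to_model(values: np.ndarray, iir_range=(0.0, 2.0)) -> np.ndarray:
    lo, hi = iir_range
    return 2.0 * (values - lo) / (hi - lo) - 1.0


def model_to_iir(values: np.ndarray, iir_range=(0.0, 2.0)) -> np.ndarray:
    lo, hi = iir_range
    return np.clip((values + 1.0) * (hi - lo) / 2.0 + lo, lo, hi)


# ---------------------------------------------------------------------------
# U-Net denoiser
# ---------------------------------------------------------------------------

def sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Transformer-style sinusoidal embedding of (integer) timesteps."""
    half = dim // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = np.asarray(t, dtype=float)[:, None] * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1)


class _ResBlock(nn.Module):
    def __init__(self, in_ch, out_ch, emb_dim, rng):
        super().__init__()
        g = math.gcd(8, in_ch)
        self.norm1 = nn.GroupNorm(g, in_ch)
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.emb_proj = nn.Linear(emb_dim, out_ch, rng)
        self.norm2 = nn.GroupNorm(math.gcd(8, out_ch), out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.skip = nn.Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def forward(self, x, emb):
        h = self.conv1(self.norm1(x).silu())
        e = self.emb_proj(emb.silu())
        h = h + e.reshape(e.shape[0], e.shape[1], 1, 1)
        h = self.conv2(self.norm2(h).silu())
        s = self.skip(x) if self.skip is not None else x
        return h + s


class _AttentionBlock(nn.Module):
    """Single-head self-attention over spatial positions."""

    def __init__(self, ch, rng):
        super().__init__()
        self.norm = nn.GroupNorm(math.gcd(8, ch), ch)
        self.q = nn.Linear(ch, ch, rng)
        self.k = nn.Linear(ch, ch, rng)
        self.v = nn.Linear(ch, ch, rng)
        self.proj = nn.Linear(ch, ch, rng)
        self.scale = 1.0 / math.sqrt(ch)

    def forward(self, x):
        N, C, H, W = x.shape
        h = self.norm(x).reshape(N, C, H * W).transpose(0, 2, 1)  # N, HW, C
        q, k, v = self.q(h), self.k(h), self.v(h)
        scores = nn.softmax(q @ k.transpose(0, 2, 1) * self.scale, axis=-1)
        out = self.proj(scores @ v)
        return x + out.transpose(0, 2, 1).reshape(N, C, H, W)


class UNetDenoiser(nn.Module):
    """Epsilon-predicting 2D U-Net: 3 resolution levels, attention at the
    2nd and 3rd, sinusoidal timestep embedding."""

    def __init__(self, config: DdpmTrainConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(config.seed)
        ch = config.channels
        emb = config.time_embed_dim
        self.config = config
        self.emb_mlp1 = nn.Linear(emb, emb, rng)
        self.emb_mlp2 = nn.Linear(emb, emb, rng)
        self.conv_in = nn.Conv2d(1, ch[0], 3, rng)
        self.down_blocks = [_ResBlock(c, c, emb, rng) for c in ch]
        self.down_attn = [
            _AttentionBlock(ch[i], rng) if i in config.attention_levels else None
            for i in range(len(ch))
        ]
        self.downsamplers = [
            nn.Conv2d(ch[i], ch[i + 1], 3, rng, stride=2, padding=1)
            for i in range(len(ch) - 1)
        ]
        self.mid = _ResBlock(ch[-1], ch[-1], emb, rng)
        self.mid_attn = _AttentionBlock(ch[-1], rng)
        self.upsample_convs = [
            nn.Conv2d(ch[i + 1], ch[i], 3, rng) for i in reversed(range(len(ch) - 1))
        ]
        self.up_blocks = [
            _ResBlock(2 * ch[i], ch[i], emb, rng) for i in reversed(range(len(ch) - 1))
        ]
        self.norm_out = nn.GroupNorm(math.gcd(8, ch[0]), ch[0])
        self.conv_out = nn.Conv2d(ch[0], 1, 3, rng)
        self.conv_out.w.data[:] = 0.0  # zero-init output head (stable start)

    def forward(self, x: nn.Tensor, t: np.ndarray) -> nn.Tensor:
        emb = nn.Tensor(sinusoidal_embedding(t, self.config.time_embed_dim))
        emb = self.emb_mlp2(self.emb_mlp1(emb).silu())
        h = self.conv_in(x)
        skips = []
        for i, block in enumerate(self.down_blocks):
            h = block(h, emb)
            if self.down_attn[i] is not None:
                h = self.down_attn[i](h)
            if i < len(self.downsamplers):
                skips.append(h)
                h = self.downsamplers[i](h)
        h = self.mid_attn(self.mid(h, emb))
        for conv, block in zip(self.upsample_convs, self.up_blocks):
            h = conv(nn.upsample_nearest(h, 2))
            h = block(nn.concat([h, skips.pop()], axis=1), emb)
        return self.conv_out(self.norm_out(h).silu())

    def predict(self, x_t: np.ndarray, t) -> np.ndarray:
        """Predicted noise for a batch (N,H,W) or single (H,W) map; numpy in/out."""
        single = np.asarray(x_t).ndim == 2
        xb = np.asarray(x_t, dtype=float)
        if single:
            xb = xb[None]
        tb = np.full(xb.shape[0], t) if np.isscalar(t) else np.asarray(t)
        self.eval()
        with nn.no_grad():
            out = self.forward(nn.Tensor(xb[:, None]), tb).data[:, 0]
        return out[0] if single else out


# ---------------------------------------------------------------------------
# Forward / reverse processes
# ---------------------------------------------------------------------------

def forward_noising(x0: np.ndarray, t, schedule: NoiseSchedule,
                    rng: np.random.Generator | int = 0,
                    eps: np.ndarray | None = None) -> np.ndarray:
    """Closed-form forward marginal x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps."""
    if np.any(np.asarray(t) < 1) or np.any(np.asarray(t) > schedule.T):
        raise ValueError(f"t out of range [1, {schedule.T}]")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    x0 = np.asarray(x0, dtype=float)
    if eps is None:
        eps = rng.standard_normal(x0.shape)
    abar = schedule.alpha_bar[np.asarray(t) - 1]
    abar = np.reshape(abar, np.shape(abar) + (1,) * (x0.ndim - np.ndim(abar)))
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps


def reverse_step(x_t: np.ndarray, t: int, model, schedule: NoiseSchedule,
                 rng: np.random.Generator | int = 0,
                 add_noise: bool = True) -> np.ndarray:
    """One ancestral sampling step x_t -> x_{t-1} with sigma_t^2 = beta_t."""
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t out of range [1, {schedule.T}]")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    beta = schedule.beta[t - 1]
    alpha = schedule.alpha[t - 1]
    abar = schedule.alpha_bar[t - 1]
    eps_hat = model.predict(x_t, t) if hasattr(model, "predict") else model(x_t, t)
    mu = (x_t - beta / math.sqrt(1.0 - abar) * eps_hat) / math.sqrt(alpha)
    if t > 1 and add_noise:
        mu = mu + math.sqrt(beta) * rng.standard_normal(np.shape(x_t))
    return mu


def train_ddpm(maps, config: DdpmTrainConfig | None = None,
               schedule: NoiseSchedule | None = None):
    """Train the epsilon-predicting U-Net on fibrosis maps.

    Returns ``(model, loss_trace)`` where ``loss_trace`` is the per-epoch mean
    MSE.  Fully seeded: identical config and data give identical traces.
    """
    config = config or DdpmTrainConfig()
    schedule = schedule or NoiseSchedule.linear()
    data = np.stack([
        m.values if isinstance(m, FibrosisMap) else np.asarray(m, float) for m in maps
    ]) if len(maps) else np.empty((0, 1, 1))
    if data.shape[0] < 2:
        raise ValueError("need at least 2 training maps")
    x0 = iir_to_model(data, config.iir_range)
    rng = np.random.default_rng(config.seed)
    model = UNetDenoiser(config, np.random.default_rng(config.seed + 1))
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    n = x0.shape[0]
    trace = []
    ema = [np.zeros_like(a) for a in model.state_arrays()]
    ema_steps = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        model.train()
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = x0[idx]
            t = rng.integers(1, schedule.T + 1, size=len(idx))
            eps = rng.standard_normal(xb.shape)
            x_t = forward_noising(xb, t, schedule, eps=eps, rng=rng)
            pred = model.forward(nn.Tensor(x_t[:, None]), t)
            loss = ((pred - nn.Tensor(eps[:, None])) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            ema_steps += 1
            # warmup EMA: short runs track the live weights, long runs
            # converge to the configured decay
            d = min(config.ema_decay, (1.0 + ema_steps) / (10.0 + ema_steps))
            for e, p in zip(ema, model.parameters()):
                e *= d
                e += (1.0 - d) * p.data
        trace.append(float(np.mean(losses)))
        opt.lr *= config.lr_decay
    model.load_state_arrays(ema)  # the averaged model is what samples
    return model, trace


def sample_maps(model, schedule: NoiseSchedule, n: int, seed: int = 0,
                shape: tuple[int, int] = (96, 96),
                iir_range=(0.0, 2.0)) -> list[FibrosisMap]:
    """Run the full T-step reverse chain from N(0, I); returns IIR maps."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n,) + shape)
    for t in range(schedule.T, 0, -1):
        x = reverse_step(x, t, model, schedule, rng)
    return [
        FibrosisMap(model_to_iir(x[i], iir_range), "synthetic",
                    f"synthetic-{seed}-{i}", seed)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: UNetDenoiser, schedule: NoiseSchedule) -> None:
    """Single-file archive with weights, schedule and config manifest."""
    cfg = model.config
    manifest = {
        "epochs": cfg.epochs, "learning_rate": cfg.learning_rate,
        "batch_size": cfg.batch_size, "seed": cfg.seed,
        "channels": list(cfg.channels),
        "attention_levels": list(cfg.attention_levels),
        "time_embed_dim": cfg.time_embed_dim,
        "iir_range": list(cfg.iir_range),
    }
    buf = io.BytesIO()
    np.savez(buf, beta=schedule.beta,
             **{f"p{i}": a for i, a in enumerate(model.state_arrays())})
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest))
        zf.writestr("arrays.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[UNetDenoiser, NoiseSchedule]:
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        with zf.open("arrays.npz") as f:
            data = np.load(io.BytesIO(f.read()))
            beta = data["beta"]
            arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    cfg = DdpmTrainConfig(
        epochs=manifest["epochs"], learning_rate=manifest["learning_rate"],
        batch_size=manifest["batch_size"], seed=manifest["seed"],
        channels=tuple(manifest["channels"]),
        attention_levels=tuple(manifest["attention_levels"]),
        time_embed_dim=manifest["time_embed_dim"],
        iir_range=tuple(manifest["iir_range"]),
    )
    model = UNetDenoiser(cfg)
    model.load_state_arrays(arrays)
    return model, NoiseSchedule(beta)
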
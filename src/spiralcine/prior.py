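"""Score-based spatio-temporal diffusion prior: VE SDE, training-clip
pipeline (normalize, random circular frame shift, crop, two-channel complex
encoding), denoising score matching, EMA training loop and checkpoints."""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from spiralcine.nn import Adam, ScoreUNet
from spiralcine.synthetic import CineImage, normalize_series
from spiralcine.operators import extract_crop


@dataclass(frozen=True)
class VESDE:
    """Variance-exploding SDE with geometric noise schedule."""

    sigma_min: float = 0.01
    sigma_max: float = 50.0

    def __post_init__(self):
        if not (self.sigma_max > self.sigma_min > 0):
            raise ValueError("need sigma_max > sigma_min > 0")

    def sigma(self, t) -> np.ndarray:
        """sigma(t) = sigma_min * (sigma_max/sigma_min)**t for t in [0,1]."""
        return self.sigma_min * (self.sigma_max / self.sigma_min) ** np.asarray(t)

    def sigma_grid(self, t_start: float, n_steps: int) -> np.ndarray:
        """Geometrically spaced noise levels from sigma(t_start) down to sigma_min."""
        return np.geomspace(self.sigma(t_start), self.sigma_min, n_steps)


@dataclass(frozen=True)
class ScoreModelConfig:
    base_channels: int = 16
    channel_multipliers: tuple = (1, 2)
    n_frames_train: int = 18
    crop_size: int = 304
    sigma_min: float = 0.01
    sigma_max: float | None = None  # default: 50 * crop_size / 304
    temporal_layers: bool = True
    ema_decay: float = 0.999
    recompute_activations: bool = False
    emb_dim: int = 32
    dtype: str = "float64"

    def __post_init__(self):
        if not self.channel_multipliers:
            raise ValueError("channel_multipliers must be nonempty")

    def sde(self) -> VESDE:
        smax = self.sigma_max
        if smax is None:
            smax = 50.0 * self.crop_size / 304.0
        return VESDE(sigma_min=self.sigma_min, sigma_max=smax)

    def build_model(self, seed: int = 0) -> ScoreUNet:
        return ScoreUNet(
            in_ch=2,
            base=self.base_channels,
            mults=self.channel_multipliers,
            emb_dim=self.emb_dim,
            temporal=self.temporal_layers,
            seed=seed,
            dtype=np.dtype(self.dtype).type,
            recompute=self.recompute_activations,
        )


@dataclass
class TrainBatch:
    """Batch of two-channel clips with per-sample noise levels.

    ``clips`` has shape (batch, n_frames, 2, crop, crop); inputs are
    expected max-magnitude normalized before the channel split.
    """

    clips: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self) -> None:
        self.clips = np.asarray(self.clips)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.clips.ndim != 5 or self.clips.shape[2] != 2:
            raise ValueError("clips must be (batch, frames, 2, crop, crop)")
        if self.sigmas.shape != (self.clips.shape[0],):
            raise ValueError("need one noise level per clip")
        if np.any(self.sigmas <= 0):
            raise ValueError("noise levels must be positive")


@dataclass
class DiffusionState:
    """Reverse-chain iterate: two-channel clip, noise level, step index."""

    x_t: np.ndarray  # (F, 2, H, W) real
    sigma_t: float
    step_index: int = 0
    info: dict = field(default_factory=dict)


# ----------------------------------------------------------------------------
# complex <-> two-channel encoding
# ----------------------------------------------------------------------------


def complex_to_channels(x: np.ndarray) -> np.ndarray:
    """(F, H, W) complex -> (F, 2, H, W) real; channel 0 real, 1 imaginary."""
    return np.stack([x.real, x.imag], axis=1)


def channels_to_complex(x: np.ndarray) -> np.ndarray:
    return x[:, 0] + 1j * x[:, 1]


# ----------------------------------------------------------------------------
# training clips
# ----------------------------------------------------------------------------


def make_training_clip(
    cine: CineImage, config: ScoreModelConfig, rng: np.random.Generator
) -> np.ndarray:
    """One training clip: normalize, random circular frame shift, keep the
    first ``n_frames_train`` frames, central crop, split into two channels."""
    nft = config.n_frames_train
    if cine.n_frames < nft:
        raise ValueError(
            f"cine has {cine.n_frames} frames; need at least {nft}"
        )
    norm = cine if cine.is_normalized else normalize_series(cine)
    shift = int(rng.integers(cine.n_frames))
    rolled = np.roll(norm.data, -shift, axis=0)[:nft]
    cropped = extract_crop(rolled, config.crop_size)
    return complex_to_channels(cropped)


def clip_stream(cine_set: list, config: ScoreModelConfig, seed: int = 0):
    """Infinite generator of training clips drawn from a list of cine."""
    if not cine_set:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    normed = [c if c.is_normalized else normalize_series(c) for c in cine_set]
    while True:
        idx = int(rng.integers(len(normed)))
        yield make_training_clip(normed[idx], config, rng)


# ----------------------------------------------------------------------------
# score and loss
# ----------------------------------------------------------------------------


def score(model: ScoreUNet, state: DiffusionState) -> np.ndarray:
    """s_theta(x_t, sigma_t) = -eps_hat / sigma_t, same shape as x_t."""
    return -model.forward(state.x_t, state.sigma_t) / state.sigma_t


def dsm_loss(
    model: ScoreUNet,
    clip: np.ndarray,
    sde: VESDE,
    rng: np.random.Generator,
    with_grad: bool = False,
):
    """Denoising score-matching loss for one clip.

    With the noise-prediction parametrization the sigma^2-weighted score
    loss sigma^2 ||s_theta + z/sigma||^2 reduces to ||eps_hat - z||^2
    (summed over all entries).
    """
    if not np.all(np.isfinite(clip)):
        raise FloatingPointError("non-finite values in training clip")
    t = rng.uniform()
    sigma = float(sde.sigma(t))
    z = rng.standard_normal(clip.shape)
    x_sigma = clip + sigma * z
    eps = model.forward(x_sigma, sigma)
    resid = eps - z
    loss = float(np.sum(resid**2))
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite DSM loss at sigma={sigma:.3g}")
    if with_grad:
        model.backward(2.0 * resid)
    return loss


# ----------------------------------------------------------------------------
# training
# ----------------------------------------------------------------------------


@dataclass
class TrainResult:
    model: ScoreUNet
    ema_weights: list
    loss_history: np.ndarray
    config: ScoreModelConfig
    seed: int
    step: int

    def ema_model(self) -> ScoreUNet:
        m = self.config.build_model(seed=self.seed)
        m.set_weights(self.ema_weights)
        return m


def train(
    config: ScoreModelConfig,
    clips,
    n_steps: int,
    lr: float = 2e-4,
    seed: int = 0,
    resume: "TrainResult | None" = None,
    log_every: int = 0,
) -> TrainResult:
    """Train (or resume) the score model by DSM with EMA weights.

    ``clips`` is an iterable/generator of (F, 2, H, W) arrays.  Training is
    deterministic given the seed and the stream.  Aborts when the loss
    exceeds 1000x its initial value.
    """
    sde = config.sde()
    if resume is not None:
        model = resume.model
        ema = [w.copy() for w in resume.ema_weights]
        start_step = resume.step
        history = list(resume.loss_history)
    else:
        model = config.build_model(seed=seed)
        ema = model.get_weights()
        start_step = 0
        history = []
    opt = Adam(model.params(), lr=lr)
    rng = np.random.default_rng(np.random.SeedSequence([seed, start_step, 0xD5]))

    it = iter(clips)
    initial = None
    for step in range(start_step, start_step + n_steps):
        clip = np.asarray(next(it), dtype=model.dtype)
        model.zero_grad()
        loss = dsm_loss(model, clip, sde, rng, with_grad=True)
        opt.step()
        d = config.ema_decay
        for w, p in zip(ema, model.params()):
            w *= d
            w += (1 - d) * p.value
        history.append(loss)
        if initial is None:
            initial = loss
        if loss > 1e3 * max(initial, 1e-12):
            raise FloatingPointError(f"training diverged at step {step}")
        if log_every and (step + 1) % log_every == 0:
            print(f"step {step + 1}: loss {loss:.4g}")
    return TrainResult(
        model=model,
        ema_weights=ema,
        loss_history=np.asarray(history),
        config=config,
        seed=seed,
        step=start_step + n_steps,
    )


# ----------------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(path: str, result: TrainResult) -> None:
    """Single-file container: npz with weights + embedded JSON config."""
    cfg = asdict(result.config)
    cfg["channel_multipliers"] = list(cfg["channel_multipliers"])
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": cfg,
        "seed": result.seed,
        "step": result.step,
    }
    arrays = {f"w{i}": w for i, w in enumerate(result.model.get_weights())}
    arrays.update({f"e{i}": w for i, w in enumerate(result.ema_weights)})
    arrays["loss_history"] = result.loss_history
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> TrainResult:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode("utf-8"))
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        cfg = meta["config"]
        cfg["channel_multipliers"] = tuple(cfg["channel_multipliers"])
        cfg["sigma_max"] = cfg.get("sigma_max")
        config = ScoreModelConfig(**cfg)
        n = sum(1 for k in z.files if k.startswith("w"))
        weights = [z[f"w{i}"] for i in range(n)]
        ema = [z[f"e{i}"] for i in range(n)]
        history = z["loss_history"]
    model = config.build_model(seed=meta["seed"])
    model.set_weights(weights)
    return TrainResult(
        model=model,
        ema_weights=ema,
        loss_history=history,
        config=config,
        seed=meta["seed"],
        step=meta["step"],
    )
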
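"""Paired image-level harmonization with a shallow-CNN generator under
WGAN-GP.

One harmonizer maps 2D slices of a source protocol group onto the
reference group.  The generator is a seven-layer shallow CNN with
decreasing kernel sizes (15..3) whose per-layer outputs are aggregated
into a final tanh convolution, blended residually with the input, and
passed through a ramp (clip to [0, 1]).  The critic is a four-layer
strided CNN with spectral normalization scoring images with a single
unbounded scalar, trained with the Wasserstein loss plus gradient
penalty.  The generator minimizes a composite of adversarial,
perceptual, L1, NMSE and (negated, normalized) PSNR terms.

Images entering this module are expected on the [0, 1] scale; use
:func:`hu_to_unit` / :func:`unit_to_hu` at the HU boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ctharmony.nn import autodiff as ad
from ctharmony.nn.layers import Conv2d, Dense, RMSprop, dropout

HU_WINDOW = (-45.0, 125.0)
PSNR_NORM_DB = 100.0


class ShapeError(ValueError):
    pass


class ScalingError(ValueError):
    """Input images are not on the [0, 1] scale."""


class LossError(ValueError):
    """A loss component is non-finite."""


class TrainingDivergedError(RuntimeError):
    def __init__(self, message: str, history: pd.DataFrame):
        super().__init__(message)
        self.history = history


class DataError(ValueError):
    pass


# ------------------------------------------------------------- scaling


def hu_to_unit(x: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    lo, hi = window
    return np.clip((np.asarray(x, float) - lo) / (hi - lo), 0.0, 1.0)


def unit_to_hu(x: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    lo, hi = window
    return np.asarray(x, float) * (hi - lo) + lo


# --------------------------------------------------------------- specs


@dataclass(frozen=True)
class GeneratorSpec:
    kernel_sizes: tuple[int, ...] = (15, 13, 11, 9, 7, 5, 3)
    n_filters: int = 16
    aggregation: str = "concat"  # or "sum"
    final_kernel: int = 3

    def __post_init__(self):
        if self.aggregation not in ("concat", "sum"):
            raise ValueError("aggregation must be 'concat' or 'sum'")


@dataclass(frozen=True)
class CriticSpec:
    filters: tuple[int, ...] = (32, 64, 128, 256)
    kernel_size: int = 5
    stride: int = 2
    leaky_slope: float = 0.2
    dropout: float = 0.25
    spectral_norm: bool = True


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite generator loss.

    total = w_adversarial * L_adv + w_perceptual * L_perc
          + w_l1 * L_L1 + w_nmse * L_nmse + w_psnr * L_psnr
    """

    w_adversarial: float = 1.0
    w_perceptual: float = 1000.0
    w_l1: float = 100.0
    w_nmse: float = 100.0
    w_psnr: float = 100.0
    gp_weight: float = 10.0

    def __post_init__(self):
        if any(
            w < 0
            for w in (
                self.w_adversarial,
                self.w_perceptual,
                self.w_l1,
                self.w_nmse,
                self.w_psnr,
                self.gp_weight,
            )
        ):
            raise ValueError("loss weights must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    steps: int = 300
    learning_rate: float = 0.0002
    lr_decay: float = 0.999  # exponential, per generator step
    batch_size: int = 1
    critic_updates: int = 5
    train_fraction: float = 0.75
    augment: bool = True
    rotation_deg: float = 15.0
    jitter: float = 0.05
    seed: int = 0
    perceptual_backbone: str = "random-conv"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")


# -------------------------------------------------------------- models


class ShallowCNNGenerator:
    """Seven consecutive convolutions (kernels 15..3, stride 1, ReLU);
    all seven outputs aggregated into a final tanh convolution whose
    output is added to the input and clipped to [0, 1] (ramp)."""

    def __init__(self, spec: GeneratorSpec, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.layers: list[Conv2d] = []
        in_ch = 1
        for k in spec.kernel_sizes:
            self.layers.append(Conv2d(in_ch, spec.n_filters, k, rng))
            in_ch = spec.n_filters
        agg_ch = spec.n_filters * (len(spec.kernel_sizes) if spec.aggregation == "concat" else 1)
        self.final = Conv2d(agg_ch, 1, spec.final_kernel, rng)

    @property
    def params(self) -> list[ad.Tensor]:
        out = []
        for layer in self.layers + [self.final]:
            out.extend(layer.params)
        return out

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        h = x
        outputs = []
        for layer in self.layers:
            h = ad.relu(layer(h))
            outputs.append(h)
        if self.spec.aggregation == "concat":
            agg = ad.concat(outputs, axis=1)
        else:
            agg = outputs[0]
            for o in outputs[1:]:
                agg = ad.add(agg, o)
        fusion = ad.tanh(self.final(agg))
        return ad.clip01(ad.add(fusion, x))


class ConvCritic:
    """Strided spectral-normalized CNN producing one unbounded scalar per image."""

    def __init__(self, spec: CriticSpec, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.layers: list[Conv2d] = []
        in_ch = 1
        for f in spec.filters:
            self.layers.append(
                Conv2d(
                    in_ch,
                    f,
                    spec.kernel_size,
                    rng,
                    stride=spec.stride,
                    spectral_norm=spec.spectral_norm,
                )
            )
            in_ch = f
        self.head = Dense(spec.filters[-1], 1, rng)

    @property
    def params(self) -> list[ad.Tensor]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend(self.head.params)
        return out

    def forward(self, x: ad.Tensor, rng: np.random.Generator | None = None) -> ad.Tensor:
        """Score a (B, 1, H, W) batch; pass an rng to enable dropout (train mode)."""
        h = x
        for layer in self.layers:
            h = ad.leaky_relu(layer(h), self.spec.leaky_slope)
            h = dropout(h, self.spec.dropout, rng)
        pooled = ad.mean(h, axis=(2, 3))  # (B, F)
        return ad.reshape(self.head(pooled), (-1,))


class RandomConvBackbone:
    """Fixed-seed random-convolution feature extractor for the perceptual
    loss.  A drop-in stand-in interface: any callable mapping a (B,1,H,W)
    Tensor to a list of feature Tensors (e.g. a pretrained deep network)
    can be plugged in via ``TrainConfig.perceptual_backbone``/the
    ``backbone`` argument."""

    def __init__(self, seed: int = 12345, n_layers: int = 3, n_filters: int = 8):
        rng = np.random.default_rng(seed)
        self.layers = []
        in_ch = 1
        for _ in range(n_layers):
            self.layers.append(Conv2d(in_ch, n_filters, 3, rng, stride=2))
            in_ch = n_filters
        for layer in self.layers:  # frozen features
            layer.weight.requires_grad = False
            layer.bias.requires_grad = False

    def __call__(self, x: ad.Tensor) -> list[ad.Tensor]:
        feats = []
        h = x
        for layer in self.layers:
            h = ad.relu(layer(h))
            feats.append(h)
        return feats


def make_backbone(name: str) -> Callable[[ad.Tensor], list[ad.Tensor]]:
    if name == "random-conv":
        return RandomConvBackbone()
    raise ValueError(f"unknown perceptual backbone {name!r}")


# -------------------------------------------------------------- losses


def _gradient_penalty_tensor(
    critic: Callable[[ad.Tensor], ad.Tensor],
    real: np.ndarray,
    fake: np.ndarray,
    seed: int,
) -> ad.Tensor:
    if real.shape != fake.shape:
        raise ShapeError(f"shape mismatch: real {real.shape} vs fake {fake.shape}")
    rng = np.random.default_rng(seed)
    eps = rng.random((real.shape[0],) + (1,) * (real.ndim - 1))
    x_hat = ad.Tensor(eps * real + (1.0 - eps) * fake, requires_grad=True)
    score = ad.sum_(critic(x_hat))
    (gx,) = ad.grad(score, [x_hat])
    axes = tuple(range(1, real.ndim))
    norm = ad.sqrt(ad.sum_(ad.mul(gx, gx), axis=axes) + ad.Tensor(1e-12))
    return ad.mean(ad.power(norm - ad.Tensor(1.0), 2.0))


def gradient_penalty(
    critic: Callable[[ad.Tensor], ad.Tensor],
    real: np.ndarray,
    fake: np.ndarray,
    seed: int,
) -> float:
    """Mean over samples of (||grad_x critic(x_interp)||_2 - 1)^2 (unweighted)."""
    return float(_gradient_penalty_tensor(critic, np.asarray(real, float), np.asarray(fake, float), seed).data)


LOSS_COMPONENTS = ("adversarial", "perceptual", "l1", "nmse", "psnr")


def generator_loss(terms: Mapping[str, "ad.Tensor | float"], weights: LossWeights):
    """Weighted composite generator loss; Tensor in, Tensor out."""
    w = {
        "adversarial": weights.w_adversarial,
        "perceptual": weights.w_perceptual,
        "l1": weights.w_l1,
        "nmse": weights.w_nmse,
        "psnr": weights.w_psnr,
    }
    total = None
    for name in LOSS_COMPONENTS:
        term = terms[name]
        value = float(term.data) if isinstance(term, ad.Tensor) else float(term)
        if not np.isfinite(value):
            raise LossError(f"non-finite loss component: {name}")
        piece = term * w[name] if isinstance(term, ad.Tensor) else term * w[name]
        total = piece if total is None else total + piece
    return total


def _loss_terms(fake: ad.Tensor, target: np.ndarray, critic_score, backbone) -> dict:
    t = ad.Tensor(target)
    diff = ad.sub(fake, t)
    l1 = ad.mean(ad.abs_(diff))
    nmse = ad.div(ad.sum_(ad.mul(diff, diff)), ad.Tensor(np.array(float((target**2).sum()) + 1e-12)))
    mse = ad.mean(ad.mul(diff, diff))
    psnr_db = ad.mul(ad.log(mse + ad.Tensor(1e-10)), ad.Tensor(np.array(-10.0 / np.log(10.0))))
    l_psnr = ad.mul(psnr_db, ad.Tensor(np.array(-1.0 / PSNR_NORM_DB)))
    feats_f = backbone(fake)
    feats_t = backbone(t)
    perc = None
    for ff, ft in zip(feats_f, feats_t):
        d = ad.sub(ff, ft)
        piece = ad.mean(ad.mul(d, d))
        perc = piece if perc is None else ad.add(perc, piece)
    perc = ad.mul(perc, ad.Tensor(np.array(1.0 / len(feats_f))))
    return {"adversarial": critic_score, "perceptual": perc, "l1": l1, "nmse": nmse, "psnr": l_psnr}


# ------------------------------------------------------------ training


@dataclass
class HarmonizerModel:
    """Trained generator/critic pair for one source -> reference mapping."""

    generator: ShallowCNNGenerator
    critic: ConvCritic
    weights: LossWeights
    config: TrainConfig
    history: pd.DataFrame
    train_indices: list[int]
    test_indices: list[int]
    source_group: int | None = None
    reference_group: int | None = None

    def save(self, path) -> None:
        payload = {
            "weights": asdict(self.weights),
            "config": asdict(self.config),
            "generator_spec": asdict(self.generator.spec),
            "critic_spec": asdict(self.critic.spec),
            "source_group": self.source_group,
            "reference_group": self.reference_group,
            "train_indices": self.train_indices,
            "test_indices": self.test_indices,
            "generator_params": [p.data.tolist() for p in self.generator.params],
            "critic_params": [p.data.tolist() for p in self.critic.params],
            "history": self.history.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "HarmonizerModel":
        with open(path) as fh:
            d = json.load(fh)
        config = TrainConfig(**d["config"])
        weights = LossWeights(**d["weights"])
        gen = ShallowCNNGenerator(GeneratorSpec(**{**d["generator_spec"], "kernel_sizes": tuple(d["generator_spec"]["kernel_sizes"])}), config.seed)
        crit = ConvCritic(CriticSpec(**{**d["critic_spec"], "filters": tuple(d["critic_spec"]["filters"])}), config.seed + 1)
        for p, v in zip(gen.params, d["generator_params"]):
            p.data = np.asarray(v, float)
        for p, v in zip(crit.params, d["critic_params"]):
            p.data = np.asarray(v, float)
        return cls(
            gen,
            crit,
            weights,
            config,
            pd.DataFrame(d["history"]),
            d["train_indices"],
            d["test_indices"],
            d["source_group"],
            d["reference_group"],
        )


def _augment_pair(src: np.ndarray, tgt: np.ndarray, config: TrainConfig, rng) -> tuple:
    angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
    if abs(angle) > 1e-6:
        src = ndimage.rotate(src, angle, reshape=False, order=1, mode="nearest")
        tgt = ndimage.rotate(tgt, angle, reshape=False, order=1, mode="nearest")
    if rng.random() < 0.5:
        src, tgt = src[::-1], tgt[::-1]
    if rng.random() < 0.5:
        src, tgt = src[:, ::-1], tgt[:, ::-1]
    jit = rng.uniform(-config.jitter, config.jitter)
    return np.clip(src + jit, 0.0, 1.0), np.clip(tgt + jit, 0.0, 1.0)


def train_harmonizer(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig | None = None,
    weights: LossWeights | None = None,
    generator_spec: GeneratorSpec | None = None,
    critic_spec: CriticSpec | None = None,
    backbone: Callable | None = None,
    source_group: int | None = None,
    reference_group: int | None = None,
) -> HarmonizerModel:
    """Train one source->reference harmonizer on aligned (source, target)
    2D slice pairs scaled to [0, 1].

    Alternates ``critic_updates`` WGAN-GP critic steps with one generator
    step under the composite loss; records the full per-step loss history.
    Deterministic for a fixed ``config.seed``.
    """
    config = config or TrainConfig()
    weights = weights or LossWeights()
    if len(pairs) == 0:
        raise DataError("empty pair set")
    for s, t in pairs:
        s, t = np.asarray(s), np.asarray(t)
        if s.shape != t.shape or s.ndim != 2:
            raise ShapeError("pairs must be aligned 2D slices of equal shape")
        if s.min() < -1e-6 or s.max() > 1 + 1e-6 or t.min() < -1e-6 or t.max() > 1 + 1e-6:
            raise ScalingError("images must be scaled to [0, 1]")

    rng = np.random.default_rng(config.seed)
    gen = ShallowCNNGenerator(generator_spec or GeneratorSpec(), config.seed)
    crit = ConvCritic(critic_spec or CriticSpec(), config.seed + 1)
    backbone = backbone or make_backbone(config.perceptual_backbone)

    order = rng.permutation(len(pairs))
    n_train = max(1, int(round(config.train_fraction * len(pairs))))
    train_idx = [int(i) for i in order[:n_train]]
    test_idx = [int(i) for i in order[n_train:]]

    opt_g = RMSprop(gen.params, config.learning_rate)
    opt_c = RMSprop(crit.params, config.learning_rate)

    def sample_batch():
        out_s, out_t = [], []
        for _ in range(config.batch_size):
            i = train_idx[rng.integers(len(train_idx))]
            s, t = np.asarray(pairs[i][0], float), np.asarray(pairs[i][1], float)
            if config.augment:
                s, t = _augment_pair(s, t, config, rng)
            out_s.append(s)
            out_t.append(t)
        return np.stack(out_s)[:, None], np.stack(out_t)[:, None]

    records = []
    for step in range(config.steps):
        lr = config.learning_rate * config.lr_decay**step

        critic_loss_val = gp_val = float("nan")
        for _ in range(config.critic_updates):
            src_b, tgt_b = sample_batch()
            fake = ad.Tensor(gen.forward(ad.Tensor(src_b)).data)  # detached
            drop_rng = np.random.default_rng(rng.integers(2**31))

            def critic_fn(x):
                return crit.forward(x, rng=drop_rng)

            gp = _gradient_penalty_tensor(critic_fn, tgt_b, fake.data, int(rng.integers(2**31)))
            c_loss = (
                ad.mean(critic_fn(fake))
                - ad.mean(critic_fn(ad.Tensor(tgt_b)))
                + ad.Tensor(np.array(weights.gp_weight)) * gp
            )
            grads = ad.grad(c_loss, crit.params)
            opt_c.step(grads, lr=lr)
            critic_loss_val, gp_val = float(c_loss.data), float(gp.data)

        src_b, tgt_b = sample_batch()
        fake = gen.forward(ad.Tensor(src_b))
        drop_rng = np.random.default_rng(rng.integers(2**31))
        adv = ad.neg(ad.mean(crit.forward(fake, rng=drop_rng)))
        terms = _loss_terms(fake, tgt_b, adv, backbone)
        total = generator_loss(terms, weights)
        grads = ad.grad(total, gen.params)
        opt_g.step(grads, lr=lr)

        rec = {
            "step": step,
            "l_total": float(total.data),
            "l_adversarial": float(terms["adversarial"].data),
            "l_perceptual": float(terms["perceptual"].data),
            "l_l1": float(terms["l1"].data),
            "l_nmse": float(terms["nmse"].data),
            "l_psnr": float(terms["psnr"].data),
            "critic_loss": critic_loss_val,
            "gradient_penalty": gp_val,
            "lr": lr,
        }
        records.append(rec)
        if not np.isfinite(rec["l_total"]):
            raise TrainingDivergedError(
                f"non-finite generator loss at step {step}", pd.DataFrame(records)
            )

    return HarmonizerModel(
        gen,
        crit,
        weights,
        config,
        pd.DataFrame(records),
        train_idx,
        test_idx,
        source_group,
        reference_group,
    )


# ------------------------------------------------------------ inference


def harmonize_images(model: HarmonizerModel, images) -> np.ndarray:
    """Apply the trained generator slice-wise.

    Accepts a single 2D slice, a stack of slices (N, H, W), or a 3D
    volume (H, W, Z) processed along the last axis.  Inputs must be on
    the [0, 1] scale; outputs match the input shape and stay in [0, 1].
    Inference is deterministic (no dropout).
    """
    arr = np.asarray(images, dtype=float)
    if arr.min() < -1e-6 or arr.max() > 1 + 1e-6:
        raise ScalingError("images must be scaled to [0, 1]")
    if arr.ndim == 2:
        return _infer_batch(model, arr[None])[0]
    if arr.ndim == 3:
        # heuristic: (N, H, W) stacks keep slices square in the last two axes;
        # volumes are processed along the last axis
        if arr.shape[1] == arr.shape[2] and arr.shape[0] != arr.shape[1]:
            return _infer_batch(model, arr)
        stack = np.moveaxis(arr, 2, 0)
        out = _infer_batch(model, stack)
        return np.moveaxis(out, 0, 2)
    raise ShapeError(f"expected 2D or 3D input, got shape {arr.shape}")


def _infer_batch(model: HarmonizerModel, stack: np.ndarray) -> np.ndarray:
    out = np.empty_like(stack)
    for i, sl in enumerate(stack):
        out[i] = model.generator.forward(ad.Tensor(sl[None, None])).data[0, 0]
    return out


class GANHarmonizer:
    """sklearn-style wrapper: ``fit(pairs)`` trains, ``transform(images)``
    harmonizes."""

    def __init__(
        self,
        config: TrainConfig | None = None,
        weights: LossWeights | None = None,
        generator_spec: GeneratorSpec | None = None,
        critic_spec: CriticSpec | None = None,
    ):
        self.config = config
        self.weights = weights
        self.generator_spec = generator_spec
        self.critic_spec = critic_spec

    def get_params(self, deep: bool = True) -> dict:
        return {
            "config": self.config,
            "weights": self.weights,
            "generator_spec": self.generator_spec,
            "critic_spec": self.critic_spec,
        }

    def set_params(self, **params) -> "GANHarmonizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, pairs, source_group=None, reference_group=None) -> "GANHarmonizer":
        self.model_ = train_harmonizer(
            pairs,
            self.config,
            self.weights,
            self.generator_spec,
            self.critic_spec,
            source_group=source_group,
            reference_group=reference_group,
        )
        return self

    def transform(self, images) -> np.ndarray:
        return harmonize_images(self.model_, images)
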
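"""Conv/dense layers, dropout and spectral normalization."""

from __future__ import annotations

import numpy as np

from ctharmony.nn import autodiff as ad

SPECTRAL_EPS = 1e-12


class Conv2d:
    """2D convolution with optional exact spectral normalization.

    Spectral normalization divides the weight by its largest singular
    value (computed exactly on the (out, in*kh*kw) matrix), so the
    normalized weight always has spectral norm 1.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
        spectral_norm: bool = False,
    ):
        k = kernel_size
        scale = np.sqrt(2.0 / (in_channels * k * k))
        self.weight = ad.parameter(rng.normal(0.0, scale, size=(out_channels, in_channels, k, k)))
        self.bias = ad.parameter(np.zeros(out_channels))
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.spectral_norm = spectral_norm

    @property
    def params(self) -> list[ad.Tensor]:
        return [self.weight, self.bias]

    def normalized_weight(self) -> ad.Tensor:
        if not self.spectral_norm:
            return self.weight
        mat = self.weight.data.reshape(self.weight.data.shape[0], -1)
        sigma = np.linalg.norm(mat, 2)
        return ad.mul(self.weight, ad.Tensor(np.array(1.0 / (sigma + SPECTRAL_EPS))))

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return ad.conv2d(
            x, self.normalized_weight(), self.bias, stride=self.stride, padding=self.padding
        )


class Dense:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / in_features)
        self.weight = ad.parameter(rng.normal(0.0, scale, size=(in_features, out_features)))
        self.bias = ad.parameter(np.zeros(out_features))

    @property
    def params(self) -> list[ad.Tensor]:
        return [self.weight, self.bias]

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return ad.add(ad.matmul(x, self.weight), ad.reshape(self.bias, (1, -1)))


def dropout(x: ad.Tensor, rate: float, rng: np.random.Generator | None) -> ad.Tensor:
    """Inverted dropout; identity when rng is None (eval mode) or rate 0."""
    if rng is None or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return ad.mul(x, ad.Tensor(mask))


class RMSprop:
    """RMSprop with optional exponential learning-rate decay."""

    def __init__(self, params: list[ad.Tensor], lr: float, rho: float = 0.9, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p.data) for p in params]

    def step(self, grads: list[ad.Tensor], lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        for p, g, c in zip(self.params, grads, self.cache):
            gd = g.data
            c *= self.rho
            c += (1.0 - self.rho) * gd**2
            p.data -= lr * gd / (np.sqrt(c) + self.eps)
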
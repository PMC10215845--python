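"""1D self-organizing operational (Self-ONN) layers.

A generative neuron replaces the inner product of a convolution with a
learnable q-th order polynomial of the input,

    f(x) = b + w1*x + w2*x^2 + ... + wq*x^q,

lifted to multichannel 1D cross-correlation: the input is raised to each
elementwise power k = 1..q, correlated with a separate kernel bank, and the
banks are summed with one bias per output channel. q = 1 recovers an
ordinary convolution layer.

Two routes compute the same contract: :func:`selfonn_forward` (vectorized,
the one the network uses) and :func:`selfonn_oracle` (explicit nested loops,
kept free of any shared numerics so it can serve as an independent check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .exceptions import ContractError


@dataclass(frozen=True)
class SelfOnnSpec:
    """Shape hyperparameters of one Self-ONN layer."""

    in_channels: int
    out_channels: int
    kernel_size: int
    q: int = 3
    padding: int = field(default=-1)

    def __post_init__(self):
        if self.q < 1:
            raise ValueError(f"q must be >= 1, got {self.q}")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for same-length output")
        if self.padding < 0:
            object.__setattr__(self, "padding", (self.kernel_size - 1) // 2)


@dataclass
class SelfOnnParams:
    """Learnable state of one Self-ONN layer.

    ``weights`` stacks one kernel bank per polynomial power:
    shape (q, out_channels, in_channels, kernel_size). ``bias`` is per
    output channel.
    """

    weights: np.ndarray
    bias: np.ndarray

    def validate(self, spec: SelfOnnSpec) -> None:
        expected = (spec.q, spec.out_channels, spec.in_channels, spec.kernel_size)
        if tuple(self.weights.shape) != expected:
            raise ContractError(
                f"weights shape {self.weights.shape} != spec shape {expected}"
            )
        if tuple(self.bias.shape) != (spec.out_channels,):
            raise ContractError(
                f"bias shape {self.bias.shape} != ({spec.out_channels},)"
            )
        if not (np.isfinite(self.weights).all() and np.isfinite(self.bias).all()):
            raise ContractError("non-finite parameter values")


def init_selfonn_params(
    spec: SelfOnnSpec, rng: np.random.Generator, dtype=np.float32
) -> SelfOnnParams:
    """Variance-scaled init, with bank k damped by 1/k!.

    The k = 1 bank gets a Glorot-style scale; higher-power banks start
    progressively smaller so that early activations sit in tanh's linear
    range and the layer behaves near-linearly at initialization.
    """
    fan_in = spec.in_channels * spec.kernel_size
    fan_out = spec.out_channels * spec.kernel_size
    base = math.sqrt(2.0 / (fan_in + fan_out))
    w = np.empty(
        (spec.q, spec.out_channels, spec.in_channels, spec.kernel_size), dtype=dtype
    )
    for k in range(1, spec.q + 1):
        scale = base / math.factorial(k)
        w[k - 1] = rng.normal(0.0, scale, size=w.shape[1:]).astype(dtype)
    b = np.zeros(spec.out_channels, dtype=dtype)
    return SelfOnnParams(weights=w, bias=b)


def selfonn_forward(
    x: np.ndarray, spec: SelfOnnSpec, params: SelfOnnParams
) -> np.ndarray:
    """Vectorized generative-neuron forward pass.

    ``x`` is (in_channels, L) or (N, in_channels, L); the output matches,
    with out_channels channels and unchanged length (zero 'same' padding).
    """
    params.validate(spec)
    x = np.asarray(x)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.shape[1] != spec.in_channels:
        raise ContractError(
            f"input has {x.shape[1]} channels, spec expects {spec.in_channels}"
        )
    y = None
    for k in range(1, spec.q + 1):
        term = ad.correlate1d_same(x**k, params.weights[k - 1])
        y = term if y is None else y + term
    y += params.bias[None, :, None]
    return y[0] if squeeze else y


def selfonn_oracle(
    x: np.ndarray, spec: SelfOnnSpec, params: SelfOnnParams
) -> np.ndarray:
    """Nested-loop reference for :func:`selfonn_forward` (no shared numerics)."""
    params.validate(spec)
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    n, c_in, L = x.shape
    K = spec.kernel_size
    p = spec.padding
    out = np.zeros((n, spec.out_channels, L))
    for i in range(n):
        for o in range(spec.out_channels):
            for t in range(L):
                acc = float(params.bias[o])
                for k in range(1, spec.q + 1):
                    for c in range(c_in):
                        for j in range(K):
                            src = t + j - p
                            if 0 <= src < L:
                                acc += float(params.weights[k - 1, o, c, j]) * (
                                    float(x[i, c, src]) ** k
                                )
                out[i, o, t] = acc
    return out[0] if squeeze else out


class SelfOnn1d:
    """Autodiff Self-ONN layer module used by the network.

    Internally stores the q kernel banks stacked along the input-channel
    axis, shape (out, q*in, kernel), so that one GEMM computes all powers;
    :meth:`get_params` / :meth:`set_params` convert to the bank-major
    :class:`SelfOnnParams` layout.
    """

    def __init__(
        self,
        spec: SelfOnnSpec,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        self.spec = spec
        if rng is None:
            rng = np.random.default_rng(0)
        p = init_selfonn_params(spec, rng, dtype=dtype)
        # (q, O, C, K) -> (O, q*C, K), power-major blocks along axis 1
        w_int = p.weights.transpose(1, 0, 2, 3).reshape(
            spec.out_channels, spec.q * spec.in_channels, spec.kernel_size
        )
        self.weight = ad.parameter(w_int, dtype=dtype)
        self.bias = ad.parameter(p.bias, dtype=dtype)

    def parameters(self) -> list[ad.Tensor]:
        return [self.weight, self.bias]

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return ad.selfonn_conv1d(x, self.weight, self.bias, self.spec.q)

    def get_params(self) -> SelfOnnParams:
        s = self.spec
        w = self.weight.data.reshape(
            s.out_channels, s.q, s.in_channels, s.kernel_size
        ).transpose(1, 0, 2, 3)
        return SelfOnnParams(weights=w.copy(), bias=self.bias.data.copy())

    def set_params(self, params: SelfOnnParams) -> None:
        s = self.spec
        params.validate(s)
        self.weight.data[...] = params.weights.transpose(1, 0, 2, 3).reshape(
            s.out_channels, s.q * s.in_channels, s.kernel_size
        )
        self.bias.data[...] = params.bias

    def num_parameters(self) -> int:
        return self.weight.data.size + self.bias.data.size
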
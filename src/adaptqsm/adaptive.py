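"""Filter manifold network (FMN) and adaptive convolution.

An adaptive convolution layer does not store its filter weights: a small
fully connected network (the FMN) maps the acquisition side information
s = (vx, vy, vz, ox, oy, oz) to the full weight tensor of the convolution.
As the voxel size or B0 orientation changes, the generated filters sweep a
low-dimensional manifold in weight space, so a single trained model adapts
its feature extraction to the acquisition geometry instead of assuming
1 mm isotropic axial data.

The default FMN is four linear layers 6 -> 12 -> 48 -> 196 -> 13824 with
ELU between the hidden layers; the 13,824 outputs are reshaped to the
(32, 16, 3, 3, 3) weight tensor of the 16 -> 32 convolution in the first
encoder block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from . import nn
from .dipole import ContractError
from .nn import Linear, Module, Parameter, Tensor


@dataclass(frozen=True)
class FilterManifoldSpec:
    """Layer plan of a filter manifold network."""

    input_size: int = 6
    hidden_sizes: Tuple[int, ...] = (12, 48, 196)
    kernel_shape: Tuple[int, int, int, int, int] = (32, 16, 3, 3, 3)

    def __post_init__(self) -> None:
        if self.input_size <= 0:
            raise ValueError("input size must be positive")
        if any(b <= a for a, b in zip(self.hidden_sizes, self.hidden_sizes[1:])):
            raise ValueError(f"hidden sizes must be strictly increasing, got {self.hidden_sizes}")
        if len(self.kernel_shape) != 5 or any(n <= 0 for n in self.kernel_shape):
            raise ValueError(f"kernel shape must be 5 positive dims, got {self.kernel_shape}")

    @property
    def output_size(self) -> int:
        return int(np.prod(self.kernel_shape))

    def layer_sizes(self) -> Tuple[int, ...]:
        return (self.input_size, *self.hidden_sizes, self.output_size)

    def parameter_count(self) -> int:
        """Sum of (fan_in + 1) * fan_out over the linear layers."""
        sizes = self.layer_sizes()
        return sum((a + 1) * b for a, b in zip(sizes, sizes[1:]))


class FilterManifoldNetwork(Module):
    """Fully connected network mapping side information to filter weights.

    The final layer's bias is initialized to a He-style random kernel and
    its weights to a small scale, so the generated filters start out as a
    conventional random initialization with a weak, learnable dependence on
    the side information.
    """

    def __init__(self, spec: FilterManifoldSpec, rng: np.random.Generator,
                 elu_alpha: float = 1.0):
        super().__init__()
        self.spec = spec
        self.elu_alpha = elu_alpha
        sizes = spec.layer_sizes()
        self.layers = [
            Linear(a, b, rng) for a, b in zip(sizes[:-2], sizes[1:-1])
        ]
        final = Linear(sizes[-2], sizes[-1], rng, init_scale=0.05 * math.sqrt(2.0 / sizes[-2]))
        conv_fan_in = spec.kernel_shape[1] * spec.kernel_shape[2] * spec.kernel_shape[3] * spec.kernel_shape[4]
        final.bias.data = rng.normal(0.0, math.sqrt(2.0 / conv_fan_in), size=sizes[-1])
        self.layers.append(final)

    def __call__(self, side_info: Sequence[float]) -> Tensor:
        s = np.asarray(side_info, dtype=float).reshape(1, -1)
        if s.shape[1] != self.spec.input_size:
            raise ContractError(f"side info must have length {self.spec.input_size}, got {s.shape[1]}")
        h = Tensor(s)
        for layer in self.layers[:-1]:
            h = nn.elu(layer(h), self.elu_alpha)
        out = self.layers[-1](h)
        return nn.reshape(out, self.spec.kernel_shape)

    def kernel(self, side_info: Sequence[float]) -> np.ndarray:
        """Generated filter weights as a plain array (no tape)."""
        return self(side_info).data.copy()


def build_fmn(
    spec: FilterManifoldSpec = FilterManifoldSpec(),
    rng: np.random.Generator | int | None = None,
) -> FilterManifoldNetwork:
    """Construct a filter manifold network from its spec."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return FilterManifoldNetwork(spec, rng)


class AdaptiveConv3d(Module):
    """3D convolution whose weights are generated per call by an FMN.

    A static trainable bias per output channel is kept alongside the
    generated weights.  All patches of one forward pass share the same side
    information (they come from the same acquisition).
    """

    def __init__(self, spec: FilterManifoldSpec, rng: np.random.Generator):
        super().__init__()
        self.fmn = FilterManifoldNetwork(spec, rng)
        self.bias = Parameter(np.zeros(spec.kernel_shape[0]))

    @property
    def in_channels(self) -> int:
        return self.fmn.spec.kernel_shape[1]

    @property
    def out_channels(self) -> int:
        return self.fmn.spec.kernel_shape[0]

    def __call__(self, x: Tensor, side_info: Sequence[float]) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ContractError(
                f"adaptive layer expects {self.in_channels} input channels, got {x.shape[1]}"
            )
        w = self.fmn(side_info)
        return nn.conv3d(x, w, self.bias)


def adaptive_forward(x: Tensor, side_info: Sequence[float], layer: AdaptiveConv3d) -> Tensor:
    """Convolve feature maps with the FMN-generated kernel for ``side_info``."""
    return layer(x, side_info)


def kernel_sensitivity(
    fmn: FilterManifoldNetwork, side_info: Sequence[float], delta: Sequence[float]
) -> float:
    """||w(s + delta) - w(s)|| / ||delta||: finite-difference slope of the
    filter manifold along ``delta`` (diagnostic for manifold inspection)."""
    delta = np.asarray(delta, dtype=float)
    nd = float(np.linalg.norm(delta))
    if nd <= 0:
        raise ValueError("delta must be non-zero")
    s = np.asarray(side_info, dtype=float)
    w0 = fmn.kernel(s)
    w1 = fmn.kernel(s + delta)
    return float(np.linalg.norm(w1 - w0) / nd)
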
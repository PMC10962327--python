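"""Adaptive 3D U-Net for field-to-susceptibility inversion.

The model maps a local-field patch (ppm) plus the acquisition side
information to a susceptibility patch of identical shape.  It is a standard
3D U-Net: two 3x3x3 convolutions per block (channels doubling on the
second), batch normalization and ELU after every convolution, 2x2x2 max
pooling on the way down, 2x2x2 transposed convolutions on the way up, and
encoder-decoder concatenation skips.  A global input-to-output residual
addition makes the network learn the difference between the field
perturbation and the susceptibility map.

Three variants share this skeleton:

* ``adaptive`` (default): the second convolution of the first encoder block
  (16 -> 32) is an adaptive convolution whose weights come from a filter
  manifold network fed with the side information.
* ``conventional``: the same network with a static 16 -> 32 convolution; it
  ignores the side information.
* ``adaptive_encoder``: every encoder and bottleneck convolution (10 in the
  default depth) is adaptive, each with its own FMN.

The default configuration counts ~8.3 million trainable parameters
including the FMN: channels double per encoder level up to a cap of 256,
and the decoder is a lightweight fixed-width design (see docs/methods.md
for why this split).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .adaptive import AdaptiveConv3d, FilterManifoldSpec
from .dipole import (
    AcquisitionGeometry,
    ContractError,
    LocalFieldVolume,
    SusceptibilityVolume,
)
from .nn import BatchNorm3d, Conv3d, ConvTranspose3d, Module, Tensor


@dataclass(frozen=True)
class AdaptiveUNetSpec:
    """Architecture hyperparameters of the (adaptive) 3D U-Net."""

    initial_channels: int = 16
    levels: int = 4
    channel_cap: int = 256
    decoder_channels: int = 16
    variant: str = "adaptive"  # adaptive | conventional | adaptive_encoder
    fmn_hidden: Tuple[int, ...] = (12, 48, 196)
    elu_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in ("adaptive", "conventional", "adaptive_encoder"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.initial_channels < 1 or self.levels < 1:
            raise ValueError("initial channels and levels must be >= 1")

    @property
    def divisor(self) -> int:
        return 2**self.levels

    def encoder_plan(self) -> List[Tuple[int, int, int]]:
        """(in, mid, out) channels of each encoder block plus bottleneck."""
        plan = []
        c_in, c = 1, self.initial_channels
        for _ in range(self.levels + 1):  # encoder levels + bottleneck
            c_out = min(2 * c, self.channel_cap)
            plan.append((c_in, c, c_out))
            c_in = c_out
            c = c_out
        return plan

    def fingerprint(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


class _EncoderBlock(Module):
    def __init__(self, c_in: int, c_mid: int, c_out: int, spec: AdaptiveUNetSpec,
                 rng: np.random.Generator, adaptive_first: bool, adaptive_second: bool):
        super().__init__()

        def make_conv(ci, co, adaptive):
            if adaptive:
                return AdaptiveConv3d(
                    FilterManifoldSpec(hidden_sizes=spec.fmn_hidden, kernel_shape=(co, ci, 3, 3, 3)),
                    rng,
                )
            return Conv3d(ci, co, rng)

        self.conv1 = make_conv(c_in, c_mid, adaptive_first)
        self.bn1 = BatchNorm3d(c_mid)
        self.conv2 = make_conv(c_mid, c_out, adaptive_second)
        self.bn2 = BatchNorm3d(c_out)
        self.alpha = spec.elu_alpha

    def __call__(self, x: Tensor, s) -> Tensor:
        def run(conv, h):
            return conv(h, s) if isinstance(conv, AdaptiveConv3d) else conv(h)

        h = nn.elu(self.bn1(run(self.conv1, x)), self.alpha)
        return nn.elu(self.bn2(run(self.conv2, h)), self.alpha)


class _DecoderBlock(Module):
    def __init__(self, c_low: int, c_skip: int, c_out: int, spec: AdaptiveUNetSpec,
                 rng: np.random.Generator):
        super().__init__()
        self.up = ConvTranspose3d(c_low, c_out, rng)
        self.conv1 = Conv3d(c_skip + c_out, c_out, rng)
        self.bn1 = BatchNorm3d(c_out)
        self.conv2 = Conv3d(c_out, c_out, rng)
        self.bn2 = BatchNorm3d(c_out)
        self.alpha = spec.elu_alpha

    def __call__(self, low: Tensor, skip: Tensor) -> Tensor:
        h = nn.concat([skip, self.up(low)], axis=1)
        h = nn.elu(self.bn1(self.conv1(h)), self.alpha)
        return nn.elu(self.bn2(self.conv2(h)), self.alpha)


class AdaptiveUNet(Module):
    """U-Net with optional adaptive (FMN-generated) encoder convolutions."""

    def __init__(self, spec: AdaptiveUNetSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        plan = spec.encoder_plan()
        enc_adaptive = {
            "adaptive": lambda b, j: b == 0 and j == 1,
            "conventional": lambda b, j: False,
            "adaptive_encoder": lambda b, j: True,
        }[spec.variant]
        self.encoder = [
            _EncoderBlock(ci, cm, co, spec, rng, enc_adaptive(b, 0), enc_adaptive(b, 1))
            for b, (ci, cm, co) in enumerate(plan)
        ]
        dec = spec.decoder_channels
        self.decoder = []
        c_low = plan[-1][2]
        for lev in range(spec.levels - 1, -1, -1):
            c_skip = plan[lev][2]
            self.decoder.append(_DecoderBlock(c_low, c_skip, dec, spec, rng))
            c_low = dec
        self.final = Conv3d(dec, 1, rng, zero_init=True)

    def __call__(self, x: Tensor, side_info: Sequence[float]) -> Tensor:
        if x.data.ndim != 5 or x.shape[1] != 1:
            raise ContractError(f"input must be (B, 1, D, H, W), got {x.shape}")
        div = self.spec.divisor
        if any(n % div for n in x.shape[2:]):
            raise ContractError(
                f"spatial dims {x.shape[2:]} must be divisible by {div}; pad the input"
            )
        skips = []
        h = x
        for block in self.encoder[:-1]:
            h = block(h, side_info)
            skips.append(h)
            h = nn.maxpool3d(h)
        h = self.encoder[-1](h, side_info)
        for block, skip in zip(self.decoder, reversed(skips)):
            h = block(h, skip)
        return nn.add(self.final(h), x)

    # --- parameter grouping helpers -------------------------------------
    def fmn_parameter_names(self) -> List[str]:
        """Parameters of the adaptive layer(s): the FMN weights and the
        static bias of each adaptive convolution."""
        names = []
        for name, _ in self.named_parameters():
            if ".fmn." in name:
                names.append(name)
            elif name.endswith(".bias") and ".conv" in name:
                # static bias belonging to an adaptive conv
                owner = name.rsplit(".bias", 1)[0]
                if any(n.startswith(owner + ".fmn.") for n, _ in self.named_parameters()):
                    names.append(name)
        return names

    def decoder_parameter_names(self) -> List[str]:
        return [n for n, _ in self.named_parameters()
                if n.startswith("decoder.") or n.startswith("final.")]

    def adaptive_layer_count(self) -> int:
        return sum(
            isinstance(conv, AdaptiveConv3d)
            for block in self.encoder
            for conv in (block.conv1, block.conv2)
        )


def build_adaptive_unet(
    spec: AdaptiveUNetSpec = AdaptiveUNetSpec(), seed: int = 0
) -> AdaptiveUNet:
    if spec.variant != "adaptive":
        spec = AdaptiveUNetSpec(**{**asdict(spec), "variant": "adaptive"})
    return AdaptiveUNet(spec, np.random.default_rng(seed))


def build_conventional_unet(
    spec: AdaptiveUNetSpec = AdaptiveUNetSpec(variant="conventional"), seed: int = 0
) -> AdaptiveUNet:
    if spec.variant != "conventional":
        spec = AdaptiveUNetSpec(**{**asdict(spec), "variant": "conventional"})
    return AdaptiveUNet(spec, np.random.default_rng(seed))


def build_adaptive_encoder_unet(
    spec: AdaptiveUNetSpec = AdaptiveUNetSpec(variant="adaptive_encoder"), seed: int = 0
) -> AdaptiveUNet:
    if spec.variant != "adaptive_encoder":
        spec = AdaptiveUNetSpec(**{**asdict(spec), "variant": "adaptive_encoder"})
    return AdaptiveUNet(spec, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Checkpoints


@dataclass
class Checkpoint:
    """Trained parameters plus the spec fingerprint they belong to."""

    spec: AdaptiveUNetSpec
    state: Dict[str, np.ndarray]
    metadata: Dict = field(default_factory=dict)

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "spec": asdict(self.spec),
            "fingerprint": self.spec.fingerprint(),
            "metadata": self.metadata,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            spec_dict = meta["spec"]
            spec_dict["fmn_hidden"] = tuple(spec_dict["fmn_hidden"])
            spec = AdaptiveUNetSpec(**spec_dict)
            if spec.fingerprint() != meta["fingerprint"]:
                raise ValueError("checkpoint fingerprint does not match its spec")
            state = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(spec=spec, state=state, metadata=meta.get("metadata", {}))

    def build_model(self) -> AdaptiveUNet:
        model = AdaptiveUNet(self.spec, np.random.default_rng(0))
        model.load_state_dict(self.state)
        return model


def checkpoint_from_model(model: AdaptiveUNet, **metadata) -> Checkpoint:
    return Checkpoint(spec=model.spec, state=model.state_dict(), metadata=dict(metadata))


# ---------------------------------------------------------------------------
# Inference on whole volumes


def infer(
    field: LocalFieldVolume,
    geometry: Optional[AcquisitionGeometry] = None,
    checkpoint: Optional[Checkpoint] = None,
    model: Optional[AdaptiveUNet] = None,
) -> SusceptibilityVolume:
    """Apply a trained model to a whole local-field volume.

    The volume is reflect-padded up to the next multiple of the model's
    downsampling factor, processed in evaluation mode with the geometry's
    side information, cropped back, and masked if the field carries a mask.
    """
    if geometry is None:
        geometry = field.geometry
    if geometry is None:
        raise ContractError(
            "no acquisition geometry available: pass voxel size and B0 direction"
        )
    if model is None:
        if checkpoint is None:
            raise ValueError("provide a checkpoint or a model")
        model = checkpoint.build_model()
    model.eval()
    div = model.spec.divisor
    values = field.values
    pads = [(0, (-n) % div) for n in values.shape]
    padded = np.pad(values, pads, mode="reflect")
    x = Tensor(padded[None, None].astype(np.float64))
    y = model(x, geometry.side_info).data[0, 0]
    out = y[tuple(slice(0, n) for n in values.shape)]
    if field.mask is not None:
        out = out * field.mask
    return SusceptibilityVolume(values=out, geometry=geometry, mask=field.mask)
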
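"""Model-based loss, synthetic pre-training and transfer learning.

Pre-training draws random patches from synthetic susceptibility scenes,
simulates the matching local field with a patch-sized dipole kernel under a
randomly sampled acquisition geometry, and optimizes

    L = ||chi_gt - chi_rec||^2 + lambda * ||B_gt - d * chi_rec||^2

with AdamW and a cosine-annealing learning-rate schedule with warm
restarts.  Transfer learning fine-tunes a pre-trained model on paired
(field, susceptibility) volumes: the adaptive layer (FMN) stays frozen, the
decoder trains at a higher rate than the remaining parameters, and with
probability 0.5 the input field is replaced by the forward convolution of
the randomly re-scaled ground truth, which preserves susceptibility scale
invariance.

Every stage is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .dipole import (
    AcquisitionGeometry,
    ContractError,
    LocalFieldVolume,
    LossBreakdown,
    SusceptibilityVolume,
    apply_kernel,
    build_dipole_kernel,
    forward_field,
)
from .nn import AdamW, CosineWarmRestarts, Tensor, schedule_lr
from .phantoms import (
    AugmentOptions,
    GeometrySamplerSpec,
    ShapeSceneSpec,
    augment_patch,
    sample_geometry,
    sample_scene,
)
from .unet import AdaptiveUNet, AdaptiveUNetSpec, Checkpoint, checkpoint_from_model

__all__ = [
    "TrainRunConfig",
    "SyntheticSceneSource",
    "model_loss",
    "pretrain",
    "transfer_learn",
    "schedule_lr",
]


@dataclass(frozen=True)
class TrainRunConfig:
    """Hyperparameters of a pre-training / transfer-learning run.

    Defaults are the reference training recipe: AdamW (beta1 0.9,
    beta2 0.99, eps 1e-8, weight decay 0.01), cosine annealing with warm
    restarts (T0 500, Tmult 0.5, eta 1e-3 -> 1e-8), 500 pre-training epochs
    with four 160^3 patches per volume, lambda = 1, geometry variation
    probability 0.8; transfer learning for 30 epochs on 96^3 patches padded
    to 128^3 with the adaptive layer frozen, decoder at 1e-3 and everything
    else at 1e-5.
    """

    model_spec: AdaptiveUNetSpec = field(default_factory=AdaptiveUNetSpec)
    # optimizer
    betas: Tuple[float, float] = (0.9, 0.99)
    eps: float = 1e-8
    weight_decay: float = 0.01
    # schedule
    t0: float = 500.0
    t_mult: float = 0.5
    eta_init: float = 1e-3
    eta_min: float = 1e-8
    # pre-training
    epochs: int = 500
    patches_per_volume: int = 4
    patch_size: int = 160
    lam: float = 1.0
    loss_reduction: str = "mean"  # "mean" or "sum" (plain squared L2 norms)
    variation_probability: float = 0.8
    noise_sd: float = 0.01
    scale_range: Tuple[float, float] = (0.5, 2.0)
    # transfer learning
    transfer_epochs: int = 30
    transfer_patch_size: int = 96
    transfer_padded_size: int = 128
    field_source_probability: float = 0.5
    transfer_scale_interval: Tuple[float, float] = (0.0, 2.0)
    decoder_lr: float = 1e-3
    other_lr: float = 1e-5
    mask_chi_term: bool = False
    # bookkeeping
    seed: int = 0
    dtype: str = "float64"

    def __post_init__(self) -> None:
        for p in (self.variation_probability, self.field_source_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.eta_init <= 0 or self.decoder_lr <= 0 or self.other_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.loss_reduction not in ("mean", "sum"):
            raise ValueError("loss_reduction must be 'mean' or 'sum'")

    def schedule(self) -> CosineWarmRestarts:
        return CosineWarmRestarts(self.t0, self.t_mult, self.eta_init, self.eta_min)


# ---------------------------------------------------------------------------
# Loss


def model_loss(
    chi_rec: np.ndarray,
    chi_gt: np.ndarray,
    b_gt: np.ndarray,
    geometry: AcquisitionGeometry,
    lam: float = 1.0,
    reduction: str = "mean",
) -> LossBreakdown:
    """Physics-consistent loss on plain arrays (no gradients).

    L_chi is the mean (or sum) squared susceptibility error; L_B compares
    ``b_gt`` with the dipole forward convolution of the reconstruction
    under ``geometry``.
    """
    chi_rec = np.asarray(chi_rec, dtype=float)
    if chi_rec.shape != np.shape(chi_gt) or chi_rec.shape != np.shape(b_gt):
        raise ContractError("chi_rec, chi_gt and b_gt must share one shape")
    red = np.mean if reduction == "mean" else np.sum
    b_rec = forward_field(SusceptibilityVolume(chi_rec, geometry)).values
    chi_term = float(red((chi_rec - chi_gt) ** 2))
    field_term = float(red((b_gt - b_rec) ** 2))
    return LossBreakdown(
        total=chi_term + lam * field_term, chi_term=chi_term, field_term=field_term, lam=lam
    )


def _loss_tensor(
    chi_rec: Tensor,
    chi_gt: np.ndarray,
    b_gt: np.ndarray,
    kernel: np.ndarray,
    lam: float,
    reduction: str,
    mask: Optional[np.ndarray] = None,
) -> Tuple[Tensor, LossBreakdown]:
    """Differentiable loss on (B, 1, D, H, W) tensors."""
    red = nn.mean_sq if reduction == "mean" else nn.sum_sq
    resid_chi = nn.sub(chi_rec, Tensor(chi_gt))
    if mask is not None:
        resid_chi = nn.mul(resid_chi, Tensor(mask.astype(chi_gt.dtype)))
    chi_term = red(resid_chi)
    b_rec = nn.dipole_convolve(chi_rec, kernel)
    field_term = red(nn.sub(b_rec, Tensor(b_gt)))
    total = nn.add(chi_term, nn.mul(field_term, lam))
    breakdown = LossBreakdown(
        total=float(total.data),
        chi_term=float(chi_term.data),
        field_term=float(field_term.data),
        lam=lam,
    )
    return total, breakdown


# ---------------------------------------------------------------------------
# Scene sources


class SyntheticSceneSource:
    """Deterministic collection of synthetic scenes (index -> scene).

    Scene ``i`` is generated with seed ``base_seed + i``, so a source is
    reproducible and cheap to regenerate; scenes are cached once built.
    """

    def __init__(self, scene_spec: ShapeSceneSpec, n_scenes: int, base_seed: int = 0):
        self.scene_spec = scene_spec
        self.n_scenes = int(n_scenes)
        self.base_seed = int(base_seed)
        self._cache: Dict[int, SusceptibilityVolume] = {}

    def __len__(self) -> int:
        return self.n_scenes

    def __getitem__(self, i: int) -> SusceptibilityVolume:
        if not 0 <= i < self.n_scenes:
            raise IndexError(i)
        if i not in self._cache:
            spec = replace(self.scene_spec, seed=self.base_seed + i)
            self._cache[i] = sample_scene(spec)
        return self._cache[i]


def _random_patch(
    values: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    if any(n < size for n in values.shape):
        raise ContractError(f"patch size {size} exceeds volume shape {values.shape}")
    corner = [int(rng.integers(0, n - size + 1)) for n in values.shape]
    sl = tuple(slice(c, c + size) for c in corner)
    return values[sl]


# ---------------------------------------------------------------------------
# Pre-training


def pretrain(
    config: TrainRunConfig,
    scene_source: Sequence[SusceptibilityVolume],
    geometry_spec: Optional[GeometrySamplerSpec] = None,
    model: Optional[AdaptiveUNet] = None,
) -> Tuple[Checkpoint, List[float]]:
    """Pre-train on synthetic scenes; returns checkpoint and loss history.

    Per epoch and volume: sample an acquisition geometry, cut
    ``patches_per_volume`` random patches, augment them (susceptibility
    scaling, flips, 90-degree rotations), simulate the clean field with a
    patch-sized dipole kernel, feed the noise-corrupted field to the model
    and take one AdamW step on the combined loss.  The learning rate
    follows the warm-restart cosine schedule per epoch.
    """
    dtype = np.dtype(config.dtype)
    rng = np.random.default_rng(config.seed)
    if geometry_spec is None:
        geometry_spec = GeometrySamplerSpec(
            variation_probability=config.variation_probability
        )
    if model is None:
        model = AdaptiveUNet(config.model_spec, np.random.default_rng(config.seed))
    model.astype(dtype)
    model.train()
    opt = AdamW(
        model.parameters(),
        lr=config.eta_init,
        betas=config.betas,
        eps=config.eps,
        weight_decay=config.weight_decay,
    )
    sched = config.schedule()
    augment = AugmentOptions(
        scale=True, scale_range=config.scale_range, noise=False, flip=True, rot90=True
    )
    p = config.patch_size
    history: List[float] = []
    for epoch in range(config.epochs):
        lr = sched.lr(epoch)
        for g in opt.groups:
            g["lr"] = lr
        epoch_losses = []
        for i in range(len(scene_source)):
            scene = scene_source[i]
            geometry = sample_geometry(geometry_spec, rng)
            kernel = build_dipole_kernel((p, p, p), geometry).values
            chi_batch = np.stack(
                [
                    augment_patch(_random_patch(scene.values, p, rng), rng, augment)
                    for _ in range(config.patches_per_volume)
                ]
            )[:, None].astype(dtype)
            b_clean = np.stack(
                [apply_kernel(chi_batch[j, 0], kernel) for j in range(chi_batch.shape[0])]
            )[:, None].astype(dtype)
            b_in = b_clean + rng.normal(0.0, config.noise_sd, size=b_clean.shape).astype(dtype)
            opt.zero_grad()
            chi_rec = model(Tensor(b_in), geometry.side_info)
            total, breakdown = _loss_tensor(
                chi_rec, chi_batch, b_clean, kernel, config.lam, config.loss_reduction
            )
            total.backward()
            opt.step()
            epoch_losses.append(breakdown.total)
        history.append(float(np.mean(epoch_losses)))
    checkpoint = checkpoint_from_model(
        model, stage="pretrain", epochs=config.epochs, seed=config.seed,
        final_loss=history[-1] if history else None,
    )
    return checkpoint, history


# ---------------------------------------------------------------------------
# Transfer learning


def transfer_learn(
    checkpoint: Checkpoint,
    paired_data: Sequence[Tuple[LocalFieldVolume, SusceptibilityVolume]],
    config: TrainRunConfig,
    debug_hook=None,
) -> Checkpoint:
    """Fine-tune a pre-trained model on paired field/susceptibility volumes.

    The adaptive layer (FMN and its bias) is frozen; decoder parameters
    train at ``decoder_lr``, all remaining parameters at ``other_lr``.  Per
    item, with probability ``field_source_probability`` the stored
    (measured) field patch is used as input; otherwise both the patch and
    its field are re-derived from the ground truth scaled by a factor drawn
    uniformly from ``transfer_scale_interval``.  Patches of
    ``transfer_patch_size`` are zero-padded to ``transfer_padded_size``.
    """
    dtype = np.dtype(config.dtype)
    model = checkpoint.build_model()
    if model.spec != config.model_spec:
        raise ContractError("checkpoint spec does not match training config")
    model.astype(dtype)
    model.train()
    rng = np.random.default_rng(config.seed)
    frozen = set(model.fmn_parameter_names())
    decoder = set(model.decoder_parameter_names())
    named = dict(model.named_parameters())
    dec_params = [p for n, p in named.items() if n in decoder and n not in frozen]
    other_params = [p for n, p in named.items() if n not in decoder and n not in frozen]
    opt = AdamW(
        [
            {"params": dec_params, "lr": config.decoder_lr},
            {"params": other_params, "lr": config.other_lr},
        ],
        betas=config.betas,
        eps=config.eps,
        weight_decay=config.weight_decay,
    )
    p = config.transfer_patch_size
    pp = config.transfer_padded_size
    if pp < p:
        raise ValueError("padded size must be >= patch size")
    lo = (pp - p) // 2
    for _ in range(config.transfer_epochs):
        for b_vol, chi_vol in paired_data:
            if b_vol.values.shape != chi_vol.values.shape:
                raise ContractError("paired field and susceptibility shapes differ")
            geometry = chi_vol.geometry
            kernel_full = build_dipole_kernel(chi_vol.values.shape, geometry).values
            kernel_patch = build_dipole_kernel((pp, pp, pp), geometry).values
            corner = [
                int(rng.integers(0, n - p + 1)) for n in chi_vol.values.shape
            ]
            sl = tuple(slice(c, c + p) for c in corner)
            use_measured = rng.random() < config.field_source_probability
            if use_measured:
                chi_patch = chi_vol.values[sl]
                b_patch = b_vol.values[sl]
            else:
                scale = rng.uniform(*config.transfer_scale_interval)
                chi_scaled = scale * chi_vol.values
                b_scaled = apply_kernel(chi_scaled, kernel_full)
                chi_patch = chi_scaled[sl]
                b_patch = b_scaled[sl]
            if debug_hook is not None:
                debug_hook(
                    chi_full=chi_patch if use_measured else chi_scaled,
                    b_full=b_patch if use_measured else b_scaled,
                    geometry=geometry,
                    measured=use_measured,
                )
            pad = [(lo, pp - p - lo)] * 3
            chi_pad = np.pad(chi_patch, pad).astype(dtype)[None, None]
            b_pad = np.pad(b_patch, pad).astype(dtype)[None, None]
            mask = None
            if config.mask_chi_term and chi_vol.mask is not None:
                mask = np.pad(chi_vol.mask[sl], pad)[None, None]
            opt.zero_grad()
            chi_rec = model(Tensor(b_pad), geometry.side_info)
            total, _ = _loss_tensor(
                chi_rec, chi_pad, b_pad, kernel_patch, config.lam,
                config.loss_reduction, mask,
            )
            total.backward()
            opt.step()
    return checkpoint_from_model(
        model, stage="transfer", epochs=config.transfer_epochs, seed=config.seed,
        parent=checkpoint.metadata,
    )
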
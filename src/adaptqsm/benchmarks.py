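"""Self-contained verification runs: physics checks and a desk-scale
training benchmark.

These routines recompute the package's headline quantities from scratch —
the magic-angle zero of the dipole kernel, agreement of the fast forward
model with a naive discrete-transform oracle, the closed-form sphere field,
and a scaled-down synthetic pre-training run scored on held-out scenes
against the residual-identity baseline.  They are used by the test suite
and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .dipole import (
    AcquisitionGeometry,
    SusceptibilityVolume,
    build_dipole_kernel,
    forward_field,
    forward_field_oracle,
)
from .metrics import scatter_fit, ssim3d
from .phantoms import GeometrySamplerSpec, ShapeSceneSpec, sample_geometry
from .training import SyntheticSceneSource, TrainRunConfig, pretrain
from .unet import AdaptiveUNetSpec, infer

# Desk-scale pre-training surrogate (problem sizes: docs/methods.md).
SMOKE_MODEL = AdaptiveUNetSpec(initial_channels=8, levels=2, decoder_channels=8)
SMOKE_EPOCHS = 25
SMOKE_SCENES = 15
SMOKE_PATCHES_PER_SCENE = 2
SMOKE_HOLDOUT = 5
SMOKE_GRID = (48, 48, 48)
SMOKE_PATCH = 32
SMOKE_ETA = 2e-3


def measure_magic_angle(grid: int = 64) -> Dict[str, float]:
    """Locate the dipole kernel's zero as a function of the angle to B0.

    d(k) depends on k only through that angle, so all kernel samples lie on
    one curve d(theta); the zero crossing is found by linear interpolation
    between the two samples straddling it.
    """
    kernel = build_dipole_kernel((grid, grid, grid), AcquisitionGeometry()).values
    freqs = np.fft.fftfreq(grid)
    KX, KY, KZ = np.meshgrid(freqs, freqs, freqs, indexing="ij")
    norm = np.sqrt(KX**2 + KY**2 + KZ**2)
    # positive-frequency region only (Nyquist entries mix +-1/2 assignments)
    sl = np.ix_(*[range(1, grid // 2)] * 3)
    theta = np.degrees(np.arccos(np.clip(KZ[sl] / norm[sl], -1, 1))).ravel()
    d = kernel[sl].ravel()
    order = np.argsort(theta)
    th, dv = theta[order], d[order]
    cross = np.where(np.diff(np.sign(dv)) != 0)[0][0]
    t0, t1, d0, d1 = th[cross], th[cross + 1], dv[cross], dv[cross + 1]
    zero = t0 - d0 * (t1 - t0) / (d1 - d0)
    return {"value": float(zero), "n": int(dv.size)}


def measure_oracle_agreement(seed: int, trials: int = 20) -> Dict[str, float]:
    """Worst relative deviation between the FFT forward model and the naive
    discrete-transform oracle over random small grids and geometries."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(trials):
        shape = tuple(rng.integers(4, 17, size=3))
        geom = AcquisitionGeometry(rng.uniform(0.5, 2.5, 3), rng.normal(size=3))
        chi = SusceptibilityVolume(rng.normal(size=shape), geom)
        fast = forward_field(chi).values
        slow = forward_field_oracle(chi).values
        scale = max(1.0, float(np.max(np.abs(slow))))
        worst = max(worst, float(np.max(np.abs(fast - slow)) / scale))
    return {"value": worst, "n": trials}


def measure_sphere_error(grid: int = 64, radius: float = 8.0, r_probe: int = 16,
                         dchi: float = 0.1) -> Dict[str, float]:
    """Relative error (%) of the simulated external field of a uniform
    sphere at ``r_probe`` voxels along B0 against the closed-form
    Lorentz-corrected dipole solution (dchi/3)(a/r)^3 * 2."""
    idx = np.arange(grid) - grid // 2
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    chi = np.where(np.sqrt(X**2 + Y**2 + Z**2) <= radius, dchi, 0.0)
    f = forward_field(
        SusceptibilityVolume(np.fft.ifftshift(chi), AcquisitionGeometry())
    ).values
    f = np.fft.fftshift(f)
    c = grid // 2
    expected = (dchi / 3.0) * (radius / r_probe) ** 3 * 2.0
    rel = abs(f[c, c, c + r_probe] - expected) / expected * 100.0
    return {"value": float(rel), "n": grid**3}


def run_smoke_training(seed: int) -> Dict[str, Dict[str, float]]:
    """Scaled-down synthetic pre-training, scored on held-out scenes.

    Trains the smoke model on ``SMOKE_SCENES`` scenes and evaluates masked
    SSIM and whole-volume OLS slope on ``SMOKE_HOLDOUT`` unseen scenes,
    against the residual-identity baseline (the untrained network, whose
    output equals its input field).
    """
    config = TrainRunConfig(
        model_spec=SMOKE_MODEL,
        epochs=SMOKE_EPOCHS,
        patches_per_volume=SMOKE_PATCHES_PER_SCENE,
        patch_size=SMOKE_PATCH,
        t0=SMOKE_EPOCHS,
        eta_init=SMOKE_ETA,
        seed=seed,
    )
    source = SyntheticSceneSource(
        ShapeSceneSpec(grid_shape=SMOKE_GRID), SMOKE_SCENES, base_seed=seed * 1000
    )
    ckpt, history = pretrain(config, source)
    geom_spec = GeometrySamplerSpec(variation_probability=0.8, seed=seed + 1)
    rng = np.random.default_rng(seed + 1)
    ssim_model, ssim_base, slope_model, slope_base = [], [], [], []
    for i in range(SMOKE_HOLDOUT):
        scene = SyntheticSceneSource(
            ShapeSceneSpec(grid_shape=SMOKE_GRID), 1, base_seed=seed * 1000 + 5000 + i
        )[0]
        geom = sample_geometry(geom_spec, rng)
        chi = SusceptibilityVolume(scene.values, geom, mask=scene.mask)
        field = forward_field(chi)
        rec = infer(field, geom, checkpoint=ckpt)
        mask = scene.mask
        ssim_model.append(ssim3d(rec.values, chi.values, mask))
        ssim_base.append(ssim3d(field.values, chi.values, mask))
        slope_model.append(scatter_fit(rec.values, chi.values, mask, n=20_000, seed=seed)[0])
        slope_base.append(scatter_fit(field.values, chi.values, mask, n=20_000, seed=seed)[0])
    n_steps = SMOKE_EPOCHS * SMOKE_SCENES
    return {
        "pretrain_loss_ratio_final_over_initial": {
            "value": float(history[-1] / history[0]), "n": n_steps,
        },
        "holdout_ssim": {"value": float(np.mean(ssim_model)), "n": SMOKE_HOLDOUT},
        "holdout_ssim_identity_baseline": {
            "value": float(np.mean(ssim_base)), "n": SMOKE_HOLDOUT,
        },
        "holdout_ols_slope": {"value": float(np.mean(slope_model)), "n": SMOKE_HOLDOUT},
        "holdout_ols_slope_identity_baseline": {
            "value": float(np.mean(slope_base)), "n": SMOKE_HOLDOUT,
        },
    }
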
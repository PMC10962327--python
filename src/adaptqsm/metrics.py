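"""Quantitative comparison of reconstructed and reference susceptibility maps.

NRMSE (percent of the ground-truth L2 norm), SSIM (Gaussian-weighted
window, masked average), PSNR (dB, capped at equality), seeded random
scatter sampling with ordinary least-squares slope/intercept, and per-label
region statistics with optional 3x3x3 erosion.  The scatter seed is shared
across models so that identical voxel positions are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .dipole import ContractError

PSNR_CAP_DB = 100.0


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


@dataclass
class MetricsReport:
    """Bundle of map-quality metrics for one reconstruction."""

    nrmse_percent: float
    ssim: float
    psnr_db: float
    slope: float
    intercept: float
    n_samples: int
    seed: int
    region_means: Dict[int, Tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "nrmse_percent": self.nrmse_percent,
            "ssim": self.ssim,
            "psnr_db": self.psnr_db,
            "ols_slope": self.slope,
            "ols_intercept": self.intercept,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "region_means_ppm": {str(k): list(v) for k, v in self.region_means.items()},
        }


def _masked(rec: np.ndarray, gt: np.ndarray, mask: Optional[np.ndarray]):
    rec = np.asarray(rec, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if rec.shape != gt.shape:
        raise ContractError(f"shape mismatch {rec.shape} vs {gt.shape}")
    if mask is None:
        mask = np.ones(rec.shape, dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != rec.shape:
            raise ContractError("mask shape mismatch")
    return rec, gt, mask


def nrmse(rec: np.ndarray, gt: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """100 * ||rec - gt|| / ||gt|| over masked voxels (percent)."""
    rec, gt, mask = _masked(rec, gt, mask)
    denom = float(np.linalg.norm(gt[mask]))
    if denom == 0.0:
        raise UndefinedMetricError("ground truth is identically zero within the mask")
    return float(100.0 * np.linalg.norm(rec[mask] - gt[mask]) / denom)


def ssim3d(
    rec: np.ndarray,
    gt: np.ndarray,
    mask: Optional[np.ndarray] = None,
    win_size: int = 7,
    data_range: Optional[float] = None,
) -> float:
    """Structural similarity with a Gaussian-weighted window, averaged over
    masked voxels.  ``data_range`` defaults to max - min of the masked
    ground truth."""
    rec, gt, mask = _masked(rec, gt, mask)
    if any(n < win_size for n in rec.shape):
        raise ContractError(f"window {win_size} larger than volume {rec.shape}")
    if data_range is None:
        g = gt[mask]
        data_range = float(g.max() - g.min())
        if data_range == 0.0:
            data_range = 1.0
    _, smap = structural_similarity(
        gt, rec, win_size=win_size, gaussian_weights=True, sigma=1.5,
        data_range=data_range, full=True,
    )
    return float(smap[mask].mean())


def psnr(
    rec: np.ndarray,
    gt: np.ndarray,
    mask: Optional[np.ndarray] = None,
    data_range: Optional[float] = None,
) -> float:
    """10 log10(range^2 / MSE) over masked voxels, capped at 100 dB."""
    rec, gt, mask = _masked(rec, gt, mask)
    if data_range is None:
        g = gt[mask]
        data_range = float(g.max() - g.min())
        if data_range == 0.0:
            data_range = 1.0
    mse = float(np.mean((rec[mask] - gt[mask]) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return float(min(PSNR_CAP_DB, 10.0 * np.log10(data_range**2 / mse)))


def scatter_fit(
    rec: np.ndarray,
    gt: np.ndarray,
    mask: Optional[np.ndarray] = None,
    n: int = 400_000,
    seed: int = 0,
) -> Tuple[float, float]:
    """OLS fit rec ~ slope * gt + intercept on ``n`` voxels sampled without
    replacement from the mask with the given seed.

    Using one seed across models compares susceptibilities from identical
    positions.  Returns (slope, intercept).
    """
    rec, gt, mask = _masked(rec, gt, mask)
    idx = np.flatnonzero(mask.ravel())
    if n > idx.size:
        raise ValueError(f"cannot sample {n} voxels from {idx.size} masked positions")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=False)
    x = gt.ravel()[chosen]
    y = rec.ravel()[chosen]
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def region_stats(
    volume: np.ndarray,
    label_mask: np.ndarray,
    erosion_on: bool = True,
) -> Dict[int, Tuple[float, float]]:
    """Per-label mean and sd (ppm), optionally after one binary erosion with
    a 3x3x3 all-ones structuring element.  Labels eroded to nothing are
    omitted with a warning."""
    volume = np.asarray(volume, dtype=float)
    label_mask = np.asarray(label_mask)
    if label_mask.shape != volume.shape:
        raise ContractError("label mask shape mismatch")
    out: Dict[int, Tuple[float, float]] = {}
    structure = np.ones((3, 3, 3), dtype=bool)
    for lab in sorted(set(np.unique(label_mask)) - {0}):
        region = label_mask == lab
        if erosion_on:
            region = ndimage.binary_erosion(region, structure=structure)
        if not region.any():
            import warnings

            warnings.warn(f"label {lab} eroded to empty; omitted", stacklevel=2)
            continue
        vals = volume[region]
        out[int(lab)] = (float(vals.mean()), float(vals.std()))
    return out


def referencing(chi: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Reference a susceptibility map to the mean within the mask."""
    chi = np.asarray(chi, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != chi.shape:
        raise ContractError("mask shape mismatch")
    if not mask.any():
        raise ValueError("mask is empty")
    return chi - chi[mask].mean()


def evaluate(
    rec: np.ndarray,
    gt: np.ndarray,
    mask: Optional[np.ndarray] = None,
    label_mask: Optional[np.ndarray] = None,
    n_samples: Optional[int] = None,
    seed: int = 0,
) -> MetricsReport:
    """Full metrics report for one reconstruction against its reference."""
    rec, gt, m = _masked(rec, gt, mask)
    if n_samples is None:
        n_samples = min(400_000, int(m.sum()))
    slope, intercept = scatter_fit(rec, gt, m, n=n_samples, seed=seed)
    report = MetricsReport(
        nrmse_percent=nrmse(rec, gt, m),
        ssim=ssim3d(rec, gt, m),
        psnr_db=psnr(rec, gt, m),
        slope=slope,
        intercept=intercept,
        n_samples=n_samples,
        seed=seed,
    )
    if label_mask is not None:
        report.region_means = region_stats(rec, label_mask)
    return report
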
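"""Dipole physics for quantitative susceptibility mapping.

The magnetic field perturbation measured with gradient-echo MRI is, to first
order in the susceptibility, the convolution of the tissue susceptibility
distribution chi(r) with the unit dipole response.  In k-space this
convolution is a pointwise multiplication with

    d(k) = 1/3 - (k . o)^2 / |k|^2,

where ``o`` is the unit vector of the main magnetic field B0 expressed in
image axes.  The kernel vanishes on the cone at the magic angle
theta = arccos(1/sqrt(3)) ~ 54.7 deg, which is what makes the inverse problem
(field -> susceptibility) ill-posed.

Anisotropic voxels enter through the per-axis scaling of the discrete
spatial frequencies (1 / (N_i * v_i)); a tilted field of view is modelled by
tilting ``o`` rather than resampling the image grid.

Units: chi in ppm, fields in ppm of the reference field (1 T by convention),
so the forward model is unit-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

MAGIC_ANGLE_DEG = float(np.degrees(np.arccos(1.0 / np.sqrt(3.0))))


class GeometryError(ValueError):
    """Invalid acquisition geometry (voxel size or B0 orientation)."""


class ContractError(ValueError):
    """Shape or metadata mismatch between volumes."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Voxel size (mm) and B0 orientation of one acquisition.

    The B0 direction is stored normalized.  ``side_info`` is the 6-vector
    (vx, vy, vz, ox, oy, oz) used to condition the adaptive convolution
    layer.
    """

    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_direction: Tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxel_size, dtype=float)
        if v.shape != (3,) or not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise GeometryError(f"voxel size must be 3 positive numbers, got {self.voxel_size}")
        o = np.asarray(self.b0_direction, dtype=float)
        if o.shape != (3,) or not np.all(np.isfinite(o)):
            raise GeometryError(f"B0 direction must be a 3-vector, got {self.b0_direction}")
        n = float(np.linalg.norm(o))
        if n < 1e-12:
            raise GeometryError("B0 direction must be non-zero")
        object.__setattr__(self, "voxel_size", tuple(float(x) for x in v))
        object.__setattr__(self, "b0_direction", tuple(float(x) for x in o / n))

    @property
    def side_info(self) -> np.ndarray:
        """(vx, vy, vz, ox, oy, oz) as a float64 array."""
        return np.asarray(self.voxel_size + self.b0_direction, dtype=float)


def _check_volume(values: np.ndarray, mask: Optional[np.ndarray]) -> None:
    if values.ndim != 3:
        raise ContractError(f"expected a 3D volume, got ndim={values.ndim}")
    if not np.all(np.isfinite(values)):
        raise ContractError("volume contains non-finite values")
    if mask is not None and mask.shape != values.shape:
        raise ContractError(f"mask shape {mask.shape} != volume shape {values.shape}")


@dataclass
class SusceptibilityVolume:
    """3D susceptibility map chi in ppm with acquisition geometry."""

    values: np.ndarray
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
        _check_volume(self.values, self.mask)


@dataclass
class LocalFieldVolume:
    """3D relative field perturbation B_M/B0 in ppm (1 T reference)."""

    values: np.ndarray
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    mask: Optional[np.ndarray] = None
    reference_field_T: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
        _check_volume(self.values, self.mask)


@dataclass
class DipoleKernel:
    """k-space unit dipole response d(k) on a discrete grid."""

    values: np.ndarray
    geometry: AcquisitionGeometry
    dc_convention: float = 0.0

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class LossBreakdown:
    """Physics-consistent training loss L = L_chi + lambda * L_B.

    ``chi_term`` compares reconstructed and ground-truth susceptibility;
    ``field_term`` compares the ground-truth field with the forward
    convolution of the reconstruction, which pins the optimization to
    solutions obeying the dipole model.
    """

    total: float
    chi_term: float
    field_term: float
    lam: float

    def __post_init__(self) -> None:
        if self.chi_term < 0 or self.field_term < 0 or self.lam < 0:
            raise ValueError("loss terms and lambda must be non-negative")
        expected = self.chi_term + self.lam * self.field_term
        if not np.isclose(self.total, expected, rtol=1e-12, atol=1e-12):
            raise ValueError("total != chi_term + lambda * field_term")


def build_dipole_kernel(
    shape: Sequence[int],
    geometry: AcquisitionGeometry,
    dc_convention: float = 0.0,
) -> DipoleKernel:
    """Construct d(k) = 1/3 - (k.o)^2/|k|^2 on an FFT-ordered grid.

    Discrete frequencies follow the unshifted FFT layout
    (``numpy.fft.fftfreq``) scaled per axis by the reciprocal voxel size, so
    anisotropic voxels stretch the k-grid.  The DC term, where the ratio is
    undefined, is set to ``dc_convention`` (default 0: fields are defined up
    to a constant, matching referencing of maps to their mean).
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or any(n < 2 for n in shape):
        raise ContractError(f"kernel shape must be 3 dims each >= 2, got {shape}")
    if not isinstance(geometry, AcquisitionGeometry):
        geometry = AcquisitionGeometry(*geometry)
    v = geometry.voxel_size
    o = np.asarray(geometry.b0_direction)
    freqs = [np.fft.fftfreq(n, d=vi) for n, vi in zip(shape, v)]
    # On even-sized axes the Nyquist index represents both +-1/(2v) equally;
    # (k.o)^2 is evaluated as its average over independent sign choices of
    # the Nyquist components, which kills their cross terms.  This keeps the
    # kernel exactly even under index negation (so d * chi_hat stays
    # conjugate-symmetric for real chi) and exactly equivariant under joint
    # 90-degree rotations of the grid and o.  Non-Nyquist entries are the
    # plain 1/3 - (k.o)^2/|k|^2 samples.
    nyq = [
        (np.arange(n) == n // 2) & (n % 2 == 0) for n in shape
    ]
    K = np.meshgrid(*freqs, indexing="ij")
    M = np.meshgrid(*nyq, indexing="ij")
    k2 = sum(Ki**2 for Ki in K)
    lin = sum(Ki * oi * ~Mi for Ki, oi, Mi in zip(K, o, M))
    sq = sum((Ki * oi) ** 2 * Mi for Ki, oi, Mi in zip(K, o, M))
    kzp2 = lin**2 + sq
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - kzp2 / k2
    d[0, 0, 0] = dc_convention
    return DipoleKernel(values=d, geometry=geometry, dc_convention=dc_convention)


def apply_kernel(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Pointwise k-space multiplication: real(ifftn(fftn(x) * d))."""
    return np.real(np.fft.ifftn(np.fft.fftn(values) * kernel))


def forward_field(
    chi: SusceptibilityVolume,
    pad: bool = False,
    dc_convention: float = 0.0,
) -> LocalFieldVolume:
    """Fast forward model: field = F^-1 [ chi_hat(k) * d(k) ].

    Periodic boundary conditions are implied by the k-space multiplication.
    With ``pad=True`` the volume is zero-padded to twice its size before the
    convolution to suppress wrap-around (useful for validation runs).
    """
    values = chi.values
    if pad:
        padded = np.zeros(tuple(2 * n for n in values.shape), dtype=float)
        sl = tuple(slice(n // 2, n // 2 + n) for n in values.shape)
        padded[sl] = values
        kernel = build_dipole_kernel(padded.shape, chi.geometry, dc_convention)
        out = apply_kernel(padded, kernel.values)[sl]
    else:
        kernel = build_dipole_kernel(values.shape, chi.geometry, dc_convention)
        out = apply_kernel(values, kernel.values)
    return LocalFieldVolume(values=out, geometry=chi.geometry, mask=chi.mask)


def forward_field_oracle(chi: SusceptibilityVolume, max_size: int = 16) -> LocalFieldVolume:
    """Forward field by direct discrete-transform summation (no FFT).

    Test oracle: evaluates the discrete Fourier sums with explicitly
    constructed per-axis DFT matrices.  Refuses grids larger than
    ``max_size`` per axis (naive cost).
    """
    values = chi.values
    if any(n > max_size for n in values.shape):
        raise ContractError(f"oracle limited to grids <= {max_size}^3, got {values.shape}")
    kernel = build_dipole_kernel(values.shape, chi.geometry).values

    def dft_matrix(n: int, sign: float) -> np.ndarray:
        idx = np.arange(n)
        return np.exp(sign * 2j * np.pi * np.outer(idx, idx) / n)

    spec = values.astype(complex)
    for axis, n in enumerate(values.shape):
        W = dft_matrix(n, -1.0)
        spec = np.moveaxis(np.tensordot(W, np.moveaxis(spec, axis, 0), axes=(1, 0)), 0, axis)
    spec = spec * kernel
    for axis, n in enumerate(values.shape):
        W = dft_matrix(n, +1.0) / n
        spec = np.moveaxis(np.tensordot(W, np.moveaxis(spec, axis, 0), axes=(1, 0)), 0, axis)
    return LocalFieldVolume(values=np.real(spec), geometry=chi.geometry, mask=chi.mask)


def angle_to_axis(o: Sequence[float]) -> float:
    """Angle (degrees) between ``o`` and the scanner z-axis (0, 0, 1)."""
    o = np.asarray(o, dtype=float)
    n = float(np.linalg.norm(o))
    if o.shape != (3,) or n < 1e-12:
        raise GeometryError("orientation must be a non-zero 3-vector")
    c = np.clip(o[2] / n, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def voxel_aspect_ratio(v: Sequence[float]) -> float:
    """Slice-direction voxel size divided by the in-plane voxel size.

    If the two in-plane components differ, their mean is used and a warning
    is emitted.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise GeometryError(f"voxel size must be 3 positive numbers, got {v}")
    if not np.isclose(v[0], v[1]):
        import warnings

        warnings.warn("in-plane voxel sizes differ; using their mean", stacklevel=2)
    inplane = 0.5 * (v[0] + v[1])
    return float(v[2] / inplane)
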
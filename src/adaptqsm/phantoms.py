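"""Synthetic susceptibility phantoms for pre-training and evaluation.

Scenes are random compositions of rectangles, extruded polygons and
ellipsoids with per-shape susceptibilities drawn from N(0, 0.25 ppm).  Each
shape is blurred individually (Gaussian sd uniform on [0, 0.8] voxels) to
soften edges, and where shapes overlap their contributions are averaged,
which multiplies the number of edges in the scene.  A brain-like mask is the
complement of a union of ellipsoids scattered in the border region of the
grid.  Paired local-field maps come from the k-space dipole forward model
under a sampled acquisition geometry (anisotropic voxels, tilted B0).

Everything is a pure function of (spec, seed): identical seeds reproduce
scenes bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

from .dipole import (
    AcquisitionGeometry,
    ContractError,
    LocalFieldVolume,
    SusceptibilityVolume,
    forward_field,
)


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class ShapeSceneSpec:
    """Recipe for one synthetic susceptibility scene.

    Counts and distributions default to the training-scene conditions:
    80-150 rectangles, 200-300 ellipsoids, 50 polygons, 300 border
    ellipsoids for the mask, susceptibilities ~ N(0, 0.25 ppm), per-shape
    blur sd ~ U(0, 0.8) voxels.  Shape extents are sampled as fractions of
    the grid dimension (``size_range``); the mask ellipsoids are centered
    within a band covering ``border_band`` of each dimension.
    """

    grid_shape: Tuple[int, int, int] = (320, 320, 320)
    rectangle_count: Tuple[int, int] = (80, 150)
    ellipsoid_count: Tuple[int, int] = (200, 300)
    polygon_count: int = 50
    mask_ellipsoid_count: int = 300
    chi_mean: float = 0.0
    chi_sd: float = 0.25
    blur_sd_range: Tuple[float, float] = (0.0, 0.8)
    size_range: Tuple[float, float] = (0.03, 0.15)
    border_band: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for c in (self.rectangle_count, self.ellipsoid_count):
            if c[0] < 0 or c[1] < c[0]:
                raise ValueError(f"invalid count range {c}")
        if self.polygon_count < 0 or self.mask_ellipsoid_count < 0:
            raise ValueError("counts must be non-negative")
        if self.blur_sd_range[0] < 0 or self.blur_sd_range[1] < self.blur_sd_range[0]:
            raise ValueError(f"invalid blur sd range {self.blur_sd_range}")
        if min(self.grid_shape) < 4:
            raise ValueError("grid too small for any shape")


@dataclass(frozen=True)
class GeometrySamplerSpec:
    """Acquisition-geometry sampling during training.

    With probability ``1 - variation_probability`` the standard geometry
    ((1,1,1) mm, axial B0) is returned, ensuring standard parameters stay in
    the training data.  Otherwise voxel sizes are drawn per component from
    N(1, 1.5) mm truncated to ``voxel_bounds`` and the axial B0 vector
    (0,0,1) is perturbed additively (x/y components sd ``orient_sd_xy``,
    z component sd ``orient_sd_z``) and re-normalized.
    """

    variation_probability: float = 0.8
    voxel_mean: float = 1.0
    voxel_sd: float = 1.5
    voxel_bounds: Tuple[float, float] = (0.5, 3.5)
    orient_sd_xy: float = 1.0 / 11.0
    orient_sd_z: float = 1.0 / 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.variation_probability <= 1.0:
            raise ValueError("variation probability must be in [0, 1]")
        if self.voxel_bounds[0] <= 0 or self.voxel_bounds[1] < self.voxel_bounds[0]:
            raise ValueError("voxel bounds must be positive and ordered")


DEFAULT_LESION_VALUES: Dict[int, float] = {1: -1.0, 2: -0.5, 3: 0.5, 4: 1.0}


@dataclass
class LesionSpec:
    """Labelled lesion regions with assigned susceptibilities (ppm).

    Default values are the four simulated lesion susceptibilities
    (-1.0, -0.5, 0.5, 1.0 ppm); the inserted component is smoothed with a
    Gaussian of sd 0.5 voxels before being added to the base map.
    """

    label_mask: np.ndarray
    values: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_LESION_VALUES))
    smoothing_sd: float = 0.5

    def __post_init__(self) -> None:
        self.label_mask = np.asarray(self.label_mask)
        if self.smoothing_sd < 0:
            raise ValueError("smoothing sd must be >= 0")


# ---------------------------------------------------------------------------
# Rasterization primitives (voxel-center inclusion, 0-based indices)


def rasterize_box(corner_lo: Sequence[int], corner_hi: Sequence[int], grid: Sequence[int]) -> np.ndarray:
    """Half-open voxel-index box [lo, hi) on a grid."""
    lo = np.asarray(corner_lo, dtype=int)
    hi = np.asarray(corner_hi, dtype=int)
    grid = tuple(int(n) for n in grid)
    if np.any(lo > hi):
        raise ValueError(f"inverted box corners {corner_lo} > {corner_hi}")
    if np.any(lo < 0) or np.any(hi > np.asarray(grid)):
        raise ValueError("box corners outside grid")
    out = np.zeros(grid, dtype=bool)
    out[tuple(slice(a, b) for a, b in zip(lo, hi))] = True
    return out


def rasterize_ellipsoid(
    center: Sequence[float], semi_axes: Sequence[float], grid: Sequence[int]
) -> np.ndarray:
    """Voxel-center inclusion test against the ellipsoid equation."""
    c = np.asarray(center, dtype=float)
    a = np.asarray(semi_axes, dtype=float)
    if np.any(a <= 0):
        raise ValueError(f"semi-axes must be positive, got {semi_axes}")
    grid = tuple(int(n) for n in grid)
    coords = np.meshgrid(*[np.arange(n) for n in grid], indexing="ij", sparse=True)
    q = sum(((x - ci) / ai) ** 2 for x, ci, ai in zip(coords, c, a))
    return q <= 1.0


def rasterize_polygon(
    vertices_2d: Sequence[Sequence[float]],
    extrusion_range: Tuple[int, int],
    grid: Sequence[int],
) -> np.ndarray:
    """Extruded planar polygon: 2D point-in-polygon per voxel center in the
    (x, y) plane, replicated across the half-open z slab ``extrusion_range``.
    """
    verts = np.asarray(vertices_2d, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs >= 3 planar vertices")
    poly = Polygon(verts)
    if not poly.is_valid or poly.area <= 1e-12:
        raise ValueError("degenerate polygon")
    grid = tuple(int(n) for n in grid)
    z0, z1 = int(extrusion_range[0]), int(extrusion_range[1])
    if z0 > z1 or z0 < 0 or z1 > grid[2]:
        raise ValueError(f"extrusion range {extrusion_range} outside grid")
    out = np.zeros(grid, dtype=bool)
    if z0 == z1:
        return out
    xs, ys = np.meshgrid(np.arange(grid[0]), np.arange(grid[1]), indexing="ij")
    inside = shapely.contains_xy(poly, xs.ravel().astype(float), ys.ravel().astype(float))
    out[:, :, z0:z1] = inside.reshape(grid[0], grid[1])[:, :, None]
    return out


# ---------------------------------------------------------------------------
# Scene assembly


def _random_simple_polygon(rng: np.random.Generator, center: np.ndarray, radius: float) -> np.ndarray:
    """Star-shaped (hence simple) polygon with 3-8 vertices around a center."""
    n = int(rng.integers(3, 9))
    ang = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    rad = rng.uniform(0.3 * radius, radius, size=n)
    return np.stack([center[0] + rad * np.cos(ang), center[1] + rad * np.sin(ang)], axis=1)


def _shape_local(rng: np.random.Generator, kind: str, spec: ShapeSceneSpec):
    """Draw one shape; return (slices into the grid, local boolean block)."""
    g = np.asarray(spec.grid_shape)
    lo_f, hi_f = spec.size_range
    if kind == "box":
        size = np.maximum(1, (rng.uniform(lo_f, hi_f, 3) * g).astype(int))
        lo = np.array([rng.integers(0, max(1, n - s + 1)) for n, s in zip(g, size)])
        hi = np.minimum(lo + size, g)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        return sl, np.ones(tuple(hi - lo), dtype=bool)
    if kind == "ellipsoid":
        semi = np.maximum(1.0, rng.uniform(lo_f, hi_f, 3) * g / 2.0)
        center = rng.uniform(0, g - 1, 3)
        lo = np.maximum(0, np.floor(center - semi)).astype(int)
        hi = np.minimum(g, np.ceil(center + semi) + 1).astype(int)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        coords = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij", sparse=True)
        block = sum(((x - c) / s) ** 2 for x, c, s in zip(coords, center, semi)) <= 1.0
        return sl, block
    # extruded polygon
    radius = max(2.0, rng.uniform(lo_f, hi_f) * g[0] / 2.0)
    center = rng.uniform(0, g[:2] - 1, 2)
    verts = _random_simple_polygon(rng, center, radius)
    thickness = max(1, int(rng.uniform(lo_f, hi_f) * g[2]))
    z0 = int(rng.integers(0, max(1, g[2] - thickness + 1)))
    lo_xy = np.maximum(0, np.floor(verts.min(axis=0))).astype(int)
    hi_xy = np.minimum(g[:2], np.ceil(verts.max(axis=0)) + 1).astype(int)
    if np.any(lo_xy >= hi_xy):
        return None  # entirely outside in-plane
    try:
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 1e-9:
            return None
    except Exception:
        return None
    xs, ys = np.meshgrid(np.arange(lo_xy[0], hi_xy[0]), np.arange(lo_xy[1], hi_xy[1]), indexing="ij")
    inside = shapely.contains_xy(poly, xs.ravel().astype(float), ys.ravel().astype(float))
    block2d = inside.reshape(xs.shape)
    sl = (slice(lo_xy[0], hi_xy[0]), slice(lo_xy[1], hi_xy[1]), slice(z0, min(z0 + thickness, g[2])))
    depth = sl[2].stop - sl[2].start
    return sl, np.repeat(block2d[:, :, None], depth, axis=2)


def _grow(sl: Tuple[slice, ...], margin: int, grid: Sequence[int]) -> Tuple[slice, ...]:
    return tuple(
        slice(max(0, s.start - margin), min(n, s.stop + margin)) for s, n in zip(sl, grid)
    )


def sample_scene(
    spec: ShapeSceneSpec,
    rng: Optional[np.random.Generator] = None,
    stats_out: Optional[dict] = None,
) -> SusceptibilityVolume:
    """Draw one scene: valued, individually blurred shapes composited by
    averaging overlapping contributions, plus the border-ellipsoid mask.

    The per-voxel value is sum(blurred contributions) / max(1, number of
    shapes whose un-blurred support covers the voxel), which is symmetric in
    the shapes, so permuting shape order leaves the scene unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    g = spec.grid_shape
    total = np.zeros(g, dtype=float)
    count = np.zeros(g, dtype=np.int32)

    n_rect = int(rng.integers(spec.rectangle_count[0], spec.rectangle_count[1] + 1))
    n_ell = int(rng.integers(spec.ellipsoid_count[0], spec.ellipsoid_count[1] + 1))
    kinds = ["box"] * n_rect + ["polygon"] * spec.polygon_count + ["ellipsoid"] * n_ell
    if stats_out is not None:
        stats_out.update(
            {"n_rect": n_rect, "n_ellipsoid": n_ell, "n_polygon": spec.polygon_count,
             "values": [], "blur_sds": []}
        )
    for kind in kinds:
        drawn = _shape_local(rng, kind, spec)
        value = float(rng.normal(spec.chi_mean, spec.chi_sd))
        sd = float(rng.uniform(*spec.blur_sd_range))
        if stats_out is not None:
            stats_out["values"].append(value)
            stats_out["blur_sds"].append(sd)
        if drawn is None:
            continue
        sl, block = drawn
        if not block.any():
            continue
        margin = int(np.ceil(4 * sd)) + 1
        gsl = _grow(sl, margin, g)
        contrib = np.zeros(tuple(s.stop - s.start for s in gsl), dtype=float)
        inner = tuple(
            slice(s.start - gs.start, s.stop - gs.start) for s, gs in zip(sl, gsl)
        )
        contrib[inner] = value * block
        if sd > 0:
            contrib = ndimage.gaussian_filter(contrib, sd)
        total[gsl] += contrib
        count[sl][block] += 1

    values = total / np.maximum(count, 1)

    mask = np.ones(g, dtype=bool)
    band = np.maximum(1, (spec.border_band * np.asarray(g)).astype(int))
    for _ in range(spec.mask_ellipsoid_count):
        center = np.empty(3)
        for ax in range(3):
            if rng.random() < 0.5:
                center[ax] = rng.uniform(0, band[ax])
            else:
                center[ax] = rng.uniform(g[ax] - 1 - band[ax], g[ax] - 1)
        semi = np.maximum(1.0, rng.uniform(0.02, 0.10, 3) * np.asarray(g))
        lo = np.maximum(0, np.floor(center - semi)).astype(int)
        hi = np.minimum(g, np.ceil(center + semi) + 1).astype(int)
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        coords = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij", sparse=True)
        block = sum(((x - c) / s) ** 2 for x, c, s in zip(coords, center, semi)) <= 1.0
        mask[sl][block] = False

    return SusceptibilityVolume(values=values, mask=mask)


def sample_geometry(
    spec: GeometrySamplerSpec, rng: Optional[np.random.Generator] = None
) -> AcquisitionGeometry:
    """Sample an acquisition geometry (see GeometrySamplerSpec)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if rng.random() >= spec.variation_probability:
        return AcquisitionGeometry((1.0, 1.0, 1.0), (0.0, 0.0, 1.0))
    v = np.empty(3)
    for i in range(3):
        while True:
            draw = rng.normal(spec.voxel_mean, spec.voxel_sd)
            if spec.voxel_bounds[0] <= draw <= spec.voxel_bounds[1]:
                v[i] = draw
                break
    o = np.array(
        [
            rng.normal(0.0, spec.orient_sd_xy),
            rng.normal(0.0, spec.orient_sd_xy),
            1.0 + rng.normal(0.0, spec.orient_sd_z),
        ]
    )
    if np.linalg.norm(o) < 1e-6:  # vanishingly unlikely; resample axially
        o = np.array([0.0, 0.0, 1.0])
    return AcquisitionGeometry(tuple(v), tuple(o))


# ---------------------------------------------------------------------------
# Augmentation and pairing


@dataclass(frozen=True)
class AugmentOptions:
    """Patch augmentations: susceptibility scaling, Gaussian noise, exact
    flips and 90-degree rotations."""

    scale: bool = True
    scale_range: Tuple[float, float] = (0.5, 2.0)
    noise: bool = False
    noise_sd: float = 0.01
    flip: bool = True
    rot90: bool = True


def augment_patch(
    patch: np.ndarray, rng: np.random.Generator, options: AugmentOptions = AugmentOptions()
) -> np.ndarray:
    """Apply the enabled augmentation subset to a 3D patch."""
    out = np.asarray(patch, dtype=float)
    if options.scale:
        out = out * rng.uniform(*options.scale_range)
    if options.flip:
        for ax in range(3):
            if rng.random() < 0.5:
                out = np.flip(out, axis=ax)
    if options.rot90:
        ax = int(rng.integers(0, 3))
        k = int(rng.integers(0, 4))
        axes = [(1, 2), (0, 2), (0, 1)][ax]
        out = np.rot90(out, k=k, axes=axes)
    if options.noise:
        out = out + rng.normal(0.0, options.noise_sd, size=out.shape)
    return np.ascontiguousarray(out)


def make_training_example(
    scene: SusceptibilityVolume, geometry: AcquisitionGeometry
) -> Tuple[LocalFieldVolume, SusceptibilityVolume, np.ndarray]:
    """Pair a scene with its forward-simulated field under ``geometry``."""
    chi = SusceptibilityVolume(values=scene.values, geometry=geometry, mask=scene.mask)
    b = forward_field(chi)
    return b, chi, geometry.side_info


def insert_lesions(chi: SusceptibilityVolume, spec: LesionSpec) -> SusceptibilityVolume:
    """Add smoothed, labelled lesions into a susceptibility map."""
    labels = spec.label_mask
    if labels.shape != chi.values.shape:
        raise ContractError(f"label mask shape {labels.shape} != volume shape {chi.values.shape}")
    present = set(np.unique(labels)) - {0}
    unknown = present - set(int(k) for k in spec.values)
    if unknown:
        raise ValueError(f"labels without assigned susceptibility: {sorted(unknown)}")
    component = np.zeros_like(chi.values)
    for lab in sorted(present):
        component[labels == lab] = float(spec.values[int(lab)])
    if spec.smoothing_sd > 0 and present:
        component = ndimage.gaussian_filter(component, spec.smoothing_sd)
    return SusceptibilityVolume(
        values=chi.values + component, geometry=chi.geometry, mask=chi.mask
    )


def resample_trilinear(
    volume: SusceptibilityVolume, new_voxel_size: Sequence[float]
) -> SusceptibilityVolume:
    """Trilinear resampling onto a grid with the requested voxel size.

    Voxel 0 centers are aligned between grids; the new grid covers the same
    physical extent (rounded to whole voxels).
    """
    new_v = np.asarray(new_voxel_size, dtype=float)
    if np.any(new_v <= 0):
        raise ValueError("target voxel size must be positive")
    old_v = np.asarray(volume.geometry.voxel_size)
    old_n = np.asarray(volume.values.shape)
    new_n = np.maximum(1, np.round(old_n * old_v / new_v).astype(int))
    coords = np.meshgrid(
        *[np.arange(n) * nv / ov for n, nv, ov in zip(new_n, new_v, old_v)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(volume.values, np.stack(coords), order=1, mode="nearest")
    geom = AcquisitionGeometry(tuple(new_v), volume.geometry.b0_direction)
    mask = None
    if volume.mask is not None:
        m = ndimage.map_coordinates(
            volume.mask.astype(float), np.stack(coords), order=1, mode="nearest"
        )
        mask = m >= 0.5
    return SusceptibilityVolume(values=out, geometry=geom, mask=mask)


def scene_spec_scaled(spec: ShapeSceneSpec, grid_shape: Tuple[int, int, int]) -> ShapeSceneSpec:
    """Same recipe on a different grid (counts unchanged)."""
    return replace(spec, grid_shape=grid_shape)
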
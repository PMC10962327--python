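"""Tests of the synthetic phantom generator."""

import numpy as np
import pytest

from adaptqsm.dipole import AcquisitionGeometry, SusceptibilityVolume
from adaptqsm.phantoms import (
    AugmentOptions,
    GeometrySamplerSpec,
    LesionSpec,
    ShapeSceneSpec,
    augment_patch,
    insert_lesions,
    make_training_example,
    rasterize_box,
    rasterize_ellipsoid,
    rasterize_polygon,
    resample_trilinear,
    sample_geometry,
    sample_scene,
)

SMALL = ShapeSceneSpec(grid_shape=(32, 32, 32), seed=11)


class TestRasterizers:
    def test_box_counts(self):
        assert rasterize_box((0, 0, 0), (2, 3, 4), (8, 8, 8)).sum() == 24
        assert rasterize_box((3, 3, 3), (3, 3, 3), (8, 8, 8)).sum() == 0
        assert rasterize_box((0, 0, 0), (8, 8, 8), (8, 8, 8)).sum() == 512
        with pytest.raises(ValueError):
            rasterize_box((4, 4, 4), (2, 2, 2), (8, 8, 8))

    def test_ellipsoid_counts(self):
        one = rasterize_ellipsoid((4, 4, 4), (0.5, 0.5, 0.5), (9, 9, 9))
        assert one.sum() == 1 and one[4, 4, 4]
        # brute-force enumeration oracle over the full grid
        c, a = (8.0, 7.5, 9.0), (3.0, 4.0, 5.0)
        vol = rasterize_ellipsoid(c, a, (18, 18, 18))
        brute = 0
        for x in range(18):
            for y in range(18):
                for z in range(18):
                    q = ((x - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2 + ((z - c[2]) / a[2]) ** 2
                    brute += q <= 1.0
        assert vol.sum() == brute
        assert rasterize_ellipsoid((-50, -50, -50), (2, 2, 2), (8, 8, 8)).sum() == 0
        with pytest.raises(ValueError):
            rasterize_ellipsoid((0, 0, 0), (1, -1, 1), (8, 8, 8))

    def test_polygon_matches_brute_force_point_in_polygon(self):
        verts = [(1.2, 1.1), (9.4, 2.3), (5.1, 8.8)]
        vol = rasterize_polygon(verts, (2, 5), (12, 12, 8))

        def inside(px, py):  # crossing-number test
            cnt = False
            n = len(verts)
            for i in range(n):
                x1, y1 = verts[i]
                x2, y2 = verts[(i + 1) % n]
                if (y1 > py) != (y2 > py):
                    xc = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
                    if px < xc:
                        cnt = not cnt
            return cnt

        brute = sum(inside(x, y) for x in range(12) for y in range(12))
        assert vol[:, :, 2].sum() == brute
        assert vol.sum() == brute * 3  # replicated across the slab

    def test_square_polygon_equals_box(self):
        sq = rasterize_polygon([(-0.5, -0.5), (3.5, -0.5), (3.5, 2.5), (-0.5, 2.5)], (0, 4), (8, 8, 8))
        box = rasterize_box((0, 0, 0), (4, 3, 4), (8, 8, 8))
        np.testing.assert_array_equal(sq, box)

    def test_polygon_edge_cases(self):
        assert rasterize_polygon([(0, 0), (5, 0), (2, 4)], (3, 3), (8, 8, 8)).sum() == 0
        with pytest.raises(ValueError):
            rasterize_polygon([(0, 0), (1, 1), (2, 2)], (0, 2), (8, 8, 8))


class TestSceneSampler:
    def test_determinism(self):
        a = sample_scene(SMALL)
        b = sample_scene(SMALL)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.values.shape == a.mask.shape == (32, 32, 32)

    def test_empty_spec_gives_zero_scene_full_mask(self):
        spec = ShapeSceneSpec(
            grid_shape=(16, 16, 16),
            rectangle_count=(0, 0),
            ellipsoid_count=(0, 0),
            polygon_count=0,
            mask_ellipsoid_count=0,
        )
        scene = sample_scene(spec)
        assert np.all(scene.values == 0)
        assert np.all(scene.mask)

    def test_scene_susceptibility_scale(self):
        """Scene values stay within the brain-like ppm range implied by the
        N(0, 0.25 ppm) per-shape draw."""
        scene = sample_scene(SMALL)
        assert np.abs(scene.values).max() < 2.0
        assert np.abs(scene.values).max() > 0.01

    def test_shape_counts_within_ranges(self):
        for seed in range(30):
            stats = {}
            sample_scene(
                ShapeSceneSpec(grid_shape=(8, 8, 8), mask_ellipsoid_count=0, seed=seed),
                stats_out=stats,
            )
            assert 80 <= stats["n_rect"] <= 150
            assert 200 <= stats["n_ellipsoid"] <= 300
            assert stats["n_polygon"] == 50

    def test_shape_value_distribution(self):
        """Per-shape susceptibility draws follow N(0, 0.25 ppm) and blur sds
        stay in [0, 0.8] voxels (3 standard-error check at n = 10^4)."""
        spec = ShapeSceneSpec(
            grid_shape=(8, 8, 8),
            rectangle_count=(10_000, 10_000),
            ellipsoid_count=(0, 0),
            polygon_count=0,
            mask_ellipsoid_count=0,
            seed=5,
        )
        stats = {}
        sample_scene(spec, stats_out=stats)
        vals = np.asarray(stats["values"])
        sds = np.asarray(stats["blur_sds"])
        n = vals.size
        assert n == 10_000
        assert abs(vals.mean()) < 3 * 0.25 / np.sqrt(n)
        assert abs(vals.std() - 0.25) < 3 * 0.25 / np.sqrt(2 * n)
        assert sds.min() >= 0.0 and sds.max() <= 0.8


class TestGeometrySampler:
    def test_no_variation_returns_standard(self):
        spec = GeometrySamplerSpec(variation_probability=0.0)
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = sample_geometry(spec, rng)
            assert g.voxel_size == (1.0, 1.0, 1.0)
            assert g.b0_direction == (0.0, 0.0, 1.0)

    def test_contract_over_many_draws(self):
        spec = GeometrySamplerSpec(variation_probability=1.0)
        rng = np.random.default_rng(2)
        for _ in range(500):
            g = sample_geometry(spec, rng)
            assert np.isclose(np.linalg.norm(g.b0_direction), 1.0, atol=1e-9)
            assert all(0.5 <= v <= 3.5 for v in g.voxel_size)

    def test_determinism(self):
        spec = GeometrySamplerSpec(seed=9)
        assert sample_geometry(spec) == sample_geometry(spec)

    def test_standard_fraction(self):
        spec = GeometrySamplerSpec(variation_probability=0.8)
        rng = np.random.default_rng(3)
        std = sum(
            sample_geometry(spec, rng) == AcquisitionGeometry((1, 1, 1), (0, 0, 1))
            for _ in range(2000)
        )
        assert 0.15 < std / 2000 < 0.25


class TestAugmentations:
    def test_flip_twice_is_identity(self):
        x = np.random.default_rng(0).normal(size=(6, 6, 6))
        np.testing.assert_array_equal(np.flip(np.flip(x, 0), 0), x)
        # augment with flips only is always an exact voxel permutation
        opts = AugmentOptions(scale=False, noise=False, rot90=False)
        out = augment_patch(x, np.random.default_rng(1), opts)
        assert sorted(out.ravel()) == sorted(x.ravel())

    def test_rot90_four_times_identity(self):
        x = np.random.default_rng(0).normal(size=(6, 6, 6))
        y = x
        for _ in range(4):
            y = np.rot90(y, 1, axes=(0, 2))
        np.testing.assert_array_equal(y, x)

    def test_pure_scaling(self):
        x = np.random.default_rng(0).normal(size=(4, 4, 4))
        opts = AugmentOptions(scale=True, scale_range=(1.7, 1.7), noise=False, flip=False, rot90=False)
        out = augment_patch(x, np.random.default_rng(1), opts)
        np.testing.assert_allclose(out, 1.7 * x, rtol=1e-15)


class TestPairingAndLesions:
    def test_zero_scene_zero_field_and_linearity(self):
        geom = AcquisitionGeometry((1, 1, 2), (0.1, 0.0, 1.0))
        zero = SusceptibilityVolume(np.zeros((16, 16, 16)))
        b, chi, s = make_training_example(zero, geom)
        assert np.all(b.values == 0)
        np.testing.assert_allclose(s, geom.side_info)
        scene = sample_scene(ShapeSceneSpec(grid_shape=(16, 16, 16), seed=3))
        b1, _, _ = make_training_example(scene, geom)
        scene2 = SusceptibilityVolume(2 * scene.values, mask=scene.mask)
        b2, _, _ = make_training_example(scene2, geom)
        np.testing.assert_allclose(b2.values, 2 * b1.values, atol=1e-12)

    def test_lesion_insertion(self):
        base = SusceptibilityVolume(np.zeros((16, 16, 16)))
        labels = np.zeros((16, 16, 16), dtype=int)
        labels[2:8, 2:8, 2:8] = 3  # value 0.5
        spec = LesionSpec(label_mask=labels, smoothing_sd=0.0)
        out = insert_lesions(base, spec)
        assert out.values[4, 4, 4] == 0.5
        assert out.values[12, 12, 12] == 0.0
        # smoothing keeps deep-interior value, softens the boundary
        sm = insert_lesions(base, LesionSpec(label_mask=labels))
        assert sm.values[5, 5, 5] == pytest.approx(0.5, rel=1e-6)
        assert 0 < sm.values[8, 4, 4] < 0.5
        # empty mask is the identity
        empty = insert_lesions(base, LesionSpec(label_mask=np.zeros((16, 16, 16), dtype=int)))
        np.testing.assert_array_equal(empty.values, base.values)
        # default lesion susceptibilities
        assert sorted(LesionSpec(label_mask=labels).values.values()) == [-1.0, -0.5, 0.5, 1.0]

    def test_unknown_label_rejected(self):
        labels = np.zeros((8, 8, 8), dtype=int)
        labels[0, 0, 0] = 9
        with pytest.raises(ValueError):
            insert_lesions(SusceptibilityVolume(np.zeros((8, 8, 8))), LesionSpec(label_mask=labels))


class TestResampling:
    def test_identity(self):
        vol = SusceptibilityVolume(np.random.default_rng(0).normal(size=(8, 8, 8)))
        out = resample_trilinear(vol, (1, 1, 1))
        np.testing.assert_allclose(out.values, vol.values)

    def test_constant_stays_constant(self):
        vol = SusceptibilityVolume(np.full((8, 8, 8), 0.7))
        out = resample_trilinear(vol, (0.6, 1.3, 2.1))
        np.testing.assert_allclose(out.values, 0.7)

    def test_ramp_halved(self):
        z = np.arange(16, dtype=float)
        vol = SusceptibilityVolume(np.broadcast_to(z, (16, 16, 16)).copy())
        out = resample_trilinear(vol, (1, 1, 2))
        assert out.values.shape == (16, 16, 8)
        np.testing.assert_allclose(out.values[0, 0], 2 * np.arange(8.0), atol=1e-12)

    def test_invalid_target(self):
        vol = SusceptibilityVolume(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            resample_trilinear(vol, (0, 1, 1))
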
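"""Phantom generator: rasterisation, ground-truth mass, presets, kinetics series."""

import math
import warnings

import numpy as np
import pytest

from _util import straight_planar_config
from rifiber.errors import ValidationError
from rifiber.phantom import (
    FiberSpec,
    GenerationError,
    PhantomConfig,
    PolymerizationConfig,
    cell_density_from_seeding,
    generate_phantom,
    generate_polymerization_series,
    phantom_preset,
    rasterize_fiber,
    true_fiber_mass,
)


class TestTrueFiberMass:
    def test_zero_contrast_gives_zero_mass(self):
        f = FiberSpec(np.array([[0, 0, 0], [0, 0, 10.0]]), radius_um=0.5, ri_contrast=0.0)
        assert true_fiber_mass(f) == 0.0

    def test_hand_computed_cylinder(self):
        # C = 0.018/0.18 = 0.1 g/mL; V = pi * 0.25 * 10 = 7.854 um^3 -> 0.7854 pg
        f = FiberSpec(np.array([[0, 0, 0], [0, 0, 10.0]]), radius_um=0.5, ri_contrast=0.018)
        assert true_fiber_mass(f, alpha=0.18) == pytest.approx(0.1 * math.pi * 0.25 * 10)

    def test_mass_scales_with_radius_squared(self):
        pts = np.array([[0, 0, 0], [0, 0, 10.0]])
        m1 = true_fiber_mass(FiberSpec(pts, radius_um=0.5, ri_contrast=0.02))
        m2 = true_fiber_mass(FiberSpec(pts, radius_um=1.0, ri_contrast=0.02))
        assert m2 == pytest.approx(4 * m1)

    def test_invalid_alpha_rejected(self):
        f = FiberSpec(np.array([[0, 0, 0], [0, 0, 1.0]]), radius_um=0.5, ri_contrast=0.02)
        with pytest.raises(ValidationError):
            true_fiber_mass(f, alpha=0.0)


class TestRasterization:
    def test_voxel_count_matches_brute_force_cylinder_oracle(self):
        # straight axis-aligned tube, radius 2.5 px; independent oracle counts
        # voxel centers inside the analytic cylinder
        vox = (0.2, 0.2, 0.2)
        r, y0, z0 = 0.5, 6.43, 2.07
        x0, x1 = 2.0, 10.0
        fiber = FiberSpec(
            np.array([[z0, y0, x0], [z0, y0, x1]]), radius_um=r, ri_contrast=0.02
        )
        canvas = np.zeros((20, 64, 64))
        rasterize_fiber(canvas, fiber, vox)
        zz, yy, xx = np.meshgrid(
            np.arange(20) * 0.2, np.arange(64) * 0.2, np.arange(64) * 0.2, indexing="ij"
        )
        oracle = (
            ((zz - z0) ** 2 + (yy - y0) ** 2 <= r**2) & (xx >= x0) & (xx <= x1)
        )
        assert np.array_equal(canvas > 0, oracle)
        count_volume = oracle.sum() * np.prod(vox)
        analytic = math.pi * r**2 * (x1 - x0)
        assert count_volume == pytest.approx(analytic, rel=0.05)


class TestGeneratePhantom:
    def test_empty_phantom_is_pure_medium(self):
        cfg = PhantomConfig(shape_vox=(6, 32, 32), n_fibers=0, noise_sd=0.0)
        tomo, truth = generate_phantom(cfg)
        assert np.all(tomo.values == np.float32(cfg.medium_ri))
        assert truth.fibers == []

    def test_seeded_determinism(self):
        cfg = straight_planar_config(seed=11, n_fibers=3)
        a, _ = generate_phantom(cfg)
        b, _ = generate_phantom(cfg)
        assert np.array_equal(a.values, b.values)

    def test_mass_conservation_on_clean_phantom(self):
        # PSF-free, noiseless, non-overlapping: voxel-sum mass vs analytic truth
        for seed in (0, 1, 2):
            cfg = straight_planar_config(seed=seed)
            tomo, truth = generate_phantom(cfg)
            voxel_mass = float(tomo.delta_n().sum()) * tomo.voxel_volume_um3 / 0.18
            assert voxel_mass == pytest.approx(truth.total_mass_pg(), rel=0.05)

    def test_subvoxel_radius_warns(self):
        cfg = PhantomConfig(
            shape_vox=(8, 64, 64),
            n_fibers=1,
            width_lognormal=(0.2, 0.0),  # 0.1 um radius < dz/2
            noise_sd=0.0,
            planar=True,
            fiber_length_um=(5.0, 8.0),
        )
        with pytest.warns(UserWarning, match="sub-voxel"):
            generate_phantom(cfg)

    def test_infeasible_crowding_raises(self):
        cfg = PhantomConfig(
            shape_vox=(6, 48, 48),
            voxel_size=(0.4, 0.2, 0.2),
            n_fibers=60,
            min_separation_um=2.0,
            planar=True,
            noise_sd=0.0,
            fiber_length_um=(6.0, 8.0),
        )
        with pytest.raises(GenerationError):
            generate_phantom(cfg)

    def test_subtype_presets_order_true_diameters(self):
        # type I is thicker/bundled; type III finer — at every tested seed
        for seed in range(5):
            t1, truth1 = generate_phantom(
                phantom_preset("type_I", 0.8, seed=seed, shape_vox=(8, 128, 128))
            )
            t3, truth3 = generate_phantom(
                phantom_preset("type_III", 0.8, seed=seed, shape_vox=(8, 128, 128))
            )
            d1 = np.median([f.diameter_um for f in truth1.fibers])
            d3 = np.median([f.diameter_um for f in truth3.fibers])
            assert d1 > d3


class TestPolymerizationSeries:
    BASE = dict(
        shape_vox=(6, 48, 48),
        n_fibers=3,
        noise_sd=0.0,
        planar=True,
        fiber_length_um=(5.0, 8.0),
    )

    def test_noiseless_series_matches_saturating_targets(self):
        cfg = PolymerizationConfig(
            time_points_min=(0.0, 30.0, 60.0),
            dn_max=0.01,
            tau_min=30.0,
            base=PhantomConfig(**self.BASE),
            seed=2,
        )
        series, targets = generate_polymerization_series(cfg)
        # hand-evaluated 1 - e^{-t/tau} at t = 0, 30, 60 with tau = 30
        np.testing.assert_allclose(
            targets, [0.0, 0.01 * 0.6321206, 0.01 * 0.8646647], rtol=1e-6
        )
        for frame, target in zip(series.frames, targets):
            measured = float(np.clip(frame.values - frame.medium_ri, 0, None).mean())
            assert measured == pytest.approx(target, rel=0.05, abs=1e-9)

    def test_single_time_zero_frame(self):
        cfg = PolymerizationConfig(
            time_points_min=(0.0,), base=PhantomConfig(**self.BASE), seed=0
        )
        series, targets = generate_polymerization_series(cfg)
        assert len(series) == 1
        assert targets[0] == 0.0
        assert float(np.clip(series.frames[0].values - 1.337, 0, None).mean()) == 0.0

    def test_noiseless_series_is_non_decreasing(self):
        cfg = PolymerizationConfig(
            time_points_min=tuple(np.arange(0.0, 61.0, 5.0)),
            base=PhantomConfig(**self.BASE),
            seed=4,
        )
        series, _ = generate_polymerization_series(cfg)
        means = [float(np.clip(f.values - 1.337, 0, None).mean()) for f in series.frames]
        assert np.all(np.diff(means) >= 0)

    def test_fiber_count_growth_mode_hits_targets(self):
        cfg = PolymerizationConfig(
            time_points_min=(0.0, 15.0, 45.0, 90.0),
            dn_max=0.008,
            tau_min=25.0,
            base=PhantomConfig(**{**self.BASE, "n_fibers": 6}),
            growth_mode="fibers",
            seed=5,
        )
        series, targets = generate_polymerization_series(cfg)
        for frame, target in zip(series.frames, targets):
            measured = float(np.clip(frame.values - frame.medium_ri, 0, None).mean())
            assert measured == pytest.approx(target, rel=0.05, abs=1e-9)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError):
            PolymerizationConfig(
                time_points_min=(0.0, 10.0, 10.0), base=PhantomConfig(**self.BASE)
            )


class TestCellDensity:
    def test_published_seeding_density(self):
        # 8,000 cells in a 60 uL gel -> 1.3e5 cells/mL at two significant figures
        assert cell_density_from_seeding(8000, 60, sig_figs=2) == pytest.approx(1.3e5)

    def test_zero_cells(self):
        assert cell_density_from_seeding(0, 60) == 0.0

    def test_one_ml_identity(self):
        assert cell_density_from_seeding(1000, 1000) == pytest.approx(1000.0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValidationError):
            cell_density_from_seeding(100, 0)
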
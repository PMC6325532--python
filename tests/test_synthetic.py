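"""Tests for the synthetic paired-acquisition generator."""

import filecmp

import numpy as np
import pytest

from lightstripe import beams, synthetic as syn
from lightstripe.synthetic import (
    LEFT_TO_RIGHT,
    RIGHT_TO_LEFT,
    AcquisitionConfig,
    DatasetConfig,
    Obstacle,
    Phantom,
    PhantomParams,
    attenuation_bessel,
    attenuation_gaussian,
    bulk_attenuation,
    generate_dataset,
    make_phantom,
    render_slice,
    truth_stripe_fraction,
)

NOISE_FREE = dict(noise=None, bessel_haze_fraction=0.0)


def uniform_phantom(shape=(1, 200, 320), value=1.0, pixel_size=10.4):
    """Full-support phantom with constant density, for geometric tests."""
    mask = np.ones(shape, bool)
    return Phantom(np.full(shape, value, np.float32), mask, pixel_size)


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


class TestPhantom:
    def test_same_seed_is_voxel_identical(self):
        a = make_phantom("mixed", (8, 64, 64), seed=5)
        b = make_phantom("mixed", (8, 64, 64), seed=5)
        assert np.array_equal(a.density, b.density)
        assert np.array_equal(a.brain_mask, b.brain_mask)

    def test_different_seed_differs(self):
        a = make_phantom("mixed", (8, 64, 64), seed=5)
        b = make_phantom("mixed", (8, 64, 64), seed=6)
        assert not np.array_equal(a.density, b.density)

    def test_zero_blobs_zero_background_is_empty(self):
        p = PhantomParams(background=0.0, n_somata=0)
        ph = make_phantom("somata", (4, 32, 32), params=p, seed=0)
        assert np.all(ph.density == 0)

    def test_vessel_occupancy_within_expected_bounds(self):
        # structure (above background) occupies a small but nonzero share of
        # the brain: tubes of 3-10 µm radius and ~1.6 mm length, 40 of them,
        # mostly wandering off a grid this size
        p = PhantomParams(background=0.0)
        for seed in range(10):
            ph = make_phantom("vessels", (16, 96, 96), params=p, seed=seed)
            frac = (ph.density > 0).sum() / ph.brain_mask.sum()
            assert 0.002 < frac < 0.15

    def test_density_vanishes_outside_mask(self):
        ph = make_phantom("mixed", (6, 48, 48), seed=1)
        assert np.all(ph.density[~ph.brain_mask] == 0)
        assert np.all(ph.density >= 0)

    def test_background_fills_mask(self):
        ph = make_phantom("somata", (4, 32, 32), params=PhantomParams(n_somata=0), seed=0)
        assert np.all(ph.density[ph.brain_mask] == pytest.approx(0.2))

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            make_phantom("axons", (4, 32, 32))

    def test_incongruent_grids_rejected(self):
        with pytest.raises(ValueError):
            Phantom(np.zeros((2, 4, 4), np.float32), np.ones((2, 4, 5), bool), 10.4)


# ---------------------------------------------------------------------------
# Attenuation models
# ---------------------------------------------------------------------------


class TestGaussianAttenuation:
    def test_no_obstacles_all_ones(self):
        mask = np.ones((20, 30), bool)
        att = attenuation_gaussian(mask, [], LEFT_TO_RIGHT)
        assert np.array_equal(att, np.ones((20, 30)))

    def test_opaque_obstacle_zero_to_edge(self):
        mask = np.ones((21, 40), bool)
        ob = Obstacle((0.0, 10 * 10.4, 5 * 10.4), 10.4, 0.0)
        att = attenuation_gaussian(mask, [ob], LEFT_TO_RIGHT, z_um=0.0)
        band = np.abs(np.arange(21) - 10) <= 1
        assert np.all(att[band][:, 5:] == 0.0)  # exactly zero to the edge
        assert np.all(att[~band] == 1.0)
        assert np.all(att[band][:, :5] == 1.0)

    def test_two_half_transmitting_obstacles_multiply(self):
        mask = np.ones((11, 40), bool)
        obs = [
            Obstacle((0.0, 5 * 10.4, 3 * 10.4), 5.0, 0.5),
            Obstacle((0.0, 5 * 10.4, 10 * 10.4), 5.0, 0.5),
        ]
        att = attenuation_gaussian(mask, obs, LEFT_TO_RIGHT, z_um=0.0)
        assert att[5, 20] == pytest.approx(0.25)
        assert att[5, 5] == pytest.approx(0.5)
        assert att[5, 0] == pytest.approx(1.0)

    def test_right_to_left_direction(self):
        mask = np.ones((11, 40), bool)
        ob = Obstacle((0.0, 5 * 10.4, 30 * 10.4), 5.0, 0.0)
        att = attenuation_gaussian(mask, [ob], RIGHT_TO_LEFT, z_um=0.0)
        assert np.all(att[5, : 30 + 1] == 0.0)
        assert np.all(att[5, 31:] == 1.0)

    def test_unknown_direction_raises(self):
        with pytest.raises(ValueError):
            attenuation_gaussian(np.ones((4, 4), bool), [], "top-down")

    def test_bulk_beer_lambert(self):
        mask = np.ones((4, 10), bool)
        att = bulk_attenuation(mask, LEFT_TO_RIGHT, 0.01, 10.0)
        # path length grows by one pixel (10 µm) per column
        assert att[0, 0] == pytest.approx(np.exp(-0.1))
        assert att[0, 9] == pytest.approx(np.exp(-1.0))


class TestBesselAttenuation:
    BEAM = syn.DEFAULT_BESSEL_BEAM

    def test_finite_shadow_then_full_recovery(self):
        mask = np.ones((11, 400), bool)
        r = 20.0
        ob = Obstacle((0.0, 5 * 10.4, 0.0), r, 0.0)
        att = attenuation_bessel(mask, [ob], LEFT_TO_RIGHT, self.BEAM, z_um=0.0)
        heal_px = (
            syn.HEAL_SCALE
            * beams.shadow_reconstruction_distance(r, self.BEAM.cone_angle_theta)
            / 10.4
        )
        row = att[5]
        assert row[0] == pytest.approx(0.0)  # at the obstacle
        assert np.all(np.diff(row) >= -1e-12)  # monotone recovery
        assert np.all(row[int(np.ceil(heal_px)) + 1 :] == 1.0)  # bounded band
        mid = int(heal_px / 2)
        assert row[mid] == pytest.approx(mid / heal_px, abs=0.02)  # linear ramp

    def test_theta_to_zero_degenerates_to_gaussian(self):
        mask = np.ones((11, 60), bool)
        ob = Obstacle((0.0, 5 * 10.4, 10 * 10.4), 8.0, 0.3)
        # tiny cone angle -> healing length far beyond the grid
        slow = beams.BesselBeamSpec.from_cone_angle(0.488, 1e-6, 1.46, 1000.0)
        att_b = attenuation_bessel(mask, [ob], LEFT_TO_RIGHT, slow, z_um=0.0)
        att_g = attenuation_gaussian(mask, [ob], LEFT_TO_RIGHT, z_um=0.0)
        assert np.allclose(att_b, att_g, atol=1e-3)

    def test_residual_floor(self):
        mask = np.ones((5, 400), bool)
        ob = Obstacle((0.0, 2 * 10.4, 0.0), 10.0, 0.0)
        att = attenuation_bessel(
            mask, [ob], LEFT_TO_RIGHT, self.BEAM, z_um=0.0, residual=0.2
        )
        assert att[2, -1] == pytest.approx(0.8)

    def test_recovery_profile_matches_wave_oracle(self):
        # band-integrated shadow depth of the linear-ramp model vs the
        # angular-spectrum oracle, within 20%, for two obstacle radii
        lam, theta, n, dx = 0.488, 0.05, 1024, 0.75
        field = beams.gaussian_field(n, dx, 150.0) * np.exp(
            1j * beams.axicon_phase(n, dx, theta, lam)
        )
        field = beams.propagate_field(field, 400.0, lam, dx, check_sampling=False)
        _, _, rad = beams.radial_coords(n, dx)
        core = rad <= beams.bessel_core_radius(lam, theta)
        positions = np.arange(0.25, 2.51, 0.25)
        for r_obs in (8.0, 18.0):
            length = beams.shadow_reconstruction_distance(r_obs, theta)
            blocked = beams.apply_obstacle(field, dx, r_obs, 0.0, edge_width=2.0)
            oracle, model = [], []
            for s in positions:
                free = beams.propagate_field(field, s * length, lam, dx, check_sampling=False)
                shad = beams.propagate_field(blocked, s * length, lam, dx, check_sampling=False)
                ratio = (np.abs(shad) ** 2)[core].mean() / (np.abs(free) ** 2)[core].mean()
                oracle.append(max(1.0 - ratio, 0.0))
                model.append(max(1.0 - s / syn.HEAL_SCALE, 0.0))
            assert abs(np.mean(oracle) - np.mean(model)) < 0.2


# ---------------------------------------------------------------------------
# Slice rendering
# ---------------------------------------------------------------------------


class TestRenderSlice:
    def test_zero_obstacles_channels_equal_noise_free(self):
        ph = make_phantom("mixed", (3, 64, 64), seed=2)
        cfg = AcquisitionConfig(**NOISE_FREE)
        pair = render_slice(ph, 1, cfg, [])
        assert not pair.truth_stripe_mask.any()
        assert np.array_equal(pair.gauss_image, pair.bessel_image)

    def test_determinism_bit_identical(self):
        ph = make_phantom("mixed", (3, 64, 64), seed=2)
        cfg = AcquisitionConfig(seed=9)
        obs = syn.place_surface_obstacles(ph, 4, seed=2)
        a = render_slice(ph, 1, cfg, obs)
        b = render_slice(ph, 1, cfg, obs)
        assert np.array_equal(a.gauss_image, b.gauss_image)
        assert np.array_equal(a.bessel_image, b.bessel_image)
        assert np.array_equal(a.truth_stripe_mask, b.truth_stripe_mask)

    def test_truth_mask_contained_in_brain(self):
        ph = make_phantom("mixed", (4, 96, 128), seed=3)
        obs = syn.place_surface_obstacles(ph, 10, seed=3)
        for z in range(4):
            pair = render_slice(ph, z, AcquisitionConfig(seed=3), obs)
            assert not np.any(pair.truth_stripe_mask & ~pair.brain_mask_slice)

    def test_modality_ordering_in_truth_regions(self):
        # noise-free: the Gaussian channel is strictly darker than the Bessel
        # channel inside rescued-stripe regions (opaque obstacles)
        ph = make_phantom("mixed", (3, 96, 128), seed=4)
        obs = syn.place_surface_obstacles(ph, 8, seed=4)
        cfg = AcquisitionConfig(**NOISE_FREE)
        pair = render_slice(ph, 1, cfg, obs)
        if pair.truth_stripe_mask.any():
            g = pair.gauss_image[pair.truth_stripe_mask]
            b = pair.bessel_image[pair.truth_stripe_mask]
            assert g.mean() < b.mean()

    def test_truth_area_matches_geometric_count(self):
        # one opaque obstacle of radius r at the left edge, unidirectional:
        # Gaussian shadow spans the full width over a band of 2r; the Bessel
        # channel heals past 0.95 of the ramp, so the rescued area is
        # band_height x (width - healed columns), a pure geometric count
        px = 10.4
        ph = uniform_phantom((1, 200, 320), pixel_size=px)
        r = 26.0
        ob = Obstacle((0.0, 100 * px, 0.0), r, 0.0)
        cfg = AcquisitionConfig(bidirectional=False, direction=LEFT_TO_RIGHT, **NOISE_FREE)
        pair = render_slice(ph, 0, cfg, [ob])
        heal_px = (
            syn.HEAL_SCALE
            * beams.shadow_reconstruction_distance(r, cfg.bessel_beam.cone_angle_theta)
            / px
        )
        n_rows = int(np.sum(np.abs(np.arange(200) - 100) <= r / px))
        n_cols = 320 - int(np.ceil(0.95 * heal_px))
        expected = n_rows * n_cols
        assert pair.truth_stripe_mask.sum() == pytest.approx(expected, rel=0.10)

    def test_haze_brightens_bessel_channel(self):
        ph = make_phantom("mixed", (3, 64, 64), seed=2)
        cfg = AcquisitionConfig(noise=None, bessel_haze_fraction=0.1)
        pair = render_slice(ph, 1, cfg, [])
        assert pair.bessel_image.sum() > pair.gauss_image.sum()

    def test_out_of_range_z_raises(self):
        ph = make_phantom("mixed", (2, 32, 32), seed=0)
        with pytest.raises(IndexError):
            render_slice(ph, 5, AcquisitionConfig(), [])

    def test_invalid_haze_fraction_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionConfig(bessel_haze_fraction=1.5)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


SMALL = DatasetConfig(shape=(3, 64, 80), n_obstacles=4, seed=11)


class TestGenerateDataset:
    def test_manifest_fraction_self_consistent(self):
        man = generate_dataset(SMALL, out_dir=None)
        arrays = man["arrays"]
        for z, frac in enumerate(man["truth_stripe_fraction_percent"]):
            n_brain = arrays["brain_mask"][z].sum()
            recomputed = 100.0 * arrays["truth_mask"][z].sum() / n_brain if n_brain else 0.0
            assert frac == pytest.approx(recomputed)

    def test_zero_slices_valid_manifest(self):
        man = generate_dataset(SMALL, n_slices=0, out_dir=None)
        assert man["n_slices"] == 0
        assert man["arrays"]["gauss"].shape == (0, 64, 80)
        assert man["truth_stripe_fraction_percent"] == []

    def test_regeneration_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(SMALL, out_dir=d1)
        generate_dataset(SMALL, out_dir=d2)
        for name in ["gauss.tif", "bessel.tif", "truth_mask.tif", "brain_mask.tif", "manifest.json"]:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_written_files_match_arrays(self, tmp_path):
        import tifffile

        man = generate_dataset(SMALL, out_dir=tmp_path)
        in_memory = generate_dataset(SMALL, out_dir=None)["arrays"]
        on_disk = tifffile.imread(tmp_path / "gauss.tif")
        assert np.array_equal(
            on_disk, np.clip(np.round(in_memory["gauss"]), 0, 65535).astype(np.uint16)
        )
        assert (tmp_path / "manifest.json").exists()
        assert man["files"]["gauss"] == "gauss.tif"


# ---------------------------------------------------------------------------
# Targeted stripe-fraction construction
# ---------------------------------------------------------------------------


class TestObstaclesForFraction:
    def test_reaches_target_fraction(self):
        ph = make_phantom("mixed", (1, 128, 160), seed=7, pixel_size=10.4)
        cfg = AcquisitionConfig(**NOISE_FREE)
        obs = syn.obstacles_for_stripe_fraction(
            ph, 0, cfg, target_percent=10.0, seed=7, truth_mode="gaussian"
        )
        pair = render_slice(ph, 0, cfg, obs)
        assert syn.gaussian_shadow_fraction(pair) == pytest.approx(10.0, abs=3.0)

    def test_truth_fraction_helpers(self):
        ph = uniform_phantom((1, 50, 60))
        cfg = AcquisitionConfig(bidirectional=False, **NOISE_FREE)
        pair = render_slice(ph, 0, cfg, [])
        assert truth_stripe_fraction(pair) == 0.0
        assert syn.gaussian_shadow_fraction(pair) == 0.0
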
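"""Synthetic scene generator: point processes, rendering, fission, fields."""

import dataclasses

import numpy as np
import pytest

from mitospread import (
    FundusSpec,
    GroundTruth,
    SceneSpec,
    apply_fission,
    render_axon_scene,
    render_fundus_stack,
    render_nucleus_field,
    sample_positions,
)
from mitospread.dispersion import compartmentalize, id_index
from mitospread.errors import ParameterError, PlacementError
from mitospread.synthetic import sample_areas, substream

from conftest import DEMO_SCENE


class TestSamplePositions:
    def test_zero_jitter_lattice_is_exact(self):
        pos = sample_positions("uniform", 100.0, density_per_um=1.0,
                               jitter_sd_um=0.0)
        np.testing.assert_allclose(pos, np.arange(100) + 0.5)

    def test_jitter_keeps_count_and_range(self):
        pos = sample_positions("uniform", 100.0, density_per_um=1.2,
                               jitter_sd_um=5.0, seed=1)
        assert len(pos) == 120                      # reflection loses nothing
        assert pos.min() >= 0 and pos.max() <= 100
        assert np.all(np.diff(pos) >= 0)

    def test_nearest_neighbour_cv_vanishes_with_jitter(self):
        cv = []
        for jit in (1.0, 0.1, 0.0):
            pos = sample_positions("uniform", 500.0, density_per_um=1.0,
                                   jitter_sd_um=jit, seed=2)
            gaps = np.diff(pos)
            cv.append(gaps.std() / gaps.mean())
        assert cv[0] > cv[1] > cv[2] == 0.0

    def test_poisson_count_within_three_sigma(self):
        # oracle: the count of a homogeneous Poisson process on [0, L]
        # is Poisson(lambda * L); check a fixed draw against 3 sd
        pos = sample_positions("random", 10_000.0, density_per_um=1.2,
                               seed=123)
        assert abs(len(pos) - 12_000) < 3 * np.sqrt(12_000)

    def test_poisson_rate_unbiased_over_seeds(self):
        counts = [len(sample_positions("random", 10_000.0,
                                       density_per_um=1.2, seed=s))
                  for s in range(200)]
        assert np.mean(counts) / 10_000.0 == pytest.approx(1.2, rel=0.02)

    def test_clustered_id_exceeds_one_at_cluster_scale(self):
        med = np.median([
            id_index(compartmentalize(
                sample_positions("clustered", 1000.0,
                                 cluster_rate_per_um=0.05,
                                 cluster_size_mean=8.0, cluster_sd_um=1.0,
                                 seed=s), 1000.0, 10.0))
            for s in range(100)])
        assert med > 1.0

    def test_bad_parameters_rejected(self):
        with pytest.raises(ParameterError):
            sample_positions("spiral", 10.0, density_per_um=1.0)
        with pytest.raises(ParameterError):
            sample_positions("random", 10.0, density_per_um=-1.0)
        with pytest.raises(ParameterError):
            sample_positions("random", 0.0, density_per_um=1.0)


class TestRenderScene:
    def test_zero_density_rejected(self):
        with pytest.raises(ParameterError):
            SceneSpec(density_per_um=0.0)

    def test_short_path_rejected(self):
        from mitospread.errors import GeometryError
        with pytest.raises(GeometryError):
            SceneSpec(axon_control_points=((5.0, 5.0),))

    def test_determinism_bit_identical(self):
        spec = SceneSpec(**DEMO_SCENE, seed=9)
        a = render_axon_scene(spec)
        b = render_axon_scene(SceneSpec(**DEMO_SCENE, seed=9))
        assert np.array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.truth.positions_um,
                                      b.truth.positions_um)
        np.testing.assert_array_equal(a.truth.areas_um2, b.truth.areas_um2)

    def test_noiseless_centroids_lie_in_foreground(self):
        spec = SceneSpec(**{**DEMO_SCENE, "noise_sd": 0.0,
                            "psf_sigma_px": 0.0}, seed=5)
        scene = render_axon_scene(spec)
        fg = scene.image > spec.background_level
        rows = np.round(scene.truth.centroids_px[:, 0]).astype(int)
        cols = np.round(scene.truth.centroids_px[:, 1]).astype(int)
        assert fg[rows, cols].all()
        assert scene.clamp_fraction == 0.0

    def test_truth_arrays_aligned_and_sorted(self):
        scene = render_axon_scene(SceneSpec(**DEMO_SCENE, seed=4))
        t = scene.truth
        assert len(t.positions_um) == len(t.centroids_px) == len(t.areas_um2)
        assert np.all(np.diff(t.positions_um) >= 0)
        assert t.positions_um.min() >= 0
        assert t.positions_um.max() <= t.axon_length_um

    def test_rasterized_area_tracks_truth(self):
        # discretization contract: per-particle pixel area within roughly
        # one perimeter's worth of pixels of the analytic ellipse area
        spec = SceneSpec(**{**DEMO_SCENE, "noise_sd": 0.0,
                            "psf_sigma_px": 0.0,
                            "density_per_um": 0.05}, seed=8)
        scene = render_axon_scene(spec)
        from mitospread import find_particles
        ps = find_particles(scene.image > spec.background_level,
                            spec.pixel_size_um, min_area_um2=0.0)
        assert len(ps) == scene.truth.n
        for rec, true in zip(np.sort(ps.areas_um2),
                             np.sort(scene.truth.areas_um2)):
            a_px = np.sqrt(true * spec.elongation / np.pi) / spec.pixel_size_um
            b_px = a_px / spec.elongation
            perimeter_px = np.pi * (3 * (a_px + b_px)
                                    - np.sqrt((3 * a_px + b_px)
                                              * (a_px + 3 * b_px)))
            assert abs(rec - true) <= perimeter_px * spec.pixel_size_um ** 2


class TestFission:
    def _truth(self, seed=0, n=120, L=100.0):
        rng = substream(seed, "t")
        pos = np.sort(rng.uniform(0, L, n))
        areas = sample_areas(n, 4.3, 1.5, rng)
        cent = np.stack([np.full(n, 80.0), 40 + pos / 0.2], axis=-1)
        return GroundTruth(pos, cent, areas, L)

    def test_identity_at_zero_probability(self):
        t = self._truth()
        out = apply_fission(t, 0.0, seed=1)
        np.testing.assert_array_equal(out.positions_um, t.positions_um)
        np.testing.assert_array_equal(out.areas_um2, t.areas_um2)

    def test_forced_split_doubles_count_halves_area(self):
        t = self._truth()
        out = apply_fission(t, 1.0, seed=1)
        assert out.n == 2 * t.n
        assert out.areas_um2.sum() == pytest.approx(t.areas_um2.sum(),
                                                    abs=1e-12)
        np.testing.assert_allclose(np.sort(out.areas_um2),
                                   np.sort(np.repeat(t.areas_um2 / 2, 2)))

    def test_total_area_conserved_to_machine_precision(self):
        for s in range(20):
            t = self._truth(seed=s)
            out = apply_fission(t, 0.37, seed=s)
            assert out.areas_um2.sum() == pytest.approx(t.areas_um2.sum(),
                                                        abs=1e-9)

    def test_expected_count_scaling(self):
        ratios = [apply_fission(self._truth(seed=s), 0.21, seed=s).n
                  / self._truth(seed=s).n for s in range(200)]
        assert np.mean(ratios) == pytest.approx(1.21, rel=0.02)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ParameterError):
            apply_fission(self._truth(), 1.5)


class TestFundus:
    def test_zero_jitter_full_signal_frames_identical(self):
        spec = FundusSpec(image_shape=(200, 260), disc_center_px=(100, 130),
                          disc_radius_px=15, n_axons=4, axon_length_px=60,
                          noise_sd=0.0, seed=2)
        scene = render_fundus_stack(spec, n_frames=4, jitter_px_sd=0.0,
                                    decay_factor=1.0)
        assert all(np.array_equal(scene.frames[0], f) for f in scene.frames)
        assert scene.true_shifts_px == [(0, 0)] * 4

    def test_decay_halves_intensity(self):
        spec = FundusSpec(image_shape=(200, 260), disc_center_px=(100, 130),
                          disc_radius_px=15, n_axons=4, axon_length_px=60,
                          noise_sd=0.0, background_level=0.0, seed=2)
        full = render_fundus_stack(spec, 1, 0.0, 1.0)
        half = render_fundus_stack(spec, 1, 0.0, 0.5)
        ratio = half.frames[0].mean() / full.frames[0].mean()
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_bad_decay_rejected(self):
        with pytest.raises(ParameterError):
            render_fundus_stack(FundusSpec(), 2, 1.0, 0.0)


class TestNucleusField:
    def test_empty_field(self):
        img, centers, n = render_nucleus_field(0, (128, 128), 5.0, seed=1)
        assert n == 0 and len(centers) == 0

    def test_disks_respect_separation(self):
        _, centers, _ = render_nucleus_field(40, (512, 512), 6.0, seed=3)
        d = np.hypot(*(centers[:, None, :] - centers[None, :, :]
                       ).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * 6.0 + 2.0

    def test_impossible_packing_raises(self):
        with pytest.raises(PlacementError):
            render_nucleus_field(500, (64, 64), 10.0, seed=1,
                                 max_tries_per_cell=50)
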
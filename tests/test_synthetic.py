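"""Generator correctness: exact chain sampling, frame integration, mirrors."""
from __future__ import annotations

import numpy as np
import pytest

from smg4 import (
    BindingModel,
    simulate_emsa,
    simulate_ensemble,
    simulate_fret_traces,
    simulate_movie,
    simulate_mp_events,
    simulate_trajectory,
)
from smg4.synthetic import DEFAULT_INTENSITIES


class TestBindingModelValidation:
    def test_rejects_bad_geometry(self):
        with pytest.raises(ValueError, match="frame_interval"):
            BindingModel.two_state(0.5, 0.6, frame_interval=0.0)
        with pytest.raises(ValueError, match="n_frames"):
            BindingModel.two_state(0.5, 0.6, n_frames=0)
        with pytest.raises(ValueError, match="non-negative"):
            BindingModel.two_state(-0.5, 0.6)
        with pytest.raises(ValueError, match="increase"):
            BindingModel.two_state(0.5, 0.6, state_intensities=(500.0, 0.0))


class TestSimulateTrajectory:
    def test_absorbing_bound_state_gives_constant_trace(self):
        model = BindingModel.two_state(
            0.3, 0.0, noise_sd=0.0, n_frames=200, pre_frames=0
        )
        traj, truth = simulate_trajectory(model, seed=0, start_state=1)
        assert np.allclose(traj.intensities, DEFAULT_INTENSITIES[1])
        assert truth.true_dwells == [(1, pytest.approx(20.0))]

    def test_same_seed_bit_reproducible(self):
        model = BindingModel.two_state(0.5, 0.61, n_frames=500)
        t1, g1 = simulate_trajectory(model, seed=7)
        t2, g2 = simulate_trajectory(model, seed=7)
        assert np.array_equal(t1.intensities, t2.intensities)
        assert np.array_equal(g1.true_state_path, g2.true_state_path)
        assert g1.true_dwells == g2.true_dwells

    def test_pre_injection_frames_are_baseline(self):
        model = BindingModel.two_state(2.0, 0.5, noise_sd=0.0, n_frames=600)
        traj, truth = simulate_trajectory(model, seed=3)
        assert np.all(traj.intensities[:300] == DEFAULT_INTENSITIES[0])
        assert np.all(truth.true_state_path[:300] == 0)

    def test_dwells_tile_observation_window(self):
        model = BindingModel.two_state(0.7, 0.9, n_frames=800)
        _, truth = simulate_trajectory(model, seed=11)
        total = sum(d for _, d in truth.true_dwells)
        assert total == pytest.approx(800 * 0.1, rel=1e-9)

    def test_frame_integration_bounds_intensity(self):
        # noiseless frames are occupancy-weighted averages, so they can
        # never leave the [unbound, bound] intensity interval
        model = BindingModel.two_state(3.0, 3.0, noise_sd=0.0, n_frames=400,
                                       pre_frames=0)
        traj, _ = simulate_trajectory(model, seed=5)
        lo, hi = DEFAULT_INTENSITIES
        assert traj.intensities.min() >= lo - 1e-9
        assert traj.intensities.max() <= hi + 1e-9
        # fast switching must produce genuinely intermediate frames
        assert np.any((traj.intensities > lo + 1) & (traj.intensities < hi - 1))

    def test_bound_dwell_mean_matches_rate(self):
        """Law of large numbers: pooled dwell mean converges to 1/k_off."""
        model = BindingModel.two_state(0.5, 0.61, n_frames=3000)
        _, truths = simulate_ensemble(model, 300, seed=9)
        dwells = np.concatenate([g.dwell_durations(1) for g in truths])
        assert dwells.size > 10_000
        expected = 1 / 0.61
        tol = 3 * expected / np.sqrt(dwells.size)
        assert abs(dwells.mean() - expected) < tol

    def test_bound_occupancy_matches_equilibrium(self):
        model = BindingModel.two_state(0.5, 0.61, n_frames=3000)
        _, truths = simulate_ensemble(model, 100, seed=13)
        occ = np.mean([g.true_state_path[300:].mean() for g in truths])
        assert occ == pytest.approx(0.5 / (0.5 + 0.61), abs=0.02)

    def test_bleaching_darkens_trace_tail(self):
        model = BindingModel.two_state(
            5.0, 0.01, noise_sd=0.0, n_frames=2000, pre_frames=0, bleach_rate=1.0
        )
        traj, _ = simulate_trajectory(model, seed=2, start_state=1)
        assert traj.intensities[-1] == DEFAULT_INTENSITIES[0]


class TestSimulateMovie:
    def test_density_zero_gives_pure_background(self):
        model = BindingModel.two_state(0.5, 0.6, n_frames=5, pre_frames=0)
        mv = simulate_movie(model, n_spots=0, field_size=64, noise_sd=0.0, seed=0)
        assert np.allclose(mv.stack.frames, mv.background)
        assert mv.centers.shape == (0, 2)

    def test_noiseless_spot_conserves_intensity(self):
        model = BindingModel.two_state(0.5, 0.61, n_frames=30, pre_frames=0)
        mv = simulate_movie(
            model, n_spots=1, field_size=64, psf_sigma=1.0, noise_sd=0.0, seed=4,
            start_state=1,
        )
        integrated = mv.stack.frames.sum(axis=(1, 2)) - mv.background * 64 * 64
        assert np.allclose(integrated, mv.trajectories[0].intensities, rtol=1e-6,
                           atol=1e-6)

    def test_rejects_bad_psf(self):
        model = BindingModel.two_state(0.5, 0.6, n_frames=5, pre_frames=0)
        with pytest.raises(ValueError, match="psf_sigma"):
            simulate_movie(model, n_spots=1, psf_sigma=0.0)

    def test_spots_respect_min_separation(self):
        model = BindingModel.two_state(0.5, 0.6, n_frames=5, pre_frames=0)
        mv = simulate_movie(model, n_spots=40, field_size=256, psf_sigma=1.2, seed=6)
        from scipy.spatial.distance import pdist

        assert pdist(mv.centers).min() >= 6 * 1.2


class TestSimulateFret:
    def test_equal_channels_at_half_efficiency(self):
        traces = simulate_fret_traces(0.5, 0.5, 0.0, 1000, leakage=0.0, n=3, seed=0)
        for tr in traces:
            assert np.allclose(tr.donor, tr.acceptor)

    def test_empty_request_gives_empty_list(self):
        assert simulate_fret_traces(0.3, 0.7, 0.5, n=0, seed=0) == []

    def test_rejects_out_of_range_parameters(self):
        with pytest.raises(ValueError, match="frac_high"):
            simulate_fret_traces(0.3, 0.7, 1.5, n=1, seed=0)
        with pytest.raises(ValueError, match="leakage"):
            simulate_fret_traces(0.3, 0.7, 0.5, leakage=0.6, n=1, seed=0)
        with pytest.raises(ValueError, match="e_low"):
            simulate_fret_traces(-0.1, 0.7, 0.5, n=1, seed=0)


class TestSimulateMp:
    def test_single_species_mode_near_mass(self):
        ev = simulate_mp_events([(17.32, 1.0)], mass_sd=2.0, n=5000, seed=1)
        counts, edges = np.histogram(ev, bins=np.arange(0, 40, 3.0))
        mode_bin = np.argmax(counts)
        assert edges[mode_bin] <= 17.32 < edges[mode_bin + 1]

    def test_mirrored_events_mean_zero(self):
        ev = simulate_mp_events(
            [(17.32, 0.5), (55.0, 0.5)], n=2001, include_negatives=True, seed=2
        )
        assert ev.size == 2 * 2001
        assert ev.mean() == pytest.approx(0.0, abs=1e-9)

    def test_rejects_invalid_mixture(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_mp_events([(-5.0, 1.0)], n=10, seed=0)
        with pytest.raises(ValueError, match="mass_sd"):
            simulate_mp_events([(17.0, 1.0)], mass_sd=0.0, n=10, seed=0)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_mp_events([(17.0, 0.4)], n=10, seed=0)


class TestSimulateEmsa:
    def test_half_saturation_at_kd(self):
        iso = simulate_emsa(84.0, [84.0], noise_sd=0.0, seed=0)
        assert iso.fraction_bound[0] == pytest.approx(0.5)

    def test_saturates_at_high_concentration(self):
        iso = simulate_emsa(84.0, [1e9], noise_sd=0.0, seed=0)
        assert iso.fraction_bound[0] == pytest.approx(1.0, abs=1e-6)

    def test_rejects_empty_titration(self):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_emsa(84.0, [], seed=0)
        with pytest.raises(ValueError, match="kd"):
            simulate_emsa(0.0, [1.0], seed=0)
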
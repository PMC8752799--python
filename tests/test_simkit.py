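"""Simulator: structures, binding kinetics, photon statistics."""

import numpy as np
import pytest
from scipy.stats import norm

from flpaint import simkit
from flpaint.errors import InvalidConfigurationError
from flpaint.photonio import ScanGeometry
from flpaint.simkit import (
    SimulationConfig,
    TargetSpec,
    make_structure_map,
    sample_micro_times,
    simulate_binding_events,
    simulate_photons_confocal,
    simulate_photons_widefield,
)


class TestStructures:
    def test_ring_geometry_exact_without_jitter(self):
        st = make_structure_map("ring", {"diameter": 200.0, "center": (500.0, 500.0)}, 12, seed=7)
        radii = np.hypot(st.site_positions[:, 0] - 500.0, st.site_positions[:, 1] - 500.0)
        assert st.n_sites == 12
        np.testing.assert_allclose(radii, 100.0, atol=1e-9)

    def test_peroxisome_diameters_sampled_in_range(self):
        for seed in range(50):
            st = make_structure_map("ring", {"diameter_range": (100.0, 300.0)}, 8, seed=seed)
            assert 100.0 <= st.shape_params["diameter"] <= 300.0

    def test_deterministic_under_fixed_seed(self):
        a = make_structure_map("filament-network", {"extent": 4000.0}, 40, seed=3)
        b = make_structure_map("filament-network", {"extent": 4000.0}, 40, seed=3)
        np.testing.assert_array_equal(a.site_positions, b.site_positions)

    @pytest.mark.parametrize("kind", ["ring", "grid", "filament-network", "mesh"])
    def test_all_shapes_produce_requested_sites(self, kind):
        st = make_structure_map(kind, {}, 17, seed=1)
        assert st.site_positions.shape == (17, 2)

    def test_unknown_shape_rejected(self):
        with pytest.raises(InvalidConfigurationError, match="shape_kind"):
            make_structure_map("dodecahedron", {}, 5, seed=0)

    def test_nonpositive_site_count_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            make_structure_map("ring", {}, 0, seed=0)


def _single_site_target(tau=2.8, rate=0.01, mean_dur=1.0, photons=1000.0, n_sites=1):
    pos = np.tile([[1000.0, 1000.0]], (n_sites, 1))
    st = simkit.GroundTruthStructure(pos, "grid", {})
    return TargetSpec(
        name="t",
        lifetime_tau=tau,
        structure=st,
        event_rate_per_site=rate,
        mean_event_duration=mean_dur,
        photons_per_event_mean=photons,
    )


class TestBindingKinetics:
    def test_zero_rate_gives_no_events(self):
        tgt = _single_site_target(rate=0.0)
        assert simulate_binding_events([tgt], 1000.0, seed=1) == []

    def test_event_count_is_poisson(self):
        # 100 sites x 0.01 /s x 1000 s -> expect 1000 +- 3*sqrt(1000)
        tgt = _single_site_target(rate=0.01, n_sites=100)
        events = simulate_binding_events([tgt], 1000.0, seed=2)
        assert abs(len(events) - 1000) < 3 * np.sqrt(1000)

    def test_durations_exponential_with_requested_mean(self):
        tgt = _single_site_target(rate=0.02, mean_dur=1.5, n_sites=100)
        events = simulate_binding_events([tgt], 2000.0, seed=3)
        # exclude events truncated by the movie end
        full = [e.duration for e in events if e.start_time + e.duration < 2000.0 - 1e-9]
        m = np.mean(full)
        assert abs(m - 1.5) < 3 * 1.5 / np.sqrt(len(full))

    def test_photon_budgets_poisson_fano_factor(self):
        tgt = _single_site_target(rate=0.05, mean_dur=0.5, photons=1000.0, n_sites=250)
        events = simulate_binding_events([tgt], 1000.0, seed=4)
        n = np.array([e.emitted_photons for e in events if e.start_time + e.duration < 999.0])
        assert len(n) > 10_000
        fano = n.var() / n.mean()
        assert 0.9 < fano < 1.1

    def test_events_lie_inside_movie(self):
        tgt = _single_site_target(rate=0.05, n_sites=50)
        for e in simulate_binding_events([tgt], 100.0, seed=5):
            assert 0.0 <= e.start_time <= 100.0
            assert e.start_time + e.duration <= 100.0 + 1e-9


class TestMicroTimes:
    def test_folding_invariant(self, tcspc_config, rng):
        t = sample_micro_times(100_000, 3.7, tcspc_config, rng)
        assert t.min() >= 0.0
        assert t.max() < tcspc_config.tcspc_window

    def test_distribution_matches_convolved_decay(self, tcspc_config, rng):
        """Empirical micro-time CDF agrees with the numerically convolved
        (Exp x Gaussian IRF, folded, quantized) oracle to < 0.01."""
        tau = 3.7
        cfg = tcspc_config
        t = sample_micro_times(100_000, tau, cfg, rng)
        # oracle: fine-grid convolution, folded into the window
        dt = 0.001
        grid = np.arange(0.0, 8 * cfg.tcspc_window, dt)
        exp_pdf = np.exp(-grid / tau) / tau
        irf_sigma = cfg.irf_fwhm / (2 * np.sqrt(2 * np.log(2)))
        kgrid = np.arange(-6 * irf_sigma, 6 * irf_sigma + dt, dt)
        kernel = norm.pdf(kgrid, 0.0, irf_sigma)
        kernel /= kernel.sum()
        conv = np.convolve(exp_pdf, kernel, mode="full") * dt
        offset = cfg.irf_center - 6 * irf_sigma
        centers = np.arange(len(conv)) * dt + offset
        folded = np.mod(centers, cfg.tcspc_window)
        n_bins = int(cfg.tcspc_window / cfg.tcspc_resolution)
        oracle, _ = np.histogram(folded, bins=n_bins, range=(0, cfg.tcspc_window), weights=conv)
        oracle /= oracle.sum()
        emp, _ = np.histogram(t, bins=n_bins, range=(0, cfg.tcspc_window))
        ks = np.max(np.abs(np.cumsum(oracle) - np.cumsum(emp / emp.sum())))
        assert ks < 0.01

    def test_mean_is_irf_shifted_lifetime(self, tcspc_config, rng):
        tau = 1.7
        t = sample_micro_times(20_000, tau, tcspc_config, rng)
        expected = tcspc_config.irf_center + tau  # wrap-around mass ~6e-4, negligible
        assert abs(t.mean() - expected) < 0.05


class TestWidefieldPhotons:
    def _one_event_config(self, background=0.0, drift=(0.0, 0.0)):
        tgt = _single_site_target(tau=2.8, photons=20_000.0, rate=1.0)
        return SimulationConfig(
            targets=(tgt,),
            movie_duration=10.0,
            background_rate=background,
            drift_velocity=drift,
            rng_seed=9,
        )

    def test_stream_time_ordered_and_micro_in_window(self):
        cfg = self._one_event_config(background=10.0)
        events = simulate_binding_events(cfg.targets, cfg.movie_duration, cfg.rng())
        stream = simulate_photons_widefield(events, cfg, seed=1)
        assert np.all(np.diff(stream.macro_time) >= 0)
        assert stream.micro_time.max() < cfg.tcspc_window

    def test_positions_scatter_with_psf_width(self):
        cfg = self._one_event_config()
        events = simulate_binding_events(cfg.targets, cfg.movie_duration, cfg.rng())
        stream = simulate_photons_widefield(events, cfg, seed=2)
        x_nm = stream.x * cfg.native_pixel_size
        # detector quantization (24 nm pixels) adds 24^2/12 variance
        expected = np.sqrt(cfg.psf_sigma**2 + cfg.native_pixel_size**2 / 12)
        assert abs(x_nm.std() - expected) / expected < 0.05

    def test_deterministic_for_fixed_seed(self):
        cfg = self._one_event_config(background=20.0)
        ev1 = simulate_binding_events(cfg.targets, cfg.movie_duration, cfg.rng())
        ev2 = simulate_binding_events(cfg.targets, cfg.movie_duration, cfg.rng())
        s1 = simulate_photons_widefield(ev1, cfg, seed=5)
        s2 = simulate_photons_widefield(ev2, cfg, seed=5)
        assert s1.equals(s2)

    def test_rate_bound_violation_logged(self, caplog):
        import logging

        cfg = self._one_event_config()
        hot = simkit.TruthEvent(
            target_name="t", site_index=0, start_time=1.0, duration=0.01,
            true_position=(1000.0, 1000.0), emitted_photons=10_000, lifetime_tau=2.8,
        )  # 1e6 photons/s instantaneous, above the 3e5 /s detector ceiling
        with caplog.at_level(logging.WARNING, logger="flpaint.simkit"):
            stream = simulate_photons_widefield([hot], cfg, seed=1)
        assert any("photon rate" in r.message for r in caplog.records)
        assert len(stream) > 0  # data unchanged, warning only


class TestConfocalPhotons:
    def test_frame_duration_arithmetic(self):
        assert ScanGeometry(region_um=(20.0, 20.0)).frame_duration_s == pytest.approx(0.1)

    def test_photon_budget_conserved_without_background(self):
        st = simkit.GroundTruthStructure(np.array([[5000.0, 5000.0]]), "grid", {})
        tgt = TargetSpec(
            name="t", lifetime_tau=2.8, structure=st,
            event_rate_per_site=0.05, mean_event_duration=2.0, photons_per_event_mean=3000.0,
        )
        cfg = SimulationConfig(targets=(tgt,), movie_duration=20.0, background_rate=0.0, rng_seed=6)
        events = simulate_binding_events(cfg.targets, cfg.movie_duration, cfg.rng())
        geom = ScanGeometry(region_um=(10.0, 10.0), frames_total=800)  # 0.025 s/frame, 20 s
        stream = simulate_photons_confocal(events, cfg, geom, seed=7)
        assert len(stream) == sum(e.emitted_photons for e in events)

    def test_emitter_outside_scan_region_contributes_nothing(self):
        inside = simkit.GroundTruthStructure(np.array([[2000.0, 2000.0]]), "grid", {})
        tgt_in = TargetSpec(name="in", lifetime_tau=2.8, structure=inside,
                            event_rate_per_site=1.0, photons_per_event_mean=500.0)
        outside = simkit.GroundTruthStructure(np.array([[50_000.0, 50_000.0]]), "grid", {})
        tgt_out = TargetSpec(name="out", lifetime_tau=1.7, structure=outside,
                             event_rate_per_site=1.0, photons_per_event_mean=500.0)
        cfg = SimulationConfig(targets=(tgt_in, tgt_out), movie_duration=10.0,
                               background_rate=0.0, rng_seed=8)
        events = simulate_binding_events(cfg.targets, cfg.movie_duration, cfg.rng())
        geom = ScanGeometry(region_um=(5.0, 5.0), frames_total=1600)
        stream = simulate_photons_confocal(events, cfg, geom, seed=3)
        # all photons must sit near the inside emitter (pixel 20, 20)
        assert len(stream) > 0
        assert np.all(np.abs(stream.x - 20.0) < 10)

    def test_structure_entirely_beyond_raster_is_config_error(self):
        far = simkit.GroundTruthStructure(np.array([[90_000.0, 90_000.0]]), "grid", {})
        tgt = TargetSpec(name="far", lifetime_tau=2.8, structure=far, event_rate_per_site=0.5)
        cfg = SimulationConfig(targets=(tgt,), movie_duration=5.0, rng_seed=1)
        events = simulate_binding_events(cfg.targets, cfg.movie_duration, cfg.rng())
        geom = ScanGeometry(region_um=(5.0, 5.0), frames_total=100)
        with pytest.raises(InvalidConfigurationError, match="scan region"):
            simulate_photons_confocal(events, cfg, geom, seed=1)

    def test_confocal_micro_time_resolution_is_16ps(self):
        st = simkit.GroundTruthStructure(np.array([[2000.0, 2000.0]]), "grid", {})
        tgt = TargetSpec(name="t", lifetime_tau=2.8, structure=st,
                         event_rate_per_site=0.2, photons_per_event_mean=1000.0)
        cfg = SimulationConfig(targets=(tgt,), movie_duration=5.0, background_rate=0.0, rng_seed=2)
        events = simulate_binding_events(cfg.targets, cfg.movie_duration, cfg.rng())
        geom = ScanGeometry(region_um=(5.0, 5.0), frames_total=200)
        stream = simulate_photons_confocal(events, cfg, geom, seed=4)
        assert stream.tcspc_resolution == pytest.approx(0.016)
        # values sit on 16 ps bin centres
        k = stream.micro_time / 0.016 - 0.5
        np.testing.assert_allclose(k, np.round(k), atol=1e-9)


class TestScenarioAndConfig:
    def test_multi_target_scenario_structures_do_not_overlap(self):
        cfg = simkit.multi_target_scenario(seed=23)
        from scipy.spatial.distance import cdist

        sites = [t.structure.site_positions for t in cfg.targets]
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                assert cdist(sites[i], sites[j]).min() > 600.0

    def test_config_from_dict_round_trip(self):
        raw = {
            "movie_duration": 30.0,
            "rng_seed": 4,
            "targets": [
                {
                    "name": "perox",
                    "lifetime_tau": 1.7,
                    "structure": {"shape_kind": "ring", "n_sites": 6,
                                  "shape_params": {"diameter": 200, "center": [2000, 2000]}},
                }
            ],
        }
        cfg = simkit.config_from_dict(raw)
        assert cfg.movie_duration == 30.0
        assert cfg.targets[0].lifetime_tau == 1.7
        assert cfg.targets[0].structure.n_sites == 6

    def test_invalid_lifetime_outside_window_rejected(self):
        st = simkit.GroundTruthStructure(np.array([[0.0, 0.0]]), "grid", {})
        with pytest.raises(InvalidConfigurationError):
            SimulationConfig(targets=(TargetSpec(name="x", lifetime_tau=20.0, structure=st),))
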
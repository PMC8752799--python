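"""Binning, detection, pixel-integrated Gaussian MLE, filtering, linking."""

import numpy as np
import pandas as pd
import pytest

from flpaint import localize, simkit
from flpaint.errors import FormatError, InvalidConfigurationError
from flpaint.localize import (
    _pixel_model,
    bin_confocal,
    bin_widefield,
    detect_spots,
    filter_localizations,
    fit_spot_mle,
    link_events,
)
from flpaint.photonio import CameraGeometry, PhotonStream, ScanGeometry


def _wf_stream(n=2000, seed=0):
    rng = np.random.default_rng(seed)
    return PhotonStream(
        x=rng.integers(0, 512, n).astype(float),
        y=rng.integers(0, 512, n).astype(float),
        macro_time=np.sort(rng.uniform(0, 5, n)),
        micro_time=rng.uniform(0, 12.4, n),
        geometry=CameraGeometry(),
        tcspc_resolution=0.05,
        tcspc_window=12.5,
    )


class TestBinning:
    def test_widefield_shape_and_virtual_pixel(self):
        stack = bin_widefield(_wf_stream(), spatial_bin=8, time_bin=0.5)
        assert stack.frames.shape[1:] == (64, 64)
        assert stack.virtual_pixel_size == pytest.approx(192.0)  # 24 nm x 8

    def test_counts_conserved(self):
        s = _wf_stream(3000)
        stack = bin_widefield(s, 8, 0.5)
        assert stack.frames.sum() == len(s)

    def test_non_divisible_binning_rejected(self):
        with pytest.raises(InvalidConfigurationError, match="divide"):
            bin_widefield(_wf_stream(), spatial_bin=7)

    def test_confocal_bin_duration_follows_raster(self):
        rng = np.random.default_rng(1)
        n = 500
        geom = ScanGeometry(region_um=(20.0, 20.0), frames_total=80)
        s = PhotonStream(
            x=rng.integers(0, 200, n).astype(float),
            y=rng.integers(0, 200, n).astype(float),
            macro_time=np.sort(rng.uniform(0, 8, n)),
            micro_time=rng.uniform(0, 12.4, n),
            frame_index=rng.integers(0, 80, n),
            geometry=geom, tcspc_resolution=0.016, tcspc_window=12.5,
        )
        stack = bin_confocal(s, frames_per_bin=8)
        assert stack.bin_duration == pytest.approx(0.8)
        assert stack.frames.sum() == n

    def test_confocal_without_frame_tags_rejected(self):
        s = _wf_stream(100)
        object.__setattr__(s, "geometry", ScanGeometry(region_um=(20.0, 20.0), frames_total=8))
        with pytest.raises(FormatError, match="frame"):
            bin_confocal(s)


def _spot_frame(rng, centers, n_photons=500, background=1.0, shape=(64, 64), sigma_px=0.78):
    frame = rng.poisson(background, size=shape).astype(float)
    for cx, cy in centers:
        params = np.array([0.0, 0.0, n_photons, 0.0, sigma_px])
        # place a pixel-integrated spot at (cx, cy)
        params[0], params[1] = cx, cy
        frame += rng.poisson(np.maximum(_pixel_model(params, shape[1], shape[0]), 0))
    return frame


class TestDetection:
    def test_flat_frame_has_no_candidates(self):
        assert detect_spots(np.full((64, 64), 5.0), 1.0) == []

    def test_single_emitter_detected_at_nearest_pixel(self, rng):
        frame = _spot_frame(rng, [(30.3, 41.7)])
        cands = detect_spots(frame, 0.78)
        assert len(cands) == 1
        ix, iy, _ = cands[0]
        assert (ix, iy) == (30, 41)

    def test_two_separated_emitters_detected(self, rng):
        frame = _spot_frame(rng, [(20.5, 20.5), (30.5, 20.5)])
        cands = detect_spots(frame, 0.78)
        assert len(cands) == 2

    def test_sparse_single_photons_not_detected(self, rng):
        # lone photons correlate perfectly with the template but are noise
        frame = np.zeros((64, 64))
        idx = rng.integers(0, 64, size=(20, 2))
        frame[idx[:, 0], idx[:, 1]] = 1.0
        assert detect_spots(frame, 0.78) == []

    def test_nonpositive_template_sigma_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            detect_spots(np.ones((16, 16)), 0.0)


class TestSpotMle:
    def test_symmetric_roi_fits_to_centre(self, rng):
        params = np.array([3.5, 3.5, 800.0, 1.0, 0.8])
        roi = np.round(_pixel_model(params, 7, 7))  # noiseless, symmetric
        loc = fit_spot_mle(roi, pixel_size_nm=192.0, initial_sigma_px=0.8)
        assert loc.x / 192.0 == pytest.approx(3.5, abs=1e-3)
        assert loc.y / 192.0 == pytest.approx(3.5, abs=1e-3)

    def test_doubling_counts_doubles_photons_keeps_position(self, rng):
        params = np.array([3.2, 3.8, 600.0, 2.0, 0.8])
        roi = rng.poisson(_pixel_model(params, 7, 7)).astype(float)
        a = fit_spot_mle(roi, 192.0, initial_sigma_px=0.8)
        b = fit_spot_mle(2.0 * roi, 192.0, initial_sigma_px=0.8)
        assert b.photons == pytest.approx(2.0 * a.photons, rel=1e-3)
        assert b.x == pytest.approx(a.x, abs=0.5)

    def test_precision_reports_crlb_scale(self, rng):
        # sigma/sqrt(N) heuristic: 150 nm / sqrt(1000) ~ 4.7 nm; CRLB with
        # background slightly above
        params = np.array([3.5, 3.5, 1000.0, 2.0, 150.0 / 192.0])
        roi = rng.poisson(_pixel_model(params, 7, 7))
        loc = fit_spot_mle(roi, 192.0, initial_sigma_px=150.0 / 192.0)
        assert 3.0 < loc.precision < 12.0


class TestFiltering:
    def _locs(self):
        return pd.DataFrame(
            {
                "frame": [0, 1, 2, 3],
                "x_nm": [0.0] * 4,
                "y_nm": [0.0] * 4,
                "photons": [500.0, 99.0, 100.0, 500.0],
                "background": [1.0] * 4,
                "sigma_nm": [150.0, 150.0, 150.0, 200.0],
                "precision_nm": [10.0] * 4,
            }
        )

    def test_confocal_sigma_and_photon_rules(self):
        out = filter_localizations(self._locs(), max_sigma=180.0, min_photons=100)
        # row 1 (99 photons) and row 3 (sigma 200 > 180) removed; N = 100 kept
        assert out["photons"].tolist() == [500.0, 100.0]

    def test_widefield_sigma_limit_keeps_200nm(self):
        out = filter_localizations(self._locs(), max_sigma=345.0, min_photons=100)
        assert len(out) == 3  # only the 99-photon row removed

    def test_idempotent(self):
        once = filter_localizations(self._locs(), 180.0, 100)
        twice = filter_localizations(once, 180.0, 100)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_input_empty_output(self):
        empty = self._locs().iloc[:0]
        assert len(filter_localizations(empty, 180.0, 100)) == 0


def _loc_row(frame, x, y, photons=500.0):
    return {
        "frame": frame, "x_nm": x, "y_nm": y, "photons": photons,
        "background": 1.0, "sigma_nm": 150.0, "precision_nm": 10.0,
        "photon_ids": np.empty(0, np.int64),
    }


class TestLinking:
    def test_consecutive_frames_same_position_one_event(self):
        locs = pd.DataFrame([_loc_row(0, 100.0, 100.0), _loc_row(1, 110.0, 95.0)])
        events = link_events(locs, max_displacement=384.0)
        assert len(events) == 1
        assert events[0].duration_frames == 2

    def test_single_frame_detection_discarded(self):
        locs = pd.DataFrame([_loc_row(0, 100.0, 100.0)])
        assert link_events(locs, 384.0) == []

    def test_gap_of_one_frame_bridged(self):
        locs = pd.DataFrame([_loc_row(0, 0.0, 0.0), _loc_row(2, 10.0, 0.0)])
        assert len(link_events(locs, 384.0, max_gap_frames=1)) == 1
        assert link_events(locs, 384.0, max_gap_frames=0) == []

    def test_distant_localizations_not_linked(self):
        locs = pd.DataFrame([_loc_row(0, 0.0, 0.0), _loc_row(1, 5000.0, 0.0)])
        assert link_events(locs, 384.0) == []

    def test_event_position_photon_weighted(self):
        locs = pd.DataFrame([
            _loc_row(0, 0.0, 0.0, photons=300.0), _loc_row(1, 90.0, 0.0, photons=100.0)
        ])
        (ev,) = link_events(locs, 384.0)
        assert ev.mean_x == pytest.approx(90.0 * 100.0 / 400.0)
        assert ev.total_photons == 400.0

    def test_simulation_recovery_of_multi_frame_events(self):
        """Truth events spanning >= 2 time bins with a full photon budget are
        recovered as single linked events.

        Sites sit on a sparse grid (1.5 um pitch, far beyond the linking
        radius) and binding is slow, so distinct truth events practically
        never overlap in space and time and each must come back as exactly
        one linked event.
        """
        grid = simkit.make_structure_map(
            "grid", {"pitch": 1500.0, "center": (6000.0, 6000.0)}, 16, seed=0
        )
        target = simkit.TargetSpec(
            name="t", lifetime_tau=2.8, structure=grid,
            mean_event_duration=1.5, event_rate_per_site=0.005,
            photons_per_event_mean=5000.0,
        )
        cfg = simkit.SimulationConfig(targets=(target,), movie_duration=200.0, rng_seed=3)
        rng = cfg.rng()
        truth = simkit.simulate_binding_events(cfg.targets, cfg.movie_duration, rng)
        stream = simkit.simulate_photons_widefield(truth, cfg, seed=rng)
        stack = bin_widefield(stream, 8, 0.5)
        locs = localize.localize_frames(stack, template_sigma_px=150.0 / 192.0)
        locs = filter_localizations(locs, 345.0, 100)
        events = link_events(locs, 2 * 192.0)
        recoverable = [
            t for t in truth
            if t.duration >= 2 * 0.5 and t.emitted_photons >= 1000
        ]
        # match each recoverable truth event to a linked event by time+space
        from flpaint.pipeline import match_events_to_truth

        ev_table = pd.DataFrame(
            {
                "frame": [int(locs["frame"].iloc[e.loc_indices].min()) for e in events],
                "duration_frames": [e.duration_frames for e in events],
                "x_nm": [e.mean_x for e in events],
                "y_nm": [e.mean_y for e in events],
            }
        )
        truth_df = simkit.truth_events_to_frame(truth)
        m = match_events_to_truth(ev_table, truth_df, bin_duration=0.5)
        hit = set(m[m >= 0])
        recovered = sum(
            1 for i, t in enumerate(truth) if t in recoverable and i in hit
        )
        assert len(recoverable) >= 10
        assert recovered / len(recoverable) >= 0.95

    def test_photon_ids_never_shared_between_events(self):
        locs = pd.DataFrame([
            dict(_loc_row(0, 0.0, 0.0), photon_ids=np.array([0, 1])),
            dict(_loc_row(1, 10.0, 0.0), photon_ids=np.array([2, 3])),
            dict(_loc_row(0, 5000.0, 0.0), photon_ids=np.array([4])),
            dict(_loc_row(1, 5000.0, 0.0), photon_ids=np.array([5])),
        ])
        events = link_events(locs, 384.0)
        all_ids = np.concatenate([e.photon_ids for e in events])
        assert len(all_ids) == len(np.unique(all_ids))
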
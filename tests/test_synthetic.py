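import math

import numpy as np
import pandas as pd
import pytest

from aggremorph.io_core import write_localizations
from aggremorph.synthetic import (
    FIDUCIAL_ID,
    SCENARIOS,
    SimulationParams,
    apply_drift_and_fiducials,
    lognormal_from_mean_sd,
    lognormal_from_median,
    render_frame_stack,
    sample_aggregates,
    scenario_params,
    simulate_influx_experiment,
    simulate_localizations,
)


class TestSampleAggregates:
    def test_zero_aggregates(self, rng):
        assert sample_aggregates(SimulationParams(n_aggregates=0), rng) == []

    def test_lognormal_median_recovered(self, rng):
        mu, sigma = lognormal_from_median(200.0, 0.3)
        params = SimulationParams(
            n_aggregates=10_000, length_mu=mu, length_sigma=sigma,
            fov_size=50_000.0,
        )
        lengths = [a.length for a in sample_aggregates(params, rng)]
        assert abs(np.median(lengths) - 200.0) / 200.0 < 0.05

    def test_rod_sites_within_envelope(self, rng):
        params = SimulationParams(n_aggregates=50, rod_fraction=1.0)
        for agg in sample_aggregates(params, rng):
            c = np.array(agg.center)
            d = math.hypot(math.cos(agg.orientation), math.sin(agg.orientation))
            axis = np.array([math.cos(agg.orientation), math.sin(agg.orientation)])
            rel = agg.sites - c
            axial = rel @ axis
            lateral = rel @ np.array([-axis[1], axis[0]])
            assert np.all(np.abs(axial) <= agg.length / 2 + 1e-9)
            assert np.all(np.abs(lateral) <= agg.width / 2 + 1e-9)
            assert agg.n_sites == max(1, round(params.rod_site_density * agg.length))

    def test_disk_sites_within_radius(self, rng):
        params = SimulationParams(n_aggregates=50, rod_fraction=0.0)
        for agg in sample_aggregates(params, rng):
            r = np.linalg.norm(agg.sites - np.array(agg.center), axis=1)
            assert np.all(r <= agg.length / 2 + 1e-9)

    def test_fov_too_small_raises(self, rng):
        params = SimulationParams(n_aggregates=5, fov_size=100.0,
                                  length_mu=math.log(400.0), length_sigma=0.01)
        with pytest.raises(ValueError, match="field of view"):
            sample_aggregates(params, rng)

    def test_centers_respect_margin(self, rng):
        params = SimulationParams(n_aggregates=200)
        for agg in sample_aggregates(params, rng):
            for c in agg.center:
                assert agg.length / 2 <= c <= params.fov_size - agg.length / 2


class TestSimulateLocalizations:
    def test_no_binding_no_background_is_empty(self, rng):
        params = SimulationParams(n_aggregates=5, p_bind=0.0, background_rate=0.0)
        aggs = sample_aggregates(params, rng)
        assert len(simulate_localizations(aggs, params, rng)) == 0

    def test_localization_count_is_binomial(self, rng):
        # one rod with exactly 20 sites: expect 20 * 8000 * 0.01 = 1600
        params = SimulationParams(
            n_aggregates=1, rod_fraction=1.0, p_bind=0.01,
            background_rate=0.0, length_mu=math.log(100.0), length_sigma=1e-6,
            rod_site_density=0.2,
        )
        aggs = sample_aggregates(params, rng)
        assert aggs[0].n_sites == 20
        n = len(simulate_localizations(aggs, params, rng))
        assert abs(n - 1600) <= 4 * math.sqrt(1600)

    def test_all_localizations_near_their_aggregate(self, rng):
        params = SimulationParams(n_aggregates=10, background_rate=0.0)
        aggs = sample_aggregates(params, rng)
        table = simulate_localizations(aggs, params, rng)
        centers = np.array([a.center for a in aggs])
        lengths = np.array([a.length for a in aggs])
        sid = table["source_id"].to_numpy()
        assert np.all(sid >= 0)
        d = np.linalg.norm(
            table[["x", "y"]].to_numpy() - centers[sid], axis=1
        )
        assert np.all(d <= lengths[sid] / 2 + 5 * params.sigma_loc)

    def test_count_scales_linearly_with_p_bind_and_frames(self, rng):
        base = SimulationParams(n_aggregates=30, background_rate=0.0)
        aggs = sample_aggregates(base, rng)
        n1 = len(simulate_localizations(aggs, base, rng))
        from dataclasses import replace

        n2 = len(simulate_localizations(aggs, replace(base, p_bind=2 * base.p_bind), rng))
        n3 = len(simulate_localizations(aggs, replace(base, n_frames=base.n_frames // 2), rng))
        assert abs(n2 - 2 * n1) < 6 * math.sqrt(2 * n1)
        assert abs(n3 - n1 / 2) < 6 * math.sqrt(n1 / 2)

    def test_same_seed_reproduces_bytes(self, tmp_path):
        params = scenario_params("fraction20", n_aggregates=20)
        paths = []
        for name in ("a.csv", "b.csv"):
            rng = np.random.default_rng(99)
            aggs = sample_aggregates(params, rng)
            table = simulate_localizations(aggs, params, rng)
            table, _, _ = apply_drift_and_fiducials(table, params, rng)
            paths.append(write_localizations(table, tmp_path / name))
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_scenarios_cover_study_presets(self):
        assert set(SCENARIOS) == {
            "fraction20", "fraction30", "fraction40", "fraction50",
            "pd_brain", "hc_brain",
        }
        assert math.exp(SCENARIOS["pd_brain"].length_mu) == pytest.approx(55.0)
        assert math.exp(SCENARIOS["hc_brain"].length_mu) == pytest.approx(68.0)
        mean20 = math.exp(
            SCENARIOS["fraction20"].length_mu + SCENARIOS["fraction20"].length_sigma ** 2 / 2
        )
        assert mean20 == pytest.approx(190.0)


class TestDriftAndFiducials:
    def test_zero_drift_leaves_positions(self, rng, small_params):
        from dataclasses import replace

        params = replace(small_params, n_fiducials=2, drift_mag=0.0)
        aggs = sample_aggregates(params, rng)
        table = simulate_localizations(aggs, params, rng)
        out, traj, refs = apply_drift_and_fiducials(table, params, rng)
        assert traj.dx[0] == 0.0 and traj.dy[0] == 0.0
        assert np.all(traj.dx == 0.0) and np.all(traj.dy == 0.0)
        kept = out[out["source_id"] != FIDUCIAL_ID]
        merged = kept.sort_values(["frame", "x"]).reset_index(drop=True)
        orig = table.sort_values(["frame", "x"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, orig)
        assert refs.shape == (2, 2)

    def test_linear_drift_displaces_fiducials(self, rng):
        params = SimulationParams(
            n_aggregates=0, n_frames=8000, drift_mag=0.05,
            n_fiducials=1, fiducial_noise=0.0, background_rate=0.0,
        )
        table = simulate_localizations([], params, rng)
        out, traj, refs = apply_drift_and_fiducials(table, params, rng)
        fid = out[out["source_id"] == FIDUCIAL_ID]
        first = fid[fid["frame"] == 0][["x", "y"]].to_numpy()[0]
        last = fid[fid["frame"] == 7999][["x", "y"]].to_numpy()[0]
        assert np.linalg.norm(last - first) == pytest.approx(0.05 * 7999, rel=1e-9)

    def test_warns_when_drift_without_fiducials(self, rng, small_params):
        from dataclasses import replace

        params = replace(small_params, drift_mag=0.1, n_fiducials=0)
        aggs = sample_aggregates(params, rng)
        table = simulate_localizations(aggs, params, rng)
        with pytest.warns(UserWarning, match="without fiducials"):
            apply_drift_and_fiducials(table, params, rng)


class TestRenderFrameStack:
    def test_no_spots_mean_is_baseline(self, rng):
        params = SimulationParams(fov_size=5000.0, baseline=100.0)
        stack = render_frame_stack([], 250.0, params, rng, n_frames=20)
        assert stack.mean() == pytest.approx(100.0, rel=0.02)

    def test_noiseless_peak_at_containing_pixel(self):
        params = SimulationParams(fov_size=5000.0, baseline=10.0)
        stack = render_frame_stack([((1300.0, 2600.0), 5000.0)], 250.0, params,
                                   rng=None, pixel_size=237.0, n_frames=1)
        iy, ix = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
        assert ix == int(1300.0 // 237.0)
        assert iy == int(2600.0 // 237.0)

    def test_photon_conservation(self, rng):
        params = SimulationParams(fov_size=10000.0, baseline=50.0)
        spots = [((5000.0, 5000.0), 20000.0), ((2500.0, 7000.0), 10000.0)]
        stack = render_frame_stack(spots, 250.0, params, rng, n_frames=30)
        n_px = stack.shape[1] * stack.shape[2]
        excess = stack.sum(axis=(1, 2)).mean() - 50.0 * n_px
        assert excess == pytest.approx(30000.0, rel=0.05)

    def test_invalid_psf_rejected(self, rng):
        with pytest.raises(ValueError, match="psf_sigma"):
            render_frame_stack([], -1.0, SimulationParams(), rng)


class TestInfluxSimulation:
    def test_endpoints_match_reference_stacks(self, rng):
        params = SimulationParams(fov_size=10000.0)
        bg0, s0, io0, _ = simulate_influx_experiment(9, 0.0, params, rng)
        assert abs(s0.mean() - bg0.mean()) < 0.5  # statistically equal
        rng2 = np.random.default_rng(5)
        bg1, s1, io1, _ = simulate_influx_experiment(9, 1.0, params, rng2)
        assert abs(s1.mean() - io1.mean()) < 0.5

    def test_invalid_influx_rejected(self, rng):
        with pytest.raises(ValueError, match="true_influx"):
            simulate_influx_experiment(4, 1.5, SimulationParams(), rng)
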
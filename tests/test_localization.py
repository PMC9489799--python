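import numpy as np
import pandas as pd
import pytest

from aggremorph.io_core import make_localizations
from aggremorph.localization import (
    DriftCorrectionError,
    correct_drift,
    filter_localizations,
    localize_stack,
    thompson_precision,
)
from aggremorph.synthetic import (
    FIDUCIAL_ID,
    SimulationParams,
    apply_drift_and_fiducials,
    render_frame_stack,
    simulate_localizations,
)

PIXEL = 98.8


def _render(spots, n_frames=1, rng=None, fov=4000.0, baseline=20.0):
    params = SimulationParams(fov_size=fov, baseline=baseline)
    return render_frame_stack(spots, psf_sigma=150.0, params=params,
                              rng=rng, pixel_size=PIXEL, n_frames=n_frames)


class TestLocalizeStack:
    def test_noiseless_spot_below_1nm(self):
        truth = (1234.5, 2345.6)
        stack = _render([(truth, 5000.0)], rng=None)
        table = localize_stack(stack, pixel_size=PIXEL)
        assert len(table) == 1
        err = np.hypot(table.loc[0, "x"] - truth[0], table.loc[0, "y"] - truth[1])
        assert err < 1.0
        assert table.loc[0, "intensity"] == pytest.approx(5000.0, rel=0.05)

    def test_two_well_separated_spots(self):
        spots = [((1000.0, 1000.0), 4000.0), ((3000.0, 3000.0), 4000.0)]
        table = localize_stack(_render(spots, rng=None), pixel_size=PIXEL)
        assert len(table) == 2
        found = table[["x", "y"]].to_numpy()
        for (tx, ty), _ in spots:
            d = np.min(np.hypot(found[:, 0] - tx, found[:, 1] - ty))
            assert d < 1.0

    def test_blank_frames_nearly_spotless(self, rng):
        stack = _render([], n_frames=10, rng=rng, baseline=100.0)
        table = localize_stack(stack, detect_threshold_k=5.0, pixel_size=PIXEL)
        assert len(table) <= 1  # <= 0.1 false positives per frame expected

    def test_empty_stack(self):
        assert len(localize_stack(np.empty((0, 8, 8)))) == 0

    def test_nonfinite_rejected(self):
        stack = np.full((1, 10, 10), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            localize_stack(stack)

    def test_rmse_within_factor_two_of_thompson(self, rng):
        truth = (2000.0, 2000.0)
        errors, precisions = [], []
        for _ in range(40):
            stack = _render([(truth, 1000.0)], rng=rng, baseline=20.0)
            table = localize_stack(stack, pixel_size=PIXEL)
            if len(table) != 1:
                continue
            errors.append(np.hypot(table.loc[0, "x"] - truth[0],
                                   table.loc[0, "y"] - truth[1]))
            precisions.append(table.loc[0, "precision"])
        assert len(errors) >= 30
        rmse_per_axis = np.sqrt(np.mean(np.square(errors)) / 2.0)
        pred = np.mean(precisions)
        assert pred / 2.0 < rmse_per_axis < pred * 2.0

    def test_thompson_formula_value(self):
        # hand-evaluated: s=150, a=100, N=1000, b=10
        s2, a2 = 150.0**2, 100.0**2
        expected = np.sqrt((s2 + a2 / 12.0) / 1000.0 +
                           8 * np.pi * s2**2 * 100.0 / (a2 * 1e6))
        assert thompson_precision(150.0, 100.0, 1000.0, 10.0) == pytest.approx(expected)


class TestFilter:
    def _table(self, rng, n=200):
        return make_localizations(
            frame=rng.integers(0, 100, n),
            x=rng.uniform(0, 1e4, n),
            y=rng.uniform(0, 1e4, n),
            intensity=rng.exponential(1000.0, n),
            precision=rng.uniform(1.0, 60.0, n),
        )

    def test_predicate_matches_brute_force(self, rng):
        table = self._table(rng)
        out = filter_localizations(table, 100.0, 20.0)
        expect = table[(table["intensity"] >= 100.0) & (table["precision"] <= 20.0)]
        pd.testing.assert_frame_equal(out, expect.reset_index(drop=True))

    def test_idempotent(self, rng):
        table = self._table(rng)
        once = filter_localizations(table, 100.0, 20.0)
        twice = filter_localizations(once, 100.0, 20.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_commutes_with_permutation_as_set(self, rng):
        table = self._table(rng)
        perm = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = filter_localizations(table, 100.0, 20.0)
        b = filter_localizations(perm, 100.0, 20.0)
        key = ["frame", "x", "y"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )

    def test_boundary_is_inclusive(self):
        table = make_localizations([0], [1.0], [2.0], [100.0], [20.0])
        assert len(filter_localizations(table, 100.0, 20.0)) == 1


class TestDriftCorrection:
    def _simulated(self, rng, drift_mag, n_fiducials, fiducial_noise,
                   drift_model="linear", n_frames=2000):
        params = SimulationParams(
            n_aggregates=10, n_frames=n_frames, p_bind=1e-3,
            background_rate=0.0, drift_mag=drift_mag, drift_model=drift_model,
            n_fiducials=n_fiducials, fiducial_noise=fiducial_noise,
        )
        from aggremorph.synthetic import sample_aggregates

        aggs = sample_aggregates(params, rng)
        clean = simulate_localizations(aggs, params, rng)
        drifted, traj, refs = apply_drift_and_fiducials(clean, params, rng)
        return clean, drifted, traj, refs

    def test_zero_drift_is_identity(self, rng):
        clean, drifted, _, refs = self._simulated(rng, 0.0, 2, 0.0)
        out, traj = correct_drift(drifted, refs)
        assert np.allclose(traj.dx, 0.0) and np.allclose(traj.dy, 0.0)
        key = ["frame", "x"]
        pd.testing.assert_frame_equal(
            out.sort_values(key).reset_index(drop=True),
            clean.sort_values(key).reset_index(drop=True),
        )

    def test_linear_drift_recovered(self, rng):
        clean, drifted, traj, refs = self._simulated(rng, 0.05, 4, 0.0)
        out, rec = correct_drift(drifted, refs)
        # recovered trajectory matches the applied one to < 2 nm RMS
        rms = np.sqrt(np.mean((rec.dx - traj.dx) ** 2 + (rec.dy - traj.dy) ** 2))
        assert rms < 2.0
        assert FIDUCIAL_ID not in out["source_id"].to_numpy()

    def test_noisy_fiducials_still_accurate(self, rng):
        _, drifted, traj, refs = self._simulated(rng, 0.05, 4, 10.0)
        _, rec = correct_drift(drifted, refs)
        rms = np.sqrt(np.mean((rec.dx - traj.dx) ** 2 + (rec.dy - traj.dy) ** 2))
        assert rms < 10.0

    def test_already_corrected_is_identity(self, rng):
        _, drifted, _, refs = self._simulated(rng, 0.05, 2, 0.0)
        once, traj1 = correct_drift(drifted, refs)
        # re-run on the corrected table: recovered trajectory ~ zero
        again, traj2 = correct_drift(
            pd.concat(
                [once,
                 drifted[drifted["source_id"] == FIDUCIAL_ID].assign(
                     x=lambda t: t["x"] - traj1.dx[t["frame"].to_numpy()],
                     y=lambda t: t["y"] - traj1.dy[t["frame"].to_numpy()],
                 )],
                ignore_index=True,
            ),
            refs,
        )
        assert np.abs(traj2.dx).max() < 1e-6 and np.abs(traj2.dy).max() < 1e-6

    def test_no_fiducial_in_frame_zero_errors(self, rng):
        _, drifted, _, refs = self._simulated(rng, 0.05, 2, 0.0)
        with pytest.raises(DriftCorrectionError, match="frame 0"):
            correct_drift(drifted, np.array([[1e9, 1e9]]))

    def test_low_coverage_warns(self, rng):
        table = make_localizations(
            frame=np.arange(0, 1000, 2),           # beads in even frames only
            x=np.full(500, 100.0), y=np.full(500, 100.0),
            intensity=np.full(500, 1e4), precision=np.full(500, 2.0),
        )
        with pytest.warns(UserWarning, match="coverage"):
            correct_drift(table, np.array([[100.0, 100.0]]))
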
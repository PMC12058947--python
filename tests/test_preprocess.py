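import numpy as np
import pandas as pd
import pytest

import trajsplit as ts
from trajsplit.preprocess import Movement, UnusableTrialError

from conftest import make_canonical


class TestTruncate:
    def test_constant_velocity_path_reads_off_it_and_mt(self, geometry, straight_trial):
        mv = ts.truncate(straight_trial, geometry)
        assert mv.it_ms == 500.0
        assert mv.mt_ms == 400.0
        assert mv.t[0] == 500.0 and mv.t[-1] == 900.0

    def test_it_plus_mt_equals_target_entry_time(self, geometry, straight_trial):
        mv = ts.truncate(straight_trial, geometry)
        assert mv.it_ms + mv.mt_ms == mv.t[-1]

    def test_reentry_into_start_keeps_first_exit_anchor(self, geometry):
        # exit at t=100, dip back inside the start box, then go to the target
        t = np.array([0.0, 100.0, 200.0, 300.0, 400.0, 500.0])
        x = np.array([0.0, 80.0, 20.0, 200.0, 400.0, 600.0])
        y = np.array([0.0, 60.0, 20.0, 200.0, 400.0, 500.0])
        mv = ts.truncate(make_canonical(t, x, y), geometry)
        assert mv.it_ms == 100.0
        assert mv.t[0] == 100.0

    def test_never_leaving_start_or_reaching_target_is_unusable(self, geometry):
        t = np.array([0.0, 10.0, 20.0])
        stuck = make_canonical(t, [0.0, 5.0, 10.0], [0.0, 5.0, 10.0])
        with pytest.raises(UnusableTrialError, match="never left"):
            ts.truncate(stuck, geometry)
        lost = make_canonical(t, [0.0, 100.0, 200.0], [0.0, 100.0, 100.0])
        with pytest.raises(UnusableTrialError, match="never reached"):
            ts.truncate(lost, geometry)

    def test_matches_brute_force_membership_scan(self, small_experiment):
        """Truncation anchors equal an independent sample-by-sample region scan."""
        ds, _, _ = small_experiment
        checked = 0
        for tr in ds.trials[:200]:
            ct = ts.canonicalize(tr, ds.geometry)
            og = ds.geometry.oriented(ct.flipped)
            inside_start = [
                og.start.left <= xx <= og.start.right and og.start.bottom <= yy <= og.start.top
                for xx, yy in zip(ct.x, ct.y)
            ]
            i_exit = next(i for i, ins in enumerate(inside_start) if not ins)
            tgt = og.target_right
            i_entry = next(
                i
                for i in range(i_exit, len(ct.x))
                if tgt.left <= ct.x[i] <= tgt.right and tgt.bottom <= ct.y[i] <= tgt.top
            )
            mv = ts.truncate(ct, ds.geometry)
            assert mv.it_ms == ct.t[i_exit]
            assert mv.it_ms + mv.mt_ms == ct.t[i_entry]
            checked += 1
        assert checked == 200


class TestTimeNormalize:
    def test_constant_velocity_gives_equally_spaced_points(self):
        t = np.linspace(0, 400, 5)
        mv = Movement(100.0, 400.0, t, 1.5 * t, 0.5 * t)
        nt = ts.time_normalize(mv, n=21)
        steps = np.diff(nt.points, axis=0)
        np.testing.assert_allclose(steps, np.tile(steps[0], (20, 1)), atol=1e-9)

    def test_n2_returns_exactly_the_endpoints(self):
        mv = Movement(0.0, 100.0, np.array([0.0, 30.0, 100.0]), np.array([0.0, 80.0, 10.0]),
                      np.array([0.0, -4.0, 2.0]))
        nt = ts.time_normalize(mv, n=2)
        np.testing.assert_array_equal(nt.points, [[0.0, 0.0], [10.0, 2.0]])

    def test_identity_on_already_uniform_samples_and_idempotence(self):
        rng = np.random.default_rng(0)
        t = np.linspace(100, 500, 101)
        x, y = rng.normal(size=101), rng.normal(size=101)
        nt = ts.time_normalize(Movement(100.0, 400.0, t, x, y), n=101)
        np.testing.assert_allclose(nt.points[:, 0], x, atol=1e-12)
        np.testing.assert_allclose(nt.points[:, 1], y, atol=1e-12)
        again = ts.time_normalize(
            Movement(100.0, 400.0, np.linspace(100, 500, 101), nt.points[:, 0], nt.points[:, 1]),
            n=101,
        )
        np.testing.assert_allclose(again.points, nt.points, atol=1e-12)

    def test_fewer_than_two_samples_errors(self):
        with pytest.raises(ValueError):
            ts.time_normalize(Movement(0.0, 1.0, np.array([0.0]), np.array([0.0]), np.array([0.0])))


class TestIsDownward:
    def test_monotone_upward_path_is_not_downward(self, geometry, straight_trial):
        assert not ts.is_downward(straight_trial, geometry)

    def test_dip_below_start_bottom_after_exit_is_downward(self, geometry):
        t = np.arange(5) * 100.0
        x = np.array([0.0, 80.0, 120.0, 300.0, 600.0])
        y = np.array([0.0, 20.0, -60.0, 200.0, 500.0])
        assert ts.is_downward(make_canonical(t, x, y), geometry)

    def test_exactly_on_bottom_edge_is_not_downward(self, geometry):
        t = np.arange(5) * 100.0
        x = np.array([0.0, 80.0, 120.0, 300.0, 600.0])
        y = np.array([0.0, 20.0, -50.0, 200.0, 500.0])  # start bottom edge at y = -50
        assert not ts.is_downward(make_canonical(t, x, y), geometry)


class TestFlagOutliers:
    def _table(self, values, participant="p1", condition="compatible", measure="mt_ms"):
        n = len(values)
        base = {
            "participant": participant,
            "compatibility": condition,
            "it_ms": 500.0,
            "mt_ms": 400.0,
            "auc_px2": 0.0,
            "mad_px": 0.0,
        }
        df = pd.DataFrame([dict(base) for _ in range(n)])
        df[measure] = values
        return df

    def test_hand_computed_cell_mean_and_sd(self):
        """Cell {10,10,10,10,100}: mean 28, sample SD = sqrt((4*18^2 + 72^2)/4)
        = sqrt(1620) ~ 40.25; |100-28| = 72 < 2.5*40.25 = 100.6, so nothing
        is flagged."""
        df = self._table([10.0, 10.0, 10.0, 10.0, 100.0])
        sd = np.std([10, 10, 10, 10, 100], ddof=1)
        assert sd == pytest.approx(np.sqrt(1620.0))
        flags = ts.flag_outliers(df)
        assert not flags["outlier"].any()

    def test_deviation_beyond_k_sd_is_flagged_with_measure_reason(self):
        df = self._table([400.0] * 9 + [400.0], measure="mt_ms")
        df.loc[:8, "mt_ms"] = [380, 390, 400, 410, 420, 395, 405, 385, 415]
        df.loc[9, "mt_ms"] = 1000.0
        flags = ts.flag_outliers(df)
        assert flags["outlier"].tolist() == [False] * 9 + [True]
        assert flags.loc[9, "outlier_reasons"] == "MT"

    def test_identical_values_have_zero_sd_and_no_flags(self):
        flags = ts.flag_outliers(self._table([7.0] * 6))
        assert not flags["outlier"].any()

    def test_small_cell_skipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            flags = ts.flag_outliers(self._table([1.0, 1e9]))
        assert not flags["outlier"].any()
        assert any("skipped" in r.message for r in caplog.records)

    def test_flags_invariant_under_trial_reordering(self):
        rng = np.random.default_rng(3)
        df = self._table(list(rng.normal(400, 30, 19)) + [900.0])
        flags = ts.flag_outliers(df)
        perm = rng.permutation(len(df))
        shuffled = df.iloc[perm].reset_index(drop=True)
        flags2 = ts.flag_outliers(shuffled)
        np.testing.assert_array_equal(
            flags["outlier"].to_numpy()[perm], flags2["outlier"].to_numpy()
        )
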
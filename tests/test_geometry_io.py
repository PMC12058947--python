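import numpy as np
import pandas as pd
import pytest
import yaml

import trajsplit as ts
from trajsplit.geometry import GeometryError


def _config_dict(frame="canonical"):
    if frame == "canonical":
        return {
            "start": dict(x_center=0, y_center=0, width=100, height=100),
            "target_left": dict(x_center=-600, y_center=500, width=140, height=140),
            "target_right": dict(x_center=600, y_center=500, width=140, height=140),
            "frame": "canonical",
        }
    return {
        "start": dict(x_center=640, y_center=620, width=100, height=100),
        "target_left": dict(x_center=40, y_center=120, width=140, height=140),
        "target_right": dict(x_center=1240, y_center=120, width=140, height=140),
        "frame": "screen",
    }


class TestLoadGeometry:
    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_valid_config_loads_and_roundtrips(self, tmp_path, suffix):
        path = tmp_path / f"geom{suffix}"
        path.write_text(yaml.safe_dump(_config_dict()))
        g = ts.load_geometry(path)
        assert g.start.width == 100
        out = tmp_path / f"copy{suffix}"
        ts.save_geometry(g, out)
        assert ts.load_geometry(out) == g

    def test_missing_region_is_config_error(self, tmp_path):
        cfg = _config_dict()
        del cfg["target_left"]
        path = tmp_path / "geom.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(GeometryError, match="missing region"):
            ts.load_geometry(path)

    def test_targets_on_same_side_rejected(self, tmp_path):
        cfg = _config_dict()
        cfg["target_left"]["x_center"] = 300
        path = tmp_path / "geom.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(GeometryError, match="opposite sides"):
            ts.load_geometry(path)

    def test_asymmetric_targets_rejected_unless_within_tolerance(self, tmp_path):
        cfg = _config_dict()
        cfg["target_right"]["x_center"] = 610
        path = tmp_path / "geom.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(GeometryError, match="mirror-symmetric"):
            ts.load_geometry(path)
        cfg["symmetry_tol"] = 15
        path.write_text(yaml.safe_dump(cfg))
        ts.load_geometry(path)  # within tolerance: accepted

    def test_overlapping_start_and_target_rejected(self, tmp_path):
        cfg = _config_dict()
        cfg["target_left"].update(x_center=-40, y_center=500)
        # move it back down so it overlaps the start box
        cfg["target_left"]["y_center"] = 90
        cfg["target_left"]["height"] = 120
        path = tmp_path / "geom.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(GeometryError):
            ts.load_geometry(path)

    def test_screen_frame_canonicalizes_to_same_geometry(self, tmp_path):
        """Hand-transform check: screen target_left (40, 120) with start
        centre (640, 620) maps to x' = 40-640 = -600, y' = 620-120 = 500."""
        p1 = tmp_path / "screen.yaml"
        p1.write_text(yaml.safe_dump(_config_dict("screen")))
        p2 = tmp_path / "canon.yaml"
        p2.write_text(yaml.safe_dump(_config_dict("canonical")))
        g_screen = ts.load_geometry(p1).canonical()
        g_canon = ts.load_geometry(p2).canonical()
        assert g_screen.target_left == ts.Rect(-600.0, 500.0, 140.0, 140.0)
        assert g_screen == g_canon


class TestTrajectoryIO:
    def _frame(self, n=50, participants=("p1",), trials=("t1",)):
        rows = []
        for p in participants:
            for tr in trials:
                t = np.arange(n) * 10.0
                rows.append(
                    pd.DataFrame(
                        dict(
                            participant=p,
                            trial=tr,
                            compatibility="compatible",
                            correct_side="right",
                            response_error=False,
                            t_ms=t,
                            x_px=640 + t * 0.1,
                            y_px=620 - t * 0.2,
                        )
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def test_trial_count_and_sample_count_preserved(self, tmp_path):
        df = self._frame(n=50, trials=("t1", "t2"))
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        trials = ts.load_trajectories(path)
        assert len(trials) == 2
        assert all(tr.n_samples == 50 for tr in trials)

    def test_duplicated_timestamp_rejects_only_that_trial(self, tmp_path):
        df = self._frame(trials=("t1", "t2"))
        df.loc[(df.trial == "t1") & (df.t_ms == 100.0), "t_ms"] = 90.0
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        trials, rejections = ts.load_trajectories(path, return_rejections=True)
        assert [tr.trial for tr in trials] == ["t2"]
        assert len(rejections) == 1
        assert rejections[0].trial == "t1"
        assert "monotone" in rejections[0].reason

    def test_missing_required_column_is_hard_error(self, tmp_path):
        df = self._frame().drop(columns=["correct_side"])
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="correct_side"):
            ts.load_trajectories(path)

    def test_write_then_load_roundtrip_is_exact(self, tmp_path):
        rng = np.random.default_rng(4)
        trials = [
            ts.RawTrajectory(
                participant="p1",
                trial=f"t{i}",
                condition={"compatibility": "incompatible", "block": "b2"},
                correct_side="left",
                response_error=bool(i % 2),
                t=np.cumsum(rng.uniform(5, 15, 20)),
                x=rng.normal(640, 30, 20),
                y=rng.normal(620, 30, 20),
            )
            for i in range(3)
        ]
        path = tmp_path / "d.csv"
        ts.write_trajectories(trials, path)
        back = ts.load_trajectories(path)
        assert len(back) == 3
        for a, b in zip(trials, back):
            assert a.condition == b.condition
            assert a.response_error == b.response_error
            np.testing.assert_array_equal(a.t, b.t)
            np.testing.assert_array_equal(a.x, b.x)
            np.testing.assert_array_equal(a.y, b.y)


class TestCanonicalize:
    def _raw(self, x0, y0, correct_side="right"):
        return ts.RawTrajectory(
            participant="p1",
            trial="t1",
            condition={"compatibility": "compatible"},
            correct_side=correct_side,
            response_error=False,
            t=np.array([0.0, 10.0, 20.0]),
            x=np.array([x0, x0 + 5, x0 + 10]),
            y=np.array([y0, y0 - 5, y0 - 10]),
        )

    def test_right_trial_translated_only(self, screen_geometry):
        tr = self._raw(640.0, 620.0)
        ct = ts.canonicalize(tr, screen_geometry)
        assert not ct.flipped
        np.testing.assert_allclose(ct.x, [0.0, 5.0, 10.0])
        # screen y-down flips: moving up on screen = +y canonical
        np.testing.assert_allclose(ct.y, [0.0, 5.0, 10.0])

    def test_left_trial_mirrored_about_start_centre(self, screen_geometry):
        tr = self._raw(610.0, 620.0, correct_side="left")  # x = -30 relative
        ct = ts.canonicalize(tr, screen_geometry)
        assert ct.flipped
        assert ct.x[0] == 30.0

    def test_mirroring_twice_restores_original(self, geometry):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 20, 10)
        assert np.array_equal(-(-x), x)  # trivially, but via the geometry path:
        g = geometry.canonical()
        assert g.flipped().flipped() == g

    def test_first_sample_outside_start_is_precondition_error(self, screen_geometry):
        tr = self._raw(800.0, 620.0)
        with pytest.raises(ts.TrajectoryError, match="outside start"):
            ts.canonicalize(tr, screen_geometry)

    def test_canonicalize_is_isometry(self, screen_geometry):
        rng = np.random.default_rng(7)
        for side in ("left", "right"):
            x = 640 + np.concatenate([[0], rng.normal(0, 30, 19)])
            y = 620 + np.concatenate([[0], rng.normal(0, 30, 19)])
            tr = ts.RawTrajectory(
                participant="p",
                trial="t",
                condition={"compatibility": "compatible"},
                correct_side=side,
                response_error=False,
                t=np.arange(20.0),
                x=x,
                y=y,
            )
            ct = ts.canonicalize(tr, screen_geometry)
            d_before = np.hypot(np.subtract.outer(x, x), np.subtract.outer(y, y))
            d_after = np.hypot(np.subtract.outer(ct.x, ct.x), np.subtract.outer(ct.y, ct.y))
            np.testing.assert_allclose(d_after, d_before, rtol=0, atol=1e-9)

    def test_correct_target_positive_wrong_negative(self, screen_geometry):
        for side in ("left", "right"):
            flipped = side == "left"
            g = screen_geometry.oriented(flipped)
            assert g.target_right.x_center > 0  # correct target
            assert g.target_left.x_center < 0  # wrong target
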
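"""Trajectory parsing, director extraction and the polarization series."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shoalpol import polarization as pol
from shoalpol import synthetic_data as sd
from shoalpol.exceptions import FormatError


def wide_csv(tmp_path, positions, dt=0.1, name="traj.csv"):
    T, N, _ = positions.shape
    data = {"frame": np.arange(T)}
    for i in range(N):
        data[f"x{i + 1}"] = positions[:, i, 0]
        data[f"y{i + 1}"] = positions[:, i, 1]
    path = tmp_path / name
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def table_from_array(positions, dt=0.1, N=None):
    valid = np.isfinite(positions).all(axis=2)
    return pol.TrajectoryTable(
        positions=positions, dt=dt, valid=valid, meta={"N": N or positions.shape[1]}
    )


class TestReadTrajectories:
    def test_wide_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        posi = rng.normal(size=(100, 3, 2))
        path = wide_csv(tmp_path, posi)
        table = pol.read_trajectories(path, "wide", dt=0.1)
        assert table.positions.shape == (100, 3, 2)
        assert table.valid.all()
        np.testing.assert_allclose(table.positions, posi, atol=1e-12)

    def test_nan_cell_masks_single_entry(self, tmp_path):
        posi = np.zeros((10, 2, 2))
        posi[4, 1, 0] = np.nan
        path = wide_csv(tmp_path, posi)
        table = pol.read_trajectories(path, "wide", dt=0.1)
        assert not table.valid[4, 1]
        assert table.valid.sum() == 10 * 2 - 1

    def test_duplicate_frame_rejected(self, tmp_path):
        df = pd.DataFrame({"frame": [0, 1, 1], "x1": [0, 1, 2], "y1": [0, 1, 2]})
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(FormatError, match="frame"):
            pol.read_trajectories(path, "wide", dt=0.1)

    def test_header_mismatch_rejected(self, tmp_path):
        df = pd.DataFrame({"frame": [0, 1], "a": [0, 1], "b": [0, 1]})
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(FormatError):
            pol.read_trajectories(path, "wide", dt=0.1)

    def test_long_dialect(self, tmp_path):
        rows = [
            {"frame": t, "fish_id": f, "x": float(t + f), "y": float(t - f)}
            for t in range(5)
            for f in (1, 2)
        ]
        path = tmp_path / "long.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        table = pol.read_trajectories(path, "long", dt=0.5)
        assert table.positions.shape == (5, 2, 2)
        assert table.positions[3, 1, 0] == 3 + 2

    def test_long_duplicate_pair_rejected(self, tmp_path):
        rows = [
            {"frame": 0, "fish_id": 1, "x": 0.0, "y": 0.0},
            {"frame": 0, "fish_id": 1, "x": 1.0, "y": 1.0},
        ]
        path = tmp_path / "dup_long.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        with pytest.raises(FormatError):
            pol.read_trajectories(path, "long", dt=0.5)

    def test_dt_from_sidecar(self, tmp_path):
        ds = sd.draw_directions(2, 50, sd.RegimeSpec("uncorrelated"), seed=1)
        out = tmp_path / "t.csv"
        sd.synthesize_trial(ds, out_path=out)
        table = pol.read_trajectories(out, "wide")
        assert table.dt == pytest.approx(1 / 30)

    def test_missing_dt_rejected(self, tmp_path):
        path = wide_csv(tmp_path, np.zeros((5, 1, 2)))
        with pytest.raises(FormatError, match="dt"):
            pol.read_trajectories(path, "wide")


class TestComputeDirectors:
    def test_normalized_displacement(self):
        posi = np.zeros((3, 1, 2))
        posi[1] = [[3.0, 4.0]]
        posi[2] = [[6.0, 8.0]]
        directors = pol.compute_directors(table_from_array(posi, dt=1.0))
        np.testing.assert_allclose(directors.directors[:, 0], [[0.6, 0.8], [0.6, 0.8]])
        assert directors.valid.all()

    def test_zero_displacement_is_invalid(self):
        posi = np.zeros((4, 1, 2))
        directors = pol.compute_directors(table_from_array(posi))
        assert not directors.valid.any()

    def test_constant_heading_any_speed(self):
        posi = np.zeros((10, 1, 2))
        posi[:, 0, 0] = np.arange(10) * 0.05  # 0.5 cm/s at dt=0.1
        directors = pol.compute_directors(table_from_array(posi, dt=0.1))
        np.testing.assert_allclose(directors.directors[:, 0, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(directors.directors[:, 0, 1], 0.0, atol=1e-12)

    def test_min_speed_threshold(self):
        posi = np.zeros((3, 1, 2))
        posi[1, 0, 0] = 0.005  # 0.05 cm/s at dt=0.1
        posi[2, 0, 0] = 0.5
        directors = pol.compute_directors(table_from_array(posi, dt=0.1), min_speed=0.1)
        assert not directors.valid[0, 0] and directors.valid[1, 0]

    def test_unit_norm_invariant(self):
        rng = np.random.default_rng(5)
        posi = np.cumsum(rng.normal(size=(50, 4, 2)), axis=0)
        directors = pol.compute_directors(table_from_array(posi, dt=0.1))
        norms = np.linalg.norm(directors.directors[directors.valid], axis=-1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pol.compute_directors(table_from_array(np.zeros((1, 2, 2))))


class TestPolarizationSeries:
    def series_from_directors(self, vecs):
        """vecs: (T, N, 2) unit vectors, all valid, dt = 1."""
        d = pol.DirectorSeries(
            directors=np.asarray(vecs, dtype=float),
            valid=np.ones(np.asarray(vecs).shape[:2], dtype=bool),
            dt=1.0,
            min_speed=0.1,
            n_positions=np.asarray(vecs).shape[0] + 1,
        )
        return pol.polarization_series(d)

    def test_textbook_values(self):
        s = self.series_from_directors([[[1, 0], [0, 1]]])
        assert s.P[0] == pytest.approx(math.sqrt(2) / 2)
        s = self.series_from_directors([[[1, 0], [1, 0], [1, 0]]])
        assert s.P[0] == pytest.approx(1.0)
        s = self.series_from_directors([[[1, 0], [-1, 0]]])
        assert s.P[0] == pytest.approx(0.0, abs=1e-15)

    def test_cross_term_identity(self):
        # P² = (1/n²) [n + Σ_{i≠j} cos θ_ij] must hold to round-off
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, 2 * np.pi, size=(20, 6))
        vecs = np.stack([np.cos(theta), np.sin(theta)], axis=2)
        s = self.series_from_directors(vecs)
        n = 6
        for t in range(20):
            cos_sum = 0.0
            for i in range(n):
                for j in range(n):
                    if i != j:
                        cos_sum += math.cos(theta[t, i] - theta[t, j])
            assert s.P2[t] == pytest.approx((n + cos_sum) / n**2, abs=1e-12)

    def test_partial_validity_uses_n_effective(self):
        d = np.full((1, 3, 2), np.nan)
        d[0, 0] = [1, 0]
        d[0, 1] = [0, 1]
        valid = np.array([[True, True, False]])
        series = pol.polarization_series(
            pol.DirectorSeries(d, valid, 1.0, 0.1, n_positions=2)
        )
        assert series.n_effective[0] == 2
        assert series.P[0] == pytest.approx(math.sqrt(2) / 2)

    def test_single_valid_fish_marks_frame_invalid(self):
        d = np.full((2, 2, 2), np.nan)
        d[:, 0] = [1, 0]
        valid = np.array([[True, False], [True, True]])
        d[1, 1] = [0, 1]
        series = pol.polarization_series(
            pol.DirectorSeries(d, valid, 1.0, 0.1, n_positions=3)
        )
        assert not series.valid[0] and series.valid[1]

    def test_trim_frame_accounting(self):
        # 8.5 min at 30 fps, one minute off each end: 6.5 min of frames
        # minus the single differencing loss
        T = int(8.5 * 60 * 30)
        d = np.zeros((T - 1, 2, 2))
        d[:, :, 0] = 1.0
        series = pol.polarization_series(
            pol.DirectorSeries(
                d, np.ones((T - 1, 2), bool), dt=1 / 30, min_speed=0.1, n_positions=T
            ),
            trim_start=60.0,
            trim_end=60.0,
        )
        assert series.P.size == int(6.5 * 60 * 30) - 1
        assert series.time[0] == pytest.approx(60.0)

    def test_empty_after_trim_rejected(self):
        d = np.zeros((5, 2, 2))
        with pytest.raises(ValueError):
            pol.polarization_series(
                pol.DirectorSeries(d, np.ones((5, 2), bool), 1.0, 0.1, n_positions=6),
                trim_start=10.0,
                trim_end=0.0,
            )

    @given(st.floats(min_value=-math.pi, max_value=math.pi))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_rotation_invariance(self, angle):
        rng = np.random.default_rng(11)
        posi = np.cumsum(rng.normal(size=(30, 4, 2)), axis=0)
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        s0 = pol.polarization_series(pol.compute_directors(table_from_array(posi)))
        s1 = pol.polarization_series(
            pol.compute_directors(table_from_array(posi @ rot.T))
        )
        np.testing.assert_allclose(s0.P, s1.P, atol=1e-12)


class TestEndToEnd:
    def test_synthesized_trajectories_reproduce_direct_polarization(self, tmp_path):
        ds = sd.draw_directions(5, 3000, sd.RegimeSpec("schooling", rho=0.3), seed=42)
        out = tmp_path / "trial.csv"
        sd.synthesize_trial(ds, out_path=out)
        table = pol.read_trajectories(out, "wide")
        directors = pol.compute_directors(table)
        series = pol.polarization_series(directors)
        direct = ds.polarization()[:-1]
        interior = directors.valid.all(axis=1)
        assert interior.mean() > 0.5
        np.testing.assert_allclose(
            series.P[interior], direct[interior], atol=1e-9
        )
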
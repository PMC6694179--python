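"""Tests of the indicator computation, grid building and inversion."""

import numpy as np
import pandas as pd
import pytest

import rootbranch as rb
from rootbranch.errors import (
    CalibrationQualityError,
    SampleSizeError,
)


class TestIndicators:
    def test_gaussian_limit_closed_forms(self, rng):
        # at p_em = 1 the IBD distribution is (truncation aside) Normal(2, 0.6):
        # its density mode is the mean and q80/mode = 1 + z_0.8 * cv = 1.2525
        ibd = rb.simulate_ibd(rb.BranchingParams(2.0, 0.3, 1.0), 100_000, rng)
        ind = rb.compute_indicators(ibd)
        assert ind.mode == pytest.approx(2.0, rel=0.05)
        assert ind.q80_over_mode == pytest.approx(1 + 0.8416 * 0.3, rel=0.03)
        assert ind.q10_over_mode == pytest.approx(1 - 1.2816 * 0.3, rel=0.05)

    def test_degenerate_point_mass(self):
        ind = rb.compute_indicators(np.full(100, 2.0))
        assert (ind.mode, ind.q10_over_mode, ind.q80_over_mode) == (2.0, 1.0, 1.0)

    def test_sample_size_floor(self):
        with pytest.raises(SampleSizeError):
            rb.compute_indicators(np.ones(10) + np.arange(10) * 0.01)

    def test_kde_mode_on_known_density(self, rng):
        x = rng.normal(3.0, 0.5, 50_000)
        assert rb.kde_mode(x) == pytest.approx(3.0, abs=0.1)


class TestBuildCalibration:
    def test_shape_and_marginal_monotonicity(self, rng):
        spec = {
            "isd": [0.5, 1.5, 3.0],
            "cv_d": [0.2, 0.4, 0.6],
            "p_em": [0.4, 0.7, 1.0],
        }
        tab = rb.build_calibration(spec, 5_000, rng)
        assert len(tab.grid) == 27
        vals, modes = tab.marginal("isd")
        assert np.all(np.diff(modes) > 0)
        # thinning lengthens the right tail: q80/mode smallest at p_em = 1
        by_pem = tab.grid.groupby("p_em")["q80_over_mode"].mean()
        assert by_pem.idxmin() == 1.0

    def test_reference_design_has_8000_points(self):
        spec = rb.reference_grid_spec()
        assert int(np.prod([len(v) for v in spec.values()])) == 8_000

    def test_determinism(self):
        spec = {"isd": [1.0, 2.0], "cv_d": [0.3], "p_em": [0.6, 1.0]}
        t1 = rb.build_calibration(spec, 2_000, np.random.default_rng(3))
        t2 = rb.build_calibration(spec, 2_000, np.random.default_rng(3))
        pd.testing.assert_frame_equal(t1.grid, t2.grid)

    def test_csv_roundtrip(self, tmp_path, rng):
        spec = {"isd": [1.0, 2.0], "cv_d": [0.3, 0.5], "p_em": [0.6, 1.0]}
        tab = rb.build_calibration(spec, 2_000, rng, seed=42)
        path = tmp_path / "table.csv"
        tab.to_csv(path)
        back = rb.CalibrationTable.from_csv(path)
        assert back.grid_spec == tab.grid_spec
        assert back.n_laterals == tab.n_laterals
        assert back.seed == 42
        np.testing.assert_allclose(
            back.grid["mode"], tab.grid["mode"], rtol=1e-5
        )


class TestEstimateParams:
    def test_recovery_at_grid_point(self, shipped_table):
        truth = rb.BranchingParams(2.0, 0.4, 0.8)
        ibd = rb.simulate_ibd(truth, 60_000, np.random.default_rng(21))
        est = rb.estimate_params(ibd, shipped_table).params
        assert est.isd == pytest.approx(truth.isd, rel=0.10)
        assert est.cv_d == pytest.approx(truth.cv_d, rel=0.20)
        assert est.p_em == pytest.approx(truth.p_em, rel=0.20)

    def test_pem_boundary(self, shipped_table):
        ibd = rb.simulate_ibd(
            rb.BranchingParams(2.0, 0.1, 1.0), 60_000, np.random.default_rng(4)
        )
        res = rb.estimate_params(ibd, shipped_table)
        assert res.params.p_em > 0.9

    def test_out_of_range_mode_clamped_and_flagged(self, shipped_table):
        # mode far below the smallest calibrated mode value
        ibd = np.random.default_rng(8).normal(0.05, 0.005, 5_000)
        ibd = np.abs(ibd) + 1e-6
        res = rb.estimate_params(ibd, shipped_table)
        assert "isd_clamped_low" in res.flags
        assert res.params.isd == pytest.approx(min(shipped_table.grid_spec["isd"]))

    def test_wrong_direction_raises(self, shipped_table):
        broken = rb.CalibrationTable(
            grid=shipped_table.grid.assign(mode=-shipped_table.grid["mode"] + 10),
            grid_spec=shipped_table.grid_spec,
            n_laterals=shipped_table.n_laterals,
        )
        ibd = rb.simulate_ibd(
            rb.BranchingParams(2.0, 0.3, 0.8), 5_000, np.random.default_rng(1)
        )
        with pytest.raises(CalibrationQualityError):
            rb.estimate_params(ibd, broken)

    def test_noisy_marginal_smoothed_not_fatal(self, shipped_table, rng):
        jitter = shipped_table.grid.copy()
        # perturb one mode value enough to break local monotonicity
        g = jitter.groupby("isd")["mode"].mean()
        bump = jitter["isd"] == g.index[3]
        jitter.loc[bump, "mode"] += (g.iloc[4] - g.iloc[3]) * 1.5
        noisy = rb.CalibrationTable(
            grid=jitter,
            grid_spec=shipped_table.grid_spec,
            n_laterals=shipped_table.n_laterals,
        )
        ibd = rb.simulate_ibd(rb.BranchingParams(2.0, 0.3, 0.8), 5_000, rng)
        with pytest.warns(UserWarning, match="non-monotone"):
            res = rb.estimate_params(ibd, noisy)
        assert "isd_marginal_smoothed" in res.flags

    def test_shipped_table_marginals_monotone(self, shipped_table):
        for p in ("isd", "cv_d", "p_em"):
            assert shipped_table.marginal_monotone(p)
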
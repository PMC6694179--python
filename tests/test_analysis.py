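"""Tests of per-sample diagnostics, goodness of fit and the diameter split."""

import numpy as np
import pytest
from scipy import stats

import rootbranch as rb
from rootbranch.errors import SplitError
from tests.conftest import make_sample


class TestDiagnostics:
    def test_thinned_distribution_is_right_skewed(self, rng):
        ibd = rb.simulate_ibd(rb.BranchingParams(1.0, 0.3, 0.5), 10_000, rng)
        d = rb.distribution_diagnostics(make_sample(ibd))
        assert d["skewness"] > 0
        assert d["agostino_p"] < 0.01
        assert d["shapiro_p"] < 0.01

    def test_normality_null_calibrated(self):
        # at p_em=1 and moderate cv the data are (near-)normal, so the
        # Shapiro-Wilk test should reject at roughly its nominal 5% rate
        rejections = 0
        rng = np.random.default_rng(99)
        for _ in range(100):
            ibd = rb.simulate_ibd(rb.BranchingParams(2.0, 0.2, 1.0), 200, rng)
            d = rb.distribution_diagnostics(make_sample(ibd))
            rejections += d["shapiro_p"] < 0.05
        assert rejections <= 12

    def test_diameter_independence_null(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(100):
            ibd = rb.simulate_ibd(rb.BranchingParams(1.0, 0.3, 0.7), 200, rng)
            diam = rng.uniform(0.2, 1.0, ibd.size)
            d = rb.distribution_diagnostics(make_sample(ibd, diam))
            rejections += d["diameter_ibd_p"] < 0.05
        assert rejections <= 12

    def test_constant_input_reports_nan(self):
        d = rb.distribution_diagnostics(make_sample(np.full(50, 2.0)))
        assert np.isnan(d["shapiro_p"]) and np.isnan(d["agostino_p"])
        assert d["median"] == 2.0

    def test_relabeling_invariance(self, rng):
        ibd = rb.simulate_ibd(rb.BranchingParams(1.0, 0.3, 0.7), 300, rng)
        s1 = make_sample(ibd, rng.uniform(0.2, 1.0, ibd.size))
        s2 = rb.IBDSample(
            sample_id=s1.sample_id,
            records=s1.records.assign(
                parent_root_id=[f"renamed_{i}" for i in range(len(s1.records))]
            ),
        )
        d1 = rb.distribution_diagnostics(s1)
        d2 = rb.distribution_diagnostics(s2)
        assert d1 == d2


class TestGoodnessOfFit:
    def test_gross_misfit_rejected(self, rng):
        ibd = rb.simulate_ibd(rb.BranchingParams(1.0, 0.3, 0.5), 500, rng)
        fit = rb.goodness_of_fit(
            make_sample(ibd), rb.BranchingParams(2.0, 0.3, 0.5),
            n_sim=50_000, rng=rng,
        )
        assert fit.p_value < 0.001

    def test_self_consistency_typically_accepts(self, rng):
        params = rb.BranchingParams(1.5, 0.4, 0.6)
        pvals = [
            rb.goodness_of_fit(
                make_sample(rb.simulate_ibd(params, 501, rng)),
                params, n_sim=50_000, rng=rng,
            ).p_value
            for _ in range(20)
        ]
        assert np.mean(np.array(pvals) < 0.05) <= 0.25

    def test_expected_counts_floor(self, rng):
        # a tiny sample forces bin merging; every expected count stays >= 5
        ibd = rb.simulate_ibd(rb.BranchingParams(1.5, 0.4, 0.6), 60, rng)
        fit = rb.goodness_of_fit(
            make_sample(ibd), rb.BranchingParams(1.5, 0.4, 0.6),
            n_sim=20_000, rng=rng,
        )
        assert 4 <= fit.dof + 1 <= 12


class TestFitSample:
    def test_below_inclusion_floor_flagged(self, shipped_table, rng):
        ibd = rb.simulate_ibd(rb.BranchingParams(1.5, 0.4, 0.7), 100, rng)
        fit = rb.fit_sample(make_sample(ibd), shipped_table, rng, n_sim=20_000)
        assert "below_150_records" in fit.flags

    def test_deterministic_given_seed(self, shipped_table):
        ibd = rb.simulate_ibd(
            rb.BranchingParams(1.5, 0.4, 0.7), 300, np.random.default_rng(6)
        )
        fits = [
            rb.fit_sample(
                make_sample(ibd), shipped_table, np.random.default_rng(11),
                n_sim=20_000,
            )
            for _ in range(2)
        ]
        assert fits[0] == fits[1]


class TestDiameterSplit:
    def test_threshold_is_central_diameter(self, shipped_table, rng):
        ibd = rb.simulate_ibd(rb.BranchingParams(1.5, 0.4, 0.7), 300, rng)
        diam = rng.choice([0.2, 0.5, 1.0], size=ibd.size)
        res = rb.diameter_split_analysis(
            make_sample(ibd, diam), shipped_table, rng, n_sim=20_000
        )
        assert res.threshold == pytest.approx(0.6)

    def test_ties_go_to_fine_stratum(self, shipped_table, rng):
        ibd = rb.simulate_ibd(rb.BranchingParams(1.5, 0.4, 0.7), 301, rng)
        diam = np.tile([0.2, 0.6, 1.0], 100)  # threshold exactly 0.6
        res = rb.diameter_split_analysis(
            make_sample(ibd, diam), shipped_table, rng, n_sim=20_000
        )
        assert res.fine_fit.n_obs == 200
        assert res.thick_fit.n_obs == 100

    def test_single_diameter_raises_split_error(self, shipped_table, rng):
        ibd = rb.simulate_ibd(rb.BranchingParams(1.5, 0.4, 0.7), 100, rng)
        with pytest.raises(SplitError):
            rb.diameter_split_analysis(
                make_sample(ibd, 0.5), shipped_table, rng, n_sim=20_000
            )

    def test_stratum_pem_contrast_recovered(self, shipped_table):
        rng = np.random.default_rng(31)
        sc = rb.SpeciesScenario(
            sample_id="c",
            base_params=rb.BranchingParams(2.0, 0.4, 0.9),
            n_laterals=400,
            diameter_range=(0.2, 1.0),
            diameter_effect=rb.DiameterEffect(p_em_fine=0.6, p_em_thick=0.9),
        )
        hits = 0
        for _ in range(10):
            sample = rb.generate_sample(sc, rng)
            res = rb.diameter_split_analysis(sample, shipped_table, rng, n_sim=30_000)
            hits += res.fine_fit.params.p_em < res.thick_fit.params.p_em
        assert hits >= 9


class TestPanelSummary:
    def test_requires_two_fits(self):
        with pytest.raises(ValueError):
            rb.panel_summary([])

    def test_degenerate_panel_reports_nan(self, shipped_table, rng):
        ibd = rb.simulate_ibd(rb.BranchingParams(1.5, 0.4, 0.7), 300, rng)
        fit = rb.fit_sample(make_sample(ibd), shipped_table, rng, n_sim=20_000)
        out = rb.panel_summary([fit, fit])
        assert np.isnan(out["r2_isd_cv_d"])

    def test_ranges_and_anova(self, shipped_table):
        rng = np.random.default_rng(17)
        samples, _ = rb.generate_panel(
            rb.default_panel_scenarios(6, n_laterals=200), rng
        )
        fits = [
            rb.fit_sample(s, shipped_table, rng, n_sim=20_000) for s in samples
        ]
        out = rb.panel_summary(fits, samples=samples)
        assert out["isd_fold"] > 3
        assert out["anova_species_p"] < 0.001
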
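"""Meta-analysis pooling and sample-size solvers."""

import json
import shutil
import subprocess

import numpy as np
import pytest

from nnrf.meta import (
    SiteSummary,
    aipe_mean_n,
    correlation_power,
    inflate,
    inverse_variance_meta,
    power_correlation_exact,
    power_paired_t,
    tost_equivalence_n,
    tost_power,
    _aipe_width,
    _paired_t_power,
    _pearson_r_pdf,
)

THREE_SITES = [
    SiteSummary("Oxford", 1.02, 0.75, 119),
    SiteSummary("Exeter", 0.92, 0.84, 35),
    SiteSummary("UCL", 1.33, 0.88, 72),
]


class TestInverseVarianceMeta:
    def test_three_site_pooling_reproduces_published_summary(self):
        res = inverse_variance_meta(THREE_SITES)
        assert round(res.ce_mean, 2) == 1.09
        assert round(res.ce_ci95[0], 2) == 0.98
        assert round(res.ce_ci95[1], 2) == 1.19
        assert res.Q == pytest.approx(7.86, abs=0.05)
        assert res.I2 == pytest.approx(75.0, abs=1.0)
        assert round(res.re_mean, 2) == 1.10
        assert res.re_ci95[0] == pytest.approx(0.57, abs=0.02)
        assert res.re_ci95[1] == pytest.approx(1.62, abs=0.02)
        assert res.Q_p < 0.05

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_reml_knapp_hartung_matches_metafor(self):
        """Independent oracle: metafor::rma with REML and Knapp-Hartung."""
        script = (
            "suppressMessages(library(metafor));"
            "y<-c(1.02,.92,1.33); sei<-c(.75/sqrt(119),.84/sqrt(35),.88/sqrt(72));"
            "f<-rma(yi=y, sei=sei, method='REML', test='knha');"
            "cat(jsonlite::toJSON(list(tau2=f$tau2, b=as.numeric(f$b),"
            "ci.lb=f$ci.lb, ci.ub=f$ci.ub), digits=10))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        oracle = {k: v[0] for k, v in json.loads(out.stdout).items()}
        res = inverse_variance_meta(THREE_SITES, kh_floor=False)
        assert res.tau2 == pytest.approx(oracle["tau2"], abs=1e-6)
        assert res.re_mean == pytest.approx(oracle["b"], abs=1e-6)
        assert res.re_ci95[0] == pytest.approx(oracle["ci.lb"], abs=1e-6)
        assert res.re_ci95[1] == pytest.approx(oracle["ci.ub"], abs=1e-6)

    def test_homogeneous_sites_collapse_to_common_mean(self):
        sites = [SiteSummary("a", 1.1, 0.8, 50), SiteSummary("b", 1.1, 0.8, 50)]
        res = inverse_variance_meta(sites)
        assert res.ce_mean == pytest.approx(1.1)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.I2 == 0.0 and res.tau2 == 0.0
        assert res.re_mean == pytest.approx(res.ce_mean)

    def test_equal_se_sites_pool_to_arithmetic_mean(self):
        sites = [SiteSummary(s, m, 0.8, 64) for s, m in zip("abc", (0.9, 1.0, 1.4))]
        res = inverse_variance_meta(sites)
        assert res.ce_mean == pytest.approx(np.mean([0.9, 1.0, 1.4]))

    def test_order_invariance(self):
        res1 = inverse_variance_meta(THREE_SITES)
        res2 = inverse_variance_meta(THREE_SITES[::-1])
        assert res1.ce_mean == pytest.approx(res2.ce_mean)
        assert res1.tau2 == pytest.approx(res2.tau2)
        assert res1.re_ci95 == pytest.approx(res2.re_ci95)

    def test_zero_sd_site_rejected_by_name(self):
        with pytest.raises(ValueError, match="degenerate"):
            inverse_variance_meta([SiteSummary("degenerate", 1.0, 0.0, 10)])

    def test_forest_table_weights_sum_to_100(self):
        res = inverse_variance_meta(THREE_SITES)
        from nnrf.meta import forest_table

        tab = forest_table(THREE_SITES, res)
        assert tab["weight_CE_pct"].sum() == pytest.approx(100.0)
        assert tab["weight_RE_pct"].sum() == pytest.approx(100.0)
        # REML heterogeneity evens out the RE weights
        assert tab["weight_RE_pct"].max() < tab["weight_CE_pct"].max()

    def test_single_site_degenerate_passthrough(self):
        res = inverse_variance_meta([SiteSummary("only", 1.2, 0.5, 25)])
        assert res.degenerate and res.ce_mean == 1.2 and res.Q == 0.0


class TestPairedTPower:
    def test_published_planning_scenario(self):
        assert power_paired_t(0.589, alpha=0.02, power=0.90) == 35

    def test_doubling_effect_size_reduces_n(self):
        assert power_paired_t(1.178, 0.02, 0.90) < power_paired_t(0.589, 0.02, 0.90)

    def test_two_sided_medium_effect_scenario(self):
        assert power_paired_t(0.5, alpha=0.05, power=0.80, tail="two") == 34

    def test_bracketing_property(self):
        n = power_paired_t(0.589, 0.02, 0.90)
        assert _paired_t_power(n, 0.589, 0.02, "one") >= 0.90
        assert _paired_t_power(n - 1, 0.589, 0.02, "one") < 0.90

    def test_nonpositive_effect_rejected(self):
        with pytest.raises(ValueError):
            power_paired_t(0.0)


class TestCorrelationPower:
    def test_published_planning_scenario(self):
        assert power_correlation_exact(0.51, alpha=0.02, power=0.90) == 38

    def test_exact_density_normalises(self):
        from scipy import integrate

        for n in (10, 38):
            val, _ = integrate.quad(_pearson_r_pdf, -1, 1, args=(0.51, n), limit=200)
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_fisher_z_mode_close_to_exact(self):
        n_exact = power_correlation_exact(0.51, 0.02, 0.90, method="exact")
        n_fisher = power_correlation_exact(0.51, 0.02, 0.90, method="fisher")
        assert abs(n_exact - n_fisher) <= 2

    def test_strong_correlation_needs_few_participants(self):
        assert power_correlation_exact(0.95, 0.02, 0.90) <= 10

    def test_bracketing_property(self):
        n = power_correlation_exact(0.51, 0.02, 0.90)
        assert correlation_power(n, 0.51, 0.02) >= 0.90
        assert correlation_power(n - 1, 0.51, 0.02) < 0.90

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            power_correlation_exact(1.2)


class TestAIPE:
    def test_bracketing_against_direct_width_evaluation(self):
        n = aipe_mean_n(0.75, 0.4, level=0.90)
        assert _aipe_width(n, 0.75, 0.90) <= 0.4
        assert _aipe_width(n - 1, 0.75, 0.90) > 0.4
        assert n == 40

    def test_halving_sd_roughly_quarters_n(self):
        # large-n regime where the t-quantile is nearly constant
        n_full = aipe_mean_n(1.5, 0.2)
        n_half = aipe_mean_n(0.75, 0.2)
        assert n_full / 4.5 < n_half < n_full / 3.5

    def test_huge_width_hits_minimum_n(self):
        assert aipe_mean_n(0.75, 1e6) == 2

    def test_assurance_increases_n(self):
        assert aipe_mean_n(0.75, 0.4, assurance=0.99) > aipe_mean_n(0.75, 0.4)


class TestTOST:
    def test_symmetric_true_means_have_equal_power(self):
        lo = tost_power(40, 0.5, true_mean=0.9)
        hi = tost_power(40, 0.5, true_mean=1.1)
        assert lo == pytest.approx(hi, abs=1e-6)

    def test_wider_bounds_never_need_more_participants(self):
        narrow = tost_equivalence_n(0.5, bounds=(0.9, 1.1))
        wide = tost_equivalence_n(0.5, bounds=(0.8, 1.2))
        assert wide <= narrow

    def test_bracketing_property(self):
        n = tost_equivalence_n(0.5, alpha=0.05, power=0.90)
        assert tost_power(n, 0.5) >= 0.90
        assert tost_power(n - 1, 0.5) < 0.90

    def test_true_mean_on_bound_rejected(self):
        with pytest.raises(ValueError):
            tost_equivalence_n(0.5, bounds=(0.8, 1.2), true_mean=1.2)


class TestInflate:
    @pytest.mark.parametrize("n, expected", [(35, 39), (73, 81), (38, 42), (40, 44)])
    def test_ten_percent_inflation_is_pure_ceiling(self, n, expected):
        assert inflate(n) == expected

    def test_zero_fraction_is_identity(self):
        assert inflate(35, 0.0) == 35

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            inflate(0)
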
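"""MR estimators against closed-form oracles, planted truths, and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sleepmr.estimators import (
    MRSuiteConfig,
    cochran_q,
    egger,
    ivw,
    presso_global,
    radial_outliers,
    run_mr_suite,
    weighted_median,
)
from sleepmr.simulate import MRSimConfig, simulate_mr_pair
from conftest import make_instruments, simulate_harmonized


class TestIVW:
    def test_single_snp_reduces_to_wald_ratio(self):
        fit = ivw(make_instruments([0.1], [0.02], [0.005]))
        assert fit.estimate == pytest.approx(0.2)
        assert fit.se == pytest.approx(0.005 / 0.1)

    def test_zero_outcome_effects_give_zero_estimate_p_one(self):
        fit = ivw(make_instruments([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], [0.01] * 3))
        assert fit.estimate == 0.0
        assert fit.pval == 1.0

    def test_three_snp_closed_form_oracle(self, three_snp_instruments):
        bx = three_snp_instruments["beta_exp"].to_numpy()
        by = three_snp_instruments["beta_out"].to_numpy()
        sy = three_snp_instruments["se_out"].to_numpy()
        w = 1 / sy**2
        expected = np.sum(w * bx * by) / np.sum(w * bx**2)
        fit = ivw(three_snp_instruments)
        assert fit.estimate == pytest.approx(expected, abs=1e-12)
        # multiplicative random effects floored at 1
        q = np.sum(w * (by - expected * bx) ** 2)
        se_expected = np.sqrt(max(1.0, q / 2) / np.sum(w * bx**2))
        assert fit.se == pytest.approx(se_expected, abs=1e-12)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            ivw(make_instruments([0.1], [0.02], [0.0]))

    def test_random_effects_se_never_below_fixed_effects(self):
        for seed in range(5):
            h = simulate_harmonized(n_snps=30, beta_causal=0.1, het_sd=0.01, seed=seed)
            fit = ivw(h)
            w = 1 / h["se_out"] ** 2
            se_fixed = np.sqrt(1 / np.sum(w * h["beta_exp"] ** 2))
            assert fit.se >= se_fixed - 1e-15


class TestEgger:
    def test_exact_line_recovered_without_noise(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.05 + 0.2 * bx
        fit = egger(make_instruments(bx, by, [0.01] * 4))
        assert fit.intercept == pytest.approx(0.05, abs=1e-12)
        assert fit.slope.estimate == pytest.approx(0.2, abs=1e-12)

    def test_sign_orientation_flips_negative_exposures(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = 0.05 * np.sign(bx) + 0.2 * bx  # directional w.r.t. increasing allele
        fit = egger(make_instruments(bx, by, [0.01] * 4))
        assert fit.intercept == pytest.approx(0.05, abs=1e-12)
        assert fit.slope.estimate == pytest.approx(0.2, abs=1e-12)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            egger(make_instruments([0.1, 0.2], [0.02, 0.04], [0.01, 0.01]))

    def test_matches_statsmodels_wls_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.03 + 0.15 * bx + rng.normal(0, 0.01, 8)
        sy = rng.uniform(0.005, 0.02, 8)
        fit = egger(make_instruments(bx, by, sy))
        wls = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert fit.intercept == pytest.approx(wls.params[0], abs=1e-10)
        assert fit.slope.estimate == pytest.approx(wls.params[1], abs=1e-10)


class TestWeightedMedian:
    def test_identical_ratios_returned_exactly(self):
        bx = np.array([0.1, 0.2, 0.4])
        fit = weighted_median(make_instruments(bx, 0.3 * bx, [0.01, 0.02, 0.03]),
                              n_boot=50, seed=0)
        assert fit.estimate == pytest.approx(0.3, abs=1e-12)

    def test_median_resists_outlying_ratios(self):
        """Equal weights, ratios {0.1, 0.2, 0.3, 10, 20}: the weighted median
        interpolates to the middle ratio."""
        bx = np.ones(5)
        ratios = np.array([0.1, 0.2, 0.3, 10.0, 20.0])
        fit = weighted_median(make_instruments(bx, ratios, np.ones(5)),
                              n_boot=50, seed=0)
        assert fit.estimate == pytest.approx(0.3, abs=1e-12)

    def test_seeded_bootstrap_reproducible(self, three_snp_instruments):
        a = weighted_median(three_snp_instruments, n_boot=100, seed=7)
        b = weighted_median(three_snp_instruments, n_boot=100, seed=7)
        assert a.se == b.se


class TestCochranQ:
    def test_homogeneous_data_gives_zero_q(self):
        bx = np.array([0.1, 0.2, 0.3])
        res = cochran_q(make_instruments(bx, 0.2 * bx, [0.01] * 3), 0.2)
        assert res.q == pytest.approx(0.0, abs=1e-20)
        assert res.pval == pytest.approx(1.0)

    def test_three_snp_hand_computed_oracle(self, three_snp_instruments):
        bx = three_snp_instruments["beta_exp"].to_numpy()
        by = three_snp_instruments["beta_out"].to_numpy()
        sy = three_snp_instruments["se_out"].to_numpy()
        pooled = ivw(three_snp_instruments).estimate
        ratios = by / bx
        w = (bx / sy) ** 2
        expected = np.sum(w * (ratios - pooled) ** 2)
        res = cochran_q(three_snp_instruments, pooled)
        assert res.q == pytest.approx(expected, abs=1e-12)
        assert res.df == 2
        assert res.pval == pytest.approx(stats.chi2.sf(expected, 2), abs=1e-12)

    def test_single_snp_undefined(self):
        with pytest.raises(ValueError):
            cochran_q(make_instruments([0.1], [0.02], [0.01]), 0.2)


class TestRadial:
    def test_clean_data_has_no_outliers(self):
        h = simulate_harmonized(n_snps=30, beta_causal=0.2, seed=4)
        assert radial_outliers(h).outlier_snps == []

    def test_planted_outlier_flagged_and_refit_attached(self):
        h = simulate_harmonized(n_snps=30, beta_causal=0.2, seed=4).copy()
        h.loc[h.index[0], "beta_out"] += 10 * h["se_out"].iloc[0]
        res = radial_outliers(h)
        assert h["SNP"].iloc[0] in res.outlier_snps
        assert res.refit is not None
        assert res.refit.n_snp == len(h) - len(res.outlier_snps)

    def test_flagging_invariant_to_snp_order(self):
        h = simulate_harmonized(n_snps=30, beta_causal=0.2, seed=4).copy()
        h.loc[h.index[0], "beta_out"] += 10 * h["se_out"].iloc[0]
        shuffled = h.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert radial_outliers(h).outlier_snps == radial_outliers(shuffled).outlier_snps


class TestPresso:
    def test_seeded_determinism(self):
        h = simulate_harmonized(n_snps=20, beta_causal=0.2, seed=2)
        assert presso_global(h, 300, seed=5) == presso_global(h, 300, seed=5)

    def test_planted_outlier_detected(self):
        hits = 0
        for r in range(20):
            h = simulate_harmonized(n_snps=30, beta_causal=0.2, seed=100 + r).copy()
            h.loc[h.index[0], "beta_out"] += 12 * h["se_out"].iloc[0]
            hits += presso_global(h, 300, seed=r) < 0.05
        assert hits >= 18

    def test_simulation_count_guards(self):
        h = simulate_harmonized(n_snps=20, beta_causal=0.2, seed=2)
        with pytest.raises(ValueError):
            presso_global(h, 5)
        with pytest.warns(UserWarning):
            presso_global(h, 50)


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [0.1, 3.0])
    def test_outcome_rescaling_rescales_every_estimate(self, c, three_snp_instruments):
        base = three_snp_instruments
        scaled = base.copy()
        scaled["beta_out"] *= c
        scaled["se_out"] *= c
        assert ivw(scaled).estimate == pytest.approx(c * ivw(base).estimate)
        assert egger(scaled).slope.estimate == pytest.approx(
            c * egger(base).slope.estimate
        )
        assert weighted_median(scaled, n_boot=50, seed=0).estimate == pytest.approx(
            c * weighted_median(base, n_boot=50, seed=0).estimate
        )


class TestSuite:
    def test_estimates_concordant_on_clean_causal_pair(self):
        exposure, outcome, _ = simulate_mr_pair(
            MRSimConfig(n_snps=50, beta_causal=0.2, seed=6)
        )
        res = run_mr_suite(
            exposure, outcome,
            config=MRSuiteConfig(n_boot=200, presso_n_sim=200),
        )
        assert not res.excluded
        ests = [f.estimate for f in res.fits.values()]
        ivw_fit = res.fits["ivw"]
        for e in ests:
            assert ivw_fit.ci_low - 0.05 < e < ivw_fit.ci_high + 0.05

    def test_pair_below_min_snps_excluded_without_fits(self):
        exposure, outcome, _ = simulate_mr_pair(MRSimConfig(n_snps=5, seed=1))
        res = run_mr_suite(
            exposure, outcome, config=MRSuiteConfig(min_snps=50)
        )
        assert res.excluded
        assert res.exclusion_reason == "below_min_snps"
        assert res.fits == {}

    def test_reverse_p_matches_swapped_run(self):
        expA, _, _ = simulate_mr_pair(MRSimConfig(n_snps=30, seed=21))
        expB, _, _ = simulate_mr_pair(MRSimConfig(n_snps=30, seed=22))
        cfg = MRSuiteConfig(n_boot=50, presso_n_sim=100)
        ab = run_mr_suite(expA, expB, config=cfg)
        ba = run_mr_suite(expB, expA, config=cfg)
        assert ab.reverse_ivw_p == pytest.approx(ba.fits["ivw"].pval)
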
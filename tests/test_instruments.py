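"""Instrument selection, clumping, harmonization and strength diagnostics."""

import numpy as np
import pandas as pd
import pytest

from sleepmr.instruments import (
    check_min_snps,
    compute_f_statistic,
    harmonize,
    instrument_r2,
    ld_clump,
    select_instruments,
)
from sleepmr.simulate import MRSimConfig, make_ld_matrix, simulate_mr_pair
from conftest import simulate_harmonized


def _gwas_row(snp, a1, a2, beta, p=1e-9, eaf=0.3, se=0.01, bp=1, chrom="1"):
    return {
        "SNP": snp, "CHR": chrom, "BP": bp, "A1": a1, "A2": a2,
        "EAF": eaf, "BETA": beta, "SE": se, "P": p, "N": 10000,
    }


class TestSelect:
    def test_nothing_significant_gives_empty(self):
        table = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.1, p=1.0)])
        assert select_instruments(table).empty

    def test_threshold_is_strict(self):
        table = pd.DataFrame(
            [
                _gwas_row("rs1", "A", "G", 0.1, p=4.9e-8),
                _gwas_row("rs2", "A", "G", 0.1, p=5.1e-8),
            ]
        )
        kept = select_instruments(table)
        assert kept["SNP"].tolist() == ["rs1"]

    def test_matches_brute_force_filter_on_simulated_rows(self):
        rng = np.random.default_rng(0)
        pvals = rng.uniform(0, 1e-6, size=100)
        table = pd.DataFrame(
            [_gwas_row(f"rs{i}", "A", "G", 0.1, p=p) for i, p in enumerate(pvals)]
        )
        kept = select_instruments(table, p_threshold=1e-7)
        expected = [f"rs{i}" for i, p in enumerate(pvals) if p < 1e-7]
        assert kept["SNP"].tolist() == expected

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            select_instruments(pd.DataFrame(columns=["SNP", "P"]))


def _brute_force_clump(variants, ld, r2_threshold, window_kb):
    """Independent greedy oracle, written directly from the rule statement."""
    rows = variants.sort_values(["P", "BP", "SNP"]).to_dict("records")
    accepted = []
    for row in rows:
        ok = True
        for acc in accepted:
            r2 = float(ld.loc[row["SNP"], acc["SNP"]]) ** 2
            if (
                str(row["CHR"]) == str(acc["CHR"])
                and abs(row["BP"] - acc["BP"]) <= window_kb * 1000
                and r2 > r2_threshold
            ):
                ok = False
                break
        if ok:
            accepted.append(row)
    return [r["SNP"] for r in accepted]


class TestClump:
    def test_identity_ld_retains_all(self):
        table = pd.DataFrame(
            [_gwas_row(f"rs{i}", "A", "G", 0.1, p=1e-9 * (i + 1), bp=i)
             for i in range(5)]
        )
        ld = pd.DataFrame(np.eye(5), index=table["SNP"], columns=table["SNP"])
        assert sorted(ld_clump(table, ld)) == sorted(table["SNP"])

    def test_stronger_pvalue_dominates_correlated_pair(self):
        table = pd.DataFrame(
            [
                _gwas_row("rs1", "A", "G", 0.1, p=1e-10, bp=1000),
                _gwas_row("rs2", "A", "G", 0.1, p=1e-9, bp=2000),
            ]
        )
        r = np.sqrt(0.5)
        ld = pd.DataFrame(
            [[1.0, r], [r, 1.0]], index=["rs1", "rs2"], columns=["rs1", "rs2"]
        )
        assert ld_clump(table, ld) == ["rs1"]

    def test_ten_snp_block_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        table = pd.DataFrame(
            [
                _gwas_row(f"rs{i}", "A", "G", 0.1, p=float(rng.uniform(1e-12, 1e-8)),
                          bp=int(i * 1e5))
                for i in range(10)
            ]
        )
        ld_arr = make_ld_matrix(10, "block", rho=0.6, block_size=5)
        ld = pd.DataFrame(ld_arr, index=table["SNP"], columns=table["SNP"])
        got = ld_clump(table, ld, r2_threshold=0.1)
        expected = _brute_force_clump(table, ld, 0.1, 10_000)
        assert got == expected
        # post-hoc invariant: accepted set pairwise r2 below threshold in window
        for i, a in enumerate(got):
            for b in got[i + 1 :]:
                assert float(ld.loc[a, b]) ** 2 <= 0.1

    def test_missing_snp_in_ld_matrix_is_named(self):
        table = pd.DataFrame([_gwas_row("rsX", "A", "G", 0.1)])
        ld = pd.DataFrame([[1.0]], index=["rs1"], columns=["rs1"])
        with pytest.raises(ValueError, match="rsX"):
            ld_clump(table, ld)

    def test_cross_chromosome_pairs_never_clumped(self):
        table = pd.DataFrame(
            [
                _gwas_row("rs1", "A", "G", 0.1, p=1e-10, bp=1000, chrom="1"),
                _gwas_row("rs2", "A", "G", 0.1, p=1e-9, bp=1000, chrom="2"),
            ]
        )
        ld = pd.DataFrame(
            [[1.0, 0.99], [0.99, 1.0]], index=["rs1", "rs2"], columns=["rs1", "rs2"]
        )
        assert sorted(ld_clump(table, ld)) == ["rs1", "rs2"]


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        exp = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.1, eaf=0.3)])
        out = pd.DataFrame([_gwas_row("rs1", "G", "A", 0.3, eaf=0.7)])
        harmonized, _ = harmonize(exp, out)
        assert harmonized["beta_out"].iloc[0] == pytest.approx(-0.3)
        assert harmonized["flipped"].iloc[0]

    def test_palindromic_intermediate_eaf_dropped(self):
        exp = pd.DataFrame([_gwas_row("rs1", "A", "T", 0.1, eaf=0.50)])
        out = pd.DataFrame([_gwas_row("rs1", "A", "T", 0.2, eaf=0.50)])
        harmonized, dropped = harmonize(exp, out)
        assert harmonized.empty
        assert dropped["reason"].iloc[0] == "palindromic_ambiguous"

    def test_palindromic_extreme_eaf_retained(self):
        exp = pd.DataFrame([_gwas_row("rs1", "C", "G", 0.1, eaf=0.10)])
        out = pd.DataFrame([_gwas_row("rs1", "C", "G", 0.2, eaf=0.10)])
        harmonized, _ = harmonize(exp, out)
        assert len(harmonized) == 1

    def test_twenty_snp_fixture_matches_hand_oracle(self):
        """3 swapped pairs sign-flip, ambiguous palindrome (eaf .45) drops,
        extreme palindrome (eaf .10) stays: 19 of 20 retained."""
        exp_rows, out_rows = [], []
        for i in range(20):
            snp = f"rs{i}"
            if i == 0:
                exp_rows.append(_gwas_row(snp, "A", "T", 0.1, eaf=0.45))
                out_rows.append(_gwas_row(snp, "A", "T", 0.2, eaf=0.45))
            elif i == 1:
                exp_rows.append(_gwas_row(snp, "C", "G", 0.1, eaf=0.10))
                out_rows.append(_gwas_row(snp, "C", "G", 0.2, eaf=0.10))
            elif i in (2, 3, 4):
                exp_rows.append(_gwas_row(snp, "A", "G", 0.1, eaf=0.3))
                out_rows.append(_gwas_row(snp, "G", "A", 0.2, eaf=0.7))
            else:
                exp_rows.append(_gwas_row(snp, "T", "C", 0.1, eaf=0.3))
                out_rows.append(_gwas_row(snp, "T", "C", 0.2, eaf=0.3))
        harmonized, dropped = harmonize(
            pd.DataFrame(exp_rows), pd.DataFrame(out_rows)
        )
        assert len(harmonized) == 19
        assert dropped["SNP"].tolist() == ["rs0"]
        h = harmonized.set_index("SNP")
        for snp in ("rs2", "rs3", "rs4"):
            assert h.loc[snp, "beta_out"] == pytest.approx(-0.2)
        for snp in ("rs1", "rs5"):
            assert h.loc[snp, "beta_out"] == pytest.approx(0.2)

    def test_duplicate_snp_rejected(self):
        exp = pd.DataFrame(
            [_gwas_row("rs1", "A", "G", 0.1), _gwas_row("rs1", "A", "G", 0.1)]
        )
        out = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.1)])
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(exp, out)

    def test_incompatible_alleles_dropped_with_reason(self):
        exp = pd.DataFrame([_gwas_row("rs1", "A", "G", 0.1)])
        out = pd.DataFrame([_gwas_row("rs1", "T", "C", 0.1)])
        harmonized, dropped = harmonize(exp, out)
        assert harmonized.empty
        assert dropped["reason"].iloc[0] == "incompatible_alleles"

    def test_harmonization_is_idempotent(self):
        """Re-harmonizing already-aligned tables changes nothing."""
        exposure, outcome, _ = simulate_mr_pair(MRSimConfig(n_snps=30, seed=9))
        h1, _ = harmonize(exposure, outcome)
        aligned_out = exposure.copy()
        aligned_out["BETA"] = exposure["SNP"].map(
            h1.set_index("SNP")["beta_out"]
        )
        aligned_out = aligned_out[aligned_out["BETA"].notna()]
        exp_sub = exposure[exposure["SNP"].isin(h1["SNP"])]
        h2, _ = harmonize(exp_sub, aligned_out)
        assert not h2["flipped"].any()
        pd.testing.assert_series_equal(
            h1.set_index("SNP")["beta_out"].sort_index(),
            h2.set_index("SNP")["beta_out"].sort_index(),
        )


class TestMinSnps:
    @pytest.mark.parametrize(
        "n,passed,reason",
        [(4, False, "below_min_snps"), (5, True, None), (0, False, "no_harmonized_snps")],
    )
    def test_boundaries(self, n, passed, reason):
        check = check_min_snps(n)
        assert check.passed is passed
        assert check.reason == reason


class TestFStatistic:
    def test_direct_arithmetic(self):
        f = compute_f_statistic(0.01, 10000, 10)
        assert f.f_stat == pytest.approx(0.01 * 9989 / (10 * 0.99), rel=1e-12)

    def test_zero_r2_gives_zero_f(self):
        assert compute_f_statistic(0.0, 100, 2).f_stat == 0.0

    def test_weak_flag_is_strict_greater_than_ten(self):
        strong = compute_f_statistic(10.0001 * 10 / (9989 + 10.0001 * 10), 10000, 10)
        assert strong.f_stat > 10 and not strong.weak
        # construct F exactly 10: r2 such that r2*(n-k-1)/(k(1-r2)) = 10
        r2 = 10 * 10 / (9989 + 10 * 10)
        exact = compute_f_statistic(r2, 10000, 10)
        assert exact.f_stat == pytest.approx(10.0, rel=1e-12)
        assert exact.weak

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_f_statistic(1.0, 100, 2)
        with pytest.raises(ValueError):
            compute_f_statistic(0.1, 5, 10)

    def test_instrument_r2_bounded_on_simulated_data(self):
        h = simulate_harmonized(n_snps=60, beta_causal=0.1, seed=11)
        r2 = instrument_r2(h)
        assert 0.0 <= r2 < 1.0
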
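"""Instrument selection, allele harmonization, and strength metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrcausal import (
    SimulationConfig,
    bonferroni_alpha,
    build_mv_instruments,
    f_statistic,
    harmonize,
    instrument_strength,
    ivw,
    mr_power,
    select_instruments,
    simulate_two_sample,
)
from tests.conftest import gwas_table


def _ld(snps, entries):
    ld = pd.DataFrame(np.eye(len(snps)), index=snps, columns=snps)
    for a, b, r2 in entries:
        ld.loc[a, b] = ld.loc[b, a] = r2
    return ld


class TestSelectInstruments:
    def test_greedy_clumping_keeps_best_independent_snps(self):
        table = gwas_table(
            ["SNP1", "SNP2", "SNP3"], "A", "G", 0.3, [0.1, 0.1, 0.1], 0.01,
            pval=[1e-12, 1e-10, 1e-9],
        )
        ld = _ld(["SNP1", "SNP2", "SNP3"], [("SNP1", "SNP2", 0.5)])
        assert select_instruments(table, 5e-8, ld, 1e-4) == ["SNP1", "SNP3"]

    def test_vacuous_r2_threshold_keeps_all_significant(self):
        table = gwas_table(
            ["a", "b", "c"], "A", "G", 0.3, 0.1, 0.01, pval=[1e-9, 1e-10, 0.5]
        )
        ld = _ld(["a", "b", "c"], [("a", "b", 0.99)])
        assert set(select_instruments(table, 5e-8, ld, 1.0)) == {"a", "b"}

    def test_no_significant_snps_returns_empty_with_warning(self, caplog):
        table = gwas_table(["a", "b"], "A", "G", 0.3, 0.01, 0.01, pval=[0.5, 0.1])
        with caplog.at_level("WARNING"):
            assert select_instruments(table) == []
        assert "no SNP passed" in caplog.text

    def test_missing_ld_entry_names_the_snp(self):
        table = gwas_table(["a", "b"], "A", "G", 0.3, 0.1, 0.01, pval=[1e-9, 1e-10])
        ld = _ld(["a"], [])
        with pytest.raises(KeyError, match="b"):
            select_instruments(table, 5e-8, ld, 1e-4)

    def test_row_order_invariance(self):
        table = gwas_table(
            ["s1", "s2", "s3", "s4"], "A", "G", 0.3, 0.1, 0.01,
            pval=[1e-9, 1e-12, 1e-10, 1e-11],
        )
        ld = _ld(["s1", "s2", "s3", "s4"], [("s2", "s4", 0.3), ("s1", "s3", 0.2)])
        ref = select_instruments(table, 5e-8, ld, 0.1)
        for perm_seed in range(5):
            shuffled = table.sample(frac=1, random_state=perm_seed)
            assert select_instruments(shuffled, 5e-8, ld, 0.1) == ref


class TestHarmonize:
    def test_swapped_alleles_negate_beta_and_reflect_eaf(self):
        exposure = gwas_table(["rs1"], ["A"], ["G"], [0.3], [0.10], [0.01])
        outcome = gwas_table(["rs1"], ["G"], ["A"], [0.70], [-0.05], [0.01])
        hset = harmonize(exposure, outcome)
        row = hset.table.iloc[0]
        assert row.beta_outcome == pytest.approx(0.05)
        assert row.eaf_outcome == pytest.approx(0.30)
        assert row.allele_swapped and not row.strand_flipped

    def test_intermediate_frequency_palindrome_is_dropped(self):
        exposure = gwas_table(["rs1"], ["A"], ["T"], [0.50], [0.1], [0.01])
        outcome = gwas_table(["rs1"], ["A"], ["T"], [0.50], [0.05], [0.01])
        hset = harmonize(exposure, outcome)
        assert hset.n_retained == 0
        assert hset.n_dropped_palindromic == 1
        assert list(hset.dropped.reason) == ["palindromic"]

    def test_strand_flip_is_recognized_and_kept(self):
        exposure = gwas_table(["rs1"], ["A"], ["G"], [0.2], [0.10], [0.01])
        outcome = gwas_table(["rs1"], ["T"], ["C"], [0.2], [0.07], [0.01])
        hset = harmonize(exposure, outcome)
        row = hset.table.iloc[0]
        assert row.beta_outcome == pytest.approx(0.07)
        assert row.strand_flipped and not row.allele_swapped

    def test_palindrome_outside_window_aligned_by_frequency(self):
        exposure = gwas_table(["rs1"], ["A"], ["T"], [0.10], [0.1], [0.01])
        outcome = gwas_table(["rs1"], ["A"], ["T"], [0.88], [0.05], [0.01])
        hset = harmonize(exposure, outcome)
        row = hset.table.iloc[0]
        assert row.beta_outcome == pytest.approx(-0.05)
        assert row.eaf_outcome == pytest.approx(0.12)
        assert row.allele_swapped

    def test_irreconcilable_alleles_dropped_as_unmatched(self):
        exposure = gwas_table(["rs1"], ["A"], ["G"], [0.3], [0.1], [0.01])
        outcome = gwas_table(["rs1"], ["A"], ["C"], [0.3], [0.1], [0.01])
        hset = harmonize(exposure, outcome)
        assert hset.n_retained == 0 and hset.n_unmatched == 1

    def test_duplicate_identifiers_raise(self):
        table = gwas_table(["rs1", "rs1"], "A", "G", 0.3, 0.1, 0.01)
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(table, gwas_table(["rs1"], "A", "G", 0.3, 0.1, 0.01))

    def test_attrition_identity(self):
        cfg = SimulationConfig(n_snps=60, theta=0.2, palindromic_fraction=0.3,
                               flip_fraction=0.4, maf_range=(0.3, 0.5), seed=21)
        exposure, outcome, _ = simulate_two_sample(cfg)
        hset = harmonize(exposure, outcome)
        assert hset.n_retained == hset.n_input - hset.n_dropped_palindromic - hset.n_unmatched

    def test_harmonization_is_idempotent(self):
        cfg = SimulationConfig(n_snps=40, theta=0.2, palindromic_fraction=0.2,
                               flip_fraction=0.5, maf_range=(0.1, 0.5), seed=17)
        exposure, outcome, _ = simulate_two_sample(cfg)
        first = harmonize(exposure, outcome)
        # rebuild an outcome table already in exposure coding
        rebuilt = first.table.rename(
            columns={
                "beta_outcome": "beta",
                "se_outcome": "se",
                "eaf_outcome": "eaf",
            }
        )[["snp", "effect_allele", "other_allele", "eaf", "beta", "se"]].copy()
        rebuilt["pval"] = 0.5
        rebuilt["n"] = 1000
        exposure_kept = exposure[exposure.snp.isin(first.table.snp)]
        second = harmonize(exposure_kept, rebuilt)
        np.testing.assert_allclose(second.table.beta_outcome, first.table.beta_outcome)
        assert not second.table.allele_swapped.any()
        assert second.n_dropped_palindromic == 0 and second.n_unmatched == 0


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_outcome_coding_flip_leaves_estimates_unchanged(seed):
    """Recoding every outcome record (swap alleles, negate beta, reflect EAF)
    must leave downstream causal estimates identical to machine precision."""
    cfg = SimulationConfig(n_snps=12, theta=0.25, seed=seed)
    exposure, outcome, _ = simulate_two_sample(cfg)
    flipped = outcome.copy()
    flipped["effect_allele"], flipped["other_allele"] = (
        outcome["other_allele"],
        outcome["effect_allele"],
    )
    flipped["beta"] = -outcome["beta"]
    flipped["eaf"] = 1 - outcome["eaf"]
    a = ivw(harmonize(exposure, outcome))[0]
    b = ivw(harmonize(exposure, flipped))[0]
    assert abs(a.beta - b.beta) < 1e-12
    assert abs(a.se - b.se) < 1e-12


class TestMvInstruments:
    @staticmethod
    def _panel():
        """34 distinct SNPs: 7/8/14 unique to x1/x2/x3, 5 shared by two
        traits, 6 palindromic with intermediate frequency."""
        rng = np.random.default_rng(0)
        n = 34
        snps = [f"rs{i}" for i in range(n)]
        sig_sets = {
            "x1": set(range(0, 7)) | {29, 30, 33},
            "x2": set(range(7, 15)) | {29, 31, 32},
            "x3": set(range(15, 29)) | {30, 31, 32, 33},
        }
        # rs29..rs33 are the 5 cross-trait duplicates; last 6 SNPs palindromic
        ea = ["A"] * 28 + ["A"] * 6
        oa = ["G"] * 28 + ["T"] * 6
        eaf = [0.3] * 28 + [0.5] * 6
        tables = {}
        for name, sig in sig_sets.items():
            beta = np.where([i in sig for i in range(n)], 0.1, 0.01)
            pval = np.array(
                [rng.uniform(1e-12, 1e-9) if i in sig else 0.5 for i in range(n)]
            )
            tables[name] = gwas_table(snps, ea, oa, eaf, beta, 0.01, pval=pval)
        outcome = gwas_table(snps, ea, oa, eaf, rng.normal(0, 0.01, n), 0.01)
        return tables, outcome

    def test_union_dedup_and_palindrome_arithmetic(self):
        tables, outcome = self._panel()
        mv = build_mv_instruments(tables, outcome)
        assert mv.n_union == 7 + 8 + 14 + 2 * 5  # pooled per-exposure lists
        assert mv.n_duplicates_removed == 5
        assert mv.n_dropped_palindromic == 6
        assert mv.n_retained == 28

    def test_lowest_p_occurrence_wins(self):
        x1 = gwas_table(["s1", "s2"], "A", "G", 0.3, 0.1, 0.01, pval=[1e-12, 1e-9])
        x2 = gwas_table(["s1", "s2"], "A", "G", 0.3, 0.2, 0.01, pval=[1e-9, 1e-12])
        outcome = gwas_table(["s1", "s2"], "A", "G", 0.3, 0.01, 0.01)
        mv = build_mv_instruments({"x1": x1, "x2": x2}, outcome)
        assert mv.source["s1"] == "x1"
        assert mv.source["s2"] == "x2"
        assert mv.beta_source["s1"] == pytest.approx(0.1)
        assert mv.beta_source["s2"] == pytest.approx(0.2)

    def test_significance_matrix_flags_per_exposure(self):
        tables, outcome = self._panel()
        mv = build_mv_instruments(tables, outcome)
        assert (mv.significant.sum(axis=1) >= 1).all()
        assert mv.significant.loc["rs0", "x1"] and not mv.significant.loc["rs0", "x2"]

    def test_fewer_than_two_exposures_rejected(self):
        tables, outcome = self._panel()
        with pytest.raises(ValueError, match=">= 2 exposures"):
            build_mv_instruments({"x1": tables["x1"]}, outcome)


class TestStrengthAndPower:
    def test_single_snp_r2_formula(self):
        from mrcausal import HarmonizedSet

        hset = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.01], eaf=0.5)
        strength = instrument_strength(hset, 10_000)
        assert strength.r2 == pytest.approx(2 * 0.25 * 0.01)
        assert strength.per_snp_r2.iloc[0] == pytest.approx(0.005)

    def test_f_increases_with_r2(self):
        fs = [f_statistic(r2, 50_000) for r2 in np.linspace(0.001, 0.3, 20)]
        assert all(b > a for a, b in zip(fs, fs[1:]))

    def test_null_betas_give_zero_strength(self):
        from mrcausal import HarmonizedSet

        hset = HarmonizedSet.from_arrays([0.0, 0.0], [0.01], [0.0, 0.0], [0.01])
        strength = instrument_strength(hset, 1000)
        assert strength.r2 == 0.0 and strength.f_stat == 0.0

    def test_degenerate_r2_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 1000)

    def test_power_at_null_equals_alpha(self):
        assert mr_power(100_000, 0.02, 1.0, alpha=0.05, binary=True,
                        case_fraction=0.1) == pytest.approx(0.05, abs=1e-9)
        assert mr_power(100_000, 0.0, 0.3, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_power_monotone_in_n_and_r2(self):
        # effect chosen so power stays clear of the saturation plateau at 1
        grid_n = [mr_power(n, 0.02, 0.05) for n in np.linspace(1000, 500_000, 20)]
        grid_r2 = [mr_power(100_000, r, 0.05) for r in np.linspace(0.001, 0.1, 20)]
        assert all(b > a for a, b in zip(grid_n, grid_n[1:]))
        assert all(b > a for a, b in zip(grid_r2, grid_r2[1:]))

    def test_binary_power_requires_case_fraction(self):
        with pytest.raises(ValueError, match="case_fraction"):
            mr_power(100_000, 0.02, 1.2, binary=True)


@pytest.mark.parametrize(
    "family,n,expected",
    [(0.05, 3, 0.017), (0.05, 1, 0.05), (0.05, 5, 0.01)],
)
def test_bonferroni_alpha_reported_at_three_decimals(family, n, expected):
    assert round(bonferroni_alpha(family, n), 3) == expected
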
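"""Homozygote-group t-tests, conditional association, segregation, correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tbscan.assoc import (
    AssociationStudy,
    ConditionSpec,
    association_table,
    conditional_association,
    homozygote_groups,
    load_panel_tables,
    pearson_correlation_test,
    segregation_test,
    t_test_association,
)
from tbscan.errors import DataError, EmptyInputError, InvalidParameterError
from tbscan.synthetic import CrossConfig, PhenotypeModel, simulate_phenotypes


class TestGrouping:
    def test_heterozygotes_and_missing_excluded(self):
        split = homozygote_groups([0, 0, 2, 2, 1, -1])
        assert len(split.idx_low) == 2 and len(split.idx_high) == 2
        assert split.n_het == 1 and split.n_missing == 1
        assert split.testable

    def test_single_minor_homozygote_among_130_flagged_rare(self):
        calls = np.zeros(130, dtype=int)
        calls[0] = 2
        split = homozygote_groups(calls)
        assert split.rare and not split.testable

    def test_monomorphic_site_untestable(self):
        split = homozygote_groups([0, 0, 0, 0])
        assert not split.testable


class TestTTest:
    def test_identical_groups_null_result(self):
        res = t_test_association([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert res.t == 0.0 and res.p == 1.0 and res.effect_size == 0.0

    def test_frozen_textbook_example(self):
        """Pooled t for {10,12,14} vs {20,22,24}: -6.1237 on 4 df (verified
        against scipy.stats.ttest_ind)."""
        res = t_test_association([10, 12, 14], [20, 22, 24])
        oracle = stats.ttest_ind([10, 12, 14], [20, 22, 24])
        assert res.t == pytest.approx(-6.123724, abs=1e-6)
        assert res.t == pytest.approx(oracle.statistic, rel=1e-12)
        assert res.p == pytest.approx(oracle.pvalue, rel=1e-12)
        assert res.df == 4

    def test_random_groups_match_scipy_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = rng.normal(10, 3, rng.integers(2, 40))
            b = rng.normal(11, 3, rng.integers(2, 40))
            res = t_test_association(a, b)
            oracle = stats.ttest_ind(a, b)
            assert res.t == pytest.approx(oracle.statistic, rel=1e-10)
            assert res.p == pytest.approx(oracle.pvalue, rel=1e-10)

    def test_effect_size_and_mean_value_difference_definitions(self):
        res = t_test_association([10.0, 10.0], [12.0, 12.0])
        assert res.effect_size == pytest.approx(2.0)
        assert res.mean_value_difference == pytest.approx(20.0)

    def test_zero_variance_unequal_means_floors_p(self):
        res = t_test_association([1.0, 1.0], [2.0, 2.0])
        assert res.p > 0 and res.p < 1e-300
        assert "zero_variance" in res.flags

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        r1 = t_test_association(a, b)
        r2 = t_test_association(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)
        assert r1.effect_size == pytest.approx(r2.effect_size)
        assert r1.mean_value_difference == pytest.approx(r2.mean_value_difference)

    def test_type_one_error_calibrated(self):
        """Null rejection rate near 5% (exact t null under normality)."""
        rng = np.random.default_rng(3)
        reps = 400
        hits = sum(
            t_test_association(rng.normal(0, 1, 25), rng.normal(0, 1, 25)).p < 0.05
            for _ in range(reps)
        )
        rate = hits / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_tiny_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            t_test_association([1.0], [2.0, 3.0])


class TestConditional:
    def _two_locus_panel(self, n, r, seed):
        config = CrossConfig("NIL_F2", n, loci=[("indel1", 100), ("snp3", 200)],
                             recomb_fraction_between_adjacent=r)
        m = config.simulate(seed=seed)
        return m.to_frame(site_ids=["indel1", "snp3"])

    def test_bookkeeping_of_subset_sizes(self):
        geno = self._two_locus_panel(600, 0.5, seed=4)
        values = np.random.default_rng(5).normal(10, 2, 600)
        res = conditional_association(geno["indel1"].to_numpy(),
                                      geno["snp3"].to_numpy(), 2, values)
        assert res is not None
        assert res.n1 >= 2 and res.n2 >= 2
        assert res.n1 + res.n2 <= (geno["snp3"] == 2).sum()

    def test_linkage_confounding_attenuated_by_conditioning(self):
        """A locus with no direct effect looks associated through linkage; the
        conditional effect is attenuated relative to the marginal one."""
        rng = np.random.default_rng(6)
        attenuated = 0
        reps = 30
        for s in range(reps):
            # r = 0.35 keeps both conditional homozygote classes populated
            geno = self._two_locus_panel(800, 0.35, seed=rng)
            # only snp3 is causal
            model = PhenotypeModel(additive_effects={"snp3": {40: 0.0, 50: 1.5}},
                                   plants_per_line=4)
            ph = simulate_phenotypes(geno, model, seed=rng)
            v = ph[ph.timepoint == 50].set_index("line_id")["value"].loc[geno.index]
            split = homozygote_groups(geno["indel1"].to_numpy())
            marginal = t_test_association(v.to_numpy()[split.idx_low],
                                          v.to_numpy()[split.idx_high])
            cond = conditional_association(geno["indel1"].to_numpy(),
                                           geno["snp3"].to_numpy(), 2,
                                           v.to_numpy())
            if cond is not None and cond.effect_size < marginal.effect_size:
                attenuated += 1
        assert attenuated / reps >= 0.9

    def test_absent_conditioning_genotype_returns_none(self):
        calls = np.array([0, 0, 1, 1])
        res = conditional_association(calls, np.array([0, 0, 1, 1]), 2,
                                      np.array([1.0, 2.0, 3.0, 4.0]))
        assert res is None


class TestSegregation:
    def test_ril_indel_counts_against_one_to_one(self):
        """Distorted RIL counts 32:96 vs 1:1 give chi-square exactly 32."""
        res = segregation_test([32, 96], [1, 1])
        assert res.chi2 == pytest.approx(32.0, abs=1e-12)
        assert res.df == 1

    def test_f2_snp3_counts_against_mendelian(self):
        """F2 counts 135:256:60 vs 1:2:1 give chi-square ~33.19 on 2 df."""
        res = segregation_test([135, 256, 60], [1, 2, 1])
        assert res.chi2 == pytest.approx(33.19, abs=0.01)
        assert res.df == 2

    def test_counts_at_expectation_give_null(self):
        res = segregation_test([25, 50, 25], [1, 2, 1])
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_matches_scipy_chisquare_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            obs = rng.integers(1, 200, 3)
            res = segregation_test(obs, [1, 2, 1])
            exp = np.array([1, 2, 1]) / 4 * obs.sum()
            oracle = stats.chisquare(obs, exp)
            assert res.chi2 == pytest.approx(oracle.statistic, rel=1e-12)
            assert res.p == pytest.approx(oracle.pvalue, rel=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(EmptyInputError):
            segregation_test([0, 0], [1, 1])


class TestPearson:
    def test_exact_line_gives_r_one(self):
        x = np.arange(10.0)
        res = pearson_correlation_test(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_hand_dataset_matches_scipy_oracle(self):
        x = [1.0, 2.0, 4.0, 5.0, 8.0]
        y = [2.0, 3.0, 3.5, 6.0, 7.5]
        res = pearson_correlation_test(x, y)
        r, p = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_null_calibration_at_paper_sample_size(self):
        """Independent x, y with n=39 lines: rejection rate ~5%."""
        rng = np.random.default_rng(8)
        reps = 500
        hits = sum(pearson_correlation_test(rng.normal(size=39),
                                            rng.normal(size=39)).p < 0.05
                   for _ in range(reps))
        rate = hits / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_zero_variance_flagged(self):
        res = pearson_correlation_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.r) and "zero_variance" in res.flags


class TestAssociationTable:
    def _panel(self, n=120, seed=9):
        rng = np.random.default_rng(seed)
        geno = pd.DataFrame({
            "indel1": rng.integers(0, 3, n),
            "snp3": rng.integers(0, 3, n),
        }, index=[f"L{i}" for i in range(n)])
        model = PhenotypeModel(additive_effects={"snp3": {40: 0.4, 50: 1.4}})
        pheno = simulate_phenotypes(geno, model, seed=rng)
        return pheno, geno

    def test_two_sites_two_timepoints_four_rows(self):
        pheno, geno = self._panel()
        table = association_table(pheno, geno)
        assert len(table) == 4
        assert set(table["timepoint"]) == {40, 50}

    def test_direction_column_tracks_larger_mean(self):
        pheno, geno = self._panel(n=400, seed=10)
        table = association_table(pheno, geno, sites=["snp3"])
        row = table[table.timepoint == 50].iloc[0]
        assert row["direction"].endswith("high")  # derived allele adds tillers

    def test_conditioning_plan_shapes_table(self):
        pheno, geno = self._panel(n=300, seed=11)
        conditions = [
            ConditionSpec("indel1", "snp3", 2),
            ConditionSpec("snp3", "indel1", 2),
        ]
        table = association_table(pheno, geno, conditions=conditions)
        assert len(table) == 4
        assert set(table["condition"]) == {"snp3=2", "indel1=2"}

    def test_identifier_mismatch_raises_with_orphans(self):
        pheno, geno = self._panel()
        bad = geno.copy()
        bad.index = [f"X{i}" for i in range(len(bad))]
        with pytest.raises(DataError, match="orphans"):
            association_table(pheno, bad)

    def test_effect_recovery_within_tolerance(self):
        """Programmed homozygote contrast is recovered by the full table path."""
        rng = np.random.default_rng(12)
        hits = 0
        reps = 40
        for _ in range(reps):
            geno = pd.DataFrame({"snp3": np.repeat([0, 2], [60, 135])},
                                index=[f"L{i}" for i in range(195)])
            model = PhenotypeModel(additive_effects={"snp3": {40: 0.235, 50: 1.385}})
            pheno = simulate_phenotypes(geno, model, seed=rng)
            table = association_table(pheno, geno)
            est = table[table.timepoint == 50]["effect_size"].iloc[0]
            hits += abs(est - 2.77) < 0.6
        assert hits / reps >= 0.9

    def test_study_object_end_to_end(self):
        pheno, geno = self._panel(n=200, seed=13)
        study = AssociationStudy(pheno, geno)
        res = study.fit()
        assert "Association summary" in res.summary()
        seg = study.segregation("snp3")
        assert seg.df == 2 and seg.p > 0


class TestPanelLoader:
    def test_genotype_strings_and_tiller_columns(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            "line_id\tsnp3\ttiller_40\ttiller_50\n"
            "L1\tTT\t6.0\t12.5\n"
            "L2\tTC\t6.5\t13.0\n"
            "L3\tCC\t5.0\t10.0\n"
            "L4\tNN\t5.5\t\n"
        )
        pheno, geno = load_panel_tables(p)
        assert list(geno["snp3"]) == [2, 1, 0, -1]
        assert len(pheno) == 7  # one missing tiller value dropped
        assert set(pheno["timepoint"]) == {40, 50}
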
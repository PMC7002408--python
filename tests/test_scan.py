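"""FST, windows, branch lengths, PBS, the HKA-style contrast, candidate calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tbscan.errors import (
    ConfigurationError,
    EmptyInputError,
    InvalidParameterError,
    UndefinedTestError,
)
from tbscan.io import GeneAnnotation
from tbscan.scan import (
    ScanThresholds,
    SelectionScan,
    branch_length_T,
    gene_fst_and_counts,
    hka_test,
    nei_fst,
    pbs_score,
    site_fst,
    sweep_candidates,
    top_quantile_threshold,
    window_fst,
    window_starts,
)

from conftest import make_matrix, tiled_genes

# frequencies on a 1e-6 grid: avoids float cancellation at the extremes,
# which would otherwise dominate the relabel-invariance comparison
unit = st.integers(0, 10**6).map(lambda k: k / 10**6)


class TestSiteFst:
    @pytest.mark.parametrize("p1,p2,expected", [
        (0.5, 0.5, 0.0),          # identical populations
        (1.0, 0.0, 1.0),          # fixed difference
        (0.2, 0.8, 0.36),         # hand evaluation: HT=0.5, HS=0.32
    ])
    def test_worked_examples(self, p1, p2, expected):
        res = site_fst(p1, p2)
        assert res.fst == pytest.approx(expected, abs=1e-12)

    def test_hand_example_intermediates(self):
        res = site_fst(0.2, 0.8)
        assert res.HT == pytest.approx(0.5)
        assert res.HS == pytest.approx(0.32)

    def test_monomorphic_site_is_zero_and_flagged(self):
        res = site_fst(0.0, 0.0)
        assert res.fst == 0.0 and not res.segregating

    @given(p1=unit, p2=unit)
    @settings(max_examples=200, deadline=None)
    def test_symmetric_bounded_and_allele_relabel_invariant(self, p1, p2):
        a = nei_fst(p1, p2)
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(nei_fst(p2, p1), abs=1e-9)
        assert a == pytest.approx(nei_fst(1 - p1, 1 - p2), abs=1e-9)

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(InvalidParameterError):
            nei_fst(-0.1, 0.5)


class TestWindows:
    def test_mean_of_snps_in_window(self):
        win = window_fst([100, 200, 300], [0.1, 0.2, 0.3], 20_000)
        assert len(win) == 1
        assert win["mean_fst"].iloc[0] == pytest.approx(0.2)
        assert win["n_snps"].iloc[0] == 3

    def test_window_count_floor_formula(self):
        # floor((L - w)/s) + 1 = floor(80000/2000) + 1 = 41
        assert len(window_starts(100_000, 20_000, 2_000)) == 41

    def test_snp_membership_enumeration(self):
        """A SNP at 10,500 falls in exactly the 6 windows starting 0..10000."""
        win = window_fst([10_500], [0.5], 100_000)
        hit = win[win["n_snps"] == 1]
        expected_starts = [s for s in range(0, 100_000 - 20_000 + 1, 2_000)
                           if s <= 10_500 < s + 20_000]
        assert list(hit["start"]) == expected_starts == [0, 2000, 4000, 6000, 8000, 10000]

    def test_empty_windows_reported_without_value(self):
        win = window_fst([50_000], [0.4], 100_000)
        empty = win[win["n_snps"] == 0]
        assert len(empty) == len(win) - (20_000 // 2_000)
        assert empty["mean_fst"].isna().all()

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ConfigurationError):
            window_fst([100], [0.1], 100_000, window=1_000, step=2_000)

    def test_scan_conserves_snps(self):
        rng = np.random.default_rng(1)
        L, w, s = 100_000, 20_000, 2_000
        pos = np.sort(rng.choice(L - w + s - 1, 300, replace=False)) + 1
        win = window_fst(pos, np.ones(300), L, w, s)
        # every SNP below L-w+s appears in >= 1 and <= w/s windows
        per_snp = [(win["start"] <= p) & (p < win["end"]) for p in pos]
        counts = np.array([m.sum() for m in per_snp])
        assert counts.min() >= 1 and counts.max() <= w // s
        assert win["n_snps"].sum() == counts.sum()


class TestTopQuantile:
    def test_five_per_mille_of_1000_flags_the_five_largest(self):
        values = np.arange(1, 1001, dtype=float)
        thr, flags = top_quantile_threshold(values, 0.005)
        assert set(values[flags]) == {996, 997, 998, 999, 1000}

    def test_all_equal_all_flagged(self):
        _, flags = top_quantile_threshold([2.0, 2.0, 2.0], 0.25)
        assert flags.all()

    def test_median_threshold_on_pair(self):
        thr, flags = top_quantile_threshold([1.0, 2.0], 0.5)
        assert thr == pytest.approx(1.5)
        assert list(flags) == [False, True]

    def test_all_missing_rejected(self):
        with pytest.raises(EmptyInputError):
            top_quantile_threshold([np.nan, np.nan], 0.05)


class TestBranchAndPbs:
    def test_transform_examples(self):
        assert branch_length_T(0.0) == 0.0
        assert branch_length_T(0.36) == pytest.approx(-np.log(0.64), abs=1e-9)
        assert branch_length_T(0.36) == pytest.approx(0.44629, abs=1e-5)
        assert branch_length_T(0.5) > branch_length_T(0.4)

    def test_fst_one_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            t = branch_length_T(1.0)
        assert np.isfinite(t) and t > 20

    def test_pbs_examples(self):
        t = 0.3
        assert pbs_score(t, t, t) == pytest.approx(t / 2)
        assert pbs_score(0.44629, 0.44629, 0.0) == pytest.approx(0.44629)
        assert pbs_score(0.0, 0.0, 1.0) == pytest.approx(-0.5)

    def test_paper_mode_sums_all_branches(self):
        assert pbs_score(0.1, 0.2, 0.3, mode="paper") == pytest.approx(0.3)

    @given(t12=st.floats(0, 5), t13=st.floats(0, 5), t23=st.floats(0, 5))
    @settings(max_examples=100, deadline=None)
    def test_standard_pbs_invariant_under_swapping_pops_2_and_3(self, t12, t13, t23):
        assert pbs_score(t12, t13, t23) == pytest.approx(pbs_score(t13, t12, t23))

    def test_negative_branch_rejected(self):
        with pytest.raises(InvalidParameterError):
            pbs_score(-0.1, 0.2, 0.3)


def calls_for_freqs(p, n_dip):
    """Deterministic diploid calls whose sample ALT frequency is exactly p."""
    n_chrom = 2 * n_dip
    k = int(round(p * n_chrom))
    dosages = [2] * (k // 2) + [1] * (k % 2)
    dosages += [0] * (n_dip - len(dosages))
    return dosages


class TestGeneCounts:
    def _matrix(self, freqs, positions):
        """freqs: list of (p_target, p_sister, p_third) per site; 5 diploids each."""
        calls = []
        for pt, ps, px in freqs:
            calls.append(calls_for_freqs(pt, 5) + calls_for_freqs(ps, 5)
                         + calls_for_freqs(px, 5))
        pops = ["t"] * 5 + ["s"] * 5 + ["x"] * 5
        return make_matrix(np.array(calls), positions=positions, pops=pops)

    def test_fixed_difference_counts_as_B_not_A(self):
        m = self._matrix([(1.0, 0.0, 0.0)] * 4, positions=[10, 20, 30, 40])
        genes = [GeneAnnotation("g", "chr09", [(1, 100)])]
        df = gene_fst_and_counts(m, genes, ("t", "s", "x"))
        assert df.loc[0, "B"] == 4 and df.loc[0, "A"] == 0

    def test_fixation_requires_both_comparisons(self):
        # high FST vs sister but intermediate vs third: not fixed
        m = self._matrix([(1.0, 0.0, 0.5)], positions=[10])
        genes = [GeneAnnotation("g", "chr09", [(1, 100)])]
        df = gene_fst_and_counts(m, genes, ("t", "s", "x"))
        assert df.loc[0, "B"] == 0

    def test_counts_match_brute_force_site_oracle(self):
        rng = np.random.default_rng(8)
        n_sites = 120
        freqs = [(rng.choice([0, 0.2, 0.5, 0.9, 1.0]),
                  rng.choice([0, 0.1, 0.5, 1.0]),
                  rng.choice([0, 0.5, 1.0])) for _ in range(n_sites)]
        positions = np.arange(1, n_sites + 1) * 50
        m = self._matrix(freqs, positions)
        genes = [GeneAnnotation(f"g{i}", "chr09", [(1 + i * 1000, (i + 1) * 1000)])
                 for i in range(6)]
        df = gene_fst_and_counts(m, genes, ("t", "s", "x")).set_index("gene_id")
        # brute-force oracle: per-site loop with scalar formulas
        pt, ps, px = m.alt_freq("t"), m.alt_freq("s"), m.alt_freq("x")
        for g in genes:
            A = B = 0
            for i, pos in enumerate(positions):
                if any(s <= pos <= e for s, e in g.intervals):
                    is_fixed = (site_fst(pt[i], ps[i]).fst > 0.9
                                and site_fst(pt[i], px[i]).fst > 0.9)
                    if is_fixed:
                        B += 1
                    elif 0 < pt[i] < 1:
                        A += 1
            assert df.loc[g.gene_id, "A"] == A
            assert df.loc[g.gene_id, "B"] == B

    def test_gene_without_coding_snps_reports_zero_counts(self):
        m = self._matrix([(0.5, 0.5, 0.5)], positions=[5_000])
        genes = [GeneAnnotation("empty", "chr09", [(1, 100)])]
        df = gene_fst_and_counts(m, genes, ("t", "s", "x"))
        assert df.loc[0, "A"] == 0 and df.loc[0, "B"] == 0
        assert np.isnan(df.loc[0, "fst12"])


class TestHka:
    def test_null_table_gives_chi2_zero(self):
        res = hka_test(10, 5, 1000, 500)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_matches_contingency_oracle(self):
        res = hka_test(10, 5, 1000, 50)
        chi2, p = stats.chi2_contingency([[10, 5], [990, 45]], correction=False)[:2]
        assert res.chi2 == pytest.approx(chi2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ag, bg = rng.integers(1, 40, 2)
            at, bt = ag + rng.integers(1, 400), bg + rng.integers(1, 400)
            res = hka_test(ag, bg, at, bt)
            chi2, p = stats.chi2_contingency(
                [[ag, bg], [at - ag, bt - bg]], correction=False)[:2]
            assert res.chi2 == pytest.approx(chi2, rel=1e-10)
            assert res.p == pytest.approx(p, rel=1e-10)

    def test_doubling_cells_doubles_chi2(self):
        a = hka_test(10, 5, 1000, 50)
        b = hka_test(20, 10, 2000, 100)
        assert b.chi2 == pytest.approx(2 * a.chi2, rel=1e-12)

    def test_zero_margin_is_undefined(self):
        with pytest.raises(UndefinedTestError):
            hka_test(10, 0, 1000, 0)

    def test_low_expected_cell_flagged(self):
        assert hka_test(1, 1, 2000, 2).low_count


class TestCandidates:
    def _stats_df(self, pbs, hka_p):
        import pandas as pd
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(pbs))],
                             "pbs": pbs, "hka_p": hka_p})

    def test_exchangeable_genes_all_or_none(self):
        df = self._stats_df([0.5] * 30, [0.01] * 30)
        out = sweep_candidates(df, ScanThresholds())
        assert len(out) in (0, 30)
        assert len(out) == 30  # all tie at the threshold, all significant

    def test_tiny_alpha_empties_the_list(self):
        rng = np.random.default_rng(0)
        df = self._stats_df(rng.random(40), rng.random(40))
        out = sweep_candidates(df, ScanThresholds(hka_alpha=5e-324))
        assert len(out) == 0

    def test_implanted_sweep_is_called(self, swept_matrix):
        genes = tiled_genes(800_000)
        res = SelectionScan(swept_matrix, genes,
                            ("upland_jap", "irrigated_jap", "indica")).fit(
                                chrom_length=800_000)
        swept_ids = {g.gene_id for g in genes
                     if abs((g.span[0] + g.span[1]) / 2 - 400_000) < 15_000}
        assert swept_ids & set(res.candidates["gene_id"])

    def test_sorted_by_pbs_descending(self):
        rng = np.random.default_rng(5)
        df = self._stats_df(rng.random(50), np.full(50, 0.001))
        out = sweep_candidates(df, ScanThresholds(pbs_quantile=0.2))
        assert list(out["pbs"]) == sorted(out["pbs"], reverse=True)


class TestModelSurface:
    def test_summary_mentions_candidates_and_threshold(self, swept_matrix):
        res = SelectionScan(swept_matrix, tiled_genes(800_000),
                            ("upland_jap", "irrigated_jap", "indica")).fit(
                                chrom_length=800_000)
        text = res.summary()
        assert "sweep candidates" in text and "windows" in text

    def test_unknown_population_rejected(self, neutral_matrix):
        with pytest.raises(ConfigurationError):
            SelectionScan(neutral_matrix, None, ("a", "b", "c"))
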
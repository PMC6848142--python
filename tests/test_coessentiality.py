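"""Guide-pair correlations, NTC-resampling empirical FDR, Pearson test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coessence.coessentiality import (
    depletion_vs_ntc,
    empirical_fdr,
    gene_gene_correlation,
    guide_pair_correlations,
    ntc_pair_pool,
    pearson_test,
)
from coessence.screen_io import GuideLibrary


def brute_force_pearson(x, y):
    """Two-pass textbook Pearson: sum of centered products over (n-1)*sx*sy."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xm, ym = x.mean(), y.mean()
    sx = np.sqrt(np.sum((x - xm) ** 2) / (n - 1))
    sy = np.sqrt(np.sum((y - ym) ** 2) / (n - 1))
    return np.sum((x - xm) * (y - ym)) / ((n - 1) * sx * sy)


def _lib(spec):
    rows, seqs = [], []
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    for gene, n in spec.items():
        for i in range(n):
            rows.append((f"{gene}_{i}", gene))
            seqs.append("".join(rng.choice(bases, 20)))
    df = pd.DataFrame(rows, columns=["guide_id", "gene"])
    df["sequence"] = seqs
    return GuideLibrary(records=df)


class TestGuidePairCorrelations:
    def test_identical_profiles_correlate_perfectly(self):
        lib = _lib({"GA": 1, "GB": 1, "NTC": 2})
        prof = np.sin(np.arange(5.0))
        dep = pd.DataFrame(
            [prof, prof, prof * 0 + np.arange(5), np.random.default_rng(0).normal(size=5)],
            index=lib.guide_ids, columns=list("abcde"),
        )
        rs = guide_pair_correlations(dep, lib, "GA", "GB")
        assert rs.tolist() == pytest.approx([1.0])

    def test_negated_profiles_anticorrelate(self):
        lib = _lib({"GA": 1, "GB": 1, "NTC": 2})
        prof = np.array([0.1, -2.0, 1.3, 0.7, -0.4])
        dep = pd.DataFrame(
            [prof, -prof, prof * 2, prof + 1],
            index=lib.guide_ids, columns=list("abcde"),
        )
        assert guide_pair_correlations(dep, lib, "GA", "GB").tolist() == pytest.approx([-1.0])

    def test_two_by_two_pairs_match_brute_force(self):
        lib = _lib({"GA": 2, "GB": 2, "NTC": 2})
        rng = np.random.default_rng(3)
        dep = pd.DataFrame(rng.normal(size=(6, 4)), index=lib.guide_ids, columns=list("wxyz"))
        rs = guide_pair_correlations(dep, lib, "GA", "GB")
        expected = [
            brute_force_pearson(dep.loc[f"GA_{i}"], dep.loc[f"GB_{j}"])
            for i in range(2) for j in range(2)
        ]
        assert rs == pytest.approx(expected, abs=1e-12)
        assert rs.size == 4

    def test_self_pairs_excluded_for_same_gene(self):
        lib = _lib({"GA": 3, "NTC": 2})
        rng = np.random.default_rng(4)
        dep = pd.DataFrame(rng.normal(size=(5, 6)), index=lib.guide_ids)
        rs = guide_pair_correlations(dep, lib, "GA", "GA")
        assert rs.size == 3  # C(3,2), no r=1 self terms
        assert not np.any(rs == 1.0)

    def test_zero_variance_guide_dropped_with_warning(self):
        lib = _lib({"GA": 2, "GB": 1, "NTC": 2})
        rng = np.random.default_rng(5)
        dep = pd.DataFrame(rng.normal(size=(5, 5)), index=lib.guide_ids)
        dep.loc["GA_0"] = 1.0
        with pytest.warns(UserWarning, match="GA_0"):
            rs = guide_pair_correlations(dep, lib, "GA", "GB")
        assert rs.size == 1

    def test_requires_three_tumors(self):
        lib = _lib({"GA": 1, "GB": 1, "NTC": 2})
        dep = pd.DataFrame(np.ones((4, 2)), index=lib.guide_ids)
        with pytest.raises(ValueError):
            guide_pair_correlations(dep, lib, "GA", "GB")


class TestGeneGeneCorrelation:
    def test_mean_of_pair_correlations(self, toy_library, toy_depletion):
        rec = gene_gene_correlation(toy_depletion, toy_library, "GA", "GB")
        rs = guide_pair_correlations(toy_depletion, toy_library, "GA", "GB")
        assert rec.mean_r == pytest.approx(rs.mean())
        assert rec.n_pairs == 4

    def test_record_is_symmetric_in_gene_order(self, toy_library, toy_depletion):
        ab = gene_gene_correlation(toy_depletion, toy_library, "GA", "GB")
        ba = gene_gene_correlation(toy_depletion, toy_library, "GB", "GA")
        assert ab.mean_r == ba.mean_r
        assert (ab.gene_a, ab.gene_b) == (ba.gene_a, ba.gene_b)


class TestEmpiricalFdr:
    def test_pool_size_is_ntc_pairs_choose_two(self, toy_library, toy_depletion):
        pool = ntc_pair_pool(toy_depletion, toy_library)
        assert pool.size == 3  # C(3, 2)

    def test_observed_below_pool_minimum_gives_fdr_one(self, toy_library, toy_depletion):
        pool = ntc_pair_pool(toy_depletion, toy_library)
        assert empirical_fdr(-1.5, pool, n_pairs=2, iterations=500, seed=0) == 1.0

    def test_observed_above_pool_maximum_gives_fdr_zero(self, toy_library, toy_depletion):
        pool = ntc_pair_pool(toy_depletion, toy_library)
        assert empirical_fdr(1.5, pool, n_pairs=2, iterations=500, seed=0) == 0.0

    def test_exhaustive_mode_enumerates_all_subsets(self, toy_library, toy_depletion):
        pool = ntc_pair_pool(toy_depletion, toy_library)
        obs = float(np.median(pool))
        exact = empirical_fdr(obs, pool, n_pairs=2, sampling="exhaustive")
        subsets = [np.mean(c) for c in itertools.combinations(pool, 2)]
        assert exact == np.mean([m >= obs for m in subsets])

    def test_monte_carlo_matches_enumeration_within_error(self, toy_library, toy_depletion):
        pool = ntc_pair_pool(toy_depletion, toy_library)
        obs = float(np.median(pool))
        exact = empirical_fdr(obs, pool, n_pairs=2, sampling="exhaustive")
        mc = empirical_fdr(obs, pool, n_pairs=2, iterations=10_000, seed=1)
        se = np.sqrt(exact * (1 - exact) / 10_000) + 1e-12
        assert abs(mc - exact) <= 3 * se + 1e-9

    def test_monotone_non_increasing_in_observed_mean(self, toy_library, toy_depletion):
        pool = ntc_pair_pool(toy_depletion, toy_library)
        fdrs = [
            empirical_fdr(obs, pool, n_pairs=2, iterations=2000, seed=7)
            for obs in np.linspace(-1, 1, 9)
        ]
        assert all(a >= b for a, b in zip(fdrs, fdrs[1:]))

    def test_ties_count_as_exceedances(self):
        pool = np.array([0.5, 0.5, 0.5])
        assert empirical_fdr(0.5, pool, n_pairs=2, iterations=100, seed=0) == 1.0

    def test_without_replacement_needs_large_enough_pool(self, toy_library, toy_depletion):
        pool = ntc_pair_pool(toy_depletion, toy_library)
        with pytest.raises(ValueError, match="exceeds NTC pool"):
            empirical_fdr(0.0, pool, n_pairs=4, sampling="without")

    def test_add_one_correction(self):
        pool = np.linspace(-1, 1, 10)
        raw = empirical_fdr(2.0, pool, n_pairs=2, iterations=100, seed=0)
        corrected = empirical_fdr(2.0, pool, n_pairs=2, iterations=100, seed=0, add_one=True)
        assert raw == 0.0 and corrected == pytest.approx(1 / 101)

    def test_deterministic_under_fixed_seed(self, toy_library, toy_depletion):
        pool = ntc_pair_pool(toy_depletion, toy_library)
        a = empirical_fdr(0.1, pool, n_pairs=2, iterations=1000, seed=42)
        b = empirical_fdr(0.1, pool, n_pairs=2, iterations=1000, seed=42)
        assert a == b


class TestPearsonTest:
    def test_perfect_correlation_flagged(self):
        x = np.arange(10.0)
        stat = pearson_test(x, 2 * x + 1)
        assert stat.r == 1.0 and stat.p_value == 0.0 and stat.perfect

    def test_orthogonal_input_gives_t_zero_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        stat = pearson_test(x, y)
        assert stat.r == pytest.approx(0.0, abs=1e-15)
        assert stat.t == pytest.approx(0.0, abs=1e-15)
        assert stat.p_value == pytest.approx(1.0)

    def test_formula_evaluation_at_n_340(self):
        # r = 0.5 at n = 340: t = 0.5*sqrt(338)/sqrt(0.75)
        rng = np.random.default_rng(11)
        x = rng.normal(size=340)
        y = 0.5 * (x - x.mean()) / x.std(ddof=1)
        resid = rng.normal(size=340)
        resid -= np.polyval(np.polyfit(x, resid, 1), x)  # orthogonalize to x
        y = y + np.sqrt(0.75) * resid / resid.std(ddof=1)
        stat = pearson_test(x, y)
        assert stat.r == pytest.approx(0.5, abs=1e-12)
        t_expected = 0.5 * np.sqrt(338) / np.sqrt(0.75)
        assert stat.t == pytest.approx(t_expected, rel=1e-12)
        assert stat.p_value == pytest.approx(2 * stats.t.sf(t_expected, 338), rel=1e-12)

    def test_agrees_with_brute_force_and_scipy(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            stat = pearson_test(x, y)
            assert stat.r == pytest.approx(brute_force_pearson(x, y), abs=1e-12)
            ref = stats.pearsonr(x, y)
            assert stat.r == pytest.approx(ref.statistic, abs=1e-12)
            assert stat.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDepletionVsNtc:
    def test_gene_matching_ntc_distribution_is_null(self, toy_library):
        dep = pd.DataFrame(
            {"t1": [0.4, -0.4, 9.0, 9.0, 0.4, -0.4, 0.0]},
            index=toy_library.guide_ids,
        )
        q = depletion_vs_ntc(dep, toy_library, "GA", "t1")
        assert q.mean_difference == pytest.approx(0.0)
        assert q.p_value > 0.8

    def test_fully_separated_groups_attain_exact_minimal_p(self, toy_library):
        # GA guides below every NTC guide: exact two-sided rank-sum p = 2/C(5,2)
        dep = pd.DataFrame(
            {"t1": [-5.0, -4.0, 0.0, 0.0, 1.0, 2.0, 3.0]},
            index=toy_library.guide_ids,
        )
        q = depletion_vs_ntc(dep, toy_library, "GA", "t1")
        assert q.p_value == pytest.approx(2 / 10)
        assert q.mean_difference < 0
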
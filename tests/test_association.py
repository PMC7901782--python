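"""Association stage: poscounts normalization vs a literal oracle, strict
prefilter boundaries, NB-LRT vs the Poisson-limit oracle, BH step-up,
report filter, Mann-Whitney exact enumeration and Spearman definitions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import statsmodels.api as sm

from aquamicrobe.association import (
    SizeFactors,
    bh_adjust,
    mann_whitney_u,
    nb_lrt,
    poscounts_size_factors,
    prefilter,
    report_filter,
    spearman_corr,
)


def poscounts_oracle(counts: pd.DataFrame) -> np.ndarray:
    """Independently coded literal implementation of the definition."""
    x = counts.to_numpy(dtype=float)
    n = x.shape[0]
    refs = []
    for j in range(x.shape[1]):
        col = x[:, j]
        pos = col[col > 0]
        refs.append(np.prod(pos) ** (1.0 / n) if pos.size else 0.0)
    refs = np.array(refs)
    factors = []
    for i in range(n):
        ratios = [
            x[i, j] / refs[j]
            for j in range(x.shape[1])
            if refs[j] > 0 and x[i, j] > 0
        ]
        factors.append(np.median(ratios))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestPoscounts:
    def test_scale_equivariance(self):
        base = np.array([10.0, 20, 30, 40])
        scales = np.array([1.0, 2.0, 4.0])
        counts = pd.DataFrame(np.outer(scales, base), index=list("abc"))
        f = poscounts_size_factors(counts).factors.to_numpy()
        expect = scales / np.exp(np.mean(np.log(scales)))
        np.testing.assert_allclose(f, expect, rtol=1e-12)

    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame([[5, 9, 2]] * 4, index=list("abcd"))
        np.testing.assert_allclose(
            poscounts_size_factors(counts).factors.to_numpy(), 1.0
        )

    def test_mixed_zero_pattern_matches_literal_oracle(self, rng):
        x = rng.negative_binomial(2, 0.05, size=(8, 40)).astype(float)
        x[rng.random(x.shape) < 0.3] = 0
        x[:, 0] = np.maximum(x[:, 0], 1)  # keep every sample non-empty
        counts = pd.DataFrame(x, index=[f"s{i}" for i in range(8)])
        ours = poscounts_size_factors(counts).factors.to_numpy()
        np.testing.assert_allclose(ours, poscounts_oracle(counts), rtol=1e-10)

    def test_geometric_mean_one(self, rng):
        x = rng.poisson(50, size=(6, 30)).astype(float)
        f = poscounts_size_factors(pd.DataFrame(x)).factors.to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_empty_sample_rejected(self):
        counts = pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"])
        with pytest.raises(ValueError):
            poscounts_size_factors(counts)


class TestPrefilter:
    def test_mean_boundary_strict(self):
        counts = pd.DataFrame({"t": [10, 10, 10]})  # mean exactly 10
        assert prefilter(counts).shape[1] == 0

    def test_single_sample_presence_removed(self):
        counts = pd.DataFrame({"t": [10_000, 0, 0]})
        assert prefilter(counts).shape[1] == 0

    def test_all_pass_identity(self):
        counts = pd.DataFrame({"a": [20, 30, 40], "b": [15, 0, 25]})
        out = prefilter(counts)
        assert list(out.columns) == ["a", "b"]


class TestNbLrt:
    def test_constant_covariate_rejected(self):
        counts = pd.DataFrame({"t": [5, 6, 7, 8]}, index=list("abcd"))
        sf = SizeFactors(pd.Series(1.0, index=counts.index))
        with pytest.raises(ValueError, match="constant"):
            nb_lrt(counts, sf, pd.Series(1.0, index=counts.index))

    def test_poisson_limit_matches_poisson_glm_lrt(self, rng):
        """Simulated Poisson counts: the NB LRT (dispersion MLE -> 0)
        reproduces the Poisson GLM LRT."""
        n = 40
        cov = np.repeat([0.0, 1.0], n // 2)
        mu = np.exp(4.0 + 0.5 * cov)
        y = rng.poisson(mu)
        counts = pd.DataFrame({"t": y}, index=[f"s{i}" for i in range(n)])
        sf = SizeFactors(pd.Series(1.0, index=counts.index))
        res = nb_lrt(counts, sf, pd.Series(cov, index=counts.index))
        x_full = sm.add_constant(cov)
        full = sm.GLM(y, x_full, family=sm.families.Poisson()).fit()
        red = sm.GLM(y, np.ones((n, 1)), family=sm.families.Poisson()).fit()
        lrt_oracle = 2 * (full.llf - red.llf)
        assert res.loc["t", "lrt_stat"] == pytest.approx(lrt_oracle, abs=1e-4)

    def test_planted_effect_detected_null_not(self, rng):
        n = 18
        cov = pd.Series(np.repeat([0.0, 1.0], n // 2), index=[f"s{i}" for i in range(n)])
        mu = np.exp(4 + 2.0 * cov.to_numpy())
        signal = rng.negative_binomial(10, 10 / (10 + mu))
        null = rng.negative_binomial(10, 10 / (10 + np.exp(4.5)), size=n)
        counts = pd.DataFrame({"hit": signal, "null": null}, index=cov.index)
        sf = SizeFactors(pd.Series(1.0, index=cov.index))
        res = nb_lrt(counts, sf, cov)
        assert res.loc["hit", "p_value"] < 1e-4
        assert res.loc["hit", "coefficient"] > 0
        assert res.loc["null", "p_value"] > 0.01


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_statsmodels(self, rng):
        p = rng.random(500)
        from statsmodels.stats.multitest import multipletests

        expect = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expect, rtol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_adjusted_at_least_raw_and_order_preserved(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_nan_passthrough(self):
        adj = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(adj[1]) and not np.isnan(adj[0])


class TestReportFilter:
    @staticmethod
    def results_for(taxa):
        return pd.DataFrame({"p_value": [0.01] * len(taxa)}, index=taxa)

    def test_two_samples_above_cutoff_pass(self):
        counts = pd.DataFrame({"t": [400, 350, 0]})
        out = report_filter(self.results_for(["t"]), counts, 300, 2)
        assert bool(out.loc["t", "passed_report_filter"])

    def test_single_huge_sample_fails(self):
        counts = pd.DataFrame({"t": [10**6, 0, 0]})
        out = report_filter(self.results_for(["t"]), counts, 300, 2)
        assert not bool(out.loc["t", "passed_report_filter"])

    def test_cutoff_zero_needs_two_nonzero(self):
        counts = pd.DataFrame({"a": [1, 2, 0], "b": [3, 0, 0]})
        out = report_filter(self.results_for(["a", "b"]), counts, 0, 2)
        assert bool(out.loc["a", "passed_report_filter"])
        assert not bool(out.loc["b", "passed_report_filter"])


def mw_exact_oracle(a, b):
    """Full enumeration over labelings of the pooled sample."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").statistic
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        x, y = pooled[mask], pooled[~mask]
        ranks = stats.rankdata(pooled)
        u = ranks[mask].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(6))
    def test_exact_p_matches_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n1, n2 = rng.integers(3, 6, size=2)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
        a, b = pooled[:n1], pooled[n1:]
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(mw_exact_oracle(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_corr([1, 2, 3, 5], [10, 20, 21, 40])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = spearman_corr([1, 2, 3], [9, 5, 1])
        assert rho == pytest.approx(-1.0)

    def test_tied_values_match_rank_then_pearson(self, rng):
        x = np.array([1.0, 2, 2, 3, 4, 5])
        y = rng.normal(size=6)
        rho, _ = spearman_corr(x, y)
        expect = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert rho == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("trial", range(4))
    def test_exact_p_matches_enumeration_oracle(self, trial):
        """n <= 8: p equals the fraction of permutations with |rho| at least
        as extreme, computed by direct enumeration of rank pairings."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 8))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if trial == 0:
            y[1] = y[0]  # include a tie case
        rho, p = spearman_corr(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        perms = [
            stats.pearsonr(rx, ry[list(perm)]).statistic
            for perm in itertools.permutations(range(n))
        ]
        expect = np.mean([abs(r) >= abs(rho) - 1e-12 for r in perms])
        assert p == pytest.approx(expect, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1], [1, 2, 3])
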
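from itertools import combinations

import numpy as np
import pytest
import scipy.stats

from qeeg.stats import (
    GroupSample, chi_square_equinumerosity, correlate, epsilon_squared,
    eta_squared, holm_adjust, kruskal_wallis, posthoc_pairwise,
    select_and_run_omnibus, welch_anova,
)


def _sample(a, b, c, metric="m"):
    return GroupSample(metric=metric, groups={"A": a, "B": b, "C": c})


class TestChiSquareEquinumerosity:
    def test_cohort_sizes_not_rejected(self):
        # sizes 43/30/25 against equal expected 98/3
        stat, p = chi_square_equinumerosity([43, 30, 25])
        expected = sum((n - 98 / 3) ** 2 for n in (43, 30, 25)) / (98 / 3)
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(5.29, abs=0.01)
        assert p == pytest.approx(0.0710, abs=0.002)
        assert p > 0.05

    def test_extremely_unequal_sizes_rejected(self):
        assert chi_square_equinumerosity([80, 10, 8])[1] < 0.05


class TestKruskalWallis:
    def test_fully_separated_small_groups(self):
        H, p = kruskal_wallis(_sample([1, 2, 3], [4, 5, 6], [7, 8, 9]))
        assert H == pytest.approx(7.2)  # the maximum for n=9, equal sizes
        # exact permutation: only the 3! relabelings of the tertiles reach H
        assert p == pytest.approx(6 / 1680)
        assert p < 0.05

    def test_identical_groups_have_h_zero(self):
        H, p = kruskal_wallis(_sample([1, 2, 3], [1, 2, 3], [1, 2, 3]))
        assert H == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis(_sample([5, 5, 5], [5, 5, 5], [5, 5, 5]))

    def test_small_n_p_matches_brute_force_permutations(self):
        """Exact-p path agrees with an independent permutation oracle."""
        rng = np.random.default_rng(0)
        pooled = rng.standard_normal(9)
        groups = pooled[:3], pooled[3:6], pooled[6:]
        H_obs, p_obs = kruskal_wallis(_sample(*groups))

        # oracle: enumerate index partitions, recompute H via scipy
        count = total = 0
        idx = set(range(9))
        for g1 in combinations(range(9), 3):
            for g2 in combinations(sorted(idx - set(g1)), 3):
                g3 = sorted(idx - set(g1) - set(g2))
                h = scipy.stats.kruskal(pooled[list(g1)], pooled[list(g2)],
                                        pooled[g3]).statistic
                total += 1
                count += h >= H_obs - 1e-12
        assert p_obs == pytest.approx(count / total)

    def test_large_n_uses_chi_square(self):
        rng = np.random.default_rng(1)
        groups = [rng.standard_normal(20) for _ in range(3)]
        H, p = kruskal_wallis(_sample(*groups))
        assert p == pytest.approx(scipy.stats.chi2.sf(H, 2))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = [rng.standard_normal(8) for _ in range(3)]
        H1, p1 = kruskal_wallis(_sample(*groups))
        H2, p2 = kruskal_wallis(
            _sample(*[np.exp(3 * g) for g in groups]))
        assert H1 == pytest.approx(H2)
        assert p1 == pytest.approx(p2)


class TestHolmProperties:
    """Order/monotonicity properties of the Holm adjustment."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0),
                    min_size=1, max_size=10))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_never_below_raw_and_order_preserving(self, p_values):
        p = np.asarray(p_values)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestHolm:
    def test_step_down_example(self):
        adj = holm_adjust([0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.03, 0.06, 0.06])
        assert (adj < 0.05).tolist() == [True, False, False]

    def test_uniform_case(self):
        assert np.allclose(holm_adjust([0.001] * 3), [0.003] * 3)

    def test_single_comparison_identity(self):
        assert holm_adjust([0.042])[0] == pytest.approx(0.042)

    def test_matches_step_down_enumeration(self):
        """Adjusted p equals max_j<=i min(1, (m-j+1) p_(j)) exactly."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(2, 8))
            order = np.argsort(p)
            m = p.size
            expected = np.empty(m)
            running = 0.0
            for rank, j in enumerate(order):
                running = max(running, min(1.0, (m - rank) * p[j]))
                expected[j] = running
            assert np.allclose(holm_adjust(p), expected)
            assert (holm_adjust(p) >= p - 1e-15).all()


class TestPosthocPairwise:
    def test_wilcoxon_small_n_matches_exact_enumeration(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(5), rng.standard_normal(4) + 1
        table = posthoc_pairwise(
            GroupSample(metric="m", groups={"X": x, "Y": y}), "wilcoxon")
        # oracle: exact rank-sum distribution by enumeration
        pooled = np.concatenate([x, y])
        ranks = scipy.stats.rankdata(pooled)
        obs = ranks[:5].sum()
        stats = [ranks[list(c)].sum() for c in combinations(range(9), 5)]
        stats = np.array(stats)
        mu = stats.mean()
        p_exact = np.mean(np.abs(stats - mu) >= abs(obs - mu) - 1e-12)
        assert table["p_raw"].iloc[0] == pytest.approx(p_exact)

    def test_all_pairs_present_with_holm(self):
        rng = np.random.default_rng(5)
        sample = _sample(rng.standard_normal(10), rng.standard_normal(10),
                         rng.standard_normal(10) + 3)
        for family in ("wilcoxon", "t", "welch"):
            table = posthoc_pairwise(sample, family)
            assert len(table) == 3
            assert (table["p_holm"] >= table["p_raw"] - 1e-15).all()

    def test_unknown_family_rejected(self):
        sample = _sample([1, 2, 3], [4, 5, 6], [7, 8, 9])
        with pytest.raises(ValueError):
            posthoc_pairwise(sample, "bootstrap")


class TestEffectSizes:
    def test_epsilon_squared_formula(self):
        assert epsilon_squared(5.0, 98) == pytest.approx(
            5.0 * (98 + 1) / (98 ** 2 - 1))
        assert epsilon_squared(5.0, 98) == pytest.approx(0.0515, abs=5e-4)

    def test_eta_squared_extremes(self):
        same_mean = _sample([1.0, 2.0, 3.0], [3.0, 2.0, 1.0],
                            [2.0, 1.0, 3.0])
        assert eta_squared(same_mean) == pytest.approx(0.0)
        separated = _sample([1.0, 1.0, 1.0], [2.0, 2.0, 2.0],
                            [3.0, 3.0, 3.0])
        assert eta_squared(separated) == pytest.approx(1.0)


class TestWelchAnova:
    def test_agrees_with_classic_anova_when_homoscedastic(self):
        # equal variances and sizes: Welch's F = F / (1 + 1/(3(n-1)))
        rng = np.random.default_rng(6)
        base = rng.standard_normal(100)
        base = (base - base.mean()) / base.std(ddof=1)  # exact unit variance
        sample = _sample(base, base + 0.2, base + 0.4)
        F_w, _ = welch_anova(sample)
        F, _ = scipy.stats.f_oneway(*sample.groups.values())
        assert F_w == pytest.approx(F, rel=0.01)


class TestDecisionTree:
    def test_normal_groups_take_anova_path(self):
        rng = np.random.default_rng(7)
        chosen = []
        for _ in range(100):
            sample = _sample(rng.standard_normal(30), rng.standard_normal(30),
                             rng.standard_normal(30))
            chosen.append(select_and_run_omnibus(sample).test)
        frac = np.mean([t in ("anova", "welch-anova") for t in chosen])
        assert frac >= 0.80  # Shapiro trips ~14% of triplets by chance

    def test_heavy_tailed_group_takes_kruskal_path(self):
        rng = np.random.default_rng(8)
        chosen = []
        for _ in range(100):
            sample = _sample(
                rng.standard_normal(30), rng.standard_normal(30),
                rng.lognormal(mean=0.0, sigma=2.0, size=30))
            chosen.append(select_and_run_omnibus(sample).test)
        assert np.mean([t == "kruskal-wallis" for t in chosen]) >= 0.90

    def test_unequal_sizes_force_kruskal(self):
        rng = np.random.default_rng(9)
        sample = _sample(rng.standard_normal(80), rng.standard_normal(10),
                         rng.standard_normal(8))
        res = select_and_run_omnibus(sample)
        assert res.test == "kruskal-wallis"
        assert res.assumptions["equinumerosity_p"] < 0.05
        assert res.effect_size_label == "epsilon2"

    def test_heteroscedastic_normal_groups_take_welch(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(20):
            sample = _sample(rng.standard_normal(40),
                             rng.standard_normal(40) * 6,
                             rng.standard_normal(40))
            res = select_and_run_omnibus(sample)
            hits += res.test == "welch-anova"
            if res.test == "welch-anova":
                assert res.assumptions["levene_p"] < 0.05
                assert set(res.pairwise["test"]) == {"welch"}
        assert hits >= 15

    def test_decision_trace_recorded(self):
        rng = np.random.default_rng(11)
        sample = _sample(rng.standard_normal(20), rng.standard_normal(20),
                         rng.standard_normal(20))
        res = select_and_run_omnibus(sample)
        for key in ("shapiro_A", "shapiro_B", "shapiro_C",
                    "equinumerosity_p"):
            assert key in res.assumptions
        assert 0 <= res.p_value <= 1
        assert 0 <= res.effect_size <= 1
        assert len(res.pairwise) == 3

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            _sample([1.0, 2.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_metric_rejected(self):
        with pytest.raises(ValueError):
            select_and_run_omnibus(
                _sample([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]))


class TestCorrelate:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1)
        assert res.method == "pearson"
        assert res.r == pytest.approx(1.0)

    def test_monotone_nonlinear_prefers_spearman(self):
        x = np.linspace(-3, 3, 20)
        y = x ** 3
        rho = correlate(x, y, scales="ordinal-any")
        r = correlate(x, y)
        assert rho.method == "spearman"
        assert rho.r == pytest.approx(1.0)
        assert r.r < 1.0

    def test_pearson_p_matches_t_transform(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(25)
        y = 0.5 * x + rng.standard_normal(25)
        res = correlate(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r ** 2))
        p_closed = 2 * scipy.stats.t.sf(abs(t), df=res.n - 2)
        assert res.p_value == pytest.approx(p_closed, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
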
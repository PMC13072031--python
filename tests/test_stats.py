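"""The inferential chain: gate, ANOVA variants, letters, correlations, PCA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import needlestoich as ns
from needlestoich.stats import compact_letter_display


def minimal_letter_count(P: np.ndarray, alpha: float) -> int:
    """Exhaustive oracle: minimum letters needed for the sharing contract.

    Letters are cliques of the non-significance graph; every non-significant
    pair must share one and every group must carry one, so the answer is the
    smallest cover by maximal cliques (any valid cover extends to one).
    """
    import networkx as nx

    k = P.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(k))
    for i, j in combinations(range(k), 2):
        if P[i, j] >= alpha:
            G.add_edge(i, j)
    cliques = [frozenset(c) for c in nx.find_cliques(G)]
    edges = list(G.edges)
    for size in range(1, len(cliques) + 1):
        for combo in combinations(cliques, size):
            if all(any(u in c and v in c for c in combo) for u, v in edges) and all(
                any(v in c for c in combo) for v in range(k)
            ):
                return size
    raise AssertionError("unreachable: the full clique set always covers")


class TestLevene:
    def test_identical_group_mean_deviations_give_w_zero(self):
        res = ns.levene_test([[1, 3, 5], [2, 4, 6]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_groups_are_degenerate_flagged(self):
        res = ns.levene_test([[3, 3, 3], [5, 5, 5]])
        assert (res.statistic, res.p_value) == (0.0, 1.0)
        assert "degenerate" in res.note

    def test_group_of_one_is_an_error(self):
        with pytest.raises(ValueError):
            ns.levene_test([[1.0], [2.0, 3.0]])


class TestAnovaFamily:
    def test_hand_computed_f_statistic(self):
        res = ns.oneway_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.statistic == pytest.approx(3.0, rel=1e-12)
        assert res.df == (2.0, 6.0)

    def test_all_constant_groups_have_undefined_f(self):
        with pytest.raises(ValueError, match="undefined"):
            ns.oneway_anova([[1, 1], [2, 2]])

    def test_welch_equals_classical_under_equal_variances_and_n(self):
        # exact algebraic identity for two groups with equal n and equal
        # sample variance (both reduce to the pooled t squared); for k > 2
        # Welch's denominator correction is nonzero even then
        groups = [[1, 2, 3], [4, 5, 6]]
        classic = ns.oneway_anova(groups)
        welch = ns.welch_anova(groups)
        assert welch.statistic == pytest.approx(classic.statistic, rel=1e-9)
        assert welch.p_value == pytest.approx(classic.p_value, rel=1e-6)

    def test_f_equals_squared_pooled_t_for_two_groups(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(1.0, 1.0, size=10)
        from scipy.stats import ttest_ind

        t = ttest_ind(x, y, equal_var=True).statistic
        f = ns.oneway_anova([x, y]).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_permutation_p_close_to_parametric_p_under_normality(self):
        """Sanity oracle: the F-test p agrees with its permutation p at small n."""
        rng = np.random.default_rng(42)
        groups = [rng.normal(size=4) for _ in range(3)]
        parametric = ns.oneway_anova(groups).p_value
        pooled = np.concatenate(groups)
        f_obs = ns.oneway_anova(groups).statistic
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            f = ns.oneway_anova([perm[:4], perm[4:8], perm[8:]]).statistic
            count += f >= f_obs
        assert abs(count / n_perm - parametric) <= 0.02


class TestWelchT:
    def test_hand_computed_example(self):
        res = ns.welch_t_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.674234614, rel=1e-8)
        assert res.df[0] == pytest.approx(4.0, rel=1e-9)

    def test_identical_samples_give_t_zero(self):
        assert ns.welch_t_test([1, 2, 3], [1, 2, 3]).statistic == 0.0

    def test_swapping_groups_negates_t_and_keeps_p(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=6), rng.normal(0.5, 2.0, size=9)
        a, b = ns.welch_t_test(x, y), ns.welch_t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_zero_variance_equal_means_is_flagged(self):
        res = ns.welch_t_test([2, 2, 2], [2, 2])
        assert "undefined" in res.note


class TestCompactLetterDisplay:
    def test_no_significant_pairs_all_share_a(self):
        P = np.ones((4, 4))
        assert set(compact_letter_display(P).values()) == {"a"}

    def test_all_pairs_significant_three_letters(self):
        P = np.full((3, 3), 0.001)
        np.fill_diagonal(P, 1.0)
        assert sorted(compact_letter_display(P).values()) == ["a", "b", "c"]

    def test_single_significant_pair_bridges_via_middle_group(self):
        # only A vs C significant among A, B, C
        P = np.ones((3, 3))
        P[0, 2] = P[2, 0] = 0.01
        letters = compact_letter_display(P, labels=["A", "B", "C"])
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_non_symmetric_matrix_is_rejected(self):
        P = np.ones((3, 3))
        P[0, 1] = 0.01
        with pytest.raises(ValueError, match="symmetric"):
            compact_letter_display(P)

    @settings(max_examples=120, derandomize=True, database=None, deadline=None)
    @given(data=st.data(), k=st.integers(2, 6))
    def test_contract_and_minimality_against_exhaustive_oracle(self, data, k):
        """Groups share a letter iff non-significant; letter count is minimal."""
        alpha = 0.05
        P = np.ones((k, k))
        for i, j in combinations(range(k), 2):
            p = data.draw(st.sampled_from([0.001, 0.2]))
            P[i, j] = P[j, i] = p
        letters = compact_letter_display(P, alpha=alpha)
        labels = list(letters)
        for i, j in combinations(range(k), 2):
            share = bool(set(letters[labels[i]]) & set(letters[labels[j]]))
            assert share == (P[i, j] >= alpha)
        used = len(set("".join(letters.values())))
        assert used == minimal_letter_count(P, alpha)


class TestGatedComparison:
    def test_homoscedastic_groups_take_the_anova_route(self):
        rng = np.random.default_rng(1)
        groups = {c: rng.normal(loc=m, size=10) for c, m in zip("abcd", [0, 0, 0, 3])}
        res = ns.gated_group_comparison(groups)
        assert res.route == "anova_tukey"
        assert res.pairwise.method == "tukey_hsd"

    def test_hundredfold_variance_ratio_takes_the_welch_route(self):
        rng = np.random.default_rng(2)
        groups = {"lo": rng.normal(0, 1, size=30), "hi": rng.normal(0, 10, size=30)}
        res = ns.gated_group_comparison(groups)
        assert res.route == "welch_games_howell"
        assert res.pairwise.method == "games_howell"

    def test_single_outlying_group_gets_its_own_letter(self):
        rng = np.random.default_rng(4)
        groups = {c: rng.normal(loc=m, size=12) for c, m in zip("abcd", [0, 0, 0, 6])}
        res = ns.gated_group_comparison(groups)
        assert res.letters == {"a": "a", "b": "a", "c": "a", "d": "b"}


def _handmade_dataset(needle_cn, soil_cn):
    """Healthy trees with prescribed needle and 0-20 cm soil C:N per tree."""
    needles, soils = [], []
    for i, (ncn, scn) in enumerate(zip(needle_cn, soil_cn)):
        t = f"H{i + 1}"
        needles.append(ns.ElementalSample(
            sample_id=f"{t}-apical", tree_id=t, condition="healthy", compartment="needle",
            position="apical", c_conc=ncn * 10.0, n_conc=10.0, p_conc=2.0))
        soils.append(ns.ElementalSample(
            sample_id=f"{t}-soil", tree_id=t, condition="healthy", compartment="soil",
            soil_layer="0-20", c_conc=scn * 0.3, n_conc=0.3, p_conc=0.1))
    return ns.StudyDataset(needles=tuple(needles), soils=tuple(soils))


class TestNeedleSoilCorrelation:
    def test_proportional_ratios_give_r_one(self):
        ds = _handmade_dataset([10, 20, 30, 40], [5, 10, 15, 20])
        e = ns.needle_soil_correlation(ds, "AH", "0-20", "c_n")
        assert e.r == pytest.approx(1.0)
        assert e.flag == ""

    def test_constant_needle_ratios_are_flagged_undefined(self):
        ds = _handmade_dataset([10, 10, 10], [5, 10, 15])
        e = ns.needle_soil_correlation(ds, "AH", "0-20", "c_n")
        assert e.flag == "undefined" and np.isnan(e.r)

    def test_three_trees_are_stamped_low_power(self):
        ds = _handmade_dataset([10, 20, 31], [5, 11, 15])
        assert ns.needle_soil_correlation(ds, "AH", "0-20", "c_n").flag == "low-power"

    def test_fewer_than_three_trees_is_insufficient(self):
        ds = _handmade_dataset([10, 20], [5, 11])
        assert ns.needle_soil_correlation(ds, "AH", "0-20", "c_n").flag == "insufficient"

    def test_grid_covers_groups_layers_and_ratios(self, noisy_dataset):
        grid = ns.correlation_grid(noisy_dataset)
        assert len(grid) == 4 * 5 * 3
        assert {"r", "p_value", "p_bh", "flag"} <= set(grid.columns)

    def test_pearson_estimator_recovers_known_correlation(self):
        """Monte-Carlo oracle: mean sample r over replicates approaches rho."""
        rng = np.random.default_rng(8)
        rho, n = 0.8, 50
        cov = np.array([[1, rho], [rho, 1]])
        rs = []
        for _ in range(1000):
            x = rng.multivariate_normal([0, 0], cov, size=n)
            rs.append(np.corrcoef(x[:, 0], x[:, 1])[0, 1])
        assert abs(np.mean(rs) - rho) <= 0.1


class TestPCA:
    def test_independent_columns_split_variance_evenly(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(rng.normal(size=(3000, 3)), columns=["c_n", "c_p", "n_p"])
        res = ns.pca_ratios(table)
        assert np.all(np.abs(res.explained_variance_fraction - 1 / 3) < 0.04)

    def test_collinear_columns_collapse_onto_first_component(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=40)
        table = pd.DataFrame({"c_n": a, "c_p": 2 * a, "n_p": rng.normal(size=40)})
        res = ns.pca_ratios(table)
        assert res.explained_variance_fraction[0] >= 2 / 3 - 0.05
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0, rel=1e-9)

    def test_zero_variance_column_is_an_error_naming_the_ratio(self):
        table = pd.DataFrame({"c_n": [1, 1, 1, 1], "c_p": [1, 2, 3, 4], "n_p": [2, 1, 2, 1]})
        with pytest.raises(ValueError, match="c_n"):
            ns.pca_ratios(table)

    def test_reconstruction_inverts_the_transform(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame(rng.uniform(1, 50, size=(12, 3)), columns=["c_n", "c_p", "n_p"])
        res = ns.pca_ratios(table)
        back = res.reconstruct()
        assert np.allclose(back.to_numpy(), table.to_numpy(), atol=1e-9)

    def test_explained_fractions_are_non_increasing(self, noisy_dataset):
        table = pd.DataFrame(
            {n: [ns.compute_ratios(s)[n] for s in noisy_dataset.needles] for n in ("c_n", "c_p", "n_p")})
        res = ns.pca_ratios(table)
        evf = res.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-12)
        # fixed sign convention: dominant loading of each component is positive
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0
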
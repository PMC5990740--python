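"""Statistical chain: oracles, hand-computed examples, calibration."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import enamelgrowth as eg
from enamelgrowth import stats as st

TWO_GROUPS_Y = np.array([1.0, 2, 3, 4, 5, 6])
TWO_GROUPS_G = np.array(["a"] * 3 + ["b"] * 3)


def random_tree(seed, ntips=8):
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(ntips)]
    # random binary topology by sequential joining
    parts = [f"{t}:{rng.uniform(0.2, 2):.4f}" for t in taxa]
    while len(parts) > 1:
        i, j = rng.choice(len(parts), 2, replace=False)
        a, b = parts[i], parts[j]
        parts = [p for k, p in enumerate(parts) if k not in (i, j)]
        parts.append(f"({a},{b}):{rng.uniform(0.2, 2):.4f}")
    newick = f"{parts[0].rsplit(':', 1)[0]};"
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True), taxa


class TestPhyloCovariance:
    def test_two_tip_tree_by_definition(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):2);", schema="newick")
        C = st.phylo_covariance(tree, ["a", "b"])
        assert np.allclose(C, [[3, 2], [2, 3]])

    def test_missing_tip_named_in_error(self):
        tree = dendropy.Tree.get(data="(a:1,b:1);", schema="newick")
        with pytest.raises(ValueError, match="ghost"):
            st.phylo_covariance(tree, ["a", "ghost"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_mrca_depth_oracle(self, seed):
        tree, taxa = random_tree(seed)
        C = st.phylo_covariance(tree, taxa)
        pdc = tree.phylogenetic_distance_matrix()
        tx = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i == j:
                    continue
                # C[i,i] + C[j,j] - 2 C[i,j] equals the patristic distance
                want = pdc.patristic_distance(tx[a], tx[b])
                got = C[i, i] + C[j, j] - 2 * C[i, j]
                assert got == pytest.approx(want, rel=1e-9)


class TestPGLS:
    def test_identity_covariance_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = 2.0 + 0.7 * x + rng.normal(0, 0.3, 30)
        fit = st.pgls_fit(y, x, np.eye(30))
        ols = np.polyfit(x, y, 1)
        assert fit.beta[1] == pytest.approx(ols[0], rel=1e-10)
        assert fit.beta[0] == pytest.approx(ols[1], rel=1e-10)

    def test_perfect_fit_has_zero_residuals(self):
        tree, taxa = random_tree(4)
        C = st.phylo_covariance(tree, taxa)
        x = np.arange(len(taxa), dtype=float)
        y = 1.0 + 0.5 * x
        fit = st.pgls_fit(y, x, C)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_design_under_v_inner_product(self):
        tree, taxa = random_tree(5)
        C = st.phylo_covariance(tree, taxa)
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, len(taxa))
        y = rng.normal(0, 1, len(taxa))
        fit = st.pgls_fit(y, x, C)
        X = np.column_stack([np.ones_like(x), x])
        assert np.abs(X.T @ np.linalg.solve(C, fit.residuals)).max() < 1e-8

    def test_brownian_slope_recovery(self):
        tree, taxa = random_tree(6)
        C = st.phylo_covariance(tree, taxa)
        L = np.linalg.cholesky(C)
        rng = np.random.default_rng(99)
        slopes = []
        for _ in range(500):
            x = L @ rng.standard_normal(len(taxa))
            y = 0.4 * x + 0.3 * (L @ rng.standard_normal(len(taxa)))
            slopes.append(st.pgls_fit(y, x, C).beta[1])
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.4) < 2 * se + 1e-3


class TestBoxCox:
    def test_lambda_one_is_shift_only(self):
        # at lambda = 1 the transform is v - 1 (shape preserving)
        v = np.array([1.0, 2.0, 4.0, 8.0])
        res = st.boxcox(v, grid=(1.0, 1.0, 0.01))
        assert res.lambda_bc == 1.0
        assert np.allclose(res.transformed, v - 1.0)

    def test_lambda_zero_is_log(self):
        v = np.array([1.0, 2.0, 4.0, 8.0])
        res = st.boxcox(v, grid=(0.0, 0.0, 0.01))
        assert res.lambda_bc == 0.0
        assert np.allclose(res.transformed, np.log(v))

    def test_lognormal_sample_optimum_near_zero(self):
        rng = np.random.default_rng(12)
        v = np.exp(rng.normal(0.0, 0.6, 4000))
        res = st.boxcox(v)
        assert abs(res.lambda_bc) < 0.05

    def test_matches_scipy_profile_likelihood(self):
        rng = np.random.default_rng(3)
        v = rng.gamma(2.0, 1.5, 400)
        res = st.boxcox(v)
        lam_scipy = sps.boxcox_normmax(v, method="mle")
        assert res.lambda_bc == pytest.approx(lam_scipy, abs=0.02)

    def test_negative_input_shifted_first(self):
        v = np.array([-1.0, 0.0, 1.0, 3.0])
        res = st.boxcox(v)
        assert res.shift == pytest.approx(2.0)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            st.boxcox(np.ones(10))


class TestWilksManova:
    def test_equal_group_means_give_lambda_one(self):
        Y = np.array([[1.0, 0], [2, 5], [3, 1],
                      [1, 0], [2, 5], [3, 1]])
        res = st.manova_wilks(Y, ["a"] * 3 + ["b"] * 3)
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.F_stat == pytest.approx(0.0, abs=1e-10)

    def test_exact_f_identity_for_two_responses(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(0, 1, (24, 2))
        Y[:8] += 0.8
        groups = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        res = st.manova_wilks(Y, groups)
        lam, nu_h, nu_e = res.wilks_lambda, 2, 21
        want = ((1 - np.sqrt(lam)) / np.sqrt(lam)) * ((nu_e - 1) / nu_h)
        assert res.F_stat == pytest.approx(want, rel=1e-12)
        assert (res.df1, res.df2) == (2 * nu_h, 2 * (nu_e - 1))
        assert res.partial_eta_sq_mv == pytest.approx(1 - np.sqrt(lam))

    def test_matches_scatter_matrix_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n_per = rng.integers(3, 8, 3)
            Y = rng.normal(0, 1, (int(n_per.sum()), 2))
            groups = np.repeat(["a", "b", "c"], n_per)
            res = st.manova_wilks(Y, groups)
            # oracle: explicit elementwise accumulation of E and (E + H)
            grand = Y.mean(axis=0)
            E = np.zeros((2, 2))
            T = np.zeros((2, 2))
            for g in "abc":
                sub = Y[groups == g]
                m = sub.mean(axis=0)
                for row in sub:
                    E += np.outer(row - m, row - m)
            for row in Y:
                T += np.outer(row - grand, row - grand)
            lam_oracle = np.linalg.det(E) / np.linalg.det(T)
            assert res.wilks_lambda == pytest.approx(lam_oracle, rel=1e-9)

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA
        rng = np.random.default_rng(8)
        Y = rng.normal(0, 1, (30, 2))
        Y[:10, 0] += 1.0
        groups = np.repeat(["a", "b", "c"], 10)
        res = st.manova_wilks(Y, groups)
        df = pd.DataFrame({"y1": Y[:, 0], "y2": Y[:, 1], "g": groups})
        mv = MANOVA.from_formula("y1 + y2 ~ g", data=df)
        tab = mv.mv_test().results["g"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(tab.loc["Wilks' lambda", "Value"]), rel=1e-8)
        assert res.F_stat == pytest.approx(
            float(tab.loc["Wilks' lambda", "F Value"]), rel=1e-6)

    def test_tiny_group_named_in_error(self):
        Y = np.zeros((5, 2))
        with pytest.raises(ValueError, match="b"):
            st.manova_wilks(Y, ["a", "a", "a", "a", "b"])


class TestPairwise:
    def test_duplicated_group_gives_high_p(self):
        rng = np.random.default_rng(4)
        half = rng.normal(0, 1, (10, 2))
        Y = np.vstack([half, half])
        groups = ["a"] * 10 + ["b"] * 10
        mat = st.pairwise_manova(Y, groups)
        assert mat.loc["a", "b"] > 0.99

    def test_bh_hand_computed_step_up(self):
        assert np.allclose(st.bh_fdr([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])
        assert np.allclose(st.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_bh_single_p_unchanged(self):
        assert st.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_bh_matches_min_over_tail_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(2, 12))
            got = st.bh_fdr(p)
            m = len(p)
            order = np.argsort(p)
            oracle = np.empty(m)
            sorted_p = p[order]
            # step-up: adj_i = min over j >= i of p_(j) * m / (j+1)
            for i in range(m):
                oracle[i] = min(min(sorted_p[j] * m / (j + 1)
                                    for j in range(i, m)), 1.0)
            assert np.allclose(got[order], oracle)

    def test_bh_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            st.bh_fdr([0.5, 1.2])


class TestUnivariate:
    def test_anova_hand_computed_two_groups(self):
        res = st.anova_oneway(TWO_GROUPS_Y, TWO_GROUPS_G)
        assert res.F_stat == pytest.approx(13.5)
        assert res.partial_eta_sq == pytest.approx(13.5 / 17.5)

    def test_anova_matches_scipy(self):
        rng = np.random.default_rng(21)
        y = rng.normal(0, 1, 30)
        g = np.repeat(["a", "b", "c"], 10)
        res = st.anova_oneway(y, g)
        F, p = sps.f_oneway(y[:10], y[10:20], y[20:])
        assert res.F_stat == pytest.approx(F, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_anova_all_equal(self):
        res = st.anova_oneway(np.ones(6), TWO_GROUPS_G)
        assert res.F_stat == 0.0 and res.partial_eta_sq == 0.0

    def test_anova_zero_within_variance_flagged_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            res = st.anova_oneway(np.array([1.0, 1, 2, 2]),
                                  np.array(["a", "a", "b", "b"]))
        assert np.isinf(res.F_stat)

    def test_eta_squared_from_published_f(self):
        assert st.partial_eta_sq_from_f(10.75, 4, 34) == \
            pytest.approx(0.558, abs=5e-4)
        assert st.partial_eta_sq_from_f(7.578, 4, 34) == \
            pytest.approx(0.471, abs=5e-4)

    def test_kruskal_hand_computed(self):
        # 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2 = 12/42 * (3*2.25 + 3*2.25)
        H, _ = st.kruskal_wallis(TWO_GROUPS_Y, TWO_GROUPS_G)
        assert H == pytest.approx(12.0 / 42.0 * (3 * 2.25 + 3 * 2.25),
                                  rel=1e-9)
        assert H == pytest.approx(3.857, abs=1e-3)

    def test_kruskal_all_tied_is_zero(self):
        H, p = st.kruskal_wallis(np.ones(6), TWO_GROUPS_G)
        assert H == 0.0 and p == 1.0

    def test_dunn_hand_computed(self):
        z, p = st.dunn_pairwise(TWO_GROUPS_Y, TWO_GROUPS_G)
        assert abs(z.loc["a", "b"]) == pytest.approx(1.964, abs=1e-3)

    def test_dunn_identical_groups(self):
        y = np.array([1.0, 2, 3, 1, 2, 3])
        z, p = st.dunn_pairwise(y, TWO_GROUPS_G)
        assert z.loc["a", "b"] == pytest.approx(0.0)
        assert p.loc["a", "b"] == pytest.approx(1.0)

    def test_dunn_matches_brute_force_oracle_three_groups(self):
        rng = np.random.default_rng(30)
        y = np.round(rng.normal(0, 1, 18), 1)   # induce ties
        g = np.repeat(["a", "b", "c"], 6)
        z, _ = st.dunn_pairwise(y, g)
        # independent recomputation with explicit midranks and tie term
        order = np.argsort(y, kind="mergesort")
        ranks = np.empty(len(y))
        i = 0
        pos = 1
        ys = y[order]
        while i < len(ys):
            j = i
            while j < len(ys) and ys[j] == ys[i]:
                j += 1
            ranks[order[i:j]] = np.mean(np.arange(pos, pos + (j - i)))
            pos += j - i
            i = j
        N = len(y)
        _, t = np.unique(y, return_counts=True)
        tie = ((t ** 3 - t).sum()) / (12 * (N - 1))
        for a, b in (("a", "b"), ("a", "c"), ("b", "c")):
            ra, rb = ranks[g == a].mean(), ranks[g == b].mean()
            se = np.sqrt((N * (N + 1) / 12 - tie) * (1 / 6 + 1 / 6))
            assert z.loc[a, b] == pytest.approx((ra - rb) / se, rel=1e-9)


class TestPipeline:
    def test_noise_free_separation_is_decisive(self):
        cfg = eg.published_means_comparative_config(seed=0, brownian_sd=0.0,
                                                residual_sd=0.0)
        table = eg.simulate_species_dataset(cfg)
        res = st.run_group_comparison(table, cfg.tree)
        assert res.manova.p_value < 0.001
        assert res.pairwise_anova_p["cer"].loc[
            "non_probainognathian", "mammaliamorph"] < 0.05

    def test_exclusion_and_reassignment_honored(self):
        cfg = eg.published_means_comparative_config(seed=1)
        table = eg.simulate_species_dataset(cfg)
        drop = table.records[0].species
        move = table.records[-1].species
        res = st.run_group_comparison(
            table, cfg.tree, exclude=[drop],
            reassign={move: "unassigned"})
        assert res.provenance["n_species"] == len(table.records) - 2
        assert drop in res.provenance["excluded"]

    def test_permuted_labels_give_uniform_p(self):
        """Under permuted group labels the MANOVA p-value is uniform."""
        cfg = eg.published_means_comparative_config(seed=2, null=True)
        table = eg.simulate_species_dataset(cfg)
        df = table.to_dataframe()
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(200):
            perm = df.copy()
            perm["group"] = rng.permutation(perm["group"].to_numpy())
            t = eg.SpeciesTable.from_dataframe(perm)
            res = st.run_group_comparison(t, cfg.tree, posthoc=False)
            ps.append(res.manova.p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_provenance_records_lambdas_and_groups(self):
        cfg = eg.published_means_comparative_config(seed=3)
        table = eg.simulate_species_dataset(cfg)
        res = st.run_group_comparison(table, cfg.tree)
        assert set(res.provenance["boxcox_lambda"]) == {"dsr", "cer"}
        assert sum(res.provenance["groups"].values()) == 39
        assert res.manova.df1 == 8 and res.manova.df2 == 66
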
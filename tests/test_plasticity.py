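"""CV_E, variance-heterogeneity tests, variance components and H2."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

import microplast as mp


class TestLevene:
    def test_hand_computed_example(self):
        F, df1, df2, p = mp.levene_test([1, 3, 2, 0, 8, 4], [0, 0, 0, 1, 1, 1], "mean")
        assert F == pytest.approx(72 / 34)
        assert (df1, df2) == (1, 4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        labels = np.repeat([0, 1, 2], 10)
        for center in ("mean", "median"):
            F, _, _, p = mp.levene_test(y, labels, center)
            ref = scipy.stats.levene(*(y[labels == g] for g in (0, 1, 2)), center=center)
            assert F == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        labels = np.repeat([0, 1], 10)
        F1 = mp.levene_test(y, labels, "mean")[0]
        perm = rng.permutation(20)
        F2 = mp.levene_test(y[perm], labels[perm], "mean")[0]
        assert F1 == pytest.approx(F2)

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(2)
        rej = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = rng.normal(size=40)
            p = mp.levene_test(y, np.repeat([0, 1], 20), "median")[3]
            rej += p < 0.05
        assert 0.03 <= rej / n_sim <= 0.07

    def test_mean_vs_median_agree_on_symmetric_data(self):
        rng = np.random.default_rng(3)
        agree = 0
        n_sim = 200
        for _ in range(n_sim):
            y = rng.normal(size=60)
            labels = np.repeat([0, 1, 2], 20)
            d_mean = mp.levene_test(y, labels, "mean")[3] < 0.05
            d_median = mp.levene_test(y, labels, "median")[3] < 0.05
            agree += d_mean == d_median
        assert agree / n_sim >= 0.95

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            mp.levene_test([1, 1, 2, 2], [0, 0, 1, 1], "mean")


class TestCve:
    def test_constant_vector_zero(self):
        assert mp.cve([10, 10, 10, 10]) == 0.0

    def test_two_point_value(self):
        assert mp.cve([8, 12]) == pytest.approx(28.284271247461902)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(1, 10, 20)
        assert mp.cve(y) == pytest.approx(mp.cve(3.7 * y))

    def test_errors(self):
        with pytest.raises(ValueError):
            mp.cve([5.0])
        with pytest.raises(ValueError):
            mp.cve([-1.0, 1.0])  # mean 0


class TestCveTable:
    def test_cardinality(self, normalized_small):
        norm, design = normalized_small
        tab = mp.cve_table(norm.values, design)
        n_cells = 4 * 2 * 2  # G x S x R on the small design
        assert len(tab) == norm.values.shape[0] * n_cells

    def test_constant_matrix_all_zero(self, small_design):
        v = pd.DataFrame(
            np.full((3, len(small_design)), 7.0),
            index=["a", "b", "c"],
            columns=small_design["sample_id"],
        )
        tab = mp.cve_table(v, small_design)
        assert np.allclose(tab["cve"], 0.0)

    def test_planted_dispersion_raises_cve(self, small_design):
        # doubling one genotype's dispersion raises that genotype's mean CV_E
        wins = 0
        n_sim = 40
        for seed in range(n_sim):
            t = mp.generate_truth(
                1, {}, dispersion_range=(0.2, 0.2), n_genotypes=4, n_replicates=2,
                cve_config=None, seed=seed,
            )
            t.cve_multiplier[0, 0, :] = 2.0  # genotype G01 inflated
            c, s = mp.simulate_counts(small_design, t, seed=1000 + seed)
            norm = mp.normalize(c, s)
            tab = mp.cve_table(norm.values, small_design)
            by_geno = tab.groupby("genotype")["cve"].mean()
            wins += by_geno["G01"] > by_geno.drop("G01").mean()
        # one-sided: inflation must dominate well above chance
        assert wins / n_sim > 0.8


class TestCveAnova:
    def test_identical_cells_give_unit_p(self, small_design):
        v = pd.DataFrame(
            np.full((2, len(small_design)), 5.0),
            index=["a", "b"],
            columns=small_design["sample_id"],
        )
        # identical within-cell pattern in every 3-fly cell -> identical CV_E
        v += np.tile([0.0, 0.3, 0.6], len(small_design) // 3)
        tab = mp.cve_table(v, small_design)
        res = mp.cve_anova(tab)
        assert (res["F"] <= 1e-10).all()
        assert (res["p_value"] == 1.0).all()

    def test_matches_statsmodels_ols_anova(self, normalized_small):
        norm, design = normalized_small
        tab = mp.cve_table(norm.values, design)
        gene = tab["gene_id"].iloc[0]
        sub = tab[tab["gene_id"] == gene]
        res = mp.cve_anova(tab)
        mine = res[res["gene_id"] == gene].set_index("term")
        fit = ols("cve ~ C(sex) * C(genotype)", data=sub).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert mine.loc["G", "F"] == pytest.approx(ref.loc["C(genotype)", "F"])
        assert mine.loc["S", "F"] == pytest.approx(ref.loc["C(sex)", "F"])
        assert mine.loc["GxS", "F"] == pytest.approx(
            ref.loc["C(sex):C(genotype)", "F"]
        )

    def test_orthogonality_sex_swap(self, normalized_small):
        # swapping the sex labels leaves the G statistic unchanged (balance)
        norm, design = normalized_small
        tab = mp.cve_table(norm.values, design)
        res1 = mp.cve_anova(tab)
        swapped = tab.copy()
        swapped["sex"] = swapped["sex"].map({"F": "M", "M": "F"})
        res2 = mp.cve_anova(swapped)
        g1 = res1[res1["term"] == "G"].set_index("gene_id")["F"]
        g2 = res2[res2["term"] == "G"].set_index("gene_id")["F"]
        pd.testing.assert_series_equal(g1, g2)


class TestVarianceComponents:
    def test_one_way_ems_algebra(self):
        # G groups, n = 5: E[MS_G] = s_eps + n*s_G, so MS_G = 11, MSE = 1 -> s_G = 2
        a, n = 4, 5
        rng = np.random.default_rng(7)
        # construct data with exact MS values via orthogonal perturbations
        group_means = np.array([0.0, 2, 4, 6])
        y = np.repeat(group_means, n).astype(float)
        # add within-group pattern with known SS
        pat = np.array([2, -1, -1, 1, -1], dtype=float)
        pat -= pat.mean()
        y += np.tile(pat * np.sqrt(1.0 * (a * (n - 1)) / (a * (pat**2).sum())), a)
        design = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(a * n)],
                "genotype": np.repeat([f"g{j}" for j in range(a)], n),
                "sex": "F",
                "replicate": "R1",
            }
        )
        vc = mp.variance_components(y, design, "expression")
        ms_g = n * np.sum((group_means - group_means.mean()) ** 2) / (a - 1)
        mse = vc.sigma_eps
        assert vc.sigma_g == pytest.approx((ms_g - mse) / n)

    def test_constructed_ms_values(self):
        # direct EMS check on a one-way layout: MS_G = 11, MSE = 1, n = 5 -> 2
        a, n = 3, 5
        design = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(a * n)],
                "genotype": np.repeat([f"g{j}" for j in range(a)], n),
                "sex": "F",
                "replicate": "R1",
            }
        )
        # group effects giving MS_G = 11: sum sq of (c, 0, -c) * n / (a-1) = 11
        c = np.sqrt(11 * (a - 1) / (n * 2.0))
        means = np.array([c, 0, -c])
        pat = np.array([1.0, -1, 1, -1, 0])
        pat -= pat.mean()
        pat *= np.sqrt(1.0 * (n - 1) / (pat**2).sum())  # per-group SS = MSE*(n-1)
        y = np.repeat(means, n) + np.tile(pat, a)
        vc = mp.variance_components(y, design, "expression")
        assert vc.sigma_eps == pytest.approx(1.0)
        assert vc.sigma_g == pytest.approx(2.0)

    def test_brute_force_ems_oracle_three_way(self, small_design):
        rng = np.random.default_rng(8)
        y = rng.normal(size=len(small_design))
        vc = mp.variance_components(y, small_design, "expression")
        # independent solve of the EMS linear system from raw mean squares
        df = small_design.assign(y=y)
        a = df["genotype"].nunique()
        b = df["replicate"].nunique()
        c = df["sex"].nunique()
        n = len(df) // (a * b * c)
        cell = df.groupby(["genotype", "replicate", "sex"])["y"].mean()
        arr = cell.to_numpy().reshape(a, b, c)
        grand = arr.mean()
        mg = arr.mean(axis=(1, 2))
        mr = arr.mean(axis=(0, 2))
        ms_ = arr.mean(axis=(0, 1))
        mgr = arr.mean(axis=2)
        mgs = arr.mean(axis=1)
        mrs = arr.mean(axis=0)
        ms_g = n * b * c * ((mg - grand) ** 2).sum() / (a - 1)
        ms_gr = n * c * ((mgr - mg[:, None] - mr[None, :] + grand) ** 2).sum() / ((a - 1) * (b - 1))
        ms_gs = n * b * ((mgs - mg[:, None] - ms_[None, :] + grand) ** 2).sum() / ((a - 1) * (c - 1))
        r3 = (
            arr - mgr[:, :, None] - mgs[:, None, :] - mrs[None, :, :]
            + mg[:, None, None] + mr[None, :, None] + ms_[None, None, :] - grand
        )
        ms_grs = n * (r3**2).sum() / ((a - 1) * (b - 1) * (c - 1))
        mse = (
            df.groupby(["genotype", "replicate", "sex"])["y"].var(ddof=1).mean()
        )
        # EMS linear system (unrestricted mixed model), solved brute force
        A = np.array(
            [
                [n * b * c, n * c, n * b, n, 1],
                [0, n * c, 0, n, 1],
                [0, 0, n * b, n, 1],
                [0, 0, 0, n, 1],
                [0, 0, 0, 0, 1],
            ],
            dtype=float,
        )
        rhs = np.array([ms_g, ms_gr, ms_gs, ms_grs, mse])
        sol = np.linalg.solve(A, rhs)
        expect = np.maximum(sol, 0)
        got = np.array([vc.sigma_g, vc.sigma_gr, vc.sigma_gs, vc.sigma_grs, vc.sigma_eps])
        assert np.allclose(got, expect, atol=1e-8)

    def test_null_genes_truncate_to_zero(self, small_design):
        rng = np.random.default_rng(9)
        zeros = 0
        n_genes = 200
        for _ in range(n_genes):
            y = rng.normal(size=len(small_design))
            vc = mp.variance_components(y, small_design, "expression")
            zeros += vc.sigma_g == 0.0
        assert zeros >= n_genes / 2  # truncation puts the median at exactly 0

    def test_all_constant_input(self, small_design):
        vc = mp.variance_components(
            np.full(len(small_design), 3.0), small_design, "expression"
        )
        assert (
            vc.sigma_g == vc.sigma_gr == vc.sigma_gs == vc.sigma_grs == vc.sigma_eps == 0.0
        )

    def test_cve_scheme_on_cell_values(self, small_design):
        rng = np.random.default_rng(10)
        cells = small_design[["genotype", "sex", "replicate"]].drop_duplicates()
        g_eff = {g: e for g, e in zip(
            sorted(cells["genotype"].unique()), rng.normal(0, 2, 4)
        )}
        y = cells["genotype"].map(g_eff).to_numpy() + rng.normal(0, 0.5, len(cells))
        vc = mp.variance_components(y, cells, "cve")
        assert vc.scheme == "cve"
        assert vc.sigma_g > vc.sigma_eps  # strong planted line variance


class TestHeritability:
    def test_half(self):
        vc = mp.VarianceComponents("g", "expression", 1, 0, 0, 0, 1)
        assert mp.heritability(vc).h2 == 0.5

    def test_zero_genetic(self):
        vc = mp.VarianceComponents("g", "expression", 0, 0, 0, 0, 2)
        assert mp.heritability(vc).h2 == 0.0

    def test_zero_over_zero_defined_as_zero(self):
        vc = mp.VarianceComponents("g", "cve", 0, 0, 0, 0, 0)
        assert mp.heritability(vc).h2 == 0.0

    def test_cve_scheme_uses_two_components(self):
        vc = mp.VarianceComponents("g", "cve", 1, 5, 1, 5, 2)
        assert mp.heritability(vc).h2 == pytest.approx(0.5)  # GR/GRS ignored

    def test_bounded_and_monotone(self):
        rng = np.random.default_rng(11)
        prev = 0.0
        for sg in np.linspace(0, 5, 6):
            vc = mp.VarianceComponents("g", "expression", sg, 0.1, 0.1, 0.1, 1.0)
            h2 = mp.heritability(vc).h2
            assert 0 <= h2 <= 1 and h2 >= prev
            prev = h2

    def test_recovery_at_design_size(self):
        # planted variance ratio 0.3 recovered without bias (quick version)
        d = mp.generate_design(16, 3, 8, 0, seed=12)
        G = pd.Categorical(d["genotype"]).codes
        R = pd.Categorical(d["replicate"]).codes
        S = pd.Categorical(d["sex"]).codes
        rng = np.random.default_rng(13)
        est = []
        for _ in range(100):
            w = rng.dirichlet([2, 1, 1, 1]) * 0.3
            y = (
                rng.normal(0, np.sqrt(w[0]), 16)[G]
                + rng.normal(0, np.sqrt(w[1]), (16, 3))[G, R]
                + rng.normal(0, np.sqrt(w[2]), (16, 2))[G, S]
                + rng.normal(0, np.sqrt(w[3]), (16, 3, 2))[G, R, S]
                + rng.normal(0, np.sqrt(0.7), len(d))
            )
            est.append(mp.heritability(mp.variance_components(y, d, "expression")).h2)
        assert abs(np.mean(est) - 0.3) < 0.05


def test_heritability_table_both_schemes(normalized_small):
    norm, design = normalized_small
    expr = mp.heritability_table(norm.values, design, scheme="expression")
    cve_t = mp.heritability_table(norm.values, design, scheme="cve")
    assert ((expr["h2"] >= 0) & (expr["h2"] <= 1)).all()
    assert ((cve_t["h2"] >= 0) & (cve_t["h2"] <= 1)).all()
    assert len(expr) == norm.values.shape[0]


def test_hov_tests_detect_heterogeneity():
    # 8-fly cells give the Brown-Forsythe screen usable power
    design = mp.generate_design(4, 2, 8, 0, seed=15)
    rng = np.random.default_rng(14)
    n = len(design)
    quiet = rng.normal(100, 5, size=(1, n))
    loud = rng.normal(100, 5, size=(1, n))
    cells = pd.Categorical(
        design[["genotype", "sex", "replicate"]].astype(str).agg("|".join, axis=1)
    ).codes
    loud[0, cells < 8] += rng.normal(0, 60, size=(cells < 8).sum())
    v = pd.DataFrame(
        np.vstack([quiet, loud]), index=["quiet", "loud"],
        columns=design["sample_id"],
    )
    res = mp.hov_tests(v, design, center="median").set_index("gene_id")
    assert res.loc["loud", "p_value"] < 0.01
    assert res.loc["quiet", "p_value"] > 0.05
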
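"""NB-GLM core: fits vs independent oracles, dispersion recovery, LRT, FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import microplast as mp
from microplast.nbglm import (
    _irls,
    build_design_matrix,
    moment_dispersion,
)


def _design_n(n, n_geno=1):
    per = max(1, n // (n_geno * 2))
    d = mp.generate_design(n_geno, 1, per, 0, seed=0)
    return d.iloc[:n].reset_index(drop=True)


class TestFitNbGlm:
    def test_intercept_only_mean(self):
        d = _design_n(4)
        fit = mp.fit_nb_glm(np.array([3, 5, 7, 9]), d, (), phi=0.0)
        assert np.allclose(fit.fitted_means, 6.0, atol=1e-8)

    def test_poisson_deviance_closed_form(self):
        # phi = 0 deviance equals 2*sum[y log(y/mu) - (y - mu)]
        d = _design_n(6, n_geno=3)
        y = np.array([4.0, 7, 2, 9, 3, 8])
        fit = mp.fit_nb_glm(y, d, ("G",), phi=0.0)
        mu = fit.fitted_means
        direct = 2 * np.sum(np.where(y > 0, y * np.log(y / mu), 0) - (y - mu))
        assert fit.deviance == pytest.approx(direct, abs=1e-8)

    def test_saturated_design_zero_deviance(self):
        d = _design_n(8, n_geno=4)
        d = d.assign(genotype=[f"g{i}" for i in range(8)])  # one level per sample
        y = np.array([3.0, 8, 1, 9, 4, 6, 2, 7])
        fit = mp.fit_nb_glm(y, d, ("G",), phi=0.2)
        assert fit.deviance < 1e-6

    def test_matches_statsmodels_poisson_on_random_toys(self):
        rng = np.random.default_rng(10)
        d = _design_n(24, n_geno=4)
        X, _ = build_design_matrix(d, ("G", "S"))
        for _ in range(20):
            y = rng.poisson(rng.uniform(2, 50), size=24).astype(float)
            mine = mp.fit_nb_glm(y, d, ("G", "S"), phi=0.0)
            ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            assert mine.deviance == pytest.approx(ref.deviance, abs=1e-6)

    def test_matches_statsmodels_nb(self):
        rng = np.random.default_rng(11)
        d = _design_n(48, n_geno=4)
        X, _ = build_design_matrix(d, ("G", "S"))
        offset = rng.normal(0, 0.1, 48)
        y = rng.negative_binomial(5, 0.1, size=48).astype(float)
        beta, mu, dev, conv = _irls(y, X, offset, 0.2)
        ref = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=0.2), offset=offset
        ).fit()
        assert conv
        assert dev == pytest.approx(ref.deviance, abs=1e-6)
        assert np.allclose(beta, ref.params, atol=1e-6)

    def test_negative_phi_rejected(self):
        d = _design_n(4)
        with pytest.raises(ValueError):
            mp.fit_nb_glm(np.ones(4), d, (), phi=-0.1)


class TestEstimateDispersion:
    @pytest.fixture(scope="class")
    def design96(self):
        # 4 genotypes x 3 replicates x 2 sexes x 4 flies = 96 samples
        return mp.generate_design(4, 3, 4, 0, seed=0)

    def test_poisson_rows_estimate_near_zero(self, design96):
        rng = np.random.default_rng(20)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            y = rng.poisson(100, size=96).astype(float)
            if mp.estimate_dispersion(y, design96) < 0.05:
                hits += 1
        assert hits >= 0.95 * n_sim

    def test_nb_recovery(self, design96):
        rng = np.random.default_rng(21)
        r = 1 / 0.5
        est = []
        for _ in range(200):
            y = rng.negative_binomial(r, r / (r + 100), size=96).astype(float)
            est.append(mp.estimate_dispersion(y, design96))
        assert 0.4 <= np.median(est) <= 0.6

    def test_underdispersed_clamps_to_zero(self, design96):
        y = np.tile([10.0, 10, 10, 10], 24)  # zero variance in every cell
        assert mp.estimate_dispersion(y, design96) == 0.0

    def test_all_zero_row_raises(self, design96):
        with pytest.raises(ValueError):
            mp.estimate_dispersion(np.zeros(96), design96)

    def test_moment_estimator_clamped(self):
        cells = np.repeat([0, 1], 4)
        y = np.array([5.0, 5, 5, 5, 9, 9, 9, 9])  # under-dispersed
        assert moment_dispersion(y, cells) == 0.0


class TestLrtTerm:
    @pytest.fixture(scope="class")
    def fits(self):
        d = mp.generate_design(4, 2, 4, 0, seed=2)
        t = mp.generate_truth(1, {}, n_genotypes=4, n_replicates=2,
                              dispersion_range=(0.1, 0.1), seed=3)
        y, _ = mp.simulate_counts(d, t, seed=4)
        y = y.to_numpy(float)[0]
        full = mp.fit_nb_glm(y, d, ("S", "G", "R"), phi=0.1, gene_id="g")
        red = mp.fit_nb_glm(y, d, ("S", "R"), phi=0.1, gene_id="g")
        return full, red, y, d

    def test_equal_models_give_unit_p(self, fits):
        full = fits[0]
        tt = mp.lrt_term(full, full)
        assert tt.lrt_stat == 0.0 and tt.p_value == 1.0

    def test_df_is_parameter_difference(self, fits):
        full, red = fits[0], fits[1]
        tt = mp.lrt_term(full, red)
        assert tt.df == 3  # 4 genotypes -> 3 treatment contrasts
        assert tt.term == "G"
        assert tt.lrt_stat >= 0

    def test_non_nested_raises(self, fits):
        _, red, y, d = fits
        other = mp.fit_nb_glm(y, d, ("G",), phi=0.1)
        with pytest.raises(ValueError):
            mp.lrt_term(other, red)

    def test_mismatched_dispersion_raises(self, fits):
        full, red, y, d = fits
        red2 = mp.fit_nb_glm(y, d, ("S", "R"), phi=0.3)
        with pytest.raises(ValueError):
            mp.lrt_term(full, red2)

    def test_deviance_additivity(self, fits):
        _, _, y, d = fits
        a = mp.fit_nb_glm(y, d, ("S",), phi=0.1, gene_id="g")
        b = mp.fit_nb_glm(y, d, ("S", "G"), phi=0.1, gene_id="g")
        c = mp.fit_nb_glm(y, d, ("S", "G", "R"), phi=0.1, gene_id="g")
        lac = mp.lrt_term(c, a).lrt_stat
        lab = mp.lrt_term(b, a).lrt_stat
        lbc = mp.lrt_term(c, b).lrt_stat
        assert lac == pytest.approx(lab + lbc, abs=1e-6)

    def test_offset_invariance(self, fits):
        _, _, y, d = fits
        s = np.ones(len(y))
        for c in (1.0, 3.7):
            full = mp.fit_nb_glm(y, d, ("S", "G"), c * s, phi=0.1, gene_id="g")
            red = mp.fit_nb_glm(y, d, ("S",), c * s, phi=0.1, gene_id="g")
            stat = mp.lrt_term(full, red).lrt_stat
            if c == 1.0:
                base = stat
        assert stat == pytest.approx(base, abs=1e-6)


class TestBhFdr:
    def test_worked_example(self):
        q = mp.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert mp.bh_fdr([0.42])[0] == pytest.approx(0.42)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(30)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            q = mp.bh_fdr(p)
            # independent step-up definition: q(i) = min_{j >= i} p(j) * m / j
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            expect = np.empty(m)
            for pos, idx in enumerate(order):
                rank = pos + 1
                cands = [
                    p[order[j]] * m / (j + 1) for j in range(pos, m)
                ]
                expect[idx] = min(1.0, min(cands))
            assert np.allclose(q, expect)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(size=100)
        q = mp.bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_values_raise(self):
        with pytest.raises(ValueError):
            mp.bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            mp.bh_fdr([])
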
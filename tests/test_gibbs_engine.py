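"""Gibbs engine: assembly, chain bookkeeping, conjugate/GLS oracles,
posterior summaries, and the estimator façade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hetvar import data_prep as dp
from hetvar import gibbs_engine as ge
from hetvar import pedigree as pm
from .conftest import make_pedigree


def toy_matrices(y, cg=None, cov=None, animal=None, n_animals=0, pe=None, n_pe=0, mode="single"):
    n = len(y)
    cg = np.zeros(n, dtype=np.int64) if cg is None else np.asarray(cg, dtype=np.int64)
    n_cg = int(cg.max()) + 1
    cov = np.zeros((n, 0)) if cov is None else np.asarray(cov, dtype=float)
    animal = np.zeros(n, dtype=np.int64) if animal is None else np.asarray(animal, dtype=np.int64)
    pe = np.zeros(n, dtype=np.int64) if pe is None else np.asarray(pe, dtype=np.int64)
    return ge.ModelMatrices(
        y=np.asarray(y, dtype=float), cov=cov, cg=cg, n_cg=n_cg, cg_labels=list(range(n_cg)),
        animal=animal, n_animals=n_animals, animal_ids=list(range(n_animals)),
        pe=pe, n_pe=n_pe, pe_labels=list(range(n_pe)),
        trait=np.zeros(n, dtype=np.int64), mode=mode,
    )


class TestChainConfig:
    def test_retained_draw_identity(self):
        assert ge.ChainConfig(n_iter=300_000, burn_in=30_000, thin=10).n_retained == 27_000
        assert ge.ChainConfig(n_iter=1000, burn_in=100, thin=7).n_retained == (900) // 7

    def test_validation(self):
        with pytest.raises(ValueError):
            ge.ChainConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            ge.ChainConfig(thin=0)

    def test_kernel_retains_exactly_n_retained(self):
        cfg = ge.ChainConfig(n_iter=3001, burn_in=301, thin=7, seed=1, nu_e=0.0, s2_e=0.0)
        mm = toy_matrices(np.random.default_rng(0).normal(size=20))
        s = ge.gibbs_single(mm, None, cfg)
        assert s.n_retained == cfg.n_retained == len(s.vc)


class TestAssemble:
    def test_dimensions(self, small_dataset):
        res = dp.prepare(small_dataset.records, small_dataset.pedigree)
        rs = pm.renumber(small_dataset.pedigree)
        mm = ge.assemble(res.records, rs, mode="single")
        assert mm.n_records == len(res.records)
        assert mm.cov.shape == (mm.n_records, 3)
        assert mm.n_animals == rs.n_animals
        assert mm.n_pe == res.records["cow"].nunique()
        # age covariates centered
        assert abs(mm.cov[:, 0].mean()) < 1e-8
        assert abs(mm.cov[:, 1].mean()) < 1e-8

    def test_single_mode_ignores_classes(self, small_dataset):
        res = dp.prepare(small_dataset.records, small_dataset.pedigree)
        rs = pm.renumber(small_dataset.pedigree)
        a = ge.assemble(res.records, rs, mode="single")
        b = ge.assemble(res.records.drop(columns=["sd_class"]), rs, mode="single")
        assert np.array_equal(a.cg, b.cg) and np.array_equal(a.trait, b.trait)

    def test_two_trait_structure(self, small_dataset):
        res = dp.prepare(small_dataset.records, small_dataset.pedigree)
        rs = pm.renumber(small_dataset.pedigree)
        mm = ge.assemble(res.records, rs, mode="two_trait")
        # no contemporary group spans both traits; every cow in one trait
        for code in range(mm.n_cg):
            assert len(set(mm.trait[mm.cg == code])) == 1
        assert set(mm.pe_trait) <= {0, 1}

    def test_unprepared_records_rejected(self, small_dataset):
        rs = pm.renumber(small_dataset.pedigree)
        with pytest.raises(ValueError, match="not prepared"):
            ge.assemble(small_dataset.records, rs, mode="single")


class TestConjugateOracle:
    def test_residual_variance_matches_closed_form(self):
        """Mean-only model, flat priors: sigma2_e | y is scaled inv-chi2.

        The Gibbs marginal over (mu, sigma2_e) must match the closed-form
        Inv-chi2(n-1, s2) posterior; KS distance < 0.02 at 20,000 draws.
        """
        rng = np.random.default_rng(10)
        n = 200
        y = rng.normal(50.0, 3.0, n)
        mm = toy_matrices(y)
        cfg = ge.ChainConfig(
            n_iter=41_000, burn_in=1_000, thin=2, seed=9,
            nu_e=0.0, s2_e=0.0, group_moves=False,
        )
        s = ge.gibbs_single(mm, None, cfg)
        draws = s.vc["sigma2_e"].to_numpy()
        assert len(draws) == 20_000
        s2 = y.var(ddof=1)
        # sigma2 ~ (n-1) s2 / chi2_{n-1}  ==  InvGamma((n-1)/2, (n-1)s2/2)
        dist = stats.invgamma((n - 1) / 2, scale=(n - 1) * s2 / 2)
        ks = stats.kstest(draws, dist.cdf).statistic
        assert ks < 0.02

    def test_fixed_effect_posterior_matches_gls(self):
        """Known variances: posterior mean of b equals the GLS solution."""
        rng = np.random.default_rng(4)
        ped = make_pedigree([(1, 0, 0), (2, 0, 0)] + [(i, 1, 2) for i in range(3, 11)])
        rs = pm.renumber(ped)
        pm.compute_inbreeding(rs)
        ainv = pm.build_a_inverse(rs)
        s2a, s2p, s2e = 4.0, 2.0, 10.0
        n_cows = 8
        rows, cg, an, pe = [], [], [], []
        A = pm.build_a_tabular(rs)
        a_true = np.linalg.cholesky(s2a * A) @ rng.standard_normal(rs.n_animals)
        p_true = rng.normal(0, np.sqrt(s2p), n_cows)
        b_true = [5.0, -3.0]
        for c in range(n_cows):
            idx = rs.index[c + 3]
            for r in range(2):
                g = c % 2
                rows.append(b_true[g] + a_true[idx] + p_true[c] + rng.normal(0, np.sqrt(s2e)))
                cg.append(g)
                an.append(idx)
                pe.append(c)
        y = np.array(rows)
        mm = toy_matrices(y, cg=cg, animal=an, n_animals=rs.n_animals, pe=pe, n_pe=n_cows)
        cfg = ge.ChainConfig(n_iter=42_000, burn_in=2_000, thin=4, seed=2,
                             s2_a=s2a, s2_p=s2p, s2_e=s2e)
        s = ge.gibbs_single(mm, ainv, cfg, sample_variances=False, init=(s2a, s2p, s2e))
        b_post = s.b.mean(axis=0)[:2]
        # GLS oracle with V = Z A Z' s2a + W W' s2p + I s2e
        Z = np.zeros((len(y), rs.n_animals))
        Z[np.arange(len(y)), an] = 1
        W = np.zeros((len(y), n_cows))
        W[np.arange(len(y)), pe] = 1
        X = np.zeros((len(y), 2))
        X[np.arange(len(y)), cg] = 1
        V = s2a * Z @ A @ Z.T + s2p * W @ W.T + s2e * np.eye(len(y))
        Vi = np.linalg.inv(V)
        gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(b_post, gls, atol=0.12)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        mm = toy_matrices(rng.normal(size=30))
        cfg = ge.ChainConfig(n_iter=2000, burn_in=200, thin=5, seed=77, nu_e=0.0, s2_e=0.0)
        a = ge.gibbs_single(mm, None, cfg)
        b = ge.gibbs_single(mm, None, cfg)
        pd.testing.assert_frame_equal(a.vc, b.vc)


class TestGroupMoveInvariance:
    def test_single_trait_moves_preserve_posterior(self):
        """Chains with and without the scale moves target the same
        posterior: compare variance-component quantiles on a small model."""
        rng = np.random.default_rng(3)
        ped = make_pedigree(
            [(i, 0, 0) for i in range(1, 7)]
            + [(i, (i - 7) % 3 + 1, (i - 7) % 3 + 4) for i in range(7, 43)]
        )
        rs = pm.renumber(ped)
        pm.compute_inbreeding(rs)
        ainv = pm.build_a_inverse(rs)
        y, an, pe = [], [], []
        A = pm.build_a_tabular(rs)
        a_true = np.linalg.cholesky(4.0 * A + 1e-9 * np.eye(rs.n_animals)) @ rng.standard_normal(rs.n_animals)
        for c in range(36):
            idx = rs.index[c + 7]
            pc = rng.normal(0, np.sqrt(2.0))
            for _ in range(2):
                y.append(a_true[idx] + pc + rng.normal(0, 3.0))
                an.append(idx)
                pe.append(c)
        mm = toy_matrices(np.array(y), animal=an, n_animals=rs.n_animals, pe=pe, n_pe=36)
        qs = []
        for moves, n_iter in ((False, 400_000), (True, 100_000)):
            cfg = ge.ChainConfig(n_iter=n_iter, burn_in=n_iter // 10, thin=20, seed=8,
                                 group_moves=moves)
            s = ge.gibbs_single(mm, ainv, cfg)
            qs.append(np.percentile(s.vc, [10, 50, 90], axis=0))
        ref, test = qs
        assert np.allclose(ref, test, rtol=0.12)


class TestSummaries:
    def test_constant_chain(self):
        s = ge.summarize(np.full(500, 4.2))
        assert s.mean == pytest.approx(4.2) and s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.hpd95_low == s.hpd95_high == pytest.approx(4.2)

    def test_uniform_hpd_width(self):
        draws = np.random.default_rng(0).uniform(size=100_000)
        lo, hi = ge.hpd_interval(draws)
        assert (hi - lo) == pytest.approx(0.95, abs=0.01)

    def test_normal_hpd_quantiles(self):
        draws = np.random.default_rng(1).standard_normal(200_000)
        lo, hi = ge.hpd_interval(draws)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_matches_arviz_hdi(self):
        az = pytest.importorskip("arviz")
        draws = np.random.default_rng(2).gamma(2.0, 1.0, 50_000)
        lo, hi = ge.hpd_interval(draws)
        ref = az.hdi(draws, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            ge.summarize(np.ones(99))

    def test_hpd_mass_and_minimality_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(
            st.lists(st.floats(-1e6, 1e6), min_size=20, max_size=400),
            st.floats(0.5, 0.99),
        )
        def check(draws, mass):
            x = np.array(draws)
            lo, hi = ge.hpd_interval(x, mass)
            inside = ((x >= lo) & (x <= hi)).mean()
            assert inside >= mass - 1.0 / len(x) - 1e-12
            # endpoints are observed draws, so the interval cannot shrink
            assert np.isin(lo, x) and np.isin(hi, x)
            assert lo <= hi

        check()


class TestDeriveParameters:
    def test_published_ratio_single(self):
        vc = pd.DataFrame(
            {"sigma2_a": [2114.34], "sigma2_p": [5465.80], "sigma2_e": [16927.77]}
        )
        h2 = ge.heritability(vc["sigma2_a"], vc["sigma2_p"], vc["sigma2_e"]).iloc[0]
        rep = ge.repeatability(vc["sigma2_a"], vc["sigma2_p"], vc["sigma2_e"]).iloc[0]
        assert round(h2, 2) == 0.09
        # second published column: 6958.15/7829.34/26867.49 -> rep 0.35
        rep2 = ge.repeatability(6958.15, 7829.34, 26867.49)
        assert round(rep2, 2) == 0.35

    def test_zero_additive_variance(self):
        assert ge.heritability(0.0, 3.0, 7.0) == 0.0
        assert ge.repeatability(0.0, 3.0, 7.0) == pytest.approx(0.3)

    def test_h2_never_exceeds_rep(self):
        rng = np.random.default_rng(0)
        vc = pd.DataFrame(
            {
                "sigma2_a": rng.gamma(2, 100, 500),
                "sigma2_p": rng.gamma(2, 100, 500),
                "sigma2_e": rng.gamma(2, 100, 500),
            }
        )
        s = ge.GibbsSamples(vc=vc, a=np.zeros((500, 1, 1)), b=np.zeros((500, 1)),
                            p=np.zeros((500, 1)), mode="single",
                            config=ge.ChainConfig(), animal_ids=[1], pe_labels=[1])
        d = ge.derive_parameters(s)
        assert (d["draws"]["h2"] <= d["draws"]["rep"] + 1e-12).all()


class TestEstimatorFacade:
    def test_fit_sets_attributes_and_params_roundtrip(self, small_dataset):
        res = dp.prepare(small_dataset.records, small_dataset.pedigree)
        rs = pm.renumber(small_dataset.pedigree)
        pm.compute_inbreeding(rs)
        ainv = pm.build_a_inverse(rs)
        mm = ge.assemble(res.records, rs, mode="single")
        model = ge.GibbsAnimalModel(mode="single", n_iter=1500, burn_in=300, thin=4, seed=3)
        assert model.get_params()["n_iter"] == 1500
        model.set_params(n_iter=1200)
        model.fit(mm, ainv)
        assert model.n_retained_ == (1200 - 300) // 4
        assert model.ebv_.shape == (rs.n_animals, 1)
        assert (model.pev_ >= 0).all().all()
        with pytest.raises(ValueError, match="assembled for"):
            ge.GibbsAnimalModel(mode="two_trait").fit(mm, ainv)

    def test_predict_requires_fit(self):
        with pytest.raises(ValueError, match="not fitted"):
            ge.GibbsAnimalModel().predict()
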
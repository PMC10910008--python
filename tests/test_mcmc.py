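"""Sampler correctness: conjugate updates, determinism, DIC arithmetic,
prior recovery, and the estimator contract."""

import numpy as np
import pytest

import caninerx as cx
from caninerx.mcmc import MCMCConfig, PRESETS, _run_chain, precision_full_conditional

from conftest import make_pair_design, tiny_design


class TestConjugateUpdate:
    def test_closed_form(self):
        # J=100 effects with sum of squares 50 under Gamma(0.001, 0.001)
        u = np.zeros(100)
        u[0] = np.sqrt(50.0)
        shape, rate = precision_full_conditional(u, cx.PriorSpec())
        assert shape == pytest.approx(50.001, abs=1e-12)
        assert rate == pytest.approx(25.001, abs=1e-12)

    def test_general_algebra(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(17)
        prior = cx.PriorSpec(gamma_a=2.5, gamma_b=1.5)
        shape, rate = precision_full_conditional(u, prior)
        assert shape == pytest.approx(2.5 + 17 / 2)
        assert rate == pytest.approx(1.5 + (u**2).sum() / 2)


class TestProtocol:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(burn_in=-1)
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=50, thin=1)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)

    def test_paper_preset_retains_a_million(self):
        paper = PRESETS["paper"]
        assert paper.burn_in == 10_000
        assert paper.n_iter == 3_000_000
        assert paper.n_retained == 1_000_000

    def test_retained_draw_count(self, short_chain):
        chain, _, _ = short_chain
        assert chain.n_retained == chain.config.n_retained
        assert (chain.sigma_u2 > 0).all()
        assert 0 < chain.acceptance["beta"] < 1
        assert 0 < chain.acceptance["u"] < 1

    def test_determinism(self):
        design, truth = make_pair_design(seed=31, n_patients=200)
        spec = cx.ModelSpec(focal=truth.drugs[1])
        config = MCMCConfig(burn_in=200, n_iter=1000, thin=2, seed=5)
        a = cx.fit(design, spec, config)
        b = cx.fit(design, spec, config)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.sigma_u2, b.sigma_u2)
        np.testing.assert_array_equal(a.deviance, b.deviance)


class TestDIC:
    def test_identical_draws_have_zero_pd(self):
        d = tiny_design()
        beta = np.r_[0.2, -0.1, 0.3, 0.0]
        u = np.zeros(6)
        dev = -2 * cx.log_likelihood(beta, u, 1.0, d)
        chain = cx.ChainResult(
            labels=d.labels,
            beta=np.tile(beta, (200, 1)),
            sigma_u2=np.full(200, 0.5),
            deviance=np.full(200, dev),
            u_mean=u,
            acceptance={"beta": 0.5, "u": 0.5},
            dic=np.nan,
            pD=np.nan,
            config=MCMCConfig(burn_in=0, n_iter=200, thin=1),
            parameterization="normal",
        )
        dic_val, pd_val = cx.dic(chain, d)
        assert pd_val == pytest.approx(0.0, abs=1e-9)
        assert dic_val == pytest.approx(dev, abs=1e-9)

    def test_three_draw_hand_arithmetic(self):
        d = tiny_design(seed=1)
        betas = np.array(
            [[0.1, 0.0, 0.0, 0.0], [0.3, 0.2, 0.0, 0.0], [-0.1, 0.1, 0.1, 0.0]]
        )
        u = 0.1 * np.ones(6)
        devs = np.array(
            [-2 * cx.log_likelihood(b, u, 1.0, d) for b in betas]
        )
        chain = cx.ChainResult(
            labels=d.labels,
            beta=betas,
            sigma_u2=np.ones(3),
            deviance=devs,
            u_mean=u,
            acceptance={"beta": 0.5, "u": 0.5},
            dic=np.nan,
            pD=np.nan,
            config=MCMCConfig(burn_in=0, n_iter=300, thin=1),
            parameterization="normal",
        )
        dbar = devs.mean()
        dhat = -2 * cx.log_likelihood(betas.mean(axis=0), u, 1.0, d)
        dic_val, pd_val = cx.dic(chain, d)
        assert pd_val == pytest.approx(dbar - dhat, abs=1e-10)
        assert dic_val == pytest.approx(2 * dbar - dhat, abs=1e-10)

    def test_noise_column_increases_pd(self):
        # adding an uninformative covariate should cost effective parameters
        design, truth = make_pair_design(seed=41, n_patients=400)
        rng = np.random.default_rng(41)
        noisy = cx.PairedDesign(
            X=np.column_stack([design.X] + [rng.standard_normal(design.n) for _ in range(3)]),
            y=design.y,
            patient_index=design.patient_index,
            patients=design.patients,
            labels=design.labels + ("noise1", "noise2", "noise3"),
            focal=design.focal,
            reference=design.reference,
        )
        config = MCMCConfig(burn_in=500, n_iter=4000, thin=2, seed=3)
        spec = cx.ModelSpec(focal=truth.drugs[1])
        base = cx.fit(design, spec, config)
        bigger = cx.fit(noisy, spec, config)
        assert bigger.pD > base.pD - 2.0  # directional with MC noise allowance


class TestPriorOnlySampling:
    def test_recovers_prior_moments(self):
        # design with no observations: the chain must sample the prior
        d = cx.PairedDesign(
            X=np.empty((0, 2)),
            y=np.empty(0, dtype=np.int8),
            patient_index=np.empty(0, dtype=np.intp),
            patients=np.array([0]),
            labels=("a", "b"),
        )
        prior = cx.PriorSpec(beta_variance=1.0, gamma_a=3.0, gamma_b=3.0)
        chain = _run_chain(
            d, prior, MCMCConfig(burn_in=2000, n_iter=60_000, thin=2, seed=8)
        )
        assert abs(chain.beta.mean()) < 0.1
        assert abs(chain.beta.std() - 1.0) < 0.1


class TestCompareParameterizations:
    def test_report_contains_both_dics(self):
        design, truth = make_pair_design(seed=51, n_patients=250)
        spec = cx.ModelSpec(focal=truth.drugs[1])
        config = MCMCConfig(burn_in=300, n_iter=2000, thin=2, seed=2)
        report = cx.compare_parameterizations(design, spec, config)
        assert np.isfinite(report["normal"]["dic"])
        assert np.isfinite(report["orthogonal"]["dic"])
        assert report["selected"] in ("normal", "orthogonal")

    def test_orthogonal_mixes_better_with_collinear_covariates(self):
        # correlated raw covariates (weight, age, sqrt age share scale);
        # the orthogonal basis should not mix worse in the median
        wins = []
        for seed in range(5):
            design, truth = make_pair_design(seed=60 + seed, n_patients=250)
            spec = cx.ModelSpec(focal=truth.drugs[1])
            config = MCMCConfig(burn_in=400, n_iter=3000, thin=2, seed=seed)
            rep = cx.compare_parameterizations(design, spec, config)
            j = rep["chains"]["normal"].labels.index("weight_kg")
            e_n = cx.effective_sample_size(rep["chains"]["normal"].beta[:, j])
            e_o = cx.effective_sample_size(rep["chains"]["orthogonal"].beta[:, j])
            wins.append(e_o >= e_n)
        assert sum(wins) >= 3


class TestEstimator:
    def test_sklearn_contract_and_fit(self, short_chain):
        _, design, _ = short_chain
        est = cx.MultipleMembershipLogit(
            burn_in=200, n_iter=1000, thin=2, seed=0, parameterization="normal"
        )
        assert est.get_params()["burn_in"] == 200
        est.fit(design)
        assert est.coef_.shape == (design.X.shape[1],)
        assert est.sigma_u2_ > 0
        proba = est.predict_proba(design.X[:10])
        assert proba.shape == (10, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(design.X[:10])) <= {0, 1}

    def test_plain_arrays_with_groups(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(120), rng.standard_normal(120)])
        y = rng.integers(0, 2, 120)
        groups = rng.integers(0, 30, 120)
        est = cx.MultipleMembershipLogit(burn_in=100, n_iter=600, thin=2)
        est.fit(X, y, groups=groups)
        assert est.chain_.n_retained == 300

    def test_clone(self):
        from sklearn.base import clone

        est = clone(cx.MultipleMembershipLogit(n_iter=1234, thin=2))
        assert est.n_iter == 1234


def test_divergence_aborts_with_message():
    d = tiny_design()
    d.X[:, 1] = 1e200  # force non-finite linear predictor
    with pytest.raises((RuntimeError, ValueError)):
        _run_chain(d, cx.PriorSpec(), MCMCConfig(burn_in=10, n_iter=200, thin=1))
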
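"""Pair designs, likelihood/posterior oracles, and orthogonalization."""

import numpy as np
import pytest
from scipy.stats import bernoulli, gamma, norm

import caninerx as cx
from caninerx.design import DESIGN_COLUMNS

from conftest import manual_transactions, tiny_design


class TestBuildPairDataset:
    def _cohort(self):
        rows = (
            [{"drug": "cefovecin", "patient_id": f"A{i}", "age_y": 9.0} for i in range(151)]
            + [{"drug": "co-amoxiclav", "patient_id": f"B{i % 800}"} for i in range(16090)]
        )
        return manual_transactions(rows)

    def test_row_count_matches_case_counts(self):
        design = cx.build_pair_dataset(self._cohort(), "cefovecin")
        assert design.n == 16_241
        assert design.y.sum() == 151

    def test_organ_rows_sum_to_one(self, small_cohort):
        cohort, _, _ = small_cohort
        drugs = cohort["drug"].value_counts().index
        design = cx.build_pair_dataset(cohort, drugs[1], drugs[0])
        organ = [i for i, l in enumerate(design.labels) if l.startswith("w_")]
        np.testing.assert_allclose(design.X[:, organ].sum(axis=1), 1.0)

    def test_shared_flags_split_weights(self):
        rows = [
            {"drug": "cefovecin", "flag_gastrointestinal": True, "flag_respiratory": True},
            {"drug": "co-amoxiclav"},
        ]
        design = cx.build_pair_dataset(manual_transactions(rows), "cefovecin")
        i = list(design.labels)
        row = design.X[design.y == 1][0]
        assert row[i.index("w_gastrointestinal")] == 0.5
        assert row[i.index("w_respiratory")] == 0.5
        assert row[i.index("w_skin")] == 0.0

    def test_sqrt_age_column(self):
        design = cx.build_pair_dataset(self._cohort(), "cefovecin")
        i = list(design.labels)
        np.testing.assert_allclose(
            design.X[:, i.index("sqrt_age")],
            np.sqrt(design.X[:, i.index("age_y")]),
        )
        # age 9 rows have sqrt exactly 3
        nine = design.X[:, i.index("age_y")] == 9.0
        assert nine.any()
        assert (design.X[nine, i.index("sqrt_age")] == 3.0).all()

    def test_focal_equals_reference_error(self, small_cohort):
        cohort, _, _ = small_cohort
        with pytest.raises(ValueError):
            cx.build_pair_dataset(cohort, "co-amoxiclav", "co-amoxiclav")

    def test_missing_drug_error(self, small_cohort):
        cohort, _, _ = small_cohort
        sub = cohort[cohort["drug"] == "co-amoxiclav"]
        with pytest.raises(ValueError):
            cx.build_pair_dataset(sub, "cefovecin")

    def test_pair_subsets_partition_focal_rows(self, small_cohort):
        cohort, _, _ = small_cohort
        non_ref = cohort[cohort["drug"] != "co-amoxiclav"]
        total = 0
        for drug in non_ref["drug"].unique():
            d = cx.build_pair_dataset(cohort, drug)
            total += int(d.y.sum())
        assert total == len(non_ref)


class TestLogLikelihood:
    def test_zero_parameters_give_n_log_half(self):
        d = tiny_design()
        ll = cx.log_likelihood(np.zeros(4), np.zeros(6), 1.0, d)
        assert ll == pytest.approx(d.n * np.log(0.5), abs=1e-12)

    def test_matches_bernoulli_oracle(self):
        # independent oracle: per-row Bernoulli log-pmf summation
        for seed in range(5):
            d = tiny_design(seed=seed)
            rng = np.random.default_rng(100 + seed)
            beta = rng.standard_normal(4)
            u = rng.standard_normal(6)
            eta = d.X @ beta + u[d.patient_index]
            oracle = bernoulli.logpmf(d.y, 1.0 / (1.0 + np.exp(-eta))).sum()
            assert cx.log_likelihood(beta, u, 1.0, d) == pytest.approx(
                oracle, abs=1e-12
            )

    def test_saturated_limit_monotone_to_zero(self):
        d = tiny_design()
        d.y[:] = 1
        lls = [
            cx.log_likelihood(np.r_[c, 0, 0, 0], np.zeros(6), 1.0, d)
            for c in (2.0, 10.0, 30.0)
        ]
        assert lls[0] < lls[1] < lls[2] <= 0.0

    def test_extreme_eta_stable(self):
        d = tiny_design()
        ll = cx.log_likelihood(np.r_[700.0, 0, 0, 0], np.zeros(6), 1.0, d)
        assert np.isfinite(ll)

    def test_nonfinite_inputs_error(self):
        d = tiny_design()
        with pytest.raises(ValueError):
            cx.log_likelihood(np.r_[np.inf, 0, 0, 0], np.zeros(6), 1.0, d)

    def test_dimension_mismatch_error(self):
        d = tiny_design()
        with pytest.raises(ValueError):
            cx.log_likelihood(np.zeros(3), np.zeros(6), 1.0, d)


class TestLogPosterior:
    def test_matches_density_assembly_oracle(self):
        prior = cx.PriorSpec(beta_variance=4.0, gamma_a=2.0, gamma_b=3.0)
        for seed in range(3):
            d = tiny_design(seed=seed)
            rng = np.random.default_rng(seed)
            beta = rng.standard_normal(4)
            u = rng.standard_normal(6)
            s = 0.7
            oracle = (
                cx.log_likelihood(beta, u, s, d)
                + norm.logpdf(beta, scale=2.0).sum()
                + norm.logpdf(u, scale=s).sum()
                + gamma.logpdf(1 / s**2, 2.0, scale=1 / 3.0)
            )
            assert cx.log_posterior(beta, u, s, d, prior) == pytest.approx(
                oracle, abs=1e-12
            )

    def test_prior_shrinks_posterior(self):
        d = tiny_design()
        prior = cx.PriorSpec(beta_variance=1.0)
        base = np.zeros(4)
        lp0 = cx.log_posterior(base, np.zeros(6), 1.0, d, prior)
        big = base.copy()
        big[2] = 8.0
        # coefficient 2 multiplies a standard-normal column of a random
        # tiny design; the prior penalty dominates any likelihood gain
        assert cx.log_posterior(big, np.zeros(6), 1.0, d, prior) < lp0

    def test_finite_difference_gradient(self):
        d = tiny_design(seed=3)
        prior = cx.PriorSpec(beta_variance=2.0, gamma_a=1.5, gamma_b=1.5)
        rng = np.random.default_rng(9)
        beta = 0.3 * rng.standard_normal(4)
        u = 0.3 * rng.standard_normal(6)
        s = 0.8
        h = 1e-6
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            num = (
                cx.log_posterior(beta + e, u, s, d, prior)
                - cx.log_posterior(beta - e, u, s, d, prior)
            ) / (2 * h)
            # analytic gradient: X'(y - p) - beta/v
            eta = d.X @ beta + u[d.patient_index]
            p = 1 / (1 + np.exp(-eta))
            ana = d.X[:, j] @ (d.y - p) - beta[j] / 2.0
            assert num == pytest.approx(ana, abs=1e-4)


class TestOrthogonalize:
    def test_columns_mutually_orthogonal(self, small_cohort):
        cohort, _, _ = small_cohort
        drugs = cohort["drug"].value_counts().index
        design = cx.build_pair_dataset(
            cohort, drugs[1], drugs[0], drop_organ="unspecified"
        )
        orth, _ = cx.orthogonalize(design)
        G = orth.X.T @ orth.X
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(G)).max()
        # column norms preserved
        np.testing.assert_allclose(
            np.linalg.norm(orth.X, axis=0), np.linalg.norm(design.X, axis=0)
        )

    def test_rank_deficient_names_columns(self, small_cohort):
        cohort, _, _ = small_cohort
        drugs = cohort["drug"].value_counts().index
        full = cx.build_pair_dataset(cohort, drugs[1], drugs[0])
        with pytest.raises(ValueError, match="collinear"):
            cx.orthogonalize(full)

    def test_already_orthogonal_back_transform_is_identity(self):
        d = tiny_design()
        d.X = np.diag([1.0, 2.0, 3.0, 4.0]) @ np.eye(4)[:4]
        d.X = np.vstack([d.X] * 5)[: d.n]
        # build truly orthogonal columns
        X = np.zeros((d.n, 4))
        for j in range(4):
            X[j::4, j] = j + 1.0
        d.X = X
        orth, T = cx.orthogonalize(d)
        sign = np.sign(np.diag(T))
        np.testing.assert_allclose(np.abs(T), np.eye(4), atol=1e-12)
        np.testing.assert_allclose(orth.X * sign, d.X, atol=1e-12)

    def test_ml_fit_agrees_after_back_transform(self):
        import statsmodels.api as sm

        d = tiny_design(seed=4, n=200, p=4, n_patients=1)
        rng = np.random.default_rng(11)
        eta = d.X @ np.r_[0.3, -0.5, 0.8, 0.1]
        d.y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(np.int8)
        orth, T = cx.orthogonalize(d)
        b_norm = sm.Logit(d.y, d.X).fit(disp=0).params
        b_orth = sm.Logit(d.y, orth.X).fit(disp=0).params
        np.testing.assert_allclose(T @ b_orth, b_norm, atol=1e-6)

    def test_likelihood_invariant_under_back_transform(self):
        d = tiny_design(seed=5)
        orth, T = cx.orthogonalize(d)
        rng = np.random.default_rng(12)
        bp = rng.standard_normal(4)
        u = rng.standard_normal(6)
        assert cx.log_likelihood(bp, u, 1.0, orth) == pytest.approx(
            cx.log_likelihood(T @ bp, u, 1.0, d), abs=1e-9
        )


def test_design_columns_are_stable_api():
    assert DESIGN_COLUMNS[0] == "intercept"
    assert "sqrt_age" in DESIGN_COLUMNS
    assert len(DESIGN_COLUMNS) == 11
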
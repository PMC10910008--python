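"""Adaptive Metropolis-within-Gibbs sampler for the binomial contrast models.

One chain samples the posterior of a logistic regression with a patient
random intercept: the fixed-effect block β is updated by an adaptive
random-walk Metropolis step with an empirical-information proposal
(target acceptance ≈ 0.23 for the block), every patient effect u_j is
updated by a scalar random walk (target ≈ 0.44, all patients in one
vectorized sweep — they are conditionally independent given β and σ_u),
and the precision 1/σ_u² is drawn from its conjugate Gamma full
conditional. Proposal scales adapt only during burn-in, so the retained
chain is Markovian.

Sampling can run in the normal basis or in the orthogonalized fixed-effect
basis (which decorrelates the posterior and typically mixes better); in
the orthogonal case stored β draws are always back-transformed to the
original basis. Model fit is summarized by the deviance information
criterion DIC = D̄ + pD with pD = D̄ − D(θ̄).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .design import (
    ModelSpec,
    PairedDesign,
    PriorSpec,
    log_likelihood,
    orthogonalize,
)

__all__ = [
    "MCMCConfig",
    "ChainResult",
    "PRESETS",
    "precision_full_conditional",
    "fit",
    "dic",
    "compare_parameterizations",
    "MultipleMembershipLogit",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol: burn-in, total post-burn-in iterations, thinning.

    The full-scale protocol (preset ``"paper"``) is burn-in 10,000 with
    3,000,000 further iterations retaining 1,000,000 (thin 3); the default
    desk-scale protocol is burn-in 1,000 with 20,000 iterations retaining
    10,000 (thin 2).
    """

    burn_in: int = 1_000
    n_iter: int = 20_000
    thin: int = 2
    seed: int = 0
    adapt: bool = True

    def __post_init__(self):
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_iter // self.thin < 100:
            raise ValueError("n_iter/thin must be >= 100 retained draws")

    @property
    def n_retained(self) -> int:
        return self.n_iter // self.thin


PRESETS: dict[str, MCMCConfig] = {
    "test": MCMCConfig(burn_in=1_000, n_iter=20_000, thin=2),
    "paper": MCMCConfig(burn_in=10_000, n_iter=3_000_000, thin=3),
}


@dataclass
class ChainResult:
    """Retained draws and summaries from one chain.

    β draws are always in the original design basis regardless of the
    sampling parameterization. Patient-effect draws are summarized by their
    running posterior mean (``u_mean``) unless the sampler was asked to
    store them (``u``), since at full scale the J×draws array is enormous.
    """

    labels: tuple[str, ...]
    beta: np.ndarray  # (n_retained, p)
    sigma_u2: np.ndarray  # (n_retained,)
    deviance: np.ndarray  # (n_retained,)
    u_mean: np.ndarray  # (J,)
    acceptance: dict[str, float]
    dic: float
    pD: float
    config: MCMCConfig
    parameterization: str
    focal: str = ""
    reference: str = ""
    u: np.ndarray | None = None  # (n_retained, J) if stored

    @property
    def n_retained(self) -> int:
        return self.beta.shape[0]

    def coef_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)


def precision_full_conditional(
    u: np.ndarray, prior: PriorSpec
) -> tuple[float, float]:
    """Gamma full conditional (shape, rate) of the precision 1/σ_u².

    With J patient effects and a Gamma(a, b) prior, the full conditional is
    Gamma(a + J/2, b + Σu²/2).
    """
    u = np.asarray(u, dtype=float)
    return prior.gamma_a + len(u) / 2.0, prior.gamma_b + float(u @ u) / 2.0


def _row_ll(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y * eta - np.logaddexp(0.0, eta)


def _irls_init(
    X: np.ndarray, y: np.ndarray, v: float, n_steps: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-penalized logistic MLE and its covariance, for init/proposal."""
    n, p = X.shape
    beta = np.zeros(p)
    eye = np.eye(p) / v
    cov = np.linalg.inv(X.T @ X / 4.0 + eye) if n else v * np.eye(p)
    for _ in range(n_steps if n else 0):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu) + 1e-10
        H = (X * w[:, None]).T @ X + eye
        g = X.T @ (y - mu) - beta / v
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        cov = np.linalg.inv(H)
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta, cov


def _run_chain(
    design: PairedDesign,
    prior: PriorSpec,
    config: MCMCConfig,
    *,
    back_transform: np.ndarray | None = None,
    orig_labels: tuple[str, ...] | None = None,
    store_u: bool = False,
    target_accept_beta: float = 0.23,
    target_accept_u: float = 0.44,
) -> ChainResult:
    rng = np.random.default_rng(config.seed)
    X, y, idx = design.X, design.y.astype(float), design.patient_index
    n, p = X.shape
    J = design.n_patients
    v = prior.beta_variance

    beta, cov = _irls_init(X, y, v)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.diag(np.sqrt(np.abs(np.diag(cov))) + 1e-8)
    u = np.zeros(J)
    sigma2 = 0.25

    xb = X @ beta
    eta = xb + u[idx]
    row_ll = _row_ll(eta, y)
    pat_ll = np.bincount(idx, weights=row_ll, minlength=J)

    log_s_beta = np.log(2.4 / np.sqrt(max(p, 1)))
    log_s_u = np.zeros(J)

    n_ret = config.n_retained
    beta_draws = np.empty((n_ret, p))
    sigma2_draws = np.empty(n_ret)
    dev_draws = np.empty(n_ret)
    u_draws = np.empty((n_ret, J)) if store_u else None
    u_sum = np.zeros(J)
    acc_beta = 0
    acc_u = 0.0
    k = 0

    total = config.burn_in + config.n_iter
    for t in range(total):
        adapting = config.adapt and t < config.burn_in
        gamma = (t + 1) ** -0.6

        # --- fixed-effect block ---
        prop = beta + np.exp(log_s_beta) * (L @ rng.standard_normal(p))
        xb_prop = X @ prop
        row_prop = _row_ll(xb_prop + u[idx], y)
        delta = (
            row_prop.sum()
            - row_ll.sum()
            - 0.5 * (prop @ prop - beta @ beta) / v
        )
        if not np.isfinite(delta):
            raise RuntimeError(
                f"divergent deviance at iteration {t}: beta proposal {prop!r}"
            )
        if np.log(rng.random()) < delta:
            beta, xb, row_ll = prop, xb_prop, row_prop
            pat_ll = np.bincount(idx, weights=row_ll, minlength=J)
            accepted = 1.0
        else:
            accepted = 0.0
        if t >= config.burn_in:
            acc_beta += accepted
        if adapting:
            log_s_beta += gamma * (accepted - target_accept_beta)

        # --- patient effects, one vectorized sweep ---
        if J:
            u_prop = u + np.exp(log_s_u) * rng.standard_normal(J)
            row_prop = _row_ll(xb + u_prop[idx], y)
            pat_prop = np.bincount(idx, weights=row_prop, minlength=J)
            d = pat_prop - pat_ll - 0.5 * (u_prop**2 - u**2) / sigma2
            acc = np.log(rng.random(J)) < d
            if acc.any():
                u = np.where(acc, u_prop, u)
                rows = acc[idx]
                row_ll = np.where(rows, row_prop, row_ll)
                pat_ll = np.where(acc, pat_prop, pat_ll)
            if t >= config.burn_in:
                acc_u += acc.mean()
            if adapting:
                log_s_u += gamma * (acc - target_accept_u)

        # --- variance component, conjugate ---
        shape, rate = precision_full_conditional(u, prior)
        sigma2 = 1.0 / rng.gamma(shape, 1.0 / rate)

        if t >= config.burn_in and (t - config.burn_in) % config.thin == config.thin - 1:
            b_store = back_transform @ beta if back_transform is not None else beta
            beta_draws[k] = b_store
            sigma2_draws[k] = sigma2
            dev = -2.0 * row_ll.sum()
            if not np.isfinite(dev):
                raise RuntimeError(f"divergent deviance at iteration {t}")
            dev_draws[k] = dev
            u_sum += u
            if store_u:
                u_draws[k] = u
            k += 1

    u_mean = u_sum / max(k, 1)
    labels = orig_labels if orig_labels is not None else design.labels
    result = ChainResult(
        labels=tuple(labels),
        beta=beta_draws[:k],
        sigma_u2=sigma2_draws[:k],
        deviance=dev_draws[:k],
        u_mean=u_mean,
        acceptance={
            "beta": acc_beta / max(config.n_iter, 1),
            "u": float(acc_u / max(config.n_iter, 1)),
        },
        dic=np.nan,
        pD=np.nan,
        config=config,
        parameterization="orthogonal" if back_transform is not None else "normal",
        focal=design.focal,
        reference=design.reference,
        u=u_draws[:k] if store_u else None,
    )
    return result


def fit(
    design: PairedDesign,
    spec: ModelSpec | None = None,
    config: MCMCConfig | None = None,
    *,
    store_u: bool = False,
) -> ChainResult:
    """Fit one drug-vs-reference model by MCMC and attach its DIC.

    With ``spec.parameterization == "orthogonal"`` sampling runs in the
    orthogonalized basis and draws are back-transformed before storage.
    """
    config = config or MCMCConfig()
    prior = spec.prior if spec is not None else PriorSpec()
    parameterization = spec.parameterization if spec is not None else "orthogonal"
    if parameterization == "orthogonal":
        orth, T = orthogonalize(design)
        chain = _run_chain(
            orth,
            prior,
            config,
            back_transform=T,
            orig_labels=design.labels,
            store_u=store_u,
        )
    else:
        chain = _run_chain(design, prior, config, store_u=store_u)
    chain.dic, chain.pD = dic(chain, design)
    return chain


def dic(chain: ChainResult, design: PairedDesign) -> tuple[float, float]:
    """Deviance information criterion of a fitted chain.

    DIC = D̄ + pD where D̄ is the posterior mean deviance and
    pD = D̄ − D(θ̄) with θ̄ the posterior mean of (β, u).
    """
    if chain.n_retained == 0:
        raise ValueError("chain has no retained draws")
    dbar = float(chain.deviance.mean())
    dhat = -2.0 * log_likelihood(chain.coef_mean(), chain.u_mean, 1.0, design)
    pd_ = dbar - dhat
    return dbar + pd_, pd_


def compare_parameterizations(
    design: PairedDesign,
    spec: ModelSpec | None = None,
    config: MCMCConfig | None = None,
) -> dict:
    """Fit both parameterizations and choose by DIC (ESS breaks ties).

    Returns a report with both chains, both DICs, effective-sample-size
    summaries of the patient-level variance, and the selection; an exact
    DIC tie selects the orthogonal parameterization.
    """
    from .diagnostics import effective_sample_size

    config = config or MCMCConfig()
    prior = spec.prior if spec is not None else PriorSpec()
    report: dict = {}
    chains = {}
    for par in ("normal", "orthogonal"):
        s = ModelSpec(
            focal=design.focal or "focal",
            reference=design.reference or "ref",
            prior=prior,
            parameterization=par,
        ) if spec is None else replace_spec(spec, par)
        chains[par] = fit(design, s, config)
        report[par] = {
            "dic": chains[par].dic,
            "pD": chains[par].pD,
            "ess_sigma_u2": effective_sample_size(chains[par].sigma_u2),
        }
    if report["orthogonal"]["dic"] <= report["normal"]["dic"]:
        selected = "orthogonal"
    else:
        selected = "normal"
    if report["orthogonal"]["dic"] == report["normal"]["dic"]:
        selected = "orthogonal"
    report["selected"] = selected
    report["chains"] = chains
    return report


def replace_spec(spec: ModelSpec, parameterization: str) -> ModelSpec:
    return ModelSpec(
        focal=spec.focal,
        reference=spec.reference,
        prior=spec.prior,
        parameterization=parameterization,
    )


class MultipleMembershipLogit(BaseEstimator):
    """Bayesian logistic regression with a patient random intercept.

    Sklearn-style estimator wrapping the Metropolis-within-Gibbs sampler.
    ``fit`` accepts either a plain (X, y) pair with an optional ``groups``
    vector of patient identifiers, or a :class:`~caninerx.design.PairedDesign`
    as ``X``. Point predictions use posterior-mean coefficients with the
    population value (0) for unseen patients' random effects.

    Parameters
    ----------
    parameterization : {"orthogonal", "normal"}
        Basis in which the sampler runs; draws are always reported in the
        original basis.
    prior_beta_variance : float
        Variance v of the diffuse Normal(0, v) prior on each coefficient.
    gamma_a, gamma_b : float
        Shape/rate of the diffuse Gamma prior on the precision 1/σ_u².
    burn_in, n_iter, thin, seed : int
        Chain protocol (see :class:`MCMCConfig`).
    store_u : bool
        Keep the full patient-effect draw matrix (memory-heavy).

    Attributes
    ----------
    coef_ : ndarray (p,)
        Posterior-mean coefficients in the original basis.
    chain_ : ChainResult
        Full retained chain with deviance trace, DIC and acceptance rates.
    """

    def __init__(
        self,
        parameterization: str = "orthogonal",
        prior_beta_variance: float = 1e6,
        gamma_a: float = 0.001,
        gamma_b: float = 0.001,
        burn_in: int = 1_000,
        n_iter: int = 20_000,
        thin: int = 2,
        seed: int = 0,
        store_u: bool = False,
    ):
        self.parameterization = parameterization
        self.prior_beta_variance = prior_beta_variance
        self.gamma_a = gamma_a
        self.gamma_b = gamma_b
        self.burn_in = burn_in
        self.n_iter = n_iter
        self.thin = thin
        self.seed = seed
        self.store_u = store_u

    def _design(self, X, y, groups) -> PairedDesign:
        if isinstance(X, PairedDesign):
            return X
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(np.int8)
        if groups is None:
            groups = np.arange(len(y))
        patients, idx = np.unique(np.asarray(groups), return_inverse=True)
        return PairedDesign(
            X=X,
            y=y,
            patient_index=idx.astype(np.intp),
            patients=patients,
            labels=tuple(f"x{i}" for i in range(X.shape[1])),
        )

    def fit(self, X, y=None, groups=None):
        design = self._design(X, y, groups)
        prior = PriorSpec(self.prior_beta_variance, self.gamma_a, self.gamma_b)
        spec = ModelSpec(
            focal=design.focal or "focal",
            reference=design.reference or "reference",
            prior=prior,
            parameterization=self.parameterization,
        )
        config = MCMCConfig(
            burn_in=self.burn_in, n_iter=self.n_iter, thin=self.thin, seed=self.seed
        )
        self.chain_ = fit(design, spec, config, store_u=self.store_u)
        self.labels_ = self.chain_.labels
        self.coef_ = self.chain_.coef_mean()
        self.sigma_u2_ = float(self.chain_.sigma_u2.mean())
        self.dic_, self.pD_ = self.chain_.dic, self.chain_.pD
        self.patients_ = design.patients
        self.u_mean_ = self.chain_.u_mean
        self.n_features_in_ = design.X.shape[1]
        return self

    def predict_proba(self, X, groups=None) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "coef_")
        if isinstance(X, PairedDesign):
            X = X.X
        X = np.asarray(X, dtype=float)
        eta = X @ self.coef_
        if groups is not None:
            lut = {p: self.u_mean_[i] for i, p in enumerate(self.patients_)}
            eta = eta + np.array([lut.get(g, 0.0) for g in np.asarray(groups)])
        p1 = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X, groups=None) -> np.ndarray:
        return (self.predict_proba(X, groups)[:, 1] >= 0.5).astype(int)
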
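"""Design matrices, likelihood and priors for the binomial contrast models.

Because no software conveniently fits a multinomial random-effects model
with multiple-membership organ classifications, drug choice is decomposed
into a series of binomial models, each contrasting one focal antibiotic
against the reference category (co-amoxiclav, the most frequently
dispensed drug). Each model is a logistic regression with fixed effects
for weight, age, the square root of age (a polynomial term anticipating
non-monotone age preferences), sex, neutering status and the
membership-weighted organ-system columns, plus a patient-level random
intercept capturing within-dog correlation of repeated transactions.

Note the full design with an intercept *and* all five organ columns is
exactly collinear (the organ weights of every row sum to one); fitting
requires either dropping the intercept or absorbing one organ category
into it — see :func:`build_pair_dataset`'s ``drop_organ`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import membership_weights
from .vocab import ORGAN_CATEGORIES, REFERENCE_DRUG

__all__ = [
    "DESIGN_COLUMNS",
    "PairedDesign",
    "PriorSpec",
    "ModelSpec",
    "transaction_design",
    "build_pair_dataset",
    "log_likelihood",
    "log_posterior",
    "orthogonalize",
]

#: Fixed-effect columns of the full (rank-deficient) design, in order.
DESIGN_COLUMNS: tuple[str, ...] = (
    "intercept",
    "weight_kg",
    "age_y",
    "sqrt_age",
    "male",
    "neutered",
) + tuple(f"w_{c}" for c in ORGAN_CATEGORIES)


@dataclass
class PairedDesign:
    """Fixed-effect matrix and patient grouping for one drug-vs-reference model.

    Attributes
    ----------
    X : ndarray (n, p)
        Fixed-effect design; columns named in ``labels``.
    y : ndarray (n,)
        1 if the focal drug was dispensed, 0 for the reference.
    patient_index : ndarray (n,)
        Integer index of each row's patient into ``patients``.
    patients : ndarray (J,)
        Patient identifiers present in this subset.
    """

    X: np.ndarray
    y: np.ndarray
    patient_index: np.ndarray
    patients: np.ndarray
    labels: tuple[str, ...]
    focal: str = ""
    reference: str = REFERENCE_DRUG

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.labels))
        df["y"] = self.y
        df["patient_id"] = self.patients[self.patient_index]
        return df


@dataclass
class PriorSpec:
    """Diffuse priors: β ~ Normal(0, v) iid; precision 1/σ_u² ~ Gamma(a, b)."""

    beta_variance: float = 1e6
    gamma_a: float = 0.001
    gamma_b: float = 0.001

    def __post_init__(self):
        if self.beta_variance <= 0 or self.gamma_a <= 0 or self.gamma_b <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass
class ModelSpec:
    """What to fit: which contrast, with which priors and parameterization."""

    focal: str
    reference: str = REFERENCE_DRUG
    prior: PriorSpec = field(default_factory=PriorSpec)
    parameterization: str = "orthogonal"

    def __post_init__(self):
        if self.focal == self.reference:
            raise ValueError("focal drug must differ from the reference")
        if self.parameterization not in ("normal", "orthogonal"):
            raise ValueError("parameterization must be 'normal' or 'orthogonal'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "focal": self.focal,
                    "reference": self.reference,
                    "parameterization": self.parameterization,
                    "prior": self.prior.__dict__,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        prior = PriorSpec(**d.pop("prior", {}))
        return cls(prior=prior, **d)


def transaction_design(table: pd.DataFrame) -> pd.DataFrame:
    """Full fixed-effect design rows for every transaction in ``table``.

    Columns follow :data:`DESIGN_COLUMNS`; the five organ columns of each
    row sum to one by construction.
    """
    w = membership_weights(table)
    df = pd.DataFrame(
        {
            "intercept": 1.0,
            "weight_kg": table["weight_kg"].astype(float),
            "age_y": table["age_y"].astype(float),
            "sqrt_age": np.sqrt(table["age_y"].astype(float)),
            "male": (table["sex"] == "M").astype(float),
            "neutered": table["neutered"].astype(float),
        },
        index=table.index,
    )
    return pd.concat([df, w], axis=1)[list(DESIGN_COLUMNS)]


def build_pair_dataset(
    cohort: pd.DataFrame,
    focal: str,
    reference: str = REFERENCE_DRUG,
    *,
    drop_organ: str | None = None,
) -> PairedDesign:
    """Restrict the cohort to two drugs and build the binomial design.

    Parameters
    ----------
    drop_organ : str, optional
        Name of one organ category (e.g. ``"unspecified"``) to absorb into
        the intercept. The default keeps all five membership columns, which
        together with the intercept is rank-deficient; pass a category to
        obtain a full-rank design for fitting.
    """
    if focal == reference:
        raise ValueError("focal drug must differ from the reference")
    sub = cohort[cohort["drug"].isin([focal, reference])]
    if sub.empty:
        raise ValueError(f"no transactions for {focal!r} or {reference!r}")
    if not (sub["drug"] == focal).any() or not (sub["drug"] == reference).any():
        raise ValueError("both focal and reference drugs must appear in the cohort")

    Xdf = transaction_design(sub)
    if drop_organ is not None:
        col = f"w_{drop_organ}"
        if col not in Xdf.columns:
            raise ValueError(f"unknown organ category {drop_organ!r}")
        Xdf = Xdf.drop(columns=[col])
    y = (sub["drug"] == focal).to_numpy(dtype=np.int8)
    patients, patient_index = np.unique(sub["patient_id"].to_numpy(), return_inverse=True)
    return PairedDesign(
        X=np.ascontiguousarray(Xdf.to_numpy(dtype=float)),
        y=y,
        patient_index=patient_index.astype(np.intp),
        patients=patients,
        labels=tuple(Xdf.columns),
        focal=focal,
        reference=reference,
    )


def _linear_predictor(beta: np.ndarray, u: np.ndarray, design: PairedDesign) -> np.ndarray:
    return design.X @ beta + u[design.patient_index]


def log_likelihood(
    beta: np.ndarray, u: np.ndarray, sigma_u: float, design: PairedDesign
) -> float:
    """Binomial log-likelihood Σ yη − log(1 + e^η), η = x'β + u_patient.

    Stable for |η| up to ±700 via ``logaddexp``. ``sigma_u`` does not enter
    the likelihood (it is a prior parameter) but is accepted so the
    signature matches the posterior's.
    """
    beta = np.asarray(beta, dtype=float)
    u = np.asarray(u, dtype=float)
    if beta.shape != (design.X.shape[1],):
        raise ValueError(
            f"beta has length {beta.shape}, design has {design.X.shape[1]} columns"
        )
    if u.shape != (design.n_patients,):
        raise ValueError("u must have one entry per patient in the design")
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(u))):
        raise ValueError("non-finite parameter values")
    eta = _linear_predictor(beta, u, design)
    return float(np.sum(design.y * eta - np.logaddexp(0.0, eta)))


def log_posterior(
    beta: np.ndarray,
    u: np.ndarray,
    sigma_u: float,
    design: PairedDesign,
    prior: PriorSpec | None = None,
) -> float:
    """Unnormalized log posterior of (β, u, σ_u) for one contrast model.

    Adds to the likelihood: iid Normal(0, v) log-densities for β,
    Normal(0, σ_u²) for each patient effect, and the Gamma(a, b)
    log-density of the precision τ = 1/σ_u² (including the Jacobian-free
    convention of parameterizing the prior directly on τ).
    """
    prior = prior or PriorSpec()
    if sigma_u <= 0:
        raise ValueError("sigma_u must be positive")
    ll = log_likelihood(beta, u, sigma_u, design)
    beta = np.asarray(beta, dtype=float)
    u = np.asarray(u, dtype=float)
    v = prior.beta_variance
    lp_beta = -0.5 * np.sum(beta**2) / v - 0.5 * len(beta) * np.log(2 * np.pi * v)
    s2 = sigma_u**2
    lp_u = -0.5 * np.sum(u**2) / s2 - 0.5 * len(u) * np.log(2 * np.pi * s2)
    tau = 1.0 / s2
    a, b = prior.gamma_a, prior.gamma_b
    from scipy.stats import gamma as _gamma

    lp_tau = float(_gamma.logpdf(tau, a, scale=1.0 / b))
    return ll + lp_beta + lp_u + lp_tau


def orthogonalize(design: PairedDesign) -> tuple[PairedDesign, np.ndarray]:
    """Re-express the fixed-effect columns as mutually orthogonal ones.

    QR-style: X = Q R with Q orthonormal; the returned design uses
    X' = Q·diag(column norms of X), which preserves each column's norm, and
    the returned matrix ``T`` maps coefficients on X' back to the original
    basis (β = T β'), so X'β' = Xβ exactly. Columns are processed in input
    order.

    Raises
    ------
    ValueError
        If X is rank-deficient; the message names the collinear columns.
    """
    X = design.X
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = np.linalg.norm(X, axis=0)
    tol = max(n, p) * np.finfo(float).eps * max(scale.max(), 1.0)
    bad = diag <= tol
    if bad.any():
        names = [design.labels[i] for i in np.flatnonzero(bad)]
        raise ValueError(
            "design matrix is rank-deficient; collinear column(s): "
            + ", ".join(names)
            + " (hint: the intercept plus all five organ columns are exactly "
            "collinear — rebuild with drop_organ=...)"
        )
    Xp = Q * scale  # column i scaled to the norm of the original column i
    # beta = R^{-1} diag(scale) beta'
    T = np.linalg.solve(R, np.diag(scale))
    out = PairedDesign(
        X=np.ascontiguousarray(Xp),
        y=design.y,
        patient_index=design.patient_index,
        patients=design.patients,
        labels=tuple(f"orth_{l}" for l in design.labels),
        focal=design.focal,
        reference=design.reference,
    )
    return out, T
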
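"""Synthetic electronic-health-record generator for canine antibiotic dispensing.

Emulates a two-year first-opinion-practice transaction table: ~14k dogs,
~26k dispensing events across 13 antibiotics dominated by co-amoxiclav,
patient demographics matching the study population (weight mean 18.2 kg,
sd 11.6; age mean 7.1 y, sd 4.5; ~50% male, ~62% neutered), multi-label
organ-system keyword flags at their observed marginal prevalences, and
patient-level clustering of repeated prescriptions. Drug labels are drawn
from a forward multinomial-logit model whose ground-truth coefficients are
stored alongside the table, so downstream model fits can be scored against
truth. A separate injector appends records that trigger every data-quality
exclusion rule (missing weight, non-positive cost, impossible age or
weight).

Known simplifications: organ flags are independent Bernoullis (only the
marginal prevalences are emulated, not their co-occurrence), and costs and
dates are plumbing with no behavioural role.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.stats import truncnorm

from .design import DESIGN_COLUMNS, transaction_design
from .vocab import DRUGS, FLAG_COLUMNS, REFERENCE_DRUG

__all__ = [
    "ConfigError",
    "PopulationConfig",
    "TrueModel",
    "default_true_model",
    "sample_patients",
    "sample_transactions",
    "assign_drugs",
    "calibrate_intercepts",
    "inject_exclusion_artifacts",
    "generate_study",
    "save_truth",
    "load_truth",
    "TARGET_SHARES",
]


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


#: Observed per-drug share of transactions (case counts / total cases),
#: the default calibration target for simulated drug shares.
TARGET_SHARES: dict[str, float] = {
    "amoxicillin": 109 / 26087,
    "cefovecin": 151 / 26087,
    "cephalexin": 1354 / 26087,
    "clindamycin": 2484 / 26087,
    "co-amoxiclav": 16090 / 26087,
    "doxycycline": 724 / 26087,
    "enrofloxacin": 465 / 26087,
    "erythromycin": 183 / 26087,
    "marbofloxacin": 538 / 26087,
    "metronidazole": 3716 / 26087,
    "oxytetracycline": 68 / 26087,
    "pradofloxacin": 80 / 26087,
    "trimethoprim-sulfonamide": 125 / 26087,
}

# Per-unit-covariate odds ratios of dispensing each drug versus the
# reference, used to seed the default ground-truth model. Order:
# weight_kg, age_y, sqrt_age, male, neutered, GI, resp, urinary, skin,
# unspecified.
_DEFAULT_ORS: dict[str, tuple[float, ...]] = {
    "amoxicillin": (1.13, 0.69, 11.85, 0.47, 0.37, 0.91, 0.62, 1.25, 0.98, 1.43),
    "cefovecin": (0.84, 1.34, 1.00, 1.04, 1.43, 2.42, 0.99, 0.42, 1.08, 0.92),
    "cephalexin": (1.01, 0.71, 4.77, 1.44, 0.85, 0.26, 1.06, 0.60, 7.08, 1.42),
    "clindamycin": (0.96, 0.69, 14.44, 1.75, 1.45, 1.19, 0.82, 0.17, 1.52, 4.33),
    "doxycycline": (0.94, 0.96, 1.44, 2.13, 1.07, 0.33, 12.72, 0.22, 0.71, 1.78),
    "enrofloxacin": (1.00, 1.02, 1.72, 1.19, 0.52, 1.12, 2.60, 0.87, 0.56, 0.71),
    "erythromycin": (1.05, 2.09, 0.01, 0.95, 1.27, 194.42, 0.02, 0.05, 0.68, 10.36),
    "marbofloxacin": (1.02, 0.86, 3.82, 0.96, 1.02, 0.59, 0.95, 0.96, 1.08, 1.73),
    "metronidazole": (1.01, 1.22, 0.37, 1.35, 1.54, 79.20, 0.73, 0.13, 0.20, 0.46),
    "oxytetracycline": (1.0,) * 10,
    "pradofloxacin": (0.96, 0.68, 12.22, 0.96, 2.18, 0.26, 0.97, 0.36, 3.43, 3.17),
    "trimethoprim-sulfonamide": (1.05, 1.77, 0.06, 1.77, 0.96, 0.94, 1.10, 1.00, 0.94, 1.03),
}
_OR_ORDER = (
    "weight_kg", "age_y", "sqrt_age", "male", "neutered",
    "w_gastrointestinal", "w_respiratory", "w_urinary", "w_skin", "w_unspecified",
)


@dataclass
class PopulationConfig:
    """Study-population parameters for the generator.

    Defaults reproduce the analysed population's marginal moments: weight
    18.2 (11.6) kg, age 7.1 (4.5) years, 50.5% male, 61.7% neutered, 1.5%
    unknown sex, mean 1.8 prescriptions per dog, and organ-flag marginal
    prevalences (GI 28.9%, respiratory 25.7%, urinary 18.6%, skin 56.0%).
    """

    n_patients: int = 14_259
    weight_mean_kg: float = 18.2
    weight_sd_kg: float = 11.6
    age_mean_y: float = 7.1
    age_sd_y: float = 4.5
    age_max_y: float = 25.0
    p_male: float = 0.505
    p_neutered: float = 0.617
    p_sex_unknown: float = 0.015
    txn_mean_per_patient: float = 1.8
    organ_flag_probs: tuple[float, float, float, float] = (0.289, 0.257, 0.186, 0.560)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in ("weight_mean_kg", "weight_sd_kg", "age_mean_y", "age_sd_y"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("p_male", "p_neutered", "p_sex_unknown"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.p_male + self.p_sex_unknown > 1:
            raise ConfigError("p_male + p_sex_unknown must not exceed 1")
        if self.txn_mean_per_patient < 1:
            raise ConfigError("txn_mean_per_patient must be >= 1")
        self.organ_flag_probs = tuple(float(p) for p in self.organ_flag_probs)
        if len(self.organ_flag_probs) != 4 or not all(
            0 <= p <= 1 for p in self.organ_flag_probs
        ):
            raise ConfigError("organ_flag_probs must be four probabilities")

    @classmethod
    def from_file(cls, path: str | Path) -> "PopulationConfig":
        """Load a config from YAML or JSON."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class TrueModel:
    """Ground-truth forward model for drug assignment.

    ``beta[d]`` is the coefficient vector of drug *d* over
    :data:`~caninerx.design.DESIGN_COLUMNS`; the reference drug must carry
    all-zero coefficients (multinomial-logit identification). ``sigma_u[d]``
    is the patient random-intercept standard deviation of contrast *d*.
    """

    drugs: tuple[str, ...] = DRUGS
    reference: str = REFERENCE_DRUG
    beta: dict[str, np.ndarray] = field(default_factory=dict)
    sigma_u: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.drugs = tuple(self.drugs)
        if self.reference not in self.drugs:
            raise ConfigError("reference drug must be in the drug list")
        p = len(DESIGN_COLUMNS)
        for d in self.drugs:
            self.beta.setdefault(d, np.zeros(p))
            self.beta[d] = np.asarray(self.beta[d], dtype=float)
            if self.beta[d].shape != (p,):
                raise ConfigError(
                    f"beta[{d!r}] must have length {p} (design columns)"
                )
            self.sigma_u.setdefault(d, 0.0)
            if self.sigma_u[d] < 0:
                raise ConfigError(f"sigma_u[{d!r}] must be >= 0")
        if np.any(self.beta[self.reference] != 0) or self.sigma_u[self.reference] != 0:
            raise ConfigError("reference drug must carry all-zero coefficients")

    def coef(self, drug: str, column: str) -> float:
        return float(self.beta[drug][DESIGN_COLUMNS.index(column)])

    def set_coef(self, drug: str, column: str, value: float) -> None:
        self.beta[drug][DESIGN_COLUMNS.index(column)] = value


def default_true_model(sigma_u: float = 0.5) -> TrueModel:
    """Ground truth seeded from the study's reported per-covariate odds ratios.

    Intercepts start at the log of each drug's observed share relative to
    the reference and should be refined with :func:`calibrate_intercepts`
    (``generate_study`` does this automatically) so simulated shares match
    the observed prescription shares.
    """
    beta = {}
    sig = {}
    for d in DRUGS:
        b = np.zeros(len(DESIGN_COLUMNS))
        if d != REFERENCE_DRUG:
            for col, orv in zip(_OR_ORDER, _DEFAULT_ORS[d]):
                b[DESIGN_COLUMNS.index(col)] = np.log(orv)
            b[0] = np.log(TARGET_SHARES[d] / TARGET_SHARES[REFERENCE_DRUG])
            sig[d] = sigma_u
        else:
            sig[d] = 0.0
        beta[d] = b
    return TrueModel(drugs=DRUGS, reference=REFERENCE_DRUG, beta=beta, sigma_u=sig)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _truncnorm_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Location/scale of a normal truncated to (lo, hi) with given moments.

    The naive choice loc=mean, scale=sd would bias the realized mean by the
    truncation at ``lo``; solve the two-moment system instead.
    """

    def resid(x):
        loc, log_scale = x
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"truncated-normal moment match failed: {sol.message}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def sample_patients(cfg: PopulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the patient table: id, sex, neuter status, weight, age.

    Weight is log-normal (strictly positive) and age truncated-normal on
    (0, ``age_max_y``], both parameterized so the *realized* distribution
    has exactly the configured mean and sd. Deterministic given the seed.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    mu, sigma = _lognormal_params(cfg.weight_mean_kg, cfg.weight_sd_kg)
    weight = rng.lognormal(mu, sigma, size=n)
    loc, scale = _truncnorm_params(cfg.age_mean_y, cfg.age_sd_y, 0.0, cfg.age_max_y)
    a, b = (0.0 - loc) / scale, (cfg.age_max_y - loc) / scale
    age = truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    p_f = 1.0 - cfg.p_male - cfg.p_sex_unknown
    sex = rng.choice(["M", "F", "unknown"], size=n, p=[cfg.p_male, p_f, cfg.p_sex_unknown])
    neutered = rng.random(n) < cfg.p_neutered
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "neutered": neutered,
            "weight_kg": np.round(weight, 2),
            "age_y": np.round(age, 2),
        }
    )


def sample_transactions(
    patients: pd.DataFrame,
    cfg: PopulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw unlabeled dispensing events for each patient.

    Per-patient transaction counts are zero-truncated geometric with
    success probability 1/mean (mean exactly ``txn_mean_per_patient``,
    about 56% of dogs with a single prescription and 96% with four or
    fewer at the default mean of 1.8). Each transaction gets independent
    organ-system flags at the configured marginal prevalences, a date
    uniform over the two-year study window, and a positive cost.
    """
    if patients.empty:
        raise ValueError("patients table is empty")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    counts = rng.geometric(1.0 / cfg.txn_mean_per_patient, size=len(patients))
    idx = np.repeat(np.arange(len(patients)), counts)
    n = len(idx)
    txn = patients.iloc[idx].reset_index(drop=True)
    txn.insert(0, "txn_id", [f"T{i:06d}" for i in range(n)])
    start = np.datetime64("2020-02-01")
    txn["date"] = start + rng.integers(0, 730, size=n).astype("timedelta64[D]")
    txn["quantity"] = rng.integers(1, 57, size=n)
    txn["cost"] = np.round(rng.lognormal(np.log(25.0), 0.6, size=n), 2)
    for col, p in zip(FLAG_COLUMNS, cfg.organ_flag_probs):
        txn[col] = rng.random(n) < p
    return txn


def _eta_matrix(
    X: np.ndarray,
    patient_codes: np.ndarray,
    truth: TrueModel,
    u: np.ndarray,
) -> np.ndarray:
    B = np.column_stack([truth.beta[d] for d in truth.drugs])
    return X @ B + u[patient_codes]


def _draw_patient_effects(
    n_patients: int, truth: TrueModel, rng: np.random.Generator
) -> np.ndarray:
    sig = np.array([truth.sigma_u[d] for d in truth.drugs])
    return rng.standard_normal((n_patients, len(truth.drugs))) * sig


def assign_drugs(
    transactions: pd.DataFrame,
    truth: TrueModel,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Label each transaction with a drug from the forward choice model.

    Drug *d* is drawn with probability
    exp(x'β_d + u_{jd}) / Σ_{d'} exp(x'β_{d'} + u_{jd'}), where x is the
    transaction's design row (intercept, weight, age, √age, sex, neuter
    status and the five membership-weighted organ columns) and u_{jd} is a
    per-patient, per-contrast Normal(0, σ_{u,d}²) effect. Sampling uses the
    Gumbel-max trick, vectorized over transactions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = transaction_design(transactions).to_numpy(dtype=float)
    patients, codes = np.unique(transactions["patient_id"].to_numpy(), return_inverse=True)
    u = _draw_patient_effects(len(patients), truth, rng)
    eta = _eta_matrix(X, codes, truth, u)
    gumbel = rng.gumbel(size=eta.shape)
    choice = np.argmax(eta + gumbel, axis=1)
    out = transactions.copy()
    out["drug"] = np.asarray(truth.drugs, dtype=object)[choice]
    return out


def calibrate_intercepts(
    truth: TrueModel,
    transactions: pd.DataFrame,
    target_shares: dict[str, float] | None = None,
    seed: int = 0,
    n_rounds: int = 40,
) -> TrueModel:
    """Adjust non-reference intercepts so expected drug shares hit targets.

    Iterative proportional fitting on the log scale: each round updates
    every non-reference intercept by log(target/current expected share),
    with expectations over the given transactions and one draw of patient
    effects. Returns a new ground-truth model.
    """
    target_shares = target_shares or TARGET_SHARES
    rng = np.random.default_rng(seed)
    X = transaction_design(transactions).to_numpy(dtype=float)
    patients, codes = np.unique(transactions["patient_id"].to_numpy(), return_inverse=True)
    u = _draw_patient_effects(len(patients), truth, rng)
    beta = {d: truth.beta[d].copy() for d in truth.drugs}
    new = TrueModel(truth.drugs, truth.reference, beta, dict(truth.sigma_u))
    t = np.array([target_shares[d] for d in new.drugs])
    t = t / t.sum()
    for _ in range(n_rounds):
        eta = _eta_matrix(X, codes, new, u)
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        share = P.mean(axis=0)
        adj = np.log(t / share)
        for i, d in enumerate(new.drugs):
            if d != new.reference:
                new.beta[d][0] += adj[i] - adj[list(new.drugs).index(new.reference)]
        if np.max(np.abs(adj - adj[list(new.drugs).index(new.reference)])) < 1e-6:
            break
    return new


_ARTIFACT_RULES = (
    "missing_weight",
    "zero_cost",
    "negative_cost",
    "implausible_age",
    "implausible_weight",
)


def inject_exclusion_artifacts(
    table: pd.DataFrame, seed: int = 0, n_per_rule: int = 3
) -> tuple[pd.DataFrame, int]:
    """Append rows that each trigger one data-quality exclusion rule.

    Rules covered: missing body weight; zero cost; negative cost (refund);
    recorded age in the impossible 119–121 y band; an impossible 145 kg
    body weight. Injected rows are marked in an ``artifact_rule`` column
    (empty for genuine rows) and returned appended to the input; the second
    return value is the number injected. ``n_per_rule=0`` returns the table
    unchanged.
    """
    out = table.copy()
    if "artifact_rule" not in out.columns:
        out["artifact_rule"] = ""
    if n_per_rule == 0:
        return out, 0
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for rule in _ARTIFACT_RULES:
        for i in range(n_per_rule):
            row = {
                "txn_id": f"A{k:04d}",
                "patient_id": f"ART{k:04d}",
                "sex": "F",
                "neutered": False,
                "weight_kg": 12.0,
                "age_y": 5.0,
                "date": pd.Timestamp("2021-01-01"),
                "quantity": 7,
                "cost": 20.0,
                **{c: False for c in FLAG_COLUMNS},
                "drug": REFERENCE_DRUG,
                "artifact_rule": rule,
            }
            if rule == "missing_weight":
                row["weight_kg"] = np.nan
            elif rule == "zero_cost":
                row["cost"] = 0.0
            elif rule == "negative_cost":
                row["cost"] = -float(np.round(rng.uniform(1, 30), 2))
            elif rule == "implausible_age":
                row["age_y"] = float(rng.integers(119, 122))
            elif rule == "implausible_weight":
                row["weight_kg"] = 145.0
            rows.append(row)
            k += 1
    art = pd.DataFrame(rows)
    out = pd.concat([out, art[out.columns.intersection(art.columns)]], ignore_index=True)
    return out, len(rows)


def save_truth(truth: TrueModel, path: str | Path) -> None:
    """Write the ground-truth sidecar JSON next to a generated table."""
    payload = {
        "drugs": list(truth.drugs),
        "reference": truth.reference,
        "design_columns": list(DESIGN_COLUMNS),
        "beta": {d: truth.beta[d].tolist() for d in truth.drugs},
        "sigma_u": {d: float(truth.sigma_u[d]) for d in truth.drugs},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_truth(path: str | Path) -> TrueModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ground-truth sidecar not found: {path}")
    d = json.loads(path.read_text())
    return TrueModel(
        drugs=tuple(d["drugs"]),
        reference=d["reference"],
        beta={k: np.asarray(v) for k, v in d["beta"].items()},
        sigma_u=d["sigma_u"],
    )


def generate_study(
    cfg: PopulationConfig | None = None,
    truth: TrueModel | None = None,
    *,
    calibrate: bool = True,
    n_artifacts_per_rule: int = 3,
) -> tuple[pd.DataFrame, TrueModel]:
    """One-call generation: patients → transactions → drugs → artifacts.

    Returns the labeled transaction table (with injected bad rows flagged
    in ``artifact_rule``) and the ground-truth model actually used.
    """
    cfg = cfg or PopulationConfig()
    rng = np.random.default_rng(cfg.seed)
    patients = sample_patients(cfg, rng)
    txns = sample_transactions(patients, cfg, rng)
    truth = truth or default_true_model()
    if calibrate:
        truth = calibrate_intercepts(truth, txns, seed=cfg.seed)
    labeled = assign_drugs(txns, truth, rng)
    labeled, _ = inject_exclusion_artifacts(labeled, seed=cfg.seed, n_per_rule=n_artifacts_per_rule)
    return labeled, truth
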
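"""Transaction-table I/O, study exclusion rules, and multiple-membership weights.

A transaction is one antibiotic dispensing event for one dog. Each
transaction may reference zero or more of four major organ systems
(gastrointestinal, respiratory, urinary, skin) via keyword flags from the
clinical notes; the multiple-membership weight of each referenced system is
the reciprocal of the number of systems referenced, so the weights of every
transaction sum to one. Transactions with no flag belong wholly to the
"unspecified" category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .vocab import DRUGS, FLAG_COLUMNS, ORGAN_CATEGORIES, REQUIRED_COLUMNS

__all__ = [
    "SchemaError",
    "EmptyCohortError",
    "ExclusionReport",
    "ReadResult",
    "read_transactions",
    "write_transactions",
    "apply_exclusions",
    "mm_weights",
    "membership_weights",
    "CohortFilter",
]


class SchemaError(ValueError):
    """The input table does not match the documented transaction schema."""


class EmptyCohortError(ValueError):
    """Every row was removed by the exclusion rules."""


#: Exclusion rules in the order they are applied.
EXCLUSION_RULES = (
    "missing_weight",
    "nonpositive_cost",
    "implausible_age",
    "implausible_weight",
    "sex_unknown",
    "rare_drug",
)


@dataclass
class ExclusionReport:
    """Tally of rows removed by each exclusion rule.

    ``retained + sum(excluded.values())`` always equals ``input_rows``.
    """

    input_rows: int = 0
    excluded: dict[str, int] = field(default_factory=dict)
    dropped_drugs: list[str] = field(default_factory=list)
    retained_transactions: int = 0
    retained_patients: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    def check(self) -> None:
        total = self.retained_transactions + sum(self.excluded.values())
        if total != self.input_rows:
            raise AssertionError(
                f"exclusion counts do not reconcile: {total} != {self.input_rows}"
            )


class ReadResult(NamedTuple):
    table: pd.DataFrame
    rejects: pd.DataFrame  # offending rows with a 'reject_reason' column


def read_transactions(path: str | Path, *, drugs: tuple[str, ...] = DRUGS) -> ReadResult:
    """Read a transaction CSV, typing columns and collecting bad rows.

    Rows whose drug is outside the vocabulary, or whose numeric fields do
    not parse, are moved to the ``rejects`` table with a reason rather than
    silently dropped.

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype={"patient_id": str, "drug": str, "sex": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    reasons = pd.Series("", index=raw.index, dtype=str)
    bad_drug = ~raw["drug"].isin(drugs)
    reasons[bad_drug] = "drug not in vocabulary"
    for col in ("age_y", "cost", "quantity", "weight_kg"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        # missing weight is legal on input (an exclusion rule handles it)
        unparseable = vals.isna() & raw[col].notna() if col == "weight_kg" else (
            vals.isna() & (reasons == "")
        )
        if col != "weight_kg":
            reasons[unparseable & (reasons == "")] = f"unparseable {col}"
        raw[col] = vals
    raw["date"] = pd.to_datetime(raw["date"], errors="coerce")
    reasons[raw["date"].isna() & (reasons == "")] = "unparseable date"
    raw["neutered"] = raw["neutered"].astype(bool)
    for col in FLAG_COLUMNS:
        raw[col] = raw[col].astype(int).astype(bool)

    ok = reasons == ""
    rejects = raw[~ok].copy()
    rejects["reject_reason"] = reasons[~ok]
    return ReadResult(raw[ok].reset_index(drop=True), rejects.reset_index(drop=True))


def write_transactions(table: pd.DataFrame, path: str | Path) -> None:
    """Write a transaction table as CSV with ISO-8601 dates."""
    out = table.copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    for col in FLAG_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def apply_exclusions(
    table: pd.DataFrame,
    *,
    max_age: float = 25.0,
    max_weight: float = 100.0,
    min_patients_per_drug: int = 10,
    keep_unknown_sex: bool = False,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the study's exclusion rules in order and tally each.

    Rules, in order: missing body weight; cost zero or negative (free
    replacement or refund); implausible age (> ``max_age``); implausible
    weight (> ``max_weight``); sex recorded as unknown (skipped when
    ``keep_unknown_sex`` for descriptives-only use); finally every drug
    dispensed to fewer than ``min_patients_per_drug`` unique patients is
    dropped, since so few patients cannot support individual random effects.

    Raises
    ------
    EmptyCohortError
        If nothing survives the filters.
    """
    report = ExclusionReport(input_rows=len(table))
    df = table

    masks = {
        "missing_weight": df["weight_kg"].isna(),
        "nonpositive_cost": lambda d: d["cost"] <= 0,
        "implausible_age": lambda d: d["age_y"] > max_age,
        "implausible_weight": lambda d: d["weight_kg"] > max_weight,
        "sex_unknown": lambda d: ~d["sex"].isin(["F", "M"]),
    }
    for rule, mask in masks.items():
        if rule == "sex_unknown" and keep_unknown_sex:
            report.excluded[rule] = 0
            continue
        m = mask if isinstance(mask, pd.Series) else mask(df)
        report.excluded[rule] = int(m.sum())
        df = df[~m]

    per_drug = df.groupby("drug")["patient_id"].nunique()
    rare = per_drug[per_drug < min_patients_per_drug].index.tolist()
    rare_mask = df["drug"].isin(rare)
    report.excluded["rare_drug"] = int(rare_mask.sum())
    report.dropped_drugs = sorted(rare)
    df = df[~rare_mask].reset_index(drop=True)

    if df.empty:
        raise EmptyCohortError("all rows removed by exclusion rules")
    report.retained_transactions = len(df)
    report.retained_patients = int(df["patient_id"].nunique())
    report.check()
    return df, report


def mm_weights(flags) -> np.ndarray:
    """Multiple-membership weights for one transaction.

    Parameters
    ----------
    flags : sequence of 4 booleans
        Presence of (gastrointestinal, respiratory, urinary, skin) keywords.

    Returns
    -------
    ndarray of shape (5,)
        Weights over (gastrointestinal, respiratory, urinary, skin,
        unspecified). Each referenced system gets 1/k where k is the number
        referenced; if none is referenced the unspecified category gets
        weight 1. Weights always sum to exactly 1.
    """
    f = np.asarray(flags, dtype=bool)
    if f.shape != (4,):
        raise ValueError("flags must be a sequence of four booleans")
    k = int(f.sum())
    w = np.zeros(5)
    if k == 0:
        w[4] = 1.0
    else:
        w[:4][f] = 1.0 / k
    return w


def membership_weights(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`mm_weights` over a transaction table.

    Returns a frame with columns ``w_gastrointestinal`` ... ``w_unspecified``
    whose rows each sum to 1.
    """
    flags = table[list(FLAG_COLUMNS)].to_numpy(dtype=bool)
    k = flags.sum(axis=1)
    w = np.zeros((len(table), 5))
    nz = k > 0
    w[nz, :4] = flags[nz] / k[nz, None]
    w[~nz, 4] = 1.0
    return pd.DataFrame(
        w, columns=[f"w_{c}" for c in ORGAN_CATEGORIES], index=table.index
    )


class CohortFilter(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying the study exclusion rules.

    ``transform`` filters a transaction table and stores the tally of
    removed rows in ``report_``. Stateless across calls (``fit`` only
    validates), so it composes with sklearn pipelines operating on
    DataFrames.

    Parameters
    ----------
    max_age : float, default 25.0
        Ages above this (years) are treated as recording errors.
    max_weight : float, default 100.0
        Weights above this (kg) are treated as recording errors.
    min_patients_per_drug : int, default 10
        Drugs dispensed to fewer unique patients are dropped entirely.
    keep_unknown_sex : bool, default False
        Retain unknown-sex rows (descriptives-only mode).
    """

    def __init__(
        self,
        max_age: float = 25.0,
        max_weight: float = 100.0,
        min_patients_per_drug: int = 10,
        keep_unknown_sex: bool = False,
    ):
        self.max_age = max_age
        self.max_weight = max_weight
        self.min_patients_per_drug = min_patients_per_drug
        self.keep_unknown_sex = keep_unknown_sex

    def fit(self, X: pd.DataFrame, y=None) -> "CohortFilter":
        if self.max_age <= 0 or self.max_weight <= 0:
            raise ValueError("max_age and max_weight must be positive")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cohort, self.report_ = apply_exclusions(
            X,
            max_age=self.max_age,
            max_weight=self.max_weight,
            min_patients_per_drug=self.min_patients_per_drug,
            keep_unknown_sex=self.keep_unknown_sex,
        )
        return cohort
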
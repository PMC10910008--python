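"""Descriptive layer: per-drug demographics, prescription shares, and the
rank-based comparison of body weight across drug groups."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .vocab import FLAG_COLUMNS, ORGAN_SYSTEMS

__all__ = [
    "demographics_table",
    "prescription_shares",
    "prescriptions_per_patient",
    "kruskal_wallis",
    "KruskalResult",
    "PrescriptionStats",
]


def _round_half_up(x, decimals: int = 1):
    """Round half away from zero (printed-table convention), not banker's."""
    factor = 10.0**decimals
    return np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)


def _drug_row(sub: pd.DataFrame) -> dict:
    n = len(sub)
    row = {
        "cases": n,
        "unique_patients": sub["patient_id"].nunique(),
    }
    for label, mask in (
        ("female", sub["sex"] == "F"),
        ("male", sub["sex"] == "M"),
        ("sex_unknown", ~sub["sex"].isin(["F", "M"])),
        ("entire", ~sub["neutered"].astype(bool)),
        ("neutered", sub["neutered"].astype(bool)),
    ):
        row[f"{label}_n"] = int(mask.sum())
        row[f"{label}_pct"] = _round_half_up(100.0 * mask.sum() / n)
    row["weight_mean"] = _round_half_up(sub["weight_kg"].mean())
    row["weight_sd"] = _round_half_up(sub["weight_kg"].std(ddof=1)) if n > 1 else 0.0
    row["age_mean"] = _round_half_up(sub["age_y"].mean())
    row["age_sd"] = _round_half_up(sub["age_y"].std(ddof=1)) if n > 1 else 0.0
    none = np.ones(n, dtype=bool)
    for organ, col in zip(ORGAN_SYSTEMS, FLAG_COLUMNS):
        m = sub[col].astype(bool)
        none &= ~m.to_numpy()
        row[f"{organ}_n"] = int(m.sum())
        row[f"{organ}_pct"] = _round_half_up(100.0 * m.sum() / n)
    row["unspecified_n"] = int(none.sum())
    row["unspecified_pct"] = _round_half_up(100.0 * none.sum() / n)
    return row


def demographics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-drug demographic summary plus an "All" row of column totals.

    For each retained drug: case and unique-patient counts, sex and
    neutering counts with percentages of that drug's cases, weight and age
    mean (sd), and organ-system flag counts/percentages. Percentages are
    rounded half-up to one decimal.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    rows = {
        drug: _drug_row(sub) for drug, sub in cohort.groupby("drug", sort=True)
    }
    rows["All"] = _drug_row(cohort)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "drug"
    return out


def prescription_shares(cohort: pd.DataFrame, decimals: int = 1) -> pd.Series:
    """Percentage of all cases accounted for by each drug.

    Shares sum to 100 up to rounding; ``decimals`` controls the printed
    precision (the study text mixes integer and one-decimal precision).
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    counts = cohort["drug"].value_counts()
    return _round_half_up(100.0 * counts / counts.sum(), decimals)


class PrescriptionStats(NamedTuple):
    mean: float
    quantiles: dict[float, float]
    max: int
    histogram: pd.Series  # prescriptions-per-patient value -> number of patients


def prescriptions_per_patient(cohort: pd.DataFrame) -> PrescriptionStats:
    """Distribution of per-dog prescription counts over the study window."""
    if cohort.empty:
        raise ValueError("cohort is empty")
    counts = cohort.groupby("patient_id").size()
    qs = {q: float(counts.quantile(q)) for q in (0.5, 0.75, 0.9, 0.95)}
    return PrescriptionStats(
        mean=float(_round_half_up(len(cohort) / cohort["patient_id"].nunique(), 1)),
        quantiles=qs,
        max=int(counts.max()),
        histogram=counts.value_counts().sort_index(),
    )


class KruskalResult(NamedTuple):
    H: float
    df: int
    p: float


def kruskal_wallis(values, groups) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis H test.

    H = [12/(N(N+1)) · Σ nᵢ(R̄ᵢ − (N+1)/2)²] / [1 − ΣT/(N³−N)] with average
    ranks, tie term T = t³ − t per tied group, and a χ² approximation on
    k − 1 degrees of freedom. When every value is identical the tie
    divisor vanishes; by convention H = 0 and p = 1.

    Raises
    ------
    ValueError
        With fewer than two groups.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be equal-length 1-d sequences")
    labels, idx = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    N = len(values)
    ranks = rankdata(values)
    stat = 0.0
    for g in range(k):
        r = ranks[idx == g]
        stat += len(r) * (r.mean() - (N + 1) / 2.0) ** 2
    H = 12.0 / (N * (N + 1)) * stat
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    denom = 1.0 - tie_term / (N**3 - N)
    if denom <= 0:
        return KruskalResult(0.0, k - 1, 1.0)
    H /= denom
    return KruskalResult(float(H), k - 1, float(chi2.sf(H, k - 1)))
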
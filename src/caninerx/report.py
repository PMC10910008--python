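"""Reporting layer: odds-ratio tables with credible intervals and
CI-derived p-values, partial-effect curves for weight and age, and
parameter-recovery summaries against simulation ground truth.

Odds ratios are exponentiated posterior means with equal-tailed 95%
percentile intervals of the exponentiated draws. Two-sided p-values are
derived from the ratio and its interval by the Altman–Bland construction:
the interval width on the log scale gives a standard error, whose z-score
is referred to the normal distribution (exactly, or via their published
polynomial approximation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import DESIGN_COLUMNS
from .synth import TrueModel, load_truth

__all__ = [
    "p_from_ci",
    "or_table",
    "PartialEffectCurve",
    "partial_effect_weight",
    "partial_effect_age",
    "recovery_report",
    "format_p",
]

_Z95 = 1.96  # printed-convention multiplier for a 95% interval


def p_from_ci(
    or_value: float, ci_low: float, ci_high: float, method: str = "exact"
) -> float:
    """Two-sided p-value for a ratio estimate from its 95% interval.

    SE = (ln ci_high − ln ci_low) / (2·1.96) and z = ln(OR)/SE; the exact
    method returns 2(1 − Φ(|z|)), the approximate one
    exp(−0.717|z| − 0.416 z²). An OR of exactly 1 returns p = 1.

    Raises
    ------
    ValueError
        If the interval is invalid (ci_low ≤ 0, not bracketing the OR) or
        degenerate (zero width) with OR ≠ 1.
    """
    if method not in ("exact", "approximate"):
        raise ValueError("method must be 'exact' or 'approximate'")
    if ci_low <= 0:
        raise ValueError("ci_low must be positive on the ratio scale")
    if not (ci_low <= or_value <= ci_high):
        raise ValueError("interval must bracket the estimate")
    if or_value == 1.0:
        return 1.0
    se = (np.log(ci_high) - np.log(ci_low)) / (2.0 * _Z95)
    if se == 0:
        raise ValueError("degenerate interval (zero width) with OR != 1")
    z = abs(np.log(or_value) / se)
    if method == "exact":
        return float(2.0 * norm.sf(z))
    return float(np.exp(-0.717 * z - 0.416 * z**2))


def format_p(p: float) -> str:
    """Table-style display: three decimals, '< 0.001' below that."""
    if np.isnan(p):
        return "NA"
    return "< 0.001" if p < 0.0005 else f"= {p:.3f}"


def or_table(chain, labels: list[str] | None = None, method: str = "exact") -> pd.DataFrame:
    """One odds-ratio row per fixed effect of a fitted chain.

    Accepts a :class:`~caninerx.mcmc.ChainResult` or a draws matrix with
    ``labels``. Columns: OR (exp of the posterior-mean coefficient),
    ci_low/ci_high (exp of the 2.5th/97.5th draw percentiles), p (from the
    interval), a ``degenerate`` flag for zero-variance draws, and a
    formatted "OR(low, high) p" string.
    """
    if hasattr(chain, "beta"):
        draws = chain.beta
        labels = labels or list(chain.labels)
    else:
        draws = np.asarray(chain, dtype=float)
        if labels is None:
            raise ValueError("labels required when passing a raw draws matrix")
    if draws.shape[0] < 100:
        raise ValueError("need at least 100 retained draws for interval estimates")
    rows = []
    for j, name in enumerate(labels):
        d = draws[:, j]
        orv = float(np.exp(d.mean()))
        lo, hi = np.exp(np.percentile(d, [2.5, 97.5]))
        degenerate = hi == lo
        if degenerate:
            p = 1.0 if orv == 1.0 else np.nan
        else:
            p = p_from_ci(orv, min(lo, orv), max(hi, orv), method=method)
        rows.append(
            {
                "parameter": name,
                "OR": orv,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p": p,
                "degenerate": bool(degenerate),
                "display": f"{orv:.2f}({lo:.2f}, {hi:.2f}) p {format_p(p)}",
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class PartialEffectCurve:
    """Relative odds of dispensing versus a reference dog along one covariate.

    ``odds`` equals exactly 1 at the reference covariate value. Pointwise
    95% bands come from evaluating the curve on every retained draw.
    """

    covariate: str
    grid: np.ndarray
    odds: np.ndarray
    lo: np.ndarray | None
    hi: np.ndarray | None
    ref: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.covariate: self.grid, "relative_odds": self.odds})
        if self.lo is not None:
            df["lo95"], df["hi95"] = self.lo, self.hi
        return df


def _coef_draws(chain, name: str) -> np.ndarray:
    if name not in chain.labels:
        raise ValueError(f"coefficient {name!r} not present in chain")
    return chain.beta[:, chain.labels.index(name)]


def partial_effect_weight(chain, grid=None, ref: float = 18.0) -> PartialEffectCurve:
    """Relative odds across body weight versus a dog of ``ref`` kg (default
    the population mean, 18 kg): curve(w) = exp(β_weight · (w − ref))."""
    grid = np.asarray(grid if grid is not None else np.arange(1.0, 70.5, 0.5))
    bw = _coef_draws(chain, "weight_kg")
    delta = grid - ref
    odds = np.exp(bw.mean() * delta)
    draws = np.exp(np.outer(bw, delta))
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return PartialEffectCurve("weight_kg", grid, odds, lo, hi, ref)


def partial_effect_age(chain, grid=None, ref: float = 7.0) -> PartialEffectCurve:
    """Relative odds across age versus a dog of ``ref`` years (default the
    population mean, 7 y), combining the linear and square-root terms:
    curve(a) = exp(β_age·(a − ref) + β_√age·(√a − √ref)). The two terms of
    opposite sign can make the curve non-monotone (U- or hump-shaped)."""
    grid = np.asarray(grid if grid is not None else np.arange(0.25, 16.25, 0.25))
    ba = _coef_draws(chain, "age_y")
    bs = _coef_draws(chain, "sqrt_age")
    d1 = grid - ref
    d2 = np.sqrt(grid) - np.sqrt(ref)
    odds = np.exp(ba.mean() * d1 + bs.mean() * d2)
    draws = np.exp(np.outer(ba, d1) + np.outer(bs, d2))
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return PartialEffectCurve("age_y", grid, odds, lo, hi, ref)


def _truth_vector(truth, labels: tuple[str, ...], focal: str) -> np.ndarray:
    if isinstance(truth, (str, Path)):
        truth = load_truth(truth)
    if isinstance(truth, TrueModel):
        b = truth.beta[focal]
        return np.array([b[DESIGN_COLUMNS.index(l)] for l in labels])
    arr = np.asarray(truth, dtype=float)
    if arr.shape != (len(labels),):
        raise ValueError("truth vector length does not match chain labels")
    return arr


def recovery_report(truths, chains, params: list[str] | None = None) -> pd.DataFrame:
    """Bias, RMSE and 95%-interval coverage across simulation replicates.

    ``truths`` is one ground truth per chain: a :class:`TrueModel`, a
    sidecar JSON path, or a coefficient vector aligned with the chain's
    labels. Coverage counts replicates whose equal-tailed 95% posterior
    interval contains the true log-odds coefficient.
    """
    chains = list(chains)
    truths = list(truths)
    if len(chains) != len(truths):
        raise ValueError("one ground truth per chain is required")
    if not chains:
        raise ValueError("no replicates supplied")
    labels = chains[0].labels
    params = params or [l for l in labels]
    stats = {name: {"bias": [], "cover": []} for name in params}
    for truth, chain in zip(truths, chains):
        tv = _truth_vector(truth, chain.labels, chain.focal)
        for name in params:
            j = chain.labels.index(name)
            d = chain.beta[:, j]
            lo, hi = np.percentile(d, [2.5, 97.5])
            stats[name]["bias"].append(d.mean() - tv[j])
            stats[name]["cover"].append(lo <= tv[j] <= hi)
    rows = []
    for name in params:
        b = np.asarray(stats[name]["bias"])
        rows.append(
            {
                "parameter": name,
                "n_replicates": len(b),
                "mean_bias": float(b.mean()),
                "rmse": float(np.sqrt(np.mean(b**2))),
                "coverage95": float(np.mean(stats[name]["cover"])),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
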
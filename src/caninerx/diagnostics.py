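"""Single-chain convergence diagnostics: effective sample size, the
Raftery–Lewis run-length diagnostic, and trace exports for visual checks.

The study protocol is single-chain, so no multi-chain statistics (R-hat,
rank plots) are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "effective_sample_size",
    "raftery_lewis",
    "RafteryLewisResult",
    "export_traces",
]


def effective_sample_size(draws) -> float:
    """ESS = N / (1 + 2 Σ ρ_t), initial-positive-sequence truncation.

    Sample autocorrelations are summed from lag 1 until the first
    nonpositive estimate. A constant chain has no information about the
    posterior spread; it is reported as ESS 0 with a warning.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 1:
        raise ValueError("draws must be one-dimensional")
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 draws for a stable ESS estimate")
    x = x - x.mean()
    var = x @ x / n
    if var == 0:
        warnings.warn("degenerate (constant) chain; ESS reported as 0")
        return 0.0
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    ssum = 0.0
    for t in range(1, n):
        if rho[t] <= 0:
            break
        ssum += rho[t]
    return float(n / (1.0 + 2.0 * ssum))


@dataclass(frozen=True)
class RafteryLewisResult:
    """Run-length recommendation for estimating one posterior quantile.

    ``nmin`` is the iid-equivalent minimum number of draws, ``n`` the
    recommended chain length, ``m`` the recommended burn-in, ``i`` the
    dependence factor n/nmin, and ``k`` the thinning at which the
    dichotomized chain is adequately first-order Markov.
    """

    nmin: int
    n: int
    m: int
    i: float
    k: int


def _g2_first_vs_second(z: np.ndarray) -> float:
    """BIC comparing second- vs first-order Markov fit of a binary chain."""
    n = len(z) - 2
    counts = np.zeros((2, 2, 2))
    np.add.at(counts, (z[:-2], z[1:-1], z[2:]), 1.0)
    g2 = 0.0
    for j in range(2):
        col = counts[:, j, :]
        tot = col.sum()
        if tot == 0:
            continue
        fitted = np.outer(col.sum(axis=1), col.sum(axis=0)) / tot
        nz = col > 0
        g2 += 2.0 * float(np.sum(col[nz] * np.log(col[nz] / fitted[nz])))
    return g2 - np.log(n) * 2.0


def raftery_lewis(
    draws, q: float = 0.025, r: float = 0.005, s: float = 0.95
) -> RafteryLewisResult:
    """Raftery–Lewis diagnostic for estimating the q-quantile to ±r with
    probability s.

    The chain is dichotomized at its empirical q-quantile; the smallest
    thinning k making the binary chain pass a first- vs second-order
    Markov BIC comparison is selected; the fitted transition probabilities
    give the recommended burn-in M and chain length N by the standard
    formulas. The defaults target the end-points of a 95% credible
    interval with 95% probability.

    Raises
    ------
    ValueError
        If fewer draws than the iid minimum Nmin are supplied.
    """
    x = np.asarray(draws, dtype=float)
    if not (0 < q < 1 and 0 < s < 1 and r > 0):
        raise ValueError("require 0<q<1, 0<s<1, r>0")
    z_s = norm.ppf((1.0 + s) / 2.0)
    nmin = int(np.ceil(z_s**2 * q * (1 - q) / r**2))
    if len(x) < nmin:
        raise ValueError(
            f"chain too short for (q={q}, r={r}, s={s}): "
            f"{len(x)} draws < Nmin = {nmin}"
        )
    cutoff = np.quantile(x, q)
    full = (x <= cutoff).astype(np.intp)

    kmax = max(1, min(len(x) // 100, 100))
    k = kmax
    for k_try in range(1, kmax + 1):
        if _g2_first_vs_second(full[::k_try]) < 0:
            k = k_try
            break
    thinned = full[::k]

    pairs = np.zeros((2, 2))
    np.add.at(pairs, (thinned[:-1], thinned[1:]), 1.0)
    row = pairs.sum(axis=1)
    alpha = pairs[0, 1] / row[0] if row[0] else 0.0  # P(0 -> 1)
    beta = pairs[1, 0] / row[1] if row[1] else 0.0  # P(1 -> 0)
    ab = alpha + beta
    if alpha == 0 or beta == 0:
        raise ValueError("dichotomized chain never moves; cannot estimate run length")
    lam = 1.0 - ab
    eps = 0.001
    if abs(lam) >= 1 or max(alpha, beta) == 0:
        m_star = 1.0
    else:
        m_star = np.log(eps * ab / max(alpha, beta)) / np.log(abs(lam))
    m = int(np.ceil(max(m_star, 0.0))) * k
    n_star = (alpha * beta * (2.0 - ab)) / ab**3 * (z_s / r) ** 2
    n = int(np.ceil(n_star)) * k
    return RafteryLewisResult(nmin=nmin, n=n, m=max(m, k), i=n / nmin, k=k)


def export_traces(
    chain,
    out_dir: str | Path,
    params: list[str] | None = None,
    resolution: int = 500,
) -> list[Path]:
    """Write trace and running-mean plots plus a thinned CSV per parameter.

    ``params`` defaults to every fixed-effect label plus the patient-level
    variance. Chains longer than ``resolution`` are deterministically
    downsampled for plotting; the thinned CSV has exactly ``resolution``
    rows (or the chain length if shorter). Returns the list of files
    written (two images per parameter plus one CSV).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if chain.n_retained == 0:
        raise ValueError("chain has no retained draws")
    if params is None:
        params = list(chain.labels) + ["sigma_u2"]
    if not params:
        warnings.warn("no parameters requested; nothing exported")
        return []

    def series(name: str) -> np.ndarray:
        if name == "sigma_u2":
            return chain.sigma_u2
        if name == "deviance":
            return chain.deviance
        return chain.beta[:, chain.labels.index(name)]

    files: list[Path] = []
    n = chain.n_retained
    step = max(n // resolution, 1)
    sub_idx = np.arange(0, n, step)[:resolution]
    thin_df = {}
    for name in params:
        y = series(name)
        run_mean = np.cumsum(y) / np.arange(1, n + 1)
        for kind, data in (("trace", y), ("runmean", run_mean)):
            fig, ax = plt.subplots(figsize=(6, 2.2))
            ax.plot(sub_idx, data[sub_idx], lw=0.7)
            ax.set_title(f"{name} ({kind})", fontsize=9)
            ax.set_xlabel("retained iteration")
            fname = out_dir / f"{name.replace('/', '_')}_{kind}.png"
            fig.tight_layout()
            fig.savefig(fname, dpi=100)
            plt.close(fig)
            files.append(fname)
        thin_df[name] = y[sub_idx]
    csv_path = out_dir / "thinned_draws.csv"
    pd.DataFrame(thin_df, index=sub_idx).rename_axis("iteration").to_csv(csv_path)
    files.append(csv_path)
    return files
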
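"""MCMC convergence diagnostics: split R-hat and effective sample size.

Classic (non-rank-normalized) Gelman–Rubin split R-hat: each chain is
halved, and the potential scale reduction factor compares between-half to
within-half variance.  ESS follows the standard multi-chain
autocorrelation estimator: total draws deflated by the Geyer
initial-positive-sequence sum of autocorrelations.  A rank-normalized
R-hat variant is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_RHAT_MAX = 1.05
DEFAULT_ESS_MIN = 400.0


def _as_chain_matrix(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("chain matrix must be 2-D (n_chains x n_iter)")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    if x.shape[1] < 4:
        raise ValueError("need at least 4 iterations per chain")
    return x


def _split(x: np.ndarray) -> np.ndarray:
    m, n = x.shape
    if n % 2:                      # drop the last draw to split evenly
        x = x[:, :-1]
        n -= 1
    half = n // 2
    return np.vstack([x[:, :half], x[:, half:]])


def rhat(values: np.ndarray, rank_normalize: bool = False) -> float:
    """Split-chain potential scale reduction factor.

    sqrt(((n-1)/n * W + B/n) / W) over the split halves, where W is the
    mean within-half variance and B the between-half variance of the half
    means (scaled by n).  Chains that are all equal (W = B = 0) return
    exactly 1 by convention.
    """
    x = _split(_as_chain_matrix(values))
    if rank_normalize:
        flat = x.ravel()
        ranks = np.argsort(np.argsort(flat)).astype(float) + 1.0
        z = norm.ppf((ranks - 0.375) / (flat.size + 0.25))
        x = z.reshape(x.shape)
    m, n = x.shape
    means = x.mean(axis=1)
    variances = x.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def effective_sample_size(values: np.ndarray, cap_factor: float = 1.0) -> float:
    """Multi-chain effective sample size.

    ESS = m*n / (1 + 2 * sum rho_t), with lag correlations rho_t estimated
    from per-chain autocovariances pooled against the combined-chain
    variance and truncated by Geyer's initial positive sequence.  Capped
    at ``cap_factor * m * n``; zero-variance chains return the cap with a
    warning (no information to deflate).
    """
    x = _as_chain_matrix(values)
    m, n = x.shape
    total = m * n
    cap = cap_factor * total
    if np.ptp(x) == 0.0:
        warnings.warn("zero-variance chains: ESS set to the total draw "
                      "count", stacklevel=2)
        return float(cap)

    means = x.mean(axis=1)
    variances = x.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B / n
    if var_plus == 0.0 or W == 0.0:
        warnings.warn("degenerate chain variance: ESS set to the total "
                      "draw count", stacklevel=2)
        return float(cap)

    # per-chain autocovariance via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    centered = x - means[:, None]
    freq = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(freq * np.conj(freq), nfft, axis=1)[:, :n].real
    acov /= n
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    rho[0] = 1.0

    # Geyer initial positive sequence on paired sums
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0.0:
            break
        tau += 2.0 * pair
        t += 2
    ess = total / tau
    return float(min(max(ess, 1e-12), cap))


@dataclass
class ConvergenceReport:
    """Per-parameter diagnostics with an overall pass/fail gate."""

    table: pd.DataFrame
    rhat_max: float
    ess_min: float

    @property
    def passed(self) -> bool:
        return bool(self.table["ok"].all())

    def failing_parameters(self) -> list:
        return self.table.loc[~self.table["ok"], "parameter"].tolist()

    def __str__(self) -> str:
        head = (f"convergence report (thresholds: R-hat <= {self.rhat_max}, "
                f"ESS >= {self.ess_min})\n")
        return head + self.table.to_string(index=False) + (
            "\noverall: " + ("PASS" if self.passed else "FAIL"))


def convergence_report(draws, rhat_max: float = DEFAULT_RHAT_MAX,
                       ess_min: float = DEFAULT_ESS_MIN) -> ConvergenceReport:
    """Split R-hat and ESS for every free parameter of a posterior run.

    ``draws`` is a :class:`~atherotrend.inference.PosteriorDraws`; fixed
    (clamped) parameters are excluded.  The configured thresholds are
    echoed in the report.
    """
    rows = []
    for name in draws.free_names():
        cm = draws.chain_matrix(name)
        r = rhat(cm)
        e = effective_sample_size(cm)
        rows.append({"parameter": name, "rhat": r, "ess": e,
                     "ok": bool(r <= rhat_max and e >= ess_min)})
    table = pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "ok"])
    return ConvergenceReport(table=table, rhat_max=float(rhat_max),
                             ess_min=float(ess_min))
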
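"""Joint density of the trajectory state-space model.

The model for group-level latent signal areas A_{t,f} observed per mouse:

    Y_i        ~ LogNormal(log A_{t(i), f(i)} - sigma1^2 / 2, sigma1)
    A_{t,f}    = 2 A_{t-1,f} - A_{t-2,f} + mu_{t,f}   (A_0 = A_{-1} = 0)
    mu_{t,f}   ~ Normal(0, sigma2)
    sigma1, sigma2 ~ HalfNormal(scale)                (standard: scale 1)

The mean correction -sigma1^2/2 makes E[Y] = A rather than the median.
These pure functions are the single source of truth for both the MCMC
sampler and the test oracles.  All densities are log densities; parameter
values outside the support return -inf rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import latent_from_innovations

LOG_2PI = float(np.log(2.0 * np.pi))
NEG_INF = -np.inf


@dataclass(frozen=True)
class PriorSpec:
    """Prior scales and the data rescale used to keep them standard.

    ``data_rescale`` is a positive divisor applied to the measurements
    before fitting; raw signal areas are O(10^2) pixels, so dividing by
    ~100 puts the latent scale at O(1) where half-normal(1) priors on
    sigma1 and sigma2 are weakly informative.  Summaries are mapped back
    to the original units.
    """

    sigma_obs_scale: float = 1.0
    sigma_state_scale: float = 1.0
    data_rescale: float = 1.0

    def __post_init__(self):
        for name in ("sigma_obs_scale", "sigma_state_scale", "data_rescale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ModelParameters:
    """Full parameter vector: innovations mu [T x F], sigma_obs (sigma1),
    sigma_state (sigma2; scalar shared across groups, or length-F vector
    when each diet group carries its own innovation scale)."""

    mu: np.ndarray
    sigma_obs: float
    sigma_state: Union[float, np.ndarray]

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("mu contains non-finite entries")

    @property
    def shape(self) -> tuple:
        return self.mu.shape

    def latent(self) -> np.ndarray:
        """Derived trajectory A = double cumulative sum of mu."""
        return latent_from_innovations(self.mu)

    def sigma_state_per_group(self) -> np.ndarray:
        s2 = np.asarray(self.sigma_state, dtype=float)
        F = self.mu.shape[1]
        if s2.ndim == 0:
            return np.full(F, float(s2))
        if s2.shape != (F,):
            raise ValueError(f"sigma_state must be scalar or length {F}")
        return s2


class Measurements:
    """Indexed view of a long-format measurement table.

    Maps week w to time index t = w (0-based rows of mu/A) and group label
    to food index f in the supplied group order (control first).
    """

    def __init__(self, y: np.ndarray, t_idx: np.ndarray, f_idx: np.ndarray,
                 groups: Sequence[str], n_weeks: int):
        self.y = np.asarray(y, dtype=float)
        self.t_idx = np.asarray(t_idx, dtype=np.int64)
        self.f_idx = np.asarray(f_idx, dtype=np.int64)
        self.groups = tuple(groups)
        self.n_weeks = int(n_weeks)
        if not (self.y.shape == self.t_idx.shape == self.f_idx.shape):
            raise ValueError("y, t_idx, f_idx must share a shape")
        if np.any(self.y <= 0):
            raise ValueError("all measurements must be strictly positive "
                             "(log-normal support)")
        if self.y.size:
            if self.t_idx.min() < 0 or self.t_idx.max() >= self.n_weeks:
                raise ValueError("week index out of range")
            if self.f_idx.min() < 0 or self.f_idx.max() >= len(self.groups):
                raise ValueError("group index out of range")

    def __len__(self) -> int:
        return self.y.size

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @classmethod
    def from_frame(cls, table: pd.DataFrame,
                   groups: Optional[Sequence[str]] = None,
                   n_weeks: Optional[int] = None) -> "Measurements":
        """Build from a ``mouse_id,group,week,signal_area`` table.

        ``groups`` fixes the food-index order (default: order of first
        appearance); a table row with a label outside ``groups`` is an
        error.
        """
        if groups is None:
            groups = list(dict.fromkeys(table["group"]))
        groups = list(groups)
        lookup = {g: i for i, g in enumerate(groups)}
        unknown = sorted(set(table["group"]) - set(groups))
        if unknown:
            raise ValueError(f"unknown group label(s): {unknown}")
        week = table["week"].to_numpy(dtype=int)
        if week.size and week.min() < 0:
            raise ValueError("weeks must be non-negative integers")
        if n_weeks is None:
            n_weeks = int(week.max()) + 1 if week.size else 1
        y = table["signal_area"].to_numpy(dtype=float)
        f_idx = table["group"].map(lookup).to_numpy(dtype=np.int64)
        return cls(y=y, t_idx=week, f_idx=f_idx, groups=groups,
                   n_weeks=n_weeks)

    def aggregate_mean(self) -> "Measurements":
        """Collapse replicate mice to one per-cell mean observation
        (fallback reading in which Y_{t,f} is the group mean)."""
        df = pd.DataFrame({"t": self.t_idx, "f": self.f_idx, "y": self.y})
        g = df.groupby(["t", "f"], sort=True)["y"].mean().reset_index()
        return Measurements(y=g["y"].to_numpy(), t_idx=g["t"].to_numpy(),
                            f_idx=g["f"].to_numpy(), groups=self.groups,
                            n_weeks=self.n_weeks)


# ---------------------------------------------------------------------------
# densities (explicit formulas; scipy.stats serves as the independent
# oracle in the test suite)

def _normal_logpdf(x, sigma):
    return -0.5 * LOG_2PI - np.log(sigma) - 0.5 * (x / sigma) ** 2


def _halfnormal_logpdf(x, scale):
    if x < 0:
        return NEG_INF
    return (0.5 * np.log(2.0 / np.pi) - np.log(scale)
            - 0.5 * (x / scale) ** 2)


def log_likelihood(measurements: Measurements,
                   params: ModelParameters) -> float:
    """Sum of log-normal log densities of all observations.

    Each observation contributes
    ``LogNormal(y | log A_{t,f} - sigma1^2/2, sigma1)``; mice sharing a
    (week, group) cell share that cell's latent A.  Returns -inf when any
    referenced A is non-positive or sigma1 is outside its support.
    """
    T, F = params.shape
    if measurements.n_weeks > T:
        raise ValueError(
            f"measurements span {measurements.n_weeks} weeks but mu has "
            f"T={T} rows")
    if measurements.n_groups > F:
        raise ValueError("more measurement groups than mu columns")
    s1 = float(params.sigma_obs)
    if not np.isfinite(s1) or s1 <= 0:
        return NEG_INF
    A = params.latent()
    a = A[measurements.t_idx, measurements.f_idx]
    if np.any(a <= 0):
        return NEG_INF
    loc = np.log(a) - 0.5 * s1 * s1
    ly = np.log(measurements.y)
    val = np.sum(-ly - np.log(s1) - 0.5 * LOG_2PI
                 - 0.5 * ((ly - loc) / s1) ** 2)
    return float(val)


def log_prior(params: ModelParameters, prior: PriorSpec) -> float:
    """Innovation prior plus half-normal hyperpriors.

    ``sum_{t,f} Normal(mu_{t,f} | 0, sigma2_f) + HalfNormal(sigma1 | s) +
    sum HalfNormal(sigma2 | s)``; -inf outside the support.  No further
    terms: remaining priors are flat (weakly informative).
    """
    s1 = float(params.sigma_obs)
    s2 = params.sigma_state_per_group()
    if not np.isfinite(s1) or s1 <= 0:
        return NEG_INF
    if not np.all(np.isfinite(s2)) or np.any(s2 <= 0):
        return NEG_INF
    val = float(np.sum(_normal_logpdf(params.mu, s2[np.newaxis, :])))
    val += _halfnormal_logpdf(s1, prior.sigma_obs_scale)
    s2_unique = (s2[:1] if np.asarray(params.sigma_state).ndim == 0 else s2)
    for s in s2_unique:
        val += _halfnormal_logpdf(float(s), prior.sigma_state_scale)
    return float(val)


def log_posterior(measurements: Measurements, params: ModelParameters,
                  prior: PriorSpec) -> float:
    """Unnormalized log posterior: likelihood + prior; -inf propagates."""
    lp = log_prior(params, prior)
    if not np.isfinite(lp):
        return NEG_INF
    ll = log_likelihood(measurements, params)
    if not np.isfinite(ll):
        return NEG_INF
    return lp + ll
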
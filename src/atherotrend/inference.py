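"""Posterior sampling and trajectory summaries.

Draws multi-chain posterior samples of the state-space model via the
adaptive Metropolis kernel in :mod:`atherotrend._sampler` and reduces them
to the study's reporting conventions: per-week posterior mode with an 89%
equal-tailed credible band per diet group, and within-draw contrasts of
each group against the control at selected weeks.  A contrast is flagged
as excluding zero when its credible interval lies entirely on one side of
zero — this package's operational reading of "a significant difference".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from . import _sampler
from .cohort import innovations_from_latent, latent_from_innovations
from .model import Measurements, PriorSpec

__all__ = [
    "PosteriorDraws", "sample_posterior", "posterior_mode",
    "credible_interval", "hpd_interval", "group_contrast",
    "summarize_trajectories", "ContrastResult",
]


@dataclass
class PosteriorDraws:
    """Multi-chain posterior draws with derived latent trajectories.

    ``draws[c, i, :]`` is chain c, iteration i over the named parameters
    (innovations ``mu[t,f]`` in original data units, then ``sigma_obs``,
    then the state scale(s), also in data units).  ``derived_A`` holds the
    implied latent areas, strictly positive wherever a cell was observed.
    """

    draws: np.ndarray            # (n_chains, n_draws, d)
    names: list
    derived_A: np.ndarray        # (n_chains, n_draws, T, F)
    groups: tuple
    weeks: np.ndarray            # observed week labels, 0-based
    free: np.ndarray             # (d,) bool — False for fixed parameters
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    @property
    def shape_TF(self) -> tuple:
        return self.derived_A.shape[2:]

    def chain_matrix(self, name: str) -> np.ndarray:
        """Draws of one parameter as an (n_chains, n_draws) matrix."""
        j = self.names.index(name)
        return self.draws[:, :, j]

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled across chains."""
        return self.chain_matrix(name).reshape(-1)

    def flat_A(self, t: int, f: int) -> np.ndarray:
        """Pooled draws of the latent area A at time index t, group f."""
        return self.derived_A[:, :, t, f].reshape(-1)

    def free_names(self) -> list:
        return [n for n, fr in zip(self.names, self.free) if fr]

    def save(self, path) -> None:
        np.savez_compressed(
            path, draws=self.draws, names=np.asarray(self.names),
            derived_A=self.derived_A, groups=np.asarray(self.groups),
            weeks=np.asarray(self.weeks), free=self.free,
            meta=json.dumps(self.meta, default=str))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as z:
            return cls(draws=z["draws"], names=[str(n) for n in z["names"]],
                       derived_A=z["derived_A"],
                       groups=tuple(str(g) for g in z["groups"]),
                       weeks=z["weeks"].astype(int), free=z["free"],
                       meta=json.loads(str(z["meta"])))


def _initial_state(meas: Measurements, ly: np.ndarray, T: int, F: int,
                   prior: PriorSpec):
    """Data-driven starting point: per-cell geometric means, interpolated
    across unobserved cells, inverted to innovations."""
    gm = np.full((T, F), np.nan)
    if len(meas):
        df = pd.DataFrame({"t": meas.t_idx, "f": meas.f_idx, "ly": ly})
        cell = df.groupby(["t", "f"])["ly"].mean()
        for (t, f), v in cell.items():
            gm[t, f] = np.exp(v)
    gm_df = pd.DataFrame(gm).interpolate(axis=0, limit_direction="both")
    gm = gm_df.to_numpy()
    gm[~np.isfinite(gm)] = 1.0  # entirely unobserved column
    floor = max(np.nanmax(gm) * 1e-4, 1e-6)
    gm = np.clip(gm, floor, None)
    mu0 = innovations_from_latent(gm)

    if len(meas):
        resid = ly - np.log(gm[meas.t_idx, meas.f_idx])
        s1_0 = max(float(np.std(resid)), 0.05)
    else:
        s1_0 = 0.8 * prior.sigma_obs_scale
    s2_0 = max(float(np.std(mu0)), 0.1 * float(np.max(np.abs(mu0))), 1e-3)
    return gm, s1_0, s2_0


def sample_posterior(data: Optional[Union[pd.DataFrame, Measurements]],
                     *,
                     groups: Optional[Sequence[str]] = None,
                     n_weeks: Optional[int] = None,
                     prior: Optional[PriorSpec] = None,
                     n_chains: int = 4,
                     n_draws: int = 1000,
                     n_warmup: int = 1000,
                     seed: int = 0,
                     share_sigma_state: bool = True,
                     fix_sigma_obs: Optional[float] = None,
                     fix_sigma_state: Optional[float] = None,
                     aggregate: Optional[str] = None) -> PosteriorDraws:
    """Draw posterior samples of the trajectory model.

    Parameters
    ----------
    data : DataFrame, Measurements, or None
        Long-format measurements; ``None`` runs prior-only sampling (then
        ``groups`` and ``n_weeks`` are required).
    prior : PriorSpec
        Prior scales and the data rescale divisor.
    n_chains, n_draws, n_warmup, seed
        Sampler budget; ``n_chains >= 2`` so convergence diagnostics are
        defined.  Per-chain seeds are derived from the master seed.
    share_sigma_state : bool
        One innovation scale shared across diet groups (the model as
        written) or one per group.
    fix_sigma_obs, fix_sigma_state : float, optional
        Clamp a hyperparameter (in original data units) instead of
        sampling it; used by oracle checks and prior studies.
    aggregate : {"mean", None}
        ``"mean"`` collapses replicate mice to the per-cell mean before
        fitting (fallback reading of the observation model).

    Returns
    -------
    PosteriorDraws with all reported quantities in original data units.
    """
    if prior is None:
        prior = PriorSpec()
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2 for convergence diagnostics")
    if n_draws < 1 or n_warmup < 0:
        raise ValueError("n_draws must be >= 1 and n_warmup >= 0")

    if data is None:
        if groups is None or n_weeks is None:
            raise ValueError("prior-only sampling needs groups and n_weeks")
        meas = Measurements(y=np.empty(0), t_idx=np.empty(0, int),
                            f_idx=np.empty(0, int), groups=groups,
                            n_weeks=n_weeks)
    elif isinstance(data, Measurements):
        meas = data
    else:
        meas = Measurements.from_frame(data, groups=groups, n_weeks=n_weeks)
    if aggregate == "mean":
        meas = meas.aggregate_mean()
    elif aggregate is not None:
        raise ValueError("aggregate must be 'mean' or None")

    rescale = prior.data_rescale
    ys = meas.y / rescale
    ly = np.log(ys) if ys.size else np.empty(0)
    if ly.size and not np.all(np.isfinite(ly)):
        raise ValueError("non-finite log measurement encountered")
    T, F = meas.n_weeks, meas.n_groups
    n_s2 = 1 if share_sigma_state else F
    s2_idx = (np.zeros(F, np.int64) if share_sigma_state
              else np.arange(F, dtype=np.int64))
    d = T * F + 1 + n_s2

    A0, s1_0, s2_0 = _initial_state(meas, ly, T, F, prior)
    free = np.ones(d, dtype=bool)
    ls1_0 = np.log(s1_0)
    ls2_0 = np.log(s2_0)
    if fix_sigma_obs is not None:
        if not fix_sigma_obs > 0:
            raise ValueError("fix_sigma_obs must be > 0")
        ls1_0 = np.log(fix_sigma_obs)
        free[T * F] = False
    if fix_sigma_state is not None:
        if not fix_sigma_state > 0:
            raise ValueError("fix_sigma_state must be > 0")
        ls2_0 = np.log(fix_sigma_state / rescale)
        free[T * F + 1:] = False

    t_idx = meas.t_idx.astype(np.int64)
    f_idx = meas.f_idx.astype(np.int64)
    args = (ly, t_idx, f_idx, T, F, s2_idx, n_s2,
            float(prior.sigma_obs_scale), float(prior.sigma_state_scale))

    scales0 = np.empty(d)
    scales0[:T * F] = 0.3 * s2_0 + 1e-6
    scales0[T * F:] = 0.15

    chains = []
    rates = []
    chain_seeds = []
    for c in range(n_chains):
        rng = np.random.default_rng([int(seed), 13, c])
        theta0 = np.empty(d)
        # over-dispersed start: multiplicative jitter keeps latents at
        # observed cells strictly positive
        A_c = A0 * np.exp(0.2 * rng.standard_normal((T, F)))
        theta0[:T * F] = A_c.reshape(-1)
        theta0[T * F] = ls1_0 + (0.2 * rng.standard_normal()
                                 if free[T * F] else 0.0)
        for k in range(n_s2):
            theta0[T * F + 1 + k] = ls2_0 + (
                0.2 * rng.standard_normal() if free[T * F + 1 + k] else 0.0)
        lp0 = _sampler._logpost(theta0, *args)
        if not np.isfinite(lp0):
            raise RuntimeError(
                "non-finite posterior density at the initial state; "
                "consider setting prior.data_rescale near the data's "
                "typical magnitude")
        cs = int(np.random.SeedSequence([int(seed), 17, c])
                 .generate_state(1)[0]) & 0x7FFFFFFF
        chain_seeds.append(cs)
        out, rate, _ = _sampler._run_chain(
            *args, theta0, free, scales0, int(n_warmup), int(n_draws), cs)
        chains.append(out)
        rates.append(float(rate))

    if free.any() and max(rates) <= 0.0:
        raise RuntimeError(
            "sampler rejected every post-warmup proposal; the posterior is "
            "likely ill-scaled — set prior.data_rescale near the data's "
            "typical magnitude")

    raw = np.stack(chains)                      # (chains, draws, d)
    if not np.all(np.isfinite(raw)):
        raise RuntimeError("non-finite values in posterior draws")

    # natural parameterization in original data units; the sampler works
    # over A, reported draws are the innovations mu = second diff of A
    A_draws = raw[:, :, :T * F].reshape(n_chains, n_draws, T, F) * rescale
    pad = np.zeros((n_chains, n_draws, 2, F))
    mu_draws = np.diff(np.concatenate([pad, A_draws], axis=2), n=2, axis=2)
    draws = np.empty_like(raw)
    draws[:, :, :T * F] = mu_draws.reshape(n_chains, n_draws, T * F)
    draws[:, :, T * F:] = np.exp(raw[:, :, T * F:])
    draws[:, :, T * F + 1:] *= rescale
    derived_A = A_draws

    names = [f"mu[{t},{f}]" for t in range(T) for f in range(F)]
    names.append("sigma_obs")
    if share_sigma_state:
        names.append("sigma_state")
    else:
        names.extend(f"sigma_state[{f}]" for f in range(F))

    meta = {
        "seed": int(seed), "chain_seeds": chain_seeds,
        "n_warmup": int(n_warmup), "acceptance_rates": rates,
        "prior": {"sigma_obs_scale": prior.sigma_obs_scale,
                  "sigma_state_scale": prior.sigma_state_scale,
                  "data_rescale": prior.data_rescale},
        "share_sigma_state": bool(share_sigma_state),
        "fix_sigma_obs": fix_sigma_obs, "fix_sigma_state": fix_sigma_state,
        "aggregate": aggregate, "n_obs": int(len(meas)),
    }
    return PosteriorDraws(draws=draws, names=names, derived_A=derived_A,
                          groups=tuple(meas.groups),
                          weeks=np.arange(T), free=free, meta=meta)


# ---------------------------------------------------------------------------
# summaries

def posterior_mode(samples: np.ndarray) -> float:
    """Marginal posterior mode via a deterministic kernel density estimate.

    Gaussian KDE with Silverman bandwidth evaluated on a 512-point grid
    spanning [min, max] of the draws; the argmax grid point is returned.
    A constant draw vector returns that constant.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty draw vector")
    if np.ptp(x) == 0:
        return float(x[0])
    if x.size < 100:
        raise ValueError("posterior_mode needs >= 100 draws")
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[int(np.argmax(kde(grid)))])


def credible_interval(samples: np.ndarray,
                      level: float = 0.89) -> tuple[float, float]:
    """Equal-tailed percentile interval at the given level.

    Quantiles at (1-level)/2 and 1-(1-level)/2, linearly interpolated
    between order statistics.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty draw vector")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def hpd_interval(samples: np.ndarray,
                 level: float = 0.89) -> tuple[float, float]:
    """Highest-posterior-density interval (narrowest window holding
    ``level`` of the sorted draws); optional alternative to the
    equal-tailed default."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty draw vector")
    w = max(int(np.ceil(level * n)), 1)
    if w >= n:
        return float(x[0]), float(x[-1])
    widths = x[w:] - x[:n - w]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + w])


_INTERVALS = {"eti": credible_interval, "hpd": hpd_interval}


@dataclass(frozen=True)
class ContrastResult:
    """Within-draw difference of one group against the control at one week."""

    week: int
    group: str
    control: str
    mode: float
    ci_low: float
    ci_high: float
    excludes_zero: bool


def _resolve_group(draws: PosteriorDraws, group) -> int:
    if isinstance(group, str):
        if group not in draws.groups:
            raise ValueError(f"unknown group {group!r}; have {draws.groups}")
        return draws.groups.index(group)
    f = int(group)
    if not 0 <= f < len(draws.groups):
        raise ValueError(f"group index {f} out of range")
    return f


def _resolve_week(draws: PosteriorDraws, week) -> int:
    weeks = list(draws.weeks)
    if week not in weeks:
        raise ValueError(f"week {week} not among observed weeks {weeks}")
    return weeks.index(week)


def group_contrast(draws: PosteriorDraws, week: int, group,
                   control=None, level: float = 0.89,
                   interval: str = "eti") -> ContrastResult:
    """Posterior contrast A_{t,group} - A_{t,control}, paired within draw.

    The difference is formed per posterior draw (respecting the joint
    posterior's correlation), then summarized by its mode and credible
    interval; ``excludes_zero`` is True when the interval lies strictly
    on one side of zero.
    """
    f = _resolve_group(draws, group)
    f0 = _resolve_group(draws, control if control is not None else 0)
    if f == f0:
        raise ValueError("group and control must differ")
    t = _resolve_week(draws, week)
    diff = draws.flat_A(t, f) - draws.flat_A(t, f0)
    lo, hi = _INTERVALS[interval](diff, level)
    return ContrastResult(
        week=int(week), group=draws.groups[f], control=draws.groups[f0],
        mode=posterior_mode(diff), ci_low=lo, ci_high=hi,
        excludes_zero=bool(lo > 0.0 or hi < 0.0))


def summarize_trajectories(draws: PosteriorDraws,
                           weeks: Optional[Sequence[int]] = None,
                           control=None, level: float = 0.89,
                           interval: str = "eti") -> pd.DataFrame:
    """Per-(week, group) mode and credible band, plus contrasts vs control.

    Returns a frame with columns ``week, group, mode, ci_low, ci_high,
    contrast_mode, contrast_lo, contrast_hi, excludes_zero``; contrast
    columns are empty for the control group itself.
    """
    if interval not in _INTERVALS:
        raise ValueError("interval must be 'eti' or 'hpd'")
    f0 = _resolve_group(draws, control if control is not None else 0)
    if weeks is None:
        weeks = list(draws.weeks)
    rows = []
    for week in weeks:
        t = _resolve_week(draws, week)
        for f, g in enumerate(draws.groups):
            a = draws.flat_A(t, f)
            lo, hi = _INTERVALS[interval](a, level)
            row = {"week": int(week), "group": g,
                   "mode": posterior_mode(a), "ci_low": lo, "ci_high": hi,
                   "contrast_mode": np.nan, "contrast_lo": np.nan,
                   "contrast_hi": np.nan, "excludes_zero": ""}
            if f != f0:
                con = group_contrast(draws, week, f, control=f0,
                                     level=level, interval=interval)
                row.update(contrast_mode=con.mode, contrast_lo=con.ci_low,
                           contrast_hi=con.ci_high,
                           excludes_zero=con.excludes_zero)
            rows.append(row)
    return pd.DataFrame(rows)
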
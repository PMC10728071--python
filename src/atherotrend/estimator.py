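"""Scikit-learn-style estimator wrapping the full Bayesian fit.

`LatentTrajectoryModel` takes a long-format measurement table and fits the
log-normal / second-order-random-walk state-space model by MCMC, exposing
the posterior, trajectory summaries, contrasts against the control diet,
and convergence diagnostics as fitted attributes.  It composes with
sklearn tooling (`get_params`/`set_params`/`clone`); the module-level
functions in :mod:`atherotrend.inference` remain thin functional access to
the same machinery.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import diagnostics, inference
from .model import Measurements, PriorSpec


class LatentTrajectoryModel(BaseEstimator):
    """Bayesian latent-trajectory regression for grouped longitudinal data.

    Parameters
    ----------
    prior_sigma_obs_scale, prior_sigma_state_scale : float
        Half-normal prior scales for the observation noise sigma1 and the
        trend innovation scale sigma2 (standard half-normal by default).
    data_rescale : float
        Divisor applied to measurements before fitting so the standard
        priors stay weakly informative; summaries are reported in original
        units.  Use ~100 for raw pixel-area data of order hundreds.
    share_sigma_state : bool
        Single innovation scale shared across groups (default, the model
        as written) or one per group.
    n_chains, n_draws, n_warmup : int
        MCMC budget (n_chains >= 2).
    random_state : int
        Master seed; all chain streams derive from it.
    control : str, optional
        Control-group label for contrasts (default: first group in the
        data's food-index order).
    ci_level : float
        Credible level for all intervals (0.89 by convention here).
    interval : {"eti", "hpd"}
        Equal-tailed percentile interval (default) or highest-density.
    aggregate : {None, "mean"}
        Optionally collapse replicate mice to per-cell means.
    fix_sigma_obs, fix_sigma_state : float, optional
        Clamp a hyperparameter instead of sampling it.
    rhat_max, ess_min : float
        Convergence-gate thresholds recorded in ``convergence_``.

    Attributes
    ----------
    groups_ : tuple of str
    weeks_ : ndarray of observed week labels
    draws_ : PosteriorDraws
    summary_ : DataFrame — all-week trajectory summary with contrasts
    convergence_ : ConvergenceReport
    n_obs_ : int
    """

    def __init__(self, *, prior_sigma_obs_scale: float = 1.0,
                 prior_sigma_state_scale: float = 1.0,
                 data_rescale: float = 1.0,
                 share_sigma_state: bool = True,
                 n_chains: int = 4, n_draws: int = 1000,
                 n_warmup: int = 1000, random_state: int = 0,
                 control: Optional[str] = None, ci_level: float = 0.89,
                 interval: str = "eti",
                 aggregate: Optional[str] = None,
                 fix_sigma_obs: Optional[float] = None,
                 fix_sigma_state: Optional[float] = None,
                 rhat_max: float = diagnostics.DEFAULT_RHAT_MAX,
                 ess_min: float = diagnostics.DEFAULT_ESS_MIN):
        self.prior_sigma_obs_scale = prior_sigma_obs_scale
        self.prior_sigma_state_scale = prior_sigma_state_scale
        self.data_rescale = data_rescale
        self.share_sigma_state = share_sigma_state
        self.n_chains = n_chains
        self.n_draws = n_draws
        self.n_warmup = n_warmup
        self.random_state = random_state
        self.control = control
        self.ci_level = ci_level
        self.interval = interval
        self.aggregate = aggregate
        self.fix_sigma_obs = fix_sigma_obs
        self.fix_sigma_state = fix_sigma_state
        self.rhat_max = rhat_max
        self.ess_min = ess_min

    def _prior(self) -> PriorSpec:
        return PriorSpec(sigma_obs_scale=self.prior_sigma_obs_scale,
                         sigma_state_scale=self.prior_sigma_state_scale,
                         data_rescale=self.data_rescale)

    def fit(self, X: pd.DataFrame, y=None,
            groups: Optional[Sequence[str]] = None) -> "LatentTrajectoryModel":
        """Fit the model to a ``mouse_id,group,week,signal_area`` table.

        ``groups`` fixes the food-index order (control first); by default
        the order of first appearance is used.  ``y`` is ignored (present
        for sklearn API compatibility).
        """
        meas = (X if isinstance(X, Measurements)
                else Measurements.from_frame(X, groups=groups))
        if self.control is not None and self.control not in meas.groups:
            raise ValueError(
                f"control group {self.control!r} absent from data groups "
                f"{meas.groups}")
        self.draws_ = inference.sample_posterior(
            meas, prior=self._prior(), n_chains=self.n_chains,
            n_draws=self.n_draws, n_warmup=self.n_warmup,
            seed=self.random_state,
            share_sigma_state=self.share_sigma_state,
            fix_sigma_obs=self.fix_sigma_obs,
            fix_sigma_state=self.fix_sigma_state,
            aggregate=self.aggregate)
        self.groups_ = self.draws_.groups
        self.weeks_ = np.asarray(self.draws_.weeks)
        self.n_obs_ = len(meas)
        self.convergence_ = diagnostics.convergence_report(
            self.draws_, rhat_max=self.rhat_max, ess_min=self.ess_min)
        self.summary_ = inference.summarize_trajectories(
            self.draws_, control=self._control_label(),
            level=self.ci_level, interval=self.interval)
        return self

    def _control_label(self) -> str:
        return self.control if self.control is not None else self.groups_[0]

    def predict(self, X=None) -> pd.DataFrame:
        """Posterior-mode trajectory, weeks x groups (original units).

        ``X`` may be a sequence of week labels to select rows; by default
        all observed weeks are returned.
        """
        check_is_fitted(self, "draws_")
        weeks = list(self.weeks_) if X is None else list(X)
        data = {g: [inference.posterior_mode(
                    self.draws_.flat_A(list(self.weeks_).index(w), f))
                    for w in weeks]
                for f, g in enumerate(self.groups_)}
        return pd.DataFrame(data, index=pd.Index(weeks, name="week"))

    def summary(self, weeks: Optional[Sequence[int]] = None) -> pd.DataFrame:
        """Trajectory summary with contrasts at the requested weeks."""
        check_is_fitted(self, "draws_")
        return inference.summarize_trajectories(
            self.draws_, weeks=weeks, control=self._control_label(),
            level=self.ci_level, interval=self.interval)

    def contrast(self, week: int, group: str) -> inference.ContrastResult:
        """Within-draw contrast of ``group`` against the control at ``week``."""
        check_is_fitted(self, "draws_")
        return inference.group_contrast(
            self.draws_, week, group, control=self._control_label(),
            level=self.ci_level, interval=self.interval)
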
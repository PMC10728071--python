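"""Joint density: likelihood/prior/posterior vs independent scipy oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atherotrend._sampler import _logpost
from atherotrend.cohort import latent_from_innovations, innovations_from_latent
from atherotrend.model import (Measurements, ModelParameters, PriorSpec,
                               log_likelihood, log_posterior, log_prior)


def single_obs(y=1.0, week=0, group="g"):
    return Measurements.from_frame(pd.DataFrame(
        {"mouse_id": ["m1"], "group": [group], "week": [week],
         "signal_area": [y]}))


def scipy_log_likelihood(meas, params):
    A = params.latent()
    a = A[meas.t_idx, meas.f_idx]
    s1 = params.sigma_obs
    loc = np.log(a) - s1 ** 2 / 2
    return float(np.sum(stats.lognorm.logpdf(meas.y, s=s1,
                                             scale=np.exp(loc))))


def scipy_log_prior(params, prior):
    s2 = params.sigma_state_per_group()
    val = float(np.sum(stats.norm.logpdf(params.mu, 0.0,
                                         s2[np.newaxis, :])))
    val += float(stats.halfnorm.logpdf(params.sigma_obs,
                                       scale=prior.sigma_obs_scale))
    s2_terms = (s2[:1] if np.asarray(params.sigma_state).ndim == 0 else s2)
    for s in s2_terms:
        val += float(stats.halfnorm.logpdf(s,
                                           scale=prior.sigma_state_scale))
    return val


class TestLogLikelihood:
    def test_unit_observation_closed_form(self):
        # Y=1, A=1, sigma1=1: loc = -1/2, logpdf = -log(sqrt(2pi)) - 1/8
        params = ModelParameters(mu=np.array([[1.0]]), sigma_obs=1.0,
                                 sigma_state=1.0)
        expected = -np.log(np.sqrt(2 * np.pi)) - (0.0 - (-0.5)) ** 2 / 2
        assert log_likelihood(single_obs(), params) == \
            pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.04394, abs=1e-5)

    def test_nonpositive_latent_is_minus_inf(self):
        params = ModelParameters(mu=np.array([[-1.0]]), sigma_obs=0.5,
                                 sigma_state=1.0)
        assert log_likelihood(single_obs(), params) == -np.inf

    def test_two_identical_observations_double_the_value(self):
        df = pd.DataFrame({"mouse_id": ["a", "b"], "group": ["g", "g"],
                           "week": [0, 0], "signal_area": [2.5, 2.5]})
        meas2 = Measurements.from_frame(df)
        params = ModelParameters(mu=np.array([[3.0]]), sigma_obs=0.4,
                                 sigma_state=1.0)
        one = log_likelihood(single_obs(y=2.5), params)
        assert log_likelihood(meas2, params) == pytest.approx(2 * one,
                                                              rel=1e-12)

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            single_obs(y=0.0)

    def test_unknown_group_rejected(self):
        df = pd.DataFrame({"mouse_id": ["m"], "group": ["mystery"],
                           "week": [0], "signal_area": [1.0]})
        with pytest.raises(ValueError, match="unknown group"):
            Measurements.from_frame(df, groups=["g1", "g2"])

    def test_unimodal_in_log_A(self):
        # likelihood decreases as A moves away from the observed cloud
        rng = np.random.default_rng(3)
        y = 5.0 * np.exp(0.3 * rng.standard_normal(8))
        df = pd.DataFrame({"mouse_id": [f"m{i}" for i in range(8)],
                           "group": "g", "week": 0, "signal_area": y})
        meas = Measurements.from_frame(df)
        a_grid = np.exp(np.linspace(np.log(0.2), np.log(80), 120))
        ll = [log_likelihood(meas, ModelParameters(mu=np.array([[a]]),
                                                   sigma_obs=0.3,
                                                   sigma_state=1.0))
              for a in a_grid]
        ll = np.asarray(ll)
        peak = int(np.argmax(ll))
        assert np.all(np.diff(ll[:peak + 1]) > 0)
        assert np.all(np.diff(ll[peak:]) < 0)

    def test_joint_rescale_identity(self, rng):
        # scaling Y and A by c shifts the log likelihood by -n log c
        mu = rng.normal(size=(4, 2))
        mu[0] = np.abs(mu[0]) + 2.0
        A = latent_from_innovations(mu)
        assert np.all(A > 0)
        n = 10
        df = pd.DataFrame({
            "mouse_id": [f"m{i}" for i in range(n)],
            "group": rng.choice(["g1", "g2"], n),
            "week": rng.integers(0, 4, n),
            "signal_area": rng.uniform(0.5, 6.0, n)})
        meas = Measurements.from_frame(df, groups=["g1", "g2"])
        base = log_likelihood(meas, ModelParameters(mu=mu, sigma_obs=0.4,
                                                    sigma_state=1.0))
        c = 37.0
        scaled_meas = Measurements(y=meas.y * c, t_idx=meas.t_idx,
                                   f_idx=meas.f_idx, groups=meas.groups,
                                   n_weeks=meas.n_weeks)
        scaled = log_likelihood(scaled_meas,
                                ModelParameters(mu=mu * c, sigma_obs=0.4,
                                                sigma_state=1.0))
        assert scaled == pytest.approx(base - n * np.log(c), rel=1e-12)


class TestLogPrior:
    def test_assembled_value_matches_direct_formulas(self):
        T, F = 5, 3
        params = ModelParameters(mu=np.zeros((T, F)), sigma_obs=1.0,
                                 sigma_state=1.0)
        prior = PriorSpec()
        expected = (T * F * stats.norm.logpdf(0.0, 0.0, 1.0)
                    + 2 * stats.halfnorm.logpdf(1.0, scale=1.0))
        assert log_prior(params, prior) == pytest.approx(expected,
                                                         abs=1e-12)

    def test_negative_sigma_state_is_minus_inf(self):
        params = ModelParameters(mu=np.zeros((2, 1)), sigma_obs=1.0,
                                 sigma_state=-1.0)
        assert log_prior(params, PriorSpec()) == -np.inf

    def test_halfnormal_tail_monotone_in_scale(self):
        params = ModelParameters(mu=np.zeros((2, 1)), sigma_obs=1.0,
                                 sigma_state=4.0)
        lo = log_prior(params, PriorSpec(sigma_state_scale=1.0))
        hi = log_prior(params, PriorSpec(sigma_state_scale=2.0))
        assert hi > lo

    def test_per_group_sigma_state(self):
        params = ModelParameters(mu=np.zeros((3, 2)), sigma_obs=1.0,
                                 sigma_state=np.array([0.5, 2.0]))
        prior = PriorSpec()
        assert log_prior(params, prior) == \
            pytest.approx(scipy_log_prior(params, prior), abs=1e-10)


class TestLogPosterior:
    def test_sum_of_components(self):
        params = ModelParameters(mu=np.array([[2.0]]), sigma_obs=0.5,
                                 sigma_state=1.0)
        meas = single_obs(y=1.5)
        prior = PriorSpec()
        assert log_posterior(meas, params, prior) == pytest.approx(
            log_likelihood(meas, params) + log_prior(params, prior),
            rel=1e-12)

    def test_minus_inf_propagates(self):
        params = ModelParameters(mu=np.array([[-2.0]]), sigma_obs=0.5,
                                 sigma_state=1.0)
        assert log_posterior(single_obs(), params, PriorSpec()) == -np.inf

    def test_observation_order_invariance(self, rng):
        n = 12
        df = pd.DataFrame({
            "mouse_id": [f"m{i}" for i in range(n)],
            "group": "g", "week": rng.integers(0, 3, n),
            "signal_area": rng.uniform(0.5, 4.0, n)})
        params = ModelParameters(
            mu=np.abs(rng.normal(size=(3, 1))) + 0.5,
            sigma_obs=0.6, sigma_state=1.0)
        prior = PriorSpec()
        a = log_posterior(Measurements.from_frame(df), params, prior)
        shuffled = df.sample(frac=1.0, random_state=1)
        b = log_posterior(Measurements.from_frame(shuffled), params, prior)
        assert a == pytest.approx(b, rel=1e-12)


class TestDensityOracleSweep:
    def test_density_agrees_with_scipy_on_random_draws(self, rng):
        """Implementation vs direct-formula evaluation, 1000 random
        parameter/observation draws, <= 1e-10 absolute."""
        for _ in range(1000):
            T = int(rng.integers(1, 6))
            F = int(rng.integers(1, 4))
            mu = rng.normal(0, 2, size=(T, F))
            mu[0] = np.abs(mu[0]) + 1.0
            params = ModelParameters(
                mu=mu, sigma_obs=float(rng.uniform(0.1, 2.0)),
                sigma_state=float(rng.uniform(0.1, 3.0)))
            prior = PriorSpec(sigma_obs_scale=float(rng.uniform(0.5, 2)),
                              sigma_state_scale=float(rng.uniform(0.5, 2)))
            n = int(rng.integers(1, 8))
            A = params.latent()
            t_idx = rng.integers(0, T, n)
            f_idx = rng.integers(0, F, n)
            ok = A[t_idx, f_idx] > 0
            if not ok.all():
                t_idx, f_idx = t_idx[ok], f_idx[ok]
                n = int(ok.sum())
                if n == 0:
                    continue
            meas = Measurements(y=rng.uniform(0.2, 10.0, n), t_idx=t_idx,
                                f_idx=f_idx,
                                groups=[f"g{j}" for j in range(F)],
                                n_weeks=T)
            assert log_likelihood(meas, params) == pytest.approx(
                scipy_log_likelihood(meas, params), abs=1e-10)
            assert log_prior(params, prior) == pytest.approx(
                scipy_log_prior(params, prior), abs=1e-10)


class TestSamplerDensityConsistency:
    def test_jitted_kernel_density_matches_model_functions(self, rng):
        """The numba kernel's density (over state-space theta, log-sigma
        parametrization) equals log_posterior plus the log-sigma Jacobian."""
        for _ in range(50):
            T = int(rng.integers(1, 5))
            F = int(rng.integers(1, 3))
            A = rng.uniform(0.2, 5.0, size=(T, F))
            s1 = float(rng.uniform(0.2, 1.5))
            s2 = float(rng.uniform(0.2, 1.5))
            mu = innovations_from_latent(A)
            params = ModelParameters(mu=mu, sigma_obs=s1, sigma_state=s2)
            n = int(rng.integers(1, 6))
            t_idx = rng.integers(0, T, n)
            f_idx = rng.integers(0, F, n)
            y = rng.uniform(0.3, 6.0, n)
            meas = Measurements(y=y, t_idx=t_idx, f_idx=f_idx,
                                groups=[f"g{j}" for j in range(F)],
                                n_weeks=T)
            prior = PriorSpec()
            theta = np.concatenate([A.reshape(-1),
                                    [np.log(s1)], [np.log(s2)]])
            got = _logpost(theta, np.log(y), t_idx.astype(np.int64),
                           f_idx.astype(np.int64), T, F,
                           np.zeros(F, np.int64), 1, 1.0, 1.0)
            want = (log_posterior(meas, params, prior)
                    + np.log(s1) + np.log(s2))
            assert got == pytest.approx(want, abs=1e-9)
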
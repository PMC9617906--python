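import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from activegel.inference import (
    LikelihoodConfig,
    PhaseObservation,
    Priors,
    log_likelihood,
    log_prior,
    prepare_observations,
    run_mcmc,
    theta_to_constants,
)
from activegel.synthetic import GeneratorConfig, generate_phase_observations

TRUTH_THETA = np.array([math.log(1600.0), math.log(1000.0),
                        math.log(0.3), math.log(0.6 / 0.4)])
TRUTH_NATURAL = {"zeta0_over_mu0": 1600.0, "K0_over_kappa0": 1000.0,
                 "kappa0_over_zeta0": 0.3, "p0": 0.6}


@pytest.fixture(scope="module")
def observations():
    df = generate_phase_observations(GeneratorConfig(seed=42))
    return prepare_observations(df)


class TestPrepareObservations:
    def test_labels_weights_and_wavelength_masking(self):
        df = pd.DataFrame({
            "atp": [10.0] * 4, "motors": [60.0] * 4, "prc1": [100.0] * 4,
            "mt_length": [1.5] * 4,
            "B": [0.02, 0.7, 0.1, 0.45],
            "lambda_obs": [50.0, 60.0, 55.0, 58.0],
        })
        obs = prepare_observations(df)
        assert list(obs.y) == [0.0, 1.0, 0.0, 1.0]  # mixed -> nearest side
        assert list(obs.weight) == [1.0, 1.0, 0.5, 0.5]
        assert list(obs.has_lam) == [True, True, False, False]

    def test_observation_dataclass_route(self):
        obs = prepare_observations([
            PhaseObservation(atp=5.0, motors=30.0, prc1=100.0,
                             mt_length=1.5, B=0.8, lambda_obs=70.0),
            PhaseObservation(atp=500.0, motors=30.0, prc1=100.0,
                             mt_length=1.5, B=0.0),
        ])
        assert obs.n == 2 and obs.y[0] == 1.0 and not obs.has_lam[1]

    def test_validation(self):
        with pytest.raises(ValueError):
            PhaseObservation(atp=1, motors=1, prc1=1, mt_length=1, B=1.3)
        with pytest.raises(ValueError):
            prepare_observations(pd.DataFrame({"B": []}))


class TestLogLikelihood:
    def test_duplicating_observations_doubles_it(self, observations):
        df = generate_phase_observations(GeneratorConfig(seed=42))
        single = log_likelihood(TRUTH_THETA, prepare_observations(df))
        double = log_likelihood(TRUTH_THETA,
                                prepare_observations(
                                    pd.concat([df, df], ignore_index=True)))
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_boundary_composition_gives_log_half(self, true_constants):
        # exactly on the phase boundary the direction term is a coin flip
        from activegel.phase_diagram import boundary_trace

        bt = boundary_trace("motors", (5.0, 400.0, 60, "lin"),
                            "atp", np.array([8.0]),
                            {"prc1": 100.0, "mt_length": 1.5},
                            true_constants)
        m_star = float(bt["motors"].iloc[0])
        df = pd.DataFrame({"atp": [8.0], "motors": [m_star],
                           "prc1": [100.0], "mt_length": [1.5], "B": [0.9]})
        ll = log_likelihood(TRUTH_THETA, prepare_observations(df),
                            LikelihoodConfig(use_wavelength=False))
        assert ll == pytest.approx(math.log(0.5), rel=1e-5)

    def test_clearly_separated_data_near_max_likelihood(self):
        cfg = GeneratorConfig(seed=7, noise_scale=0.0)
        df = generate_phase_observations(cfg)
        clear = df[np.abs(df["true_log_ratio"]) > 2.0]
        obs = prepare_observations(clear)
        ll = log_likelihood(TRUTH_THETA, obs,
                            LikelihoodConfig(use_wavelength=False))
        # every Bernoulli term close to log(1): well above one nat per row
        assert ll > -0.05 * obs.n

    def test_rejects_bad_inputs(self, observations):
        with pytest.raises(ValueError):
            log_likelihood(np.array([0.0, 0.0, np.nan, 0.0]), observations)


class TestPrior:
    def test_box_bounds(self):
        pr = Priors()
        inside = np.array([0.0, 0.0, 0.0, 0.3])
        assert np.isfinite(log_prior(inside, pr))
        outside = inside.copy()
        outside[0] = math.log(1e6)
        assert log_prior(outside, pr) == -np.inf

    def test_theta_roundtrip_to_constants(self):
        k = theta_to_constants(TRUTH_THETA)
        assert k.zeta0 / k.mu0 == pytest.approx(1600.0, rel=1e-9)
        assert k.K0 / k.kappa0 == pytest.approx(1000.0, rel=1e-9)
        assert k.kappa0 / k.zeta0 == pytest.approx(0.3, rel=1e-9)
        assert k.p0 == pytest.approx(0.6, rel=1e-9)


class TestRunMcmc:
    def test_deterministic_replay(self, observations):
        s1 = run_mcmc(observations, n_chains=2, n_steps=400, seed=5)
        s2 = run_mcmc(observations, n_chains=2, n_steps=400, seed=5)
        assert np.array_equal(s1.chains, s2.chains)

    def test_prior_recovery_on_flat_likelihood(self):
        summary = run_mcmc(None, n_chains=4, n_steps=20_000, seed=3,
                           prior_only=True)
        draws = summary.chains.reshape(-1, 4)
        pr = Priors()
        for i, (lo, hi) in enumerate(pr.log_bounds):
            ks = kstest(draws[:, i], "uniform", args=(lo, hi - lo)).statistic
            assert ks <= 0.05
        p0 = 1.0 / (1.0 + np.exp(-draws[:, 3]))
        assert kstest(p0, "uniform").statistic <= 0.05

    def test_recovers_planted_parameters(self, observations):
        summary = run_mcmc(observations, n_chains=4, n_steps=5000, seed=1)
        for name, value in TRUTH_NATURAL.items():
            lo, hi = summary.credible_interval(name)
            assert lo <= value <= hi, f"{name}: {value} not in [{lo}, {hi}]"
        assert 0.05 <= summary.acceptance_rate <= 0.8
        table = summary.table
        assert (table["q2.5"] <= table["median"]).all()
        assert (table["median"] <= table["q97.5"]).all()

    def test_agrees_with_ensemble_sampler_oracle(self, observations):
        # independent cross-check: an affine-invariant ensemble sampler on
        # the identical posterior must land on the same posterior mass
        emcee = pytest.importorskip("emcee")
        cfg = LikelihoodConfig()
        pr = Priors()

        def log_post(t):
            lp = log_prior(t, pr)
            if not np.isfinite(lp):
                return -np.inf
            return lp + log_likelihood(t, observations, cfg)

        rng = np.random.default_rng(17)
        p0 = TRUTH_THETA + 0.4 * rng.normal(size=(24, 4))
        sampler = emcee.EnsembleSampler(24, 4, log_post)
        sampler.run_mcmc(p0, 1500, progress=False)
        flat = sampler.get_chain(discard=750, flat=True)
        ours = run_mcmc(observations, n_chains=4, n_steps=5000, seed=2)
        our_flat = ours.chains.reshape(-1, 4)
        for i in range(4):
            ens_mean, ens_sd = flat[:, i].mean(), flat[:, i].std()
            assert abs(our_flat[:, i].mean() - ens_mean) < 0.35 * ens_sd
            assert 0.5 < our_flat[:, i].std() / ens_sd < 2.0

    def test_input_validation(self, observations):
        with pytest.raises(ValueError):
            run_mcmc(observations, n_chains=1, n_steps=100, seed=0)
        with pytest.raises(ValueError):
            run_mcmc(observations, n_chains=2, n_steps=5, seed=0)


class TestPosteriorPredictiveBoundary:
    def test_band_encloses_generating_boundary(self, observations,
                                               true_constants):
        from activegel.inference import posterior_predictive_boundary
        from activegel.phase_diagram import boundary_trace

        summary = run_mcmc(observations, n_chains=4, n_steps=3000, seed=8)
        fixed = {"motors": 60.0, "mt_length": 1.5}
        prc1 = np.linspace(100.0, 400.0, 4)
        band = posterior_predictive_boundary(
            summary, "atp", (1.0, 1500.0, 40, "log"), "prc1", prc1,
            fixed, n_draws=40, seed=0)
        truth = boundary_trace("atp", (1.0, 1500.0, 40, "log"),
                               "prc1", prc1, fixed, true_constants)
        merged = band.merge(truth, on=["prc1", "crossing"])
        assert len(merged) >= 3
        inside = ((merged["q2.5"] * 0.9 <= merged["atp"]) &
                  (merged["atp"] <= merged["q97.5"] * 1.1))
        assert inside.mean() >= 0.75
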
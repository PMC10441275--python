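"""Likelihood, Metropolis-Hastings sampling and the K-swap check."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import picompete as pc
from picompete.exceptions import ConfigurationError
from picompete.incubation import _ABUND_COLS, _NUTR_COLS
from picompete.model import FitConfig, _config_to_vector


def _empty_dataset() -> pc.IncubationDataset:
    return pc.IncubationDataset(
        abundance=pd.DataFrame(columns=_ABUND_COLS),
        nutrients=pd.DataFrame(columns=_NUTR_COLS))


class TestLogLikelihood:
    def test_empty_dataset_scores_zero(self, ref_cfg):
        assert pc.log_likelihood(ref_cfg, _empty_dataset()) == 0.0

    def test_maximized_at_generating_parameters(self, ref_cfg):
        """Noise-free data score strictly higher at the generating
        parameters than with any half-saturation constant doubled."""
        data = pc.generate_incubation(ref_cfg,
                                      design=pc.IncubationDesign(duration=4),
                                      sigma_log10=0.0, seed=0)
        ll_truth = pc.log_likelihood(ref_cfg, data)
        for which, attr in (("pro", "k_nh4"), ("pro", "k_no3"),
                            ("syn", "k_nh4"), ("syn", "k_no3")):
            g = ref_cfg.genus(which)
            perturbed = g.replace(**{attr: getattr(g, attr) * 2})
            cfg2 = ref_cfg.replace(**{which: perturbed})
            assert pc.log_likelihood(cfg2, data) < ll_truth

    def test_censored_observation_contributes_tail_probability(self, ref_cfg):
        """A below-detection NH4+ record adds log P(obs < limit), verified
        against numeric integration of the Gaussian tail."""
        sigma_nutrient = 2.0
        limit = 6.0
        day = 3.0
        base = _empty_dataset()
        nut = pd.DataFrame([("add_nh4", 1, day, "nh4", limit, True)],
                           columns=_NUTR_COLS)
        data = pc.IncubationDataset(abundance=base.abundance, nutrients=nut)
        ll = pc.log_likelihood(ref_cfg, data, sigma_nutrient=sigma_nutrient)
        # independent evaluation: simulate, then integrate the density tail
        init = pc.default_initial()
        spec = [s for s in data.design.specs if s.name == "add_nh4"][0]
        traj = pc.integrate(ref_cfg, pc.treatment_initial_state(init, spec),
                            t_end=day, dt_out=1.0)
        mu = traj.state_at(day).nh4
        tail, _ = quad(lambda x: np.exp(-0.5 * ((x - mu) / sigma_nutrient) ** 2)
                       / (sigma_nutrient * np.sqrt(2 * np.pi)),
                       -np.inf, limit)
        # the sampling path integrates at rtol 1e-5, so compare loosely
        assert ll == pytest.approx(np.log(tail), abs=1e-4)


class TestMetropolisHastings:
    def test_toy_gaussian_moments(self):
        """On a two-parameter Gaussian target (in log-coordinates, which is
        the sampler's reference measure) the chain reproduces the analytic
        mean and standard deviation."""
        mu, sd = np.log(2.0), 0.3

        def log_target(theta):
            z = (np.log(theta) - mu) / sd
            return float(-0.5 * z @ z)

        rng = np.random.default_rng(12)
        samples, _, acc = pc.metropolis_hastings(
            log_target, np.array([2.0, 2.0]), 50_000, [0.4, 0.4], rng)
        logs = np.log(samples[5000:])
        assert 0.1 < acc < 0.95
        for j in range(2):  # both coordinates, exchangeable by construction
            assert np.mean(logs[:, j]) == pytest.approx(mu, abs=0.03)
            assert np.std(logs[:, j]) == pytest.approx(sd, abs=0.03)

    def test_same_seed_reproduces_chain(self, ref_cfg, small_dataset):
        model = pc.CompetitionModel(small_dataset, start=ref_cfg)
        r1 = model.fit(n_iterations=400, burn_in=100, seed=21)
        r2 = model.fit(n_iterations=400, burn_in=100, seed=21)
        assert np.array_equal(r1.chain.samples, r2.chain.samples)
        r3 = model.fit(n_iterations=400, burn_in=100, seed=22)
        assert not np.array_equal(r1.chain.samples, r3.chain.samples)

    def test_invalid_iteration_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            FitConfig(n_iterations=100, burn_in=100)
        with pytest.raises(ConfigurationError):
            FitConfig(n_iterations=100, burn_in=200)

    def test_results_surface(self, ref_cfg, small_dataset):
        model = pc.CompetitionModel(small_dataset, start=ref_cfg)
        res = model.fit(n_iterations=600, burn_in=200, seed=4)
        assert set(res.params.index) == set(pc.model.PARAM_NAMES)
        ci = res.conf_int(0.90)
        assert (ci["lower"] <= res.params).all()
        assert (res.params <= ci["upper"]).all()
        text = res.summary()
        assert "acceptance" in text and "KNH4Pro" in text
        rmse = res.rmse()
        assert set(rmse["treatment"]) == {"control", "add_no3", "add_nh4"}
        preds = res.predict()
        assert set(preds) == {"control", "add_no3", "add_nh4"}


class TestSwapExperiment:
    def test_swap_is_identity_for_equal_k(self, ref_cfg):
        """With both genera sharing the same K for a nutrient the swap
        changes nothing, so the RMSE is unchanged."""
        cfg = ref_cfg.replace(
            syn=ref_cfg.syn.replace(k_nh4=ref_cfg.pro.k_nh4))
        data = pc.generate_incubation(cfg, sigma_log10=0.0, seed=0)
        rep = pc.swap_experiment(cfg, data, "nh4")
        assert np.allclose(rep["rmse_before"], rep["rmse_after"])

    @pytest.mark.parametrize("which,treatment", [("nh4", "add_nh4"),
                                                 ("no3", "add_no3")])
    def test_swap_degrades_fit_in_matching_treatment(self, ref_cfg, which,
                                                     treatment):
        """Reversing the genera's relative affinity for a substrate makes
        the model deviate from data generated under the original traits,
        most clearly in the corresponding amendment treatment."""
        data = pc.generate_incubation(ref_cfg,
                                      design=pc.IncubationDesign(duration=4),
                                      sigma_log10=0.0, seed=0)
        rep = pc.swap_experiment(ref_cfg, data, which)
        sub = rep[rep["treatment"] == treatment]
        assert (sub["rmse_after"] > sub["rmse_before"]).all()
        # and never an improvement anywhere on truth-generated data
        assert (rep["rmse_after"] >= rep["rmse_before"] - 1e-12).all()

    def test_unknown_nutrient_rejected(self, ref_cfg, small_dataset):
        with pytest.raises(ConfigurationError):
            pc.swap_experiment(ref_cfg, small_dataset, "urea")
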
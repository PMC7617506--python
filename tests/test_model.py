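"""Hierarchical Bayesian fit: likelihood, sampler validity, diagnostics."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from teatk.kinetics import PARAM_NAMES, TKParams
from teatk.model import (
    PopTKModel,
    PopTKResults,
    PopulationPrior,
    log_likelihood,
    split_rhat,
)
from teatk.sampling import run_mh
from teatk.trial import OBS_CLASSES, gen_trial

UNIT_GSDS = {c: math.e for c in OBS_CLASSES}


def _truth_params(ds):
    return [TKParams.from_array([t[n] for n in PARAM_NAMES])
            for t in ds.truth["individuals"]]


class TestLogLikelihood:
    def test_exact_predictions_give_reference_density(self):
        # noise-free data at the generating parameters, error GSD = e:
        # every term is the standard-normal log density at zero
        ds = gen_trial(n_subjects=2, error_gsd={c: 1.0 for c in OBS_CLASSES},
                       lod={c: 0.0 for c in OBS_CLASSES}, seed=3)
        ll = log_likelihood(ds, _truth_params(ds), UNIT_GSDS)
        n_obs = len(ds.observations)
        assert ll == pytest.approx(n_obs * norm.logpdf(0.0), rel=1e-9)

    def test_scale_invariance_of_log_residuals(self):
        # doubling dose doubles predictions; doubling observations too
        # leaves every log residual unchanged
        zero_lod = {c: 0.0 for c in OBS_CLASSES}
        ds = gen_trial(n_subjects=2, seed=3, lod=zero_lod)
        params = _truth_params(ds)
        gsds = {c: 1.3 for c in OBS_CLASSES}
        ll = log_likelihood(ds, params, gsds)
        ds2 = gen_trial(n_subjects=2, seed=3, lod=zero_lod,
                        dose_ng_per_kg=3000.0)
        np.testing.assert_allclose(ds2.observations["value"],
                                   2.0 * ds.observations["value"])
        ll2 = log_likelihood(ds2, params, gsds)
        assert ll2 == pytest.approx(ll, rel=1e-9)

    def test_censored_term_matches_quadrature(self):
        # closed-form lognormal log-CDF at the LOD vs numeric integration
        ds = gen_trial(n_subjects=2, seed=11)
        obs = ds.observations
        assert obs["censored"].any()
        params = _truth_params(ds)
        gsds = {c: 1.4 for c in OBS_CLASSES}
        ll_full = log_likelihood(ds, params, gsds)

        uncens = ds.observations[~ds.observations["censored"]]
        ds_unc = gen_trial(n_subjects=2, seed=11)
        ds_unc.observations = uncens
        ll_unc = log_likelihood(ds_unc, params, gsds)
        censored_contrib = ll_full - ll_unc

        # recompute the censored contribution by quadrature
        from teatk.model import _dataset_subjects
        total = 0.0
        sigma = math.log(1.4)
        for design, p in zip(ds.designs, params):
            sub = obs[(obs["subject"] == design.subject) & obs["censored"]]
            from teatk.kinetics import observe, simulate_analytic
            traj = simulate_analytic(p, design.dose_ng_per_kg,
                                     design.blood_times_h)
            pred = observe(traj, design)
            lookup = {
                ("blood", "free"): dict(zip(design.blood_times_h,
                                            pred.blood_free)),
                ("blood", "total"): dict(zip(design.blood_times_h,
                                             pred.blood_total)),
                ("urine", "free"): {tuple(iv): v for iv, v in zip(
                    design.urine_intervals_h, pred.urine_free)},
                ("urine", "total"): {tuple(iv): v for iv, v in zip(
                    design.urine_intervals_h, pred.urine_total)},
            }
            for _, row in sub.iterrows():
                key = (row["matrix"], row["analyte"])
                m = lookup[key][row["time_h"]] if row["matrix"] == "blood" \
                    else lookup[key][(row["t_start_h"], row["t_end_h"])]
                # integrate the lognormal density in log coordinates
                dens = lambda u: np.exp(
                    -0.5 * ((u - np.log(m)) / sigma) ** 2) \
                    / (sigma * np.sqrt(2 * np.pi))
                lo = np.log(m) - 40.0 * sigma
                prob, _ = quad(dens, lo, math.log(row["lod"]), limit=400)
                total += math.log(prob)
        assert censored_contrib == pytest.approx(total, abs=1e-8 * abs(total)
                                                 + 1e-8)

    def test_nonpositive_prediction_is_minus_inf(self):
        ds = gen_trial(n_subjects=2, seed=3,
                       lod={c: 0.0 for c in OBS_CLASSES})
        # absurd parameters push late blood predictions to numerical zero
        bad = TKParams(cl_tot=500.0, vd=0.01, vd_met=0.01, cl_met=500.0,
                       k_gutabs=500.0, k_ufrac=0.9, f_gluc=0.9)
        ll = log_likelihood(ds, [bad, bad], UNIT_GSDS)
        assert ll == -np.inf

    def test_fast_path_agrees_with_reference(self, default_trial):
        from teatk.model import _StackedData, _dataset_subjects
        params = _truth_params(default_trial)
        gsds = {c: 1.27 for c in OBS_CLASSES}
        esd = np.array([math.log(gsds[c]) for c in OBS_CLASSES])
        subjects = _dataset_subjects(default_trial)
        stacked = _StackedData(subjects)
        lp = stacked.predict_log(np.array([p.to_array() for p in params]))
        fast = stacked.loglik(lp, esd).sum()
        slow = sum(s.loglik(s.predict_log(p.to_array()), esd)
                   for s, p in zip(subjects, params))
        ref = log_likelihood(default_trial, params, gsds)
        assert fast == pytest.approx(ref, rel=1e-12)
        assert slow == pytest.approx(ref, rel=1e-12)


class TestSplitRhat:
    def test_identical_chains_are_converged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        chains = np.tile(x, (4, 1))
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_constant_chains_diverge(self):
        chains = np.stack([np.zeros(100), np.ones(100)])
        assert split_rhat(chains) > 1.2

    def test_iid_normal_draws_converge(self):
        rng = np.random.default_rng(5)
        chains = rng.standard_normal((4, 5000))
        assert split_rhat(chains) < 1.01

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.zeros((1, 100)))

    def test_agrees_with_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = np.cumsum(rng.standard_normal((4, 600)), axis=1) * 0.05 \
            + rng.standard_normal((4, 600))
        ours = split_rhat(chains)
        theirs = float(arviz.rhat(
            arviz.convert_to_dataset(chains), method="split").x)
        assert ours == pytest.approx(theirs, rel=0.02)


class TestSamplerKernel:
    def test_posterior_mean_matches_grid_integration(self):
        """1-D toy posterior: adaptive MH vs dense grid quadrature."""
        ds = gen_trial(
            n_subjects=2, error_gsd={c: 1.0 for c in OBS_CLASSES},
            lod={c: 0.0 for c in OBS_CLASSES},
            blood_times=np.array([1.0, 6.0]),
            void_edges=np.array([0.0, 48.0]), seed=21)
        truths = _truth_params(ds)
        gsds = {c: 1.5 for c in OBS_CLASSES}

        def with_cl(x):
            return [TKParams(cl_tot=float(np.exp(x)), vd=t.vd,
                             vd_met=t.vd_met, cl_met=t.cl_met,
                             k_gutabs=t.k_gutabs, k_ufrac=t.k_ufrac,
                             f_gluc=t.f_gluc) for t in truths]

        prior = norm(loc=np.log(1.58), scale=0.5)

        def logpost(x):
            return log_likelihood(ds, with_cl(x[0]), gsds) \
                + prior.logpdf(x[0])

        draws, _ = run_mh(logpost, np.array([np.log(1.0)]), 20_000, seed=4)
        mcmc_mean = draws.mean()

        grid = np.linspace(np.log(0.3), np.log(8.0), 1501)
        logp = np.array([logpost(np.array([g])) for g in grid])
        w = np.exp(logp - logp.max())
        grid_mean = np.sum(grid * w) / np.sum(w)
        assert mcmc_mean == pytest.approx(grid_mean, abs=0.02 * abs(grid_mean)
                                          + 0.005)

    def test_degenerate_posterior_recovers_truth(self):
        """Noise-free data plus tight priors pin the population GMs."""
        ds = gen_trial(
            n_subjects=3,
            pop_gsd={n: 1.0 for n in PARAM_NAMES},
            error_gsd={c: 1.0 for c in OBS_CLASSES},
            lod={c: 0.0 for c in OBS_CLASSES}, seed=5)
        prior = PopulationPrior(
            gm0={n: ds.truth["pop_gm"][n] for n in PARAM_NAMES},
            gsd0={n: 1.05 for n in PARAM_NAMES})
        res = PopTKModel(ds, prior=prior).fit(
            n_chains=2, n_iter=6000, seed=9)
        med = np.median(res.population_gm().reshape(-1, 7), axis=0)
        truth = np.array([ds.truth["pop_gm"][n] for n in PARAM_NAMES])
        np.testing.assert_allclose(med, truth, rtol=0.01)

    def test_same_seed_reproducible(self, small_trial):
        model = PopTKModel(small_trial)
        r1 = model.fit(n_chains=2, n_iter=1000, seed=31)
        r2 = model.fit(n_chains=2, n_iter=1000, seed=31)
        for key in ("mu", "sigma", "theta", "esd"):
            np.testing.assert_array_equal(r1.draws[key], r2.draws[key])

    def test_requirements_validated(self, small_trial):
        model = PopTKModel(small_trial)
        with pytest.raises(ValueError):
            model.fit(n_chains=1, n_iter=2000, seed=0)
        with pytest.raises(ValueError):
            model.fit(n_chains=2, n_iter=500, seed=0)

    def test_all_censored_dataset_rejected(self):
        ds = gen_trial(n_subjects=2, seed=3)
        ds.observations["censored"] = True
        with pytest.raises(ValueError, match="censored"):
            PopTKModel(ds)

    def test_exchangeability_of_subject_order(self, small_trial):
        """Permuting subjects leaves posterior summaries invariant."""
        res1 = PopTKModel(small_trial).fit(n_chains=2, n_iter=3000, seed=13)
        ds2 = gen_trial(
            n_subjects=3,
            blood_times=small_trial.designs[0].blood_times_h,
            void_edges=np.r_[small_trial.designs[0].urine_intervals_h[:, 0],
                             48.0],
            seed=7)
        order = [2, 0, 1]
        ds2.designs = [ds2.designs[i] for i in order]
        res2 = PopTKModel(ds2).fit(n_chains=2, n_iter=3000, seed=13)
        m1 = np.median(res1.population_gm().reshape(-1, 7), axis=0)
        m2 = np.median(res2.population_gm().reshape(-1, 7), axis=0)
        # medians must agree within Monte Carlo error, scaled by the
        # posterior spread (weakly identified parameters mix slowly)
        spread = np.log(res1.population_gm()).reshape(-1, 7).std(axis=0)
        assert (np.abs(np.log(m1) - np.log(m2))
                < 0.5 * spread + 0.1).all()


def _manual_results(model, mu, sigma, n_draws=400, esd=None, jitter=0.0,
                    seed=0):
    """Assemble a PopTKResults with prescribed population draws."""
    rng = np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    shape = (2, n_draws)
    mu_d = np.broadcast_to(mu, shape + (7,)).copy()
    sig_d = np.broadcast_to(sigma, shape + (7,)).copy()
    if jitter:
        mu_d += jitter * rng.standard_normal(mu_d.shape)
    theta = np.broadcast_to(mu, shape + (model.n_subjects, 7)).copy()
    esd_d = np.broadcast_to(
        esd if esd is not None else np.full(4, 0.2), shape + (4,)).copy()
    return PopTKResults(model=model,
                        draws={"mu": mu_d, "sigma": sig_d,
                               "theta": theta, "esd": esd_d},
                        n_chains=2, n_iter=n_draws * 2, burn_frac=0.5,
                        seed=seed, thin=1)


class TestResults:
    def test_summary_of_degenerate_draws(self, small_trial, pop_params):
        model = PopTKModel(small_trial)
        logs = np.log(pop_params.to_array())
        res = _manual_results(model, logs, np.full(7, 1e-9))
        summ = res.summary()
        assert summ.loc["cl_tot", "gm_median"] == pytest.approx(1.58)
        assert summ.loc["t_half", "gm_median"] == pytest.approx(
            np.log(2) * 4.35 / 1.58)
        assert summ.loc["cl_met", "gm_median"] == pytest.approx(33.7, rel=1e-6)

    def test_per_draw_transform_consistency(self, small_trial):
        """Monotone maps commute with quantiles of per-draw transforms."""
        model = PopTKModel(small_trial)
        rng = np.random.default_rng(2)
        mu = np.log([1.58, 4.35, 7.36, 4.58, 23.9, 0.212, 0.098])
        res = _manual_results(model, mu, np.full(7, 0.1), jitter=0.25,
                              seed=2)
        summ = res.summary()
        gm = res.population_gm().reshape(-1, 7)
        th = np.log(2) * gm[:, 1] / gm[:, 0]
        assert summ.loc["t_half", "gm_median"] == pytest.approx(
            np.median(th), rel=1e-9)

    def test_posterior_contraction_vs_prior(self, default_fit):
        """The data narrow every population-mean posterior vs its prior."""
        prior_sd = np.log(9.97)
        post_sd = default_fit.draws["mu"].reshape(-1, 7).std(axis=0)
        assert (post_sd < prior_sd).all()

    def test_degenerate_band_collapses_to_trajectory(self, small_trial,
                                                     pop_params):
        from teatk.kinetics import simulate_analytic
        model = PopTKModel(small_trial)
        logs = np.log(pop_params.to_array())
        res = _manual_results(model, logs, np.full(7, 1e-12))
        design = small_trial.designs[0]
        pred = res.posterior_predict(design, n_draws=50, seed=1)
        lo, med, hi = pred.band("c_free")
        traj = simulate_analytic(pop_params, design.dose_ng_per_kg,
                                 pred.times)
        np.testing.assert_allclose(med, traj.c_free, rtol=1e-6)
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-9)

    def test_band_nominal_coverage(self, small_trial):
        """~90% of noise-free new-subject observations fall inside the
        90% band when predicting from the generating population."""
        from teatk.kinetics import simulate_analytic
        from teatk.trial import default_truth_gm, default_truth_gsd, \
            gen_population
        model = PopTKModel(small_trial)
        gm = default_truth_gm()
        gsd = default_truth_gsd()
        mu = np.log(gm.to_array())
        sigma = np.log([gsd[n] for n in PARAM_NAMES])
        res = _manual_results(model, mu, sigma, n_draws=1500)
        design = small_trial.designs[0]
        times = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        pred = res.posterior_predict(design, times=times, n_draws=3000,
                                     seed=8)
        lo, _, hi = pred.band("c_free")
        rng_pop = gen_population(400, gm, gsd, seed=123)
        inside = []
        for p in rng_pop:
            c = simulate_analytic(p, design.dose_ng_per_kg, times).c_free
            inside.append((c >= lo) & (c <= hi))
        rate = np.mean(inside)
        assert 0.84 <= rate <= 0.96

    def test_bands_widen_with_inflated_variability(self, small_trial,
                                                   pop_params):
        model = PopTKModel(small_trial)
        logs = np.log(pop_params.to_array())
        narrow = _manual_results(model, logs, np.full(7, 0.1))
        wide = _manual_results(model, logs, np.full(7, 0.5))
        design = small_trial.designs[0]
        times = np.linspace(0.5, 24.0, 20)
        b_narrow = narrow.posterior_predict(design, times=times,
                                            n_draws=1200, seed=3)
        b_wide = wide.posterior_predict(design, times=times, n_draws=1200,
                                        seed=3)
        w_n = b_narrow.band("c_free")[2] - b_narrow.band("c_free")[0]
        w_w = b_wide.band("c_free")[2] - b_wide.band("c_free")[0]
        assert (w_w >= w_n * 0.99).all()
        assert w_w.sum() > 1.5 * w_n.sum()

    def test_predicted_vs_observed_pairs(self, small_trial):
        model = PopTKModel(small_trial)
        mu = np.log([1.58, 4.35, 7.36, 4.58, 23.9, 0.212, 0.098])
        res = _manual_results(model, mu, np.full(7, 0.1))
        pairs = res.predicted_vs_observed(n_draws=50, seed=0)
        assert {"subject", "obs_class", "observed", "predicted",
                "censored"} <= set(pairs.columns)
        assert len(pairs) == len(small_trial.observations)
        assert (pairs["predicted"] > 0).all()
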
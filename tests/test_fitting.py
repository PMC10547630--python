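"""Individual and population fits: recovery, likelihood structure, AIC."""

import numpy as np
import pandas as pd
import pytest

from oralpk import (
    BatemanParams,
    ErrorModel,
    FitConfig,
    GammaParams,
    compute_aic,
    conc_bateman,
    conc_gamma,
    fit_individual,
    fit_population,
)
from oralpk.datasets import StudyDataset, SubjectRecords
from oralpk.fitting import _gauss_loglik


def _bateman_subject(A=1.0, ka=0.5, ke=0.05, n=24):
    t = np.geomspace(0.5, 48, n)
    return SubjectRecords("S1", t, conc_bateman(t, BatemanParams(A=A, ka=ka, ke=ke)), 30.0)


def _bateman_study(rng, n_subjects=12, cv=0.25):
    """Study generated from a ka1C population (log-normal, CV 25%).

    Returns the dataset and the realized geometric means of the subjects'
    true parameters — the quantity a consistent population estimator
    targets for one finite study.
    """
    t = np.geomspace(0.5, 48, 16)
    rows, logs = [], []
    sigma = np.sqrt(np.log1p(cv**2))
    for i in range(n_subjects):
        A = 1.0 * np.exp(sigma * rng.standard_normal())
        ka = 0.5 * np.exp(sigma * rng.standard_normal())
        ke = 0.05 * np.exp(sigma * rng.standard_normal())
        logs.append(np.log([A, ka, ke]))
        c = conc_bateman(t, BatemanParams(A=A, ka=ka, ke=ke))
        obs = np.maximum(c + rng.standard_normal(len(t)) * (0.005 + 0.05 * c), 0)
        for tj, cj in zip(t, obs):
            rows.append({"ID": f"S{i:02d}", "TIME": tj, "DV": cj, "DOSE": 30.0})
    gm = dict(zip(("A", "ka", "ke"), np.exp(np.mean(logs, axis=0))))
    return StudyDataset(frame=pd.DataFrame(rows)), gm


class TestFitIndividual:
    def test_noise_free_bateman_recovery(self, tiny_error):
        fit = fit_individual(_bateman_subject(), "ka1C", error=tiny_error)
        assert fit.params["A"] == pytest.approx(1.0, rel=1e-3)
        assert fit.params["ka"] == pytest.approx(0.5, rel=1e-3)
        assert fit.params["ke"] == pytest.approx(0.05, rel=1e-3)
        assert fit.converged

    def test_noise_free_gamma_recovery(self, tiny_error):
        t = np.geomspace(0.5, 48, 24)
        truth = GammaParams(A=0.3, a=2.5, b=0.2)
        sub = SubjectRecords("S1", t, conc_gamma(t, truth), 30.0)
        fit = fit_individual(sub, "gamma", error=tiny_error)
        assert fit.params["A"] == pytest.approx(0.3, rel=1e-3)
        assert fit.params["am1"] == pytest.approx(1.5, rel=1e-3)
        assert fit.params["b"] == pytest.approx(0.2, rel=1e-3)

    def test_noise_free_2ig3c_recovery(self, trospium_design, tiny_error):
        from oralpk import conc_2ig3c

        d = trospium_design
        t = np.asarray(d.sampling_times)
        c = conc_2ig3c(t, d.true_absorption, d.disposition)
        sub = SubjectRecords("S1", t, c, d.dose)
        fit = fit_individual(
            sub, "2IG3C", error=tiny_error, disposition=d.disposition
        )
        for key, truth in d.absorption_means.items():
            assert fit.params[key] == pytest.approx(truth, rel=1e-3), key

    def test_duplicated_observations_double_the_loglik(self):
        sub = _bateman_subject()
        pred = conc_bateman(sub.times, BatemanParams(A=1, ka=0.5, ke=0.05))
        err = ErrorModel(sd_intercept=0.01, sd_slope=0.1)
        single = _gauss_loglik(sub.conc, pred, err)
        double = _gauss_loglik(
            np.concatenate([sub.conc, sub.conc]),
            np.concatenate([pred, pred]),
            err,
        )
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_too_few_observations_rejected(self, tiny_error):
        sub = _bateman_subject(n=3)
        with pytest.raises(ValueError, match="observations"):
            fit_individual(sub, "ka1C", error=tiny_error)

    def test_2ig3c_requires_disposition(self, tiny_error):
        with pytest.raises(ValueError, match="disposition"):
            fit_individual(_bateman_subject(), "2IG3C", error=tiny_error)

    def test_scale_invariance_of_rate_constants(self, tiny_error):
        # multiplying concentrations and error SDs by a constant rescales
        # the amplitude but leaves the log-scale rate constants unchanged
        sub = _bateman_subject()
        scaled = SubjectRecords("S1", sub.times, 100.0 * sub.conc, sub.dose)
        err_scaled = ErrorModel(
            sd_intercept=100.0 * tiny_error.sd_intercept,
            sd_slope=tiny_error.sd_slope,
        )
        f1 = fit_individual(sub, "ka1C", error=tiny_error)
        f2 = fit_individual(scaled, "ka1C", error=err_scaled)
        assert f2.params["A"] == pytest.approx(100.0 * f1.params["A"], rel=1e-3)
        assert f2.params["ka"] == pytest.approx(f1.params["ka"], rel=1e-3)
        assert f2.params["ke"] == pytest.approx(f1.params["ke"], rel=1e-3)


class TestComputeAIC:
    def test_definition(self):
        assert compute_aic(-100.0, 5) == pytest.approx(210.0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            compute_aic(np.nan, 3)


class TestFitPopulation:
    def test_requires_three_subjects(self, tiny_error):
        rows = []
        sub = _bateman_subject()
        for tj, cj in zip(sub.times, sub.conc):
            rows.append({"ID": "S1", "TIME": tj, "DV": cj, "DOSE": 30.0})
        with pytest.raises(ValueError, match="3 subjects"):
            fit_population(pd.DataFrame(rows), "ka1C")

    def test_oral_models_reject_disposition(self, rng, trospium_design):
        study, _ = _bateman_study(rng, n_subjects=3)
        with pytest.raises(ValueError, match="oral data alone"):
            fit_population(study, "ka1C", fixed_disposition=trospium_design.disposition)

    def test_2ig3c_requires_disposition(self, rng):
        study, _ = _bateman_study(rng, n_subjects=3)
        with pytest.raises(ValueError, match="fixed_disposition"):
            fit_population(study, "2IG3C")

    def test_two_stage_recovers_generating_population(self, rng):
        study, gm = _bateman_study(rng)
        cfg = FitConfig(method="two_stage", multistart_count=3, seed=7)
        fit = fit_population(study, "ka1C", config=cfg)
        for key in ("A", "ka", "ke"):
            assert fit.population_means[key] == pytest.approx(gm[key], rel=0.10), key
        # between-subject variability within a factor of ~1.5 of the truth
        for key in ("A", "ka", "ke"):
            assert 0.125 < fit.population_cv[key] < 0.375

    def test_em_recovers_generating_population(self, rng):
        study, gm = _bateman_study(rng)
        cfg = FitConfig(
            method="em", mc_samples=200, max_em_iterations=15, multistart_count=2, seed=7
        )
        fit = fit_population(study, "ka1C", config=cfg)
        for key in ("A", "ka", "ke"):
            assert fit.population_means[key] == pytest.approx(gm[key], rel=0.10), key
        assert fit.n_subjects == 12
        assert np.isfinite(fit.loglik)
        assert fit.AIC == pytest.approx(compute_aic(fit.loglik, 8))

    def test_zero_variability_collapses_to_shared_truth(self):
        t = np.geomspace(0.5, 48, 16)
        c = conc_bateman(t, BatemanParams(A=1.0, ka=0.5, ke=0.05))
        rows = [
            {"ID": f"S{i}", "TIME": tj, "DV": cj, "DOSE": 30.0}
            for i in range(4)
            for tj, cj in zip(t, c)
        ]
        cfg = FitConfig(method="two_stage", multistart_count=2, seed=0)
        fit = fit_population(
            StudyDataset(frame=pd.DataFrame(rows)), "ka1C", config=cfg
        )
        assert fit.population_means["ka"] == pytest.approx(0.5, rel=1e-2)
        assert fit.population_cv["ka"] == pytest.approx(0.0, abs=0.02)


class TestErrorModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            ErrorModel(sd_intercept=0.0, sd_slope=0.0)
        with pytest.raises(ValueError):
            ErrorModel(sd_intercept=-0.1, sd_slope=0.1)

    def test_linear_sd(self):
        err = ErrorModel(sd_intercept=0.1, sd_slope=0.2)
        np.testing.assert_allclose(err.sd([0.0, 1.0, 5.0]), [0.1, 0.3, 1.1])
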
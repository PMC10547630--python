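"""Bias and model-comparison reporting.

Quantifies how far the simple oral-only models stray from the reference
values: percent deviations of AUC and MAT at the population level and per
subject (where positive and negative individual biases can cancel in the
mean), an AIC comparison grid across models, and tabulated input-rate /
fractional-absorption-rate profiles for the fitted input functions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .fitting import ModelFit
from .input_functions import AbsorptionInput, IGInput, ig_density, ka_of_t
from .models import IG1CParams

__all__ = [
    "BiasReport",
    "pct_deviation",
    "build_bias_report",
    "aic_table",
    "profile_curves",
    "observed_vs_predicted",
]


def pct_deviation(estimate: float, truth: float) -> float:
    """100*(estimate - truth)/truth."""
    if truth == 0:
        raise ZeroDivisionError("percent deviation undefined for zero truth")
    return 100.0 * (estimate - truth) / truth


@dataclass(frozen=True)
class ModelBias:
    """Deviations of one candidate model from the reference values."""

    model_name: str
    population: dict                 # metric -> % deviation of population means
    population_mean_of_individuals: dict  # metric -> % deviation of mean individual metric
    individual: dict                 # metric -> {subject id -> % deviation}
    summary: dict                    # metric -> mean/sd/mean_abs/n_pos/n_neg


@dataclass(frozen=True)
class BiasReport:
    """Percent deviations of AUC/MAT for every fitted candidate model."""

    models: dict = field(default_factory=dict)   # model name -> ModelBias

    def to_dict(self) -> dict:
        return {name: asdict(mb) for name, mb in self.models.items()}

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "BiasReport":
        return cls(models={name: ModelBias(**mb) for name, mb in data.items()})

    @classmethod
    def from_json(cls, path) -> "BiasReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def frame(self) -> pd.DataFrame:
        """Population-deviation grid: rows (model, metric), one % column."""
        rows = []
        for name, mb in self.models.items():
            for metric, dev in mb.population.items():
                rows.append(
                    {"model": name, "metric": metric, "population_pct_deviation": dev}
                )
        return pd.DataFrame(rows)


def _summary(devs: dict) -> dict:
    v = np.array(list(devs.values()), dtype=float)
    return {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        "mean_abs": float(np.mean(np.abs(v))),
        "n_positive": int(np.sum(v > 0)),
        "n_negative": int(np.sum(v < 0)),
    }


def build_bias_report(fits: dict[str, ModelFit], truth: pd.DataFrame) -> BiasReport:
    """Compare fitted AUC/MAT against the truth table of a simulated study.

    ``truth`` needs columns ID, AUC, MAT (per-subject true values); the
    population truth is the geometric mean over subjects, matching the
    log-normal population model.  Population deviations are reported both
    for the geometric-mean parameter set propagated through each model
    (``population``) and for the arithmetic mean of the individual metrics
    (``population_mean_of_individuals``).  MAT rows are omitted for the
    gamma curve, which provides no MAT estimate.
    """
    truth = truth.set_index("ID") if "ID" in truth.columns else truth
    pop_truth = {
        "AUC": float(np.exp(np.mean(np.log(truth["AUC"])))),
        "MAT": float(np.exp(np.mean(np.log(truth["MAT"])))),
    }
    models = {}
    for name, fit in fits.items():
        per_subject = fit.derived["per_subject"]
        missing = set(per_subject) - set(truth.index)
        if missing:
            raise ValueError(f"fit {name!r} has subjects absent from truth: {sorted(missing)}")
        metrics = ["AUC"] if fit.derived["population"]["MAT"] is None else ["AUC", "MAT"]
        individual = {
            m: {
                sid: pct_deviation(per_subject[sid][m], float(truth.loc[sid, m]))
                for sid in per_subject
            }
            for m in metrics
        }
        population = {
            m: pct_deviation(fit.derived["population"][m], pop_truth[m]) for m in metrics
        }
        pop_of_ind = {
            "AUC": pct_deviation(fit.derived["auc_mean_of_individuals"], pop_truth["AUC"])
        }
        if "MAT" in metrics and "mat_mean_of_individuals" in fit.derived:
            pop_of_ind["MAT"] = pct_deviation(
                fit.derived["mat_mean_of_individuals"], pop_truth["MAT"]
            )
        models[name] = ModelBias(
            model_name=name,
            population=population,
            population_mean_of_individuals=pop_of_ind,
            individual=individual,
            summary={m: _summary(individual[m]) for m in metrics},
        )
    return BiasReport(models=models)


def observed_vs_predicted(fits: dict[str, ModelFit], dataset) -> pd.DataFrame:
    """Goodness-of-fit table: observed vs individual-predicted concentrations.

    One row per (model, subject, time) using each subject's conditional
    parameter estimates; plain long format suitable for plotting predicted
    against measured responses.
    """
    from .fitting import _MODELS

    rows = []
    for name, fit in fits.items():
        mspec = _MODELS[name]
        for sub in dataset.subjects():
            theta = fit.individual_estimates.get(sub.subject_id)
            if theta is None:
                continue
            ctx = {
                "dose": sub.dose,
                "disposition": fit.disposition,
                "h": fit.disposition._h if fit.disposition is not None else None,
            }
            pred = mspec["predict"](sub.times, theta, ctx)
            for t, obs, pr in zip(sub.times, sub.conc, pred):
                rows.append(
                    {
                        "model": name,
                        "ID": sub.subject_id,
                        "TIME": t,
                        "observed": obs,
                        "predicted": pr,
                    }
                )
    return pd.DataFrame(rows)


def aic_table(fits: dict[str, ModelFit]) -> pd.DataFrame:
    """Model-comparison grid: AIC, log-likelihood and parameter count."""
    rows = [
        {
            "model": name,
            "AIC": fit.AIC,
            "loglik": fit.loglik,
            "n_population_params": fit.n_population_params,
            "method": fit.method,
            "converged": fit.converged,
        }
        for name, fit in fits.items()
    ]
    return pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)


def profile_curves(
    fits: dict[str, ModelFit],
    absorption_truth: AbsorptionInput,
    grid,
) -> pd.DataFrame:
    """Input-rate and k_a(t) profiles from population-mean input parameters.

    Rates are normalised per unit bioavailable dose (the input-time
    density), which is what oral data identify for the one-compartment
    models.  The first-order model contributes a constant k_a column; the
    reference mixture's k_a(t) is its hazard rate.
    """
    grid = np.asarray(grid, dtype=float)
    frames = [
        pd.DataFrame(
            {
                "model": "true",
                "time": grid,
                "input_rate": absorption_truth.mixture_density(grid),
                "ka_t": ka_of_t(grid, absorption_truth),
            }
        )
    ]
    for name, fit in fits.items():
        pm = fit.population_means
        if name == "ka1C":
            ka = pm["ka"]
            frames.append(
                pd.DataFrame(
                    {
                        "model": name,
                        "time": grid,
                        "input_rate": ka * np.exp(-ka * grid),
                        "ka_t": np.full_like(grid, ka),
                    }
                )
            )
        elif name == "IG1C":
            params = IG1CParams(scale=pm["scale"], MT=pm["MT"], RD2=pm["RD2"], ke=pm["ke"])
            # single-IG mixture with equal components: hazard of one IG
            single = AbsorptionInput(D=1.0, F=1.0, p=0.5, ig1=params.ig, ig2=params.ig)
            frames.append(
                pd.DataFrame(
                    {
                        "model": name,
                        "time": grid,
                        "input_rate": ig_density(grid, params.ig),
                        "ka_t": ka_of_t(grid, single),
                    }
                )
            )
        elif name == "2IG3C":
            absorption = AbsorptionInput(
                D=1.0,
                F=1.0,
                p=pm["p"],
                ig1=IGInput(MT=pm["MT1"], RD2=pm["RD2_1"]),
                ig2=IGInput(MT=pm["MT2"], RD2=pm["RD2_2"]),
            )
            frames.append(
                pd.DataFrame(
                    {
                        "model": name,
                        "time": grid,
                        "input_rate": absorption.mixture_density(grid),
                        "ka_t": ka_of_t(grid, absorption),
                    }
                )
            )
        # the gamma curve has no input-function decomposition
    return pd.concat(frames, ignore_index=True)
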
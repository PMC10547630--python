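"""Maximum-likelihood fitting of the candidate oral absorption models.

Individual fits maximise a Gaussian likelihood whose residual standard
deviation is linear in the model-predicted concentration,

    SD(C) = sd_intercept + sd_slope * C_pred,

with all structural parameters estimated on the log scale (log-normal
support).  The population layer assumes log-normally distributed
individual parameters with a diagonal random-effects covariance and offers
two estimation modes:

* ``two_stage`` — independent individual fits followed by a log-normal
  summary (geometric mean / between-subject variance).  Fast; used for
  smoke tests and as initialisation.
* ``em`` — importance-sampling EM (MLEM-style): individual parameters are
  sampled from the current population distribution, reweighted by their
  data likelihood to form conditional means, and the population mean,
  variance and residual-error parameters are updated from the weighted
  samples.  The marginal log-likelihood is the Monte-Carlo estimate
  log mean_k p(y_i | theta_k).

Goodness of fit is compared with the Akaike information criterion,
AIC = -2*loglik + 2*(number of population-level parameters).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gamma as gamma_fn
from scipy.special import logsumexp

from .datasets import StudyDataset, SubjectRecords
from .models import (
    BatemanParams,
    Disposition3C,
    conc_2ig3c_raw,
    conc_bateman,
    conc_gamma,
    conc_ig1c_raw,
)
from .models import GammaParams

__all__ = [
    "ErrorModel",
    "FitConfig",
    "IndividualFit",
    "ModelFit",
    "MODEL_NAMES",
    "fit_individual",
    "fit_population",
    "compute_aic",
    "model_auc",
    "model_mat",
]

MODEL_NAMES = ("2IG3C", "ka1C", "IG1C", "gamma")

_SIGMA_FLOOR = 1e-10
_PENALTY = 1e12
# mixture weight p must stay inside (0, 1); fits are rejected above this cap
_P_CAP = 0.995


@dataclass(frozen=True)
class ErrorModel:
    """Residual error SD(C) = sd_intercept + sd_slope*C, both >= 0."""

    sd_intercept: float
    sd_slope: float

    def __post_init__(self) -> None:
        if self.sd_intercept < 0 or self.sd_slope < 0:
            raise ValueError("error-model parameters must be non-negative")
        if self.sd_intercept == 0 and self.sd_slope == 0:
            raise ValueError("at least one error-model parameter must be positive")

    def sd(self, conc_pred):
        return np.maximum(self.sd_intercept + self.sd_slope * np.asarray(conc_pred), _SIGMA_FLOOR)


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the population algorithms (defaults suit desk-scale studies)."""

    method: str = "em"              # "em" or "two_stage"
    max_em_iterations: int = 60
    mc_samples: int = 400
    em_tol: float = 1e-5            # relative marginal-loglik change
    multistart_count: int = 5
    multistart_jitter: float = 0.6  # SD of log-scale jitter around the init
    seed: int = 0
    cv_floor: float = 0.02          # variance floor as a CV
    proposal_inflation: float = 2.0  # importance-proposal SD relative to the conditional SD
    optimizer_options: dict = field(default_factory=lambda: {"maxiter": 2000})


# ---------------------------------------------------------------------------
# model registry: names, prediction, derived AUC/MAT, data-driven inits
# ---------------------------------------------------------------------------


def _predict_ka1c(t, theta, ctx):
    A, ka, ke = theta["A"], theta["ka"], theta["ke"]
    if abs(ka - ke) <= 1e-6 * ka:
        return None
    return np.asarray(conc_bateman(t, BatemanParams(A=A, ka=ka, ke=ke)))


def _predict_ig1c(t, theta, ctx):
    return conc_ig1c_raw(t, theta["scale"], theta["MT"], theta["RD2"], theta["ke"])


def _predict_gamma(t, theta, ctx):
    # shape is estimated as am1 = a - 1 > 0 so that log-normal support
    # enforces the a > 1 constraint
    p = GammaParams(A=theta["A"], a=theta["am1"] + 1.0, b=theta["b"])
    return np.asarray(conc_gamma(t, p))


def _predict_2ig3c(t, theta, ctx):
    if theta["F"] > 1.0 or theta["p"] >= _P_CAP:
        return None
    return conc_2ig3c_raw(
        t,
        ctx["dose"] * theta["F"],
        theta["p"],
        theta["MT1"],
        theta["RD2_1"],
        theta["MT2"],
        theta["RD2_2"],
        ctx["h"],
    )


def model_auc(model_name: str, theta: dict, ctx: dict | None = None) -> float:
    """Closed-form AUC of one parameter set."""
    if model_name == "ka1C":
        return theta["A"] * (theta["ka"] - theta["ke"]) / (theta["ka"] * theta["ke"])
    if model_name == "IG1C":
        return theta["scale"] / theta["ke"]
    if model_name == "gamma":
        a = theta["am1"] + 1.0
        return theta["A"] * gamma_fn(a) / theta["b"] ** a
    if model_name == "2IG3C":
        return theta["F"] * ctx["dose"] / ctx["disposition"].CL
    raise KeyError(model_name)


def model_mat(model_name: str, theta: dict) -> float | None:
    """Closed-form MAT of one parameter set; None for the gamma curve."""
    if model_name == "ka1C":
        return 1.0 / theta["ka"]
    if model_name == "IG1C":
        return theta["MT"]
    if model_name == "gamma":
        return None
    if model_name == "2IG3C":
        return theta["p"] * theta["MT1"] + (1.0 - theta["p"]) * theta["MT2"]
    raise KeyError(model_name)


def _terminal_slope(times, conc):
    """Log-linear slope of the last third of positive observations."""
    mask = conc > 0
    t, c = times[mask], conc[mask]
    k = max(3, len(t) // 3)
    t, c = t[-k:], c[-k:]
    if len(t) < 2:
        return 0.1
    slope = np.polyfit(t, np.log(c), 1)[0]
    return max(-slope, 1e-3)


def _nca_auc_mbrt(times, conc, lam_z):
    """Trapezoidal AUC/AUMC with log-linear tail extrapolation."""
    auc = np.trapezoid(conc, times) + conc[-1] / lam_z
    aumc = (
        np.trapezoid(times * conc, times)
        + conc[-1] * (times[-1] / lam_z + 1.0 / lam_z**2)
    )
    return auc, aumc / auc


def _init_ka1c(times, conc, ctx):
    ke = _terminal_slope(times, conc)
    i_max = int(np.argmax(conc))
    t_max = max(times[i_max], times[0])
    ka = 3.0 * ke
    for _ in range(25):  # fixed point of t_max = ln(ka/ke)/(ka - ke)
        expo = t_max * (ka - ke)
        if expo > 50:
            break
        ka_new = ke * math.exp(expo)
        if not np.isfinite(ka_new) or ka_new > 1e3:
            break
        ka = 0.5 * ka + 0.5 * ka_new
    ka = float(np.clip(ka, 1.2 * ke, 1e3))
    denom = math.exp(-ke * t_max) - math.exp(-ka * t_max)
    A = conc[i_max] / max(denom, 1e-6)
    return {"A": max(A, 1e-8), "ka": ka, "ke": ke}


def _init_ig1c(times, conc, ctx):
    ke = _terminal_slope(times, conc)
    auc, mbrt = _nca_auc_mbrt(times, conc, ke)
    mt = max(mbrt - 1.0 / ke, 0.5)
    return {"scale": auc * ke, "MT": mt, "RD2": 0.5, "ke": ke}


def _init_gamma(times, conc, ctx):
    mask = (conc > 0) & (times > 0)
    t, c = times[mask], conc[mask]
    X = np.column_stack([np.ones_like(t), np.log(t), -t])
    beta, *_ = np.linalg.lstsq(X, np.log(c), rcond=None)
    am1 = float(np.clip(beta[1], 0.1, 50.0))
    b = float(np.clip(beta[2], 1e-3, 50.0))
    return {"A": math.exp(np.clip(beta[0], -50, 50)), "am1": am1, "b": b}


def _init_2ig3c(times, conc, ctx):
    disp: Disposition3C = ctx["disposition"]
    lam_z = _terminal_slope(times, conc)
    auc, mbrt = _nca_auc_mbrt(times, conc, lam_z)
    mat = max(mbrt - disp.mdrt, 1.0)
    f = float(np.clip(auc * disp.CL / ctx["dose"], 1e-3, 1.0))
    return {
        "F": f,
        "p": 0.5,
        "MT1": 0.5 * mat,
        "RD2_1": 0.5,
        "MT2": 1.5 * mat,
        "RD2_2": 0.5,
    }


_MODELS = {
    "ka1C": {"params": ("A", "ka", "ke"), "predict": _predict_ka1c, "init": _init_ka1c},
    "IG1C": {
        "params": ("scale", "MT", "RD2", "ke"),
        "predict": _predict_ig1c,
        "init": _init_ig1c,
    },
    "gamma": {"params": ("A", "am1", "b"), "predict": _predict_gamma, "init": _init_gamma},
    "2IG3C": {
        "params": ("F", "p", "MT1", "RD2_1", "MT2", "RD2_2"),
        "predict": _predict_2ig3c,
        "init": _init_2ig3c,
    },
}


def _check_model(model_name: str) -> dict:
    if model_name not in _MODELS:
        raise KeyError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    return _MODELS[model_name]


def _order_2ig_components(theta: dict) -> dict:
    """Canonical component order MT1 <= MT2 (mixture label switching)."""
    if "MT1" in theta and theta["MT1"] > theta["MT2"]:
        theta = dict(theta)
        theta["MT1"], theta["MT2"] = theta["MT2"], theta["MT1"]
        theta["RD2_1"], theta["RD2_2"] = theta["RD2_2"], theta["RD2_1"]
        theta["p"] = 1.0 - theta["p"]
    return theta


def _gauss_loglik(obs, pred, error: ErrorModel) -> float:
    sd = error.sd(pred)
    z = (obs - pred) / sd
    return float(-0.5 * np.sum(z**2) - np.sum(np.log(sd)) - 0.5 * len(obs) * math.log(2 * math.pi))


@dataclass(frozen=True)
class IndividualFit:
    subject_id: str
    model_name: str
    params: dict
    error: ErrorModel
    loglik: float
    converged: bool
    n_obs: int


def fit_individual(
    subject: SubjectRecords,
    model_name: str,
    error: ErrorModel | None = None,
    init: dict | None = None,
    *,
    disposition: Disposition3C | None = None,
    config: FitConfig | None = None,
) -> IndividualFit:
    """Maximum-likelihood fit of one subject's records to one model.

    When ``error`` is given, its parameters are held fixed (weighted least
    squares); otherwise sd_intercept and sd_slope are estimated jointly
    with the structural parameters.  Structural parameters are estimated on
    the log scale with multi-start Nelder-Mead.
    """
    mspec = _check_model(model_name)
    config = config or FitConfig()
    times, conc = subject.times, subject.conc
    n_struct = len(mspec["params"])
    if len(times) < n_struct + 1:
        raise ValueError(
            f"subject {subject.subject_id!r}: {len(times)} observations "
            f"cannot identify {n_struct} parameters"
        )
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    ctx = {
        "dose": subject.dose,
        "disposition": disposition,
        "h": disposition._h if disposition is not None else None,
    }
    if model_name == "2IG3C" and disposition is None:
        raise ValueError("2IG3C fits require the fixed iv disposition parameters")

    estimate_error = error is None
    if init is None:
        init = mspec["init"](times, conc, ctx)
    x0 = np.log([max(init[k], 1e-10) for k in mspec["params"]])
    if estimate_error:
        c_scale = max(float(np.max(conc)), 1e-6)
        x0 = np.concatenate([x0, np.log([0.02 * c_scale, 0.1])])

    def unpack(x):
        theta = {k: math.exp(v) for k, v in zip(mspec["params"], x)}
        if estimate_error:
            err = ErrorModel(sd_intercept=math.exp(x[n_struct]), sd_slope=math.exp(x[n_struct + 1]))
        else:
            err = error
        return theta, err

    def objective(x):
        if np.any(np.abs(x) > 50):
            return _PENALTY
        theta, err = unpack(x)
        try:
            pred = mspec["predict"](times, theta, ctx)
        except (ValueError, FloatingPointError, OverflowError):
            return _PENALTY
        if pred is None or not np.all(np.isfinite(pred)):
            return _PENALTY
        return -_gauss_loglik(conc, pred, err)

    # stable per-subject stream (crc32, not hash(): the latter is salted
    # per process and would break cross-run reproducibility)
    rng = np.random.default_rng(
        config.seed + zlib.crc32(str(subject.subject_id).encode()) % 10_000
    )
    best = None
    for start in range(max(config.multistart_count, 1)):
        x_start = x0 if start == 0 else x0 + rng.normal(0, config.multistart_jitter, len(x0))
        res = minimize(
            objective,
            x_start,
            method="Nelder-Mead",
            options={
                "maxiter": config.optimizer_options.get("maxiter", 2000),
                "xatol": 1e-8,
                "fatol": 1e-10,
                "adaptive": True,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    theta, err = unpack(best.x)
    theta = _order_2ig_components(theta)
    return IndividualFit(
        subject_id=subject.subject_id,
        model_name=model_name,
        params=theta,
        error=err,
        loglik=-best.fun,
        converged=bool(best.success and best.fun < _PENALTY),
        n_obs=len(times),
    )


def compute_aic(loglik: float, n_population_params: int) -> float:
    """AIC = -2*loglik + 2*(number of estimated population-level parameters)."""
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    return -2.0 * loglik + 2.0 * n_population_params


@dataclass(frozen=True)
class ModelFit:
    """Population fit of one candidate model to one study."""

    model_name: str
    population_means: dict
    population_cv: dict
    individual_estimates: dict          # subject id -> conditional parameter dict
    error: ErrorModel
    loglik: float
    n_population_params: int
    AIC: float
    derived: dict                       # population + per-subject AUC/MAT
    method: str
    converged: bool
    flags: tuple = ()
    disposition: Disposition3C | None = None   # fixed iv parameters (2IG3C only)

    @property
    def n_subjects(self) -> int:
        return len(self.individual_estimates)


def _derived_metrics(model_name, pop_means, individual, ctx_by_subject):
    """Population-mean and per-subject AUC/MAT.

    The population values propagate the geometric-mean parameter set through
    the model's closed-form AUC/MAT; the mean of the individual metrics is
    also reported (``auc_mean_of_individuals``) since the two differ under
    nonlinearity.
    """
    any_ctx = next(iter(ctx_by_subject.values()))
    per_subject = {}
    for sid, theta in individual.items():
        per_subject[sid] = {
            "AUC": model_auc(model_name, theta, ctx_by_subject[sid]),
            "MAT": model_mat(model_name, theta),
        }
    aucs = np.array([m["AUC"] for m in per_subject.values()])
    out = {
        "population": {
            "AUC": model_auc(model_name, pop_means, any_ctx),
            "MAT": model_mat(model_name, pop_means),
        },
        "auc_mean_of_individuals": float(np.mean(aucs)),
        "per_subject": per_subject,
    }
    mats = [m["MAT"] for m in per_subject.values()]
    if all(m is not None for m in mats):
        out["mat_mean_of_individuals"] = float(np.mean(mats))
    return out


def _lognormal_summary(param_names, thetas):
    logs = np.log(np.array([[th[k] for k in param_names] for th in thetas]))
    mu = logs.mean(axis=0)
    var = logs.var(axis=0, ddof=1) if len(thetas) > 1 else np.zeros(len(param_names))
    return mu, var


def _cv_from_var(var):
    return np.sqrt(np.expm1(var))


def _coerce_study(study) -> StudyDataset:
    if isinstance(study, StudyDataset):
        return study
    if isinstance(study, pd.DataFrame):
        return StudyDataset(frame=study)
    raise TypeError("study must be a StudyDataset or a long-format DataFrame")


def fit_population(
    study,
    model_name: str,
    fixed_disposition: Disposition3C | None = None,
    config: FitConfig | None = None,
) -> ModelFit:
    """Population (nonlinear mixed-effects) fit of one model to a study.

    The reference model (2IG3C) requires ``fixed_disposition`` — the six
    three-compartment parameters known from iv data; the three oral-only
    models must be fitted without it.  Returns population geometric means,
    between-subject CVs, per-subject conditional estimates, the marginal
    log-likelihood and the AIC.
    """
    mspec = _check_model(model_name)
    config = config or FitConfig()
    study = _coerce_study(study)
    subjects = list(study.subjects())
    if len(subjects) < 3:
        raise ValueError("population analysis requires at least 3 subjects")
    if model_name == "2IG3C" and fixed_disposition is None:
        raise ValueError("2IG3C requires fixed_disposition (iv 3C parameters)")
    if model_name != "2IG3C" and fixed_disposition is not None:
        raise ValueError(f"{model_name} is fitted to oral data alone; drop fixed_disposition")

    param_names = mspec["params"]
    ctx_by_subject = {
        s.subject_id: {
            "dose": s.dose,
            "disposition": fixed_disposition,
            "h": fixed_disposition._h if fixed_disposition is not None else None,
        }
        for s in subjects
    }
    # population parameter count: a mean and a variance per structural
    # parameter plus the two residual-error parameters
    n_pop = 2 * len(param_names) + 2
    flags: list[str] = []

    # ---- stage 1: individual fits (two-stage result and EM initialisation)
    ind_fits = [
        fit_individual(
            s, model_name, disposition=fixed_disposition, config=config
        )
        for s in subjects
    ]
    thetas = [f.params for f in ind_fits]
    mu, var = _lognormal_summary(param_names, thetas)
    err_a = float(np.mean([f.error.sd_intercept for f in ind_fits]))
    err_b = float(np.mean([f.error.sd_slope for f in ind_fits]))
    error = ErrorModel(sd_intercept=max(err_a, 1e-8), sd_slope=max(err_b, 1e-8))
    if not all(f.converged for f in ind_fits):
        flags.append("individual_nonconvergence")

    if config.method == "two_stage":
        pop_means = dict(zip(param_names, np.exp(mu)))
        pop_cv = dict(zip(param_names, _cv_from_var(var)))
        individual = {f.subject_id: f.params for f in ind_fits}
        loglik = float(sum(f.loglik for f in ind_fits))
        return ModelFit(
            model_name=model_name,
            population_means=_order_2ig_components(pop_means),
            population_cv=pop_cv,
            individual_estimates=individual,
            error=error,
            loglik=loglik,
            n_population_params=n_pop,
            AIC=compute_aic(loglik, n_pop),
            derived=_derived_metrics(model_name, pop_means, individual, ctx_by_subject),
            method="two_stage",
            converged=all(f.converged for f in ind_fits),
            flags=tuple(flags),
            disposition=fixed_disposition,
        )
    if config.method != "em":
        raise ValueError(f"unknown population method {config.method!r}")

    # ---- stage 2: importance-sampling EM
    var = np.maximum(var, np.log1p(config.cv_floor**2))
    rng = np.random.default_rng(config.seed)
    n_params = len(param_names)
    obs_times = [s.times for s in subjects]
    obs_conc = [s.conc for s in subjects]
    loglik = -np.inf
    converged = False
    # proposal centres: individual-fit estimates, updated to the conditional
    # means each iteration (importance sampling around the conditional
    # distribution rather than the population prior keeps the effective
    # sample size high)
    centres = np.log(np.array([[th[k] for k in param_names] for th in thetas]))
    # adaptive per-subject proposals: with rich data the conditional
    # (posterior) distribution of an individual's parameters is far narrower
    # than the population distribution, so the proposal SD is re-estimated
    # each iteration from the weighted posterior spread of the previous one
    prop_sds = np.tile(np.sqrt(var), (len(subjects), 1))
    # common random numbers: the same standard-normal draws are reused every
    # iteration, making the EM map deterministic so it can converge instead
    # of wandering with fresh Monte-Carlo noise
    z_draws = rng.standard_normal((len(subjects), config.mc_samples, n_params))
    cond_logmeans = None
    min_ess = np.inf
    for iteration in range(config.max_em_iterations):
        sd = np.sqrt(var)
        cond_logmeans = np.zeros((len(subjects), n_params))
        cond_logsq = np.zeros((len(subjects), n_params))
        marginal = 0.0
        cache = []  # per subject: (weights, predictions, observations)
        for i, s in enumerate(subjects):
            z = z_draws[i]
            prop_sd = np.clip(config.proposal_inflation * prop_sds[i], 1e-3, 2.0 * sd)
            log_theta = centres[i] + z * prop_sd
            # log prior minus log proposal (both diagonal Gaussians in log space)
            log_ratio = (
                -0.5 * np.sum(((log_theta - mu) / sd) ** 2, axis=1)
                - np.sum(np.log(sd))
                + 0.5 * np.sum(z**2, axis=1)
                + np.sum(np.log(prop_sd))
            )
            logliks = np.full(config.mc_samples, -np.inf)
            preds = [None] * config.mc_samples
            for k in range(config.mc_samples):
                theta = dict(zip(param_names, np.exp(log_theta[k])))
                try:
                    pred = mspec["predict"](obs_times[i], theta, ctx_by_subject[s.subject_id])
                except (ValueError, FloatingPointError, OverflowError):
                    pred = None
                if pred is None or not np.all(np.isfinite(pred)):
                    continue
                preds[k] = pred
                logliks[k] = _gauss_loglik(obs_conc[i], pred, error)
            logw = logliks + log_ratio
            lse = logsumexp(logw)
            if not np.isfinite(lse):
                raise RuntimeError(
                    f"all importance samples invalid for subject {s.subject_id!r}"
                )
            w = np.exp(logw - lse)
            min_ess = min(min_ess, 1.0 / np.sum(w**2))
            marginal += lse - math.log(config.mc_samples)
            cond_logmeans[i] = w @ log_theta
            cond_logsq[i] = w @ log_theta**2
            prop_sds[i] = np.sqrt(
                np.maximum(cond_logsq[i] - cond_logmeans[i] ** 2, 1e-6)
            )
            keep = np.flatnonzero(w > 1e-10)
            # flat (weight, prediction, residual) triples for the error update
            kept_preds = np.concatenate([preds[k] for k in keep])
            kept_resid = np.concatenate([obs_conc[i] - preds[k] for k in keep])
            kept_w = np.repeat(w[keep], len(obs_conc[i]))
            cache.append((kept_w, kept_preds, kept_resid))
        centres = cond_logmeans.copy()
        # M-step: population mean/variance of log parameters
        mu = cond_logmeans.mean(axis=0)
        var = cond_logsq.mean(axis=0) - 2 * mu * cond_logmeans.mean(axis=0) + mu**2
        floor = np.log1p(config.cv_floor**2)
        if np.any(var < floor):
            flags.append(f"variance_floored_iter{iteration}")
        var = np.maximum(var, floor)
        error = _update_error(cache, error)
        if np.isfinite(loglik) and abs(marginal - loglik) < config.em_tol * (
            1.0 + abs(marginal)
        ):
            loglik = marginal
            converged = True
            break
        loglik = marginal
    if not converged:
        flags.append("em_max_iterations")
    if min_ess < 10:
        flags.append("low_importance_ess")

    pop_means = dict(zip(param_names, np.exp(mu)))
    pop_cv = dict(zip(param_names, _cv_from_var(var)))
    individual = {
        s.subject_id: _order_2ig_components(
            dict(zip(param_names, np.exp(cond_logmeans[i])))
        )
        for i, s in enumerate(subjects)
    }
    return ModelFit(
        model_name=model_name,
        population_means=_order_2ig_components(pop_means),
        population_cv=pop_cv,
        individual_estimates=individual,
        error=error,
        loglik=float(loglik),
        n_population_params=n_pop,
        AIC=compute_aic(float(loglik), n_pop),
        derived=_derived_metrics(model_name, pop_means, individual, ctx_by_subject),
        method="em",
        converged=converged,
        flags=tuple(dict.fromkeys(flags)),
        disposition=fixed_disposition,
    )


def _update_error(cache, current: ErrorModel) -> ErrorModel:
    """M-step update of (sd_intercept, sd_slope) from cached predictions."""
    w = np.concatenate([c[0] for c in cache])
    pred = np.concatenate([c[1] for c in cache])
    resid = np.concatenate([c[2] for c in cache])

    def neg_expected_loglik(x):
        if np.any(np.abs(x) > 40):
            return _PENALTY
        sd = np.maximum(math.exp(x[0]) + math.exp(x[1]) * pred, _SIGMA_FLOOR)
        return float(np.sum(w * (np.log(sd) + resid**2 / (2.0 * sd**2))))

    x0 = np.log([max(current.sd_intercept, 1e-8), max(current.sd_slope, 1e-8)])
    res = minimize(neg_expected_loglik, x0, method="Nelder-Mead",
                   options={"maxiter": 300, "xatol": 1e-6, "fatol": 1e-9})
    if res.fun >= _PENALTY:
        return current
    return ErrorModel(
        sd_intercept=max(math.exp(res.x[0]), 1e-12),
        sd_slope=max(math.exp(res.x[1]), 1e-12),
    )
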
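"""Virtual oral bioavailability studies.

The generator emulates the statistical structure of rich single-dose oral
studies of relatively slowly absorbed drugs: a handful of subjects, dense
sampling out to several mean body residence times, log-normal
between-subject variability on the structural parameters and residual
error whose standard deviation is linear in the concentration.  True
concentration profiles come from the reference model (two-IG input, fixed
three-compartment disposition).

Three presets mirror the designs of published studies of slowly absorbed
antimuscarinics/anaesthetics — 12 subjects x 24 samples, 10 x 16 and
15 x 14 — with mean absorption times in the 8-13 h range and MAT/MDRT
ratios of about 0.6 or 1.  The preset parameter values themselves are
synthetic: they are chosen to satisfy those published design constraints,
not taken from any fitted clinical analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import StudyDataset
from .fitting import ErrorModel
from .input_functions import AbsorptionInput, IGInput
from .models import Disposition3C, conc_2ig3c

__all__ = [
    "StudyDesign",
    "SimulatedStudy",
    "PRESET_NAMES",
    "preset_design",
    "draw_subject_parameters",
    "simulate_study",
]

PRESET_NAMES = ("trospium_like", "propiverine_like", "ketamine_like")

ABSORPTION_PARAMS = ("F", "p", "MT1", "RD2_1", "MT2", "RD2_2")


@dataclass(frozen=True)
class StudyDesign:
    """Design of one virtual study.

    ``absorption_means``/``absorption_cvs`` give the population geometric
    means and between-subject CVs of (F, p, MT1, RD2_1, MT2, RD2_2);
    ``disposition`` holds the six three-compartment parameters (zero CVs by
    default: the pipeline treats disposition as known iv truth).
    """

    name: str
    n_subjects: int
    sampling_times: tuple
    dose: float
    absorption_means: dict
    absorption_cvs: dict
    disposition: Disposition3C
    disposition_cvs: dict = field(default_factory=dict)
    error: ErrorModel = ErrorModel(sd_intercept=1e-4, sd_slope=0.10)
    seed: int = 0
    mat_mdrt_target: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.sampling_times, dtype=float)
        if len(t) == 0 or t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must be strictly increasing with first > 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        missing = [k for k in ABSORPTION_PARAMS if k not in self.absorption_means]
        if missing:
            raise ValueError(f"absorption_means missing {missing}")

    @property
    def true_absorption(self) -> AbsorptionInput:
        m = self.absorption_means
        return AbsorptionInput(
            D=self.dose,
            F=m["F"],
            p=m["p"],
            ig1=IGInput(MT=m["MT1"], RD2=m["RD2_1"]),
            ig2=IGInput(MT=m["MT2"], RD2=m["RD2_2"]),
        )

    @property
    def true_mat(self) -> float:
        return self.true_absorption.mat

    @property
    def true_auc(self) -> float:
        return self.absorption_means["F"] * self.dose / self.disposition.CL

    def with_seed(self, seed: int) -> "StudyDesign":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulatedStudy:
    """A simulated dataset plus its per-subject truth table."""

    design: StudyDesign
    dataset: StudyDataset
    truth: pd.DataFrame          # per-subject true parameters, AUC, MAT
    n_truncated: int             # negative observations clipped to zero


def _sampling_grid(n_samples: int, horizon: float) -> tuple:
    """Geometric-ish grid, dense early, ending at the horizon."""
    g = np.geomspace(0.5, horizon, n_samples)
    g[-1] = horizon
    return tuple(np.round(g, 2))


def _preset(
    name,
    n_subjects,
    n_samples,
    dose,
    means,
    disposition,
    mat_mdrt_target,
    prop_error=0.10,
    intercept_frac=0.02,
):
    mbrt = (
        means["p"] * means["MT1"] + (1 - means["p"]) * means["MT2"]
    ) + disposition.mdrt
    times = _sampling_grid(n_samples, round(4.0 * mbrt))
    cvs = {"F": 0.25, "p": 0.10, "MT1": 0.25, "RD2_1": 0.25, "MT2": 0.25, "RD2_2": 0.25}
    design = StudyDesign(
        name=name,
        n_subjects=n_subjects,
        sampling_times=times,
        dose=dose,
        absorption_means=means,
        absorption_cvs=cvs,
        disposition=disposition,
        mat_mdrt_target=mat_mdrt_target,
    )
    # additive error floor anchored at ~2% of the population peak concentration
    grid = np.linspace(0.25, times[-1], 400)
    cmax = float(np.max(conc_2ig3c(grid, design.true_absorption, disposition)))
    return replace(
        design,
        error=ErrorModel(sd_intercept=intercept_frac * cmax, sd_slope=prop_error),
    )


def preset_design(name: str, seed: int = 0) -> StudyDesign:
    """One of the three built-in study designs (see module docstring)."""
    if name == "trospium_like":
        # slowly absorbed, low-F immediate-release: MAT 9 h, MDRT 15 h (ratio 0.6)
        design = _preset(
            name,
            n_subjects=12,
            n_samples=24,
            dose=30.0,
            means={"F": 0.10, "p": 0.35, "MT1": 2.5, "RD2_1": 0.5, "MT2": 12.5, "RD2_2": 0.4},
            disposition=Disposition3C(V1=40, CL=30, CLd2=60, V2=120, CLd3=20, V3=290),
            mat_mdrt_target=0.6,
        )
    elif name == "propiverine_like":
        # extended-release, moderate F: MAT 11 h, MDRT 11 h (ratio 1.0)
        design = _preset(
            name,
            n_subjects=10,
            n_samples=16,
            dose=45.0,
            means={"F": 0.50, "p": 0.40, "MT1": 5.0, "RD2_1": 0.5, "MT2": 15.0, "RD2_2": 0.4},
            disposition=Disposition3C(V1=20, CL=5, CLd2=10, V2=15, CLd3=4, V3=20),
            mat_mdrt_target=1.0,
        )
    elif name == "ketamine_like":
        # extended-release, high-clearance/first-pass: MAT 12 h, MDRT 20 h (ratio 0.6)
        design = _preset(
            name,
            n_subjects=15,
            n_samples=14,
            dose=80.0,
            means={"F": 0.15, "p": 0.50, "MT1": 7.0, "RD2_1": 0.5, "MT2": 17.0, "RD2_2": 0.4},
            disposition=Disposition3C(V1=100, CL=60, CLd2=150, V2=400, CLd3=50, V3=700),
            mat_mdrt_target=0.6,
        )
    else:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return design.with_seed(seed)


def _subject_rng(design: StudyDesign, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([int(design.seed), int(subject_index)])


def draw_subject_parameters(design: StudyDesign, subject_index: int) -> dict:
    """Log-normal draw of one subject's true absorption parameters.

    Deterministic given (design.seed, subject_index).  The population mean
    acts as the geometric mean (median) of each log-normal, so the
    empirical geometric mean of many draws converges to it.  The mixture
    weight p is clipped just below 1 to keep the two-component form valid.
    """
    rng = _subject_rng(design, subject_index)
    out = {}
    for key in ABSORPTION_PARAMS:
        mean = design.absorption_means[key]
        cv = design.absorption_cvs.get(key, 0.0)
        sigma = np.sqrt(np.log1p(cv**2))
        z = rng.standard_normal()  # always consumed: keeps the noise stream aligned
        out[key] = float(mean * np.exp(sigma * z))
    out["p"] = min(out["p"], 0.99)
    out["F"] = min(out["F"], 1.0)
    return out


def _subject_absorption(design: StudyDesign, params: dict) -> AbsorptionInput:
    return AbsorptionInput(
        D=design.dose,
        F=params["F"],
        p=params["p"],
        ig1=IGInput(MT=params["MT1"], RD2=params["RD2_1"]),
        ig2=IGInput(MT=params["MT2"], RD2=params["RD2_2"]),
    )


def simulate_study(design: StudyDesign) -> SimulatedStudy:
    """Simulate one virtual study from the reference model.

    Per subject: draw true parameters, evaluate the 2IG3C concentration at
    the sampling times, add Gaussian noise with SD = sd_intercept +
    sd_slope*C_true, truncate negatives at zero (count logged in
    ``n_truncated``).  Emits the long-format dataset and a truth table with
    each subject's parameters and true AUC/MAT.
    """
    times = np.asarray(design.sampling_times, dtype=float)
    rows, truth_rows = [], []
    n_truncated = 0
    for i in range(design.n_subjects):
        sid = f"S{i + 1:02d}"
        params = draw_subject_parameters(design, i)
        absorption = _subject_absorption(design, params)
        c_true = conc_2ig3c(times, absorption, design.disposition)
        rng = _subject_rng(design, i)
        rng.standard_normal(len(ABSORPTION_PARAMS))  # skip the parameter draws
        noise = rng.standard_normal(len(times)) * design.error.sd(c_true)
        obs = c_true + noise
        n_truncated += int(np.sum(obs < 0))
        obs = np.maximum(obs, 0.0)
        for t, dv in zip(times, obs):
            rows.append(
                {"ID": sid, "TIME": t, "DV": dv, "DOSE": design.dose, "MDV": 0}
            )
        truth_rows.append(
            {
                "ID": sid,
                **params,
                "AUC": params["F"] * design.dose / design.disposition.CL,
                "MAT": absorption.mat,
            }
        )
    dataset = StudyDataset(
        frame=pd.DataFrame(rows),
        metadata={"design": design.name, "seed": design.seed, "n_truncated": n_truncated},
    )
    return SimulatedStudy(
        design=design,
        dataset=dataset,
        truth=pd.DataFrame(truth_rows),
        n_truncated=n_truncated,
    )
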
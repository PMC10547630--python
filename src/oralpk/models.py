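"""Disposition kinetics and the four candidate oral concentration models.

Reference ("true") model — **2IG3C**: the two-IG mixture input of
:mod:`oralpk.input_functions` convolved with the impulse response of a
mammillary three-compartment disposition model whose six parameters
(V1, CL, CLd2, V2, CLd3, V3) are treated as known from intravenous data,

    C(t) = integral_0^t I(tau) * h(t - tau) dtau,
    h(t) = sum_i C_i * exp(-lambda_i * t)        (unit-bolus response),

with AUC = F*D/CL and MAT = p*MT1 + (1-p)*MT2.

Simpler models fitted to oral data alone:

* **ka1C** — one compartment, first-order absorption (Bateman function)
  ``C(t) = A*(exp(-ke*t) - exp(-ka*t))``, AUC = A*(ka-ke)/(ka*ke),
  MAT = 1/ka.
* **IG1C** — one compartment with a single IG input,
  ``C(t) = scale * integral f(tau)*exp(-ke*(t-tau)) dtau``,
  AUC = scale/ke, MAT = MT.
* **gamma** — empirical unimodal curve ``C(t) = A*t**(a-1)*exp(-b*t)``
  with a > 1, AUC = A*Gamma(a)/b**a; no MAT estimate exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.special import gamma as gamma_fn

from .input_functions import AbsorptionInput, IGInput, _ig_pdf

__all__ = [
    "Disposition3C",
    "TriExponential",
    "BatemanParams",
    "IG1CParams",
    "GammaParams",
    "impulse_response",
    "conc_2ig3c",
    "conc_bateman",
    "conc_ig1c",
    "conc_gamma",
    "bateman_auc",
    "gamma_auc",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(32)
# map from [-1, 1] to [0, 1]
_GL_NODES = 0.5 * (_GL_NODES + 1.0)
_GL_WEIGHTS = 0.5 * _GL_WEIGHTS


@dataclass(frozen=True)
class TriExponential:
    """Impulse response h(t) = sum_i coeffs[i]*exp(-rates[i]*t)."""

    coeffs: np.ndarray
    rates: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(-np.multiply.outer(t, self.rates)) @ self.coeffs

    @property
    def auc(self) -> float:
        return float(np.sum(self.coeffs / self.rates))


@dataclass(frozen=True)
class Disposition3C:
    """Mammillary three-compartment disposition in clearance/volume form.

    V1 central volume, CL elimination clearance, CLd2/V2 and CLd3/V3 the
    distribution clearances and volumes of the two peripheral compartments.
    Derived quantities: V_ss = V1+V2+V3 and the mean disposition residence
    time MDRT = V_ss/CL.
    """

    V1: float
    CL: float
    CLd2: float
    V2: float
    CLd3: float
    V3: float

    def __post_init__(self) -> None:
        for name in ("V1", "CL", "CLd2", "V2", "CLd3", "V3"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"disposition parameter {name} must be > 0, got {v}")

    @property
    def v_ss(self) -> float:
        return self.V1 + self.V2 + self.V3

    @property
    def mdrt(self) -> float:
        """Mean disposition residence time V_ss/CL (h)."""
        return self.v_ss / self.CL

    @cached_property
    def _h(self) -> TriExponential:
        return impulse_response(self)


def impulse_response(disp: Disposition3C) -> TriExponential:
    """Tri-exponential unit-bolus central concentration of the 3C model.

    Diagonalises the 3x3 first-order rate matrix of the amounts.  For a
    mammillary model with positive parameters the eigenvalues are real,
    negative and (generically) distinct; a repeated eigenvalue is rejected
    because the tri-exponential form degenerates there.
    """
    k10 = disp.CL / disp.V1
    k12 = disp.CLd2 / disp.V1
    k21 = disp.CLd2 / disp.V2
    k13 = disp.CLd3 / disp.V1
    k31 = disp.CLd3 / disp.V3
    A = np.array(
        [
            [-(k10 + k12 + k13), k21, k31],
            [k12, -k21, 0.0],
            [k13, 0.0, -k31],
        ]
    )
    eigval, eigvec = np.linalg.eig(A)
    if np.max(np.abs(eigval.imag)) > 1e-9 * np.max(np.abs(eigval.real)):
        raise ValueError("non-real eigenvalues: not a valid mammillary model")
    eigval = eigval.real
    eigvec = eigvec.real
    rates = -eigval
    if np.min(np.abs(np.diff(np.sort(rates)))) < 1e-10 * np.max(rates):
        raise ValueError("repeated disposition eigenvalues: degenerate model")
    # x(t) = V exp(Lambda t) V^-1 x0 with x0 = unit bolus in compartment 1
    w = np.linalg.solve(eigvec, np.array([1.0, 0.0, 0.0]))
    coeffs = eigvec[0, :] * w / disp.V1
    order = np.argsort(rates)
    return TriExponential(coeffs=coeffs[order], rates=rates[order])


def _convolve_density_expsum(
    t, density, breakpoints, coeffs, rates, scale: float
) -> np.ndarray:
    """scale * integral_0^t density(tau) * sum_i coeffs_i*exp(-rates_i*(t-tau)) dtau.

    Gauss-Legendre panels on [0, t], split at the supplied breakpoints
    (component mean times) so the peaked IG densities are well resolved.
    Fully vectorised over the evaluation times.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    edges = [np.zeros_like(t)]
    for b in sorted(breakpoints):
        edges.append(np.minimum(float(b), t))
    edges.append(t)
    nodes, weights = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        width = hi - lo
        nodes.append(lo[:, None] + width[:, None] * _GL_NODES[None, :])
        weights.append(width[:, None] * _GL_WEIGHTS[None, :])
    nodes = np.concatenate(nodes, axis=1)
    weights = np.concatenate(weights, axis=1)
    dens = density(nodes)
    lag = t[:, None, None] - nodes[:, :, None]
    kernel = np.einsum("ijk,k->ij", np.exp(-lag * rates[None, None, :]), coeffs)
    return scale * np.sum(weights * dens * kernel, axis=1)


def conc_2ig3c_raw(
    t,
    amount: float,
    p: float,
    mt1: float,
    rd21: float,
    mt2: float,
    rd22: float,
    h: TriExponential,
) -> np.ndarray:
    """Convolution on plain floats (hot path for fitting loops).

    ``amount`` is the bioavailable dose D*F.
    """
    brk = (
        mt1,
        mt1 + 6.0 * mt1 * np.sqrt(rd21),
        mt2,
        mt2 + 6.0 * mt2 * np.sqrt(rd22),
    )
    return _convolve_density_expsum(
        t,
        lambda x: p * _ig_pdf(x, mt1, rd21) + (1.0 - p) * _ig_pdf(x, mt2, rd22),
        brk,
        h.coeffs,
        h.rates,
        amount,
    )


def conc_2ig3c(t, absorption: AbsorptionInput, disp: Disposition3C):
    """Plasma concentration of the reference model (2IG input, 3C disposition)."""
    out = conc_2ig3c_raw(
        t,
        absorption.D * absorption.F,
        absorption.p,
        absorption.ig1.MT,
        absorption.ig1.RD2,
        absorption.ig2.MT,
        absorption.ig2.RD2,
        disp._h,
    )
    return out if np.ndim(t) else float(out[0])


@dataclass(frozen=True)
class BatemanParams:
    """Bateman-function parameters: amplitude A, rate constants ka, ke (1/h)."""

    A: float
    ka: float
    ke: float

    def __post_init__(self) -> None:
        for name in ("A", "ka", "ke"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"Bateman parameter {name} must be > 0, got {v}")
        if abs(self.ka - self.ke) <= 1e-6 * self.ka:
            raise ValueError("ka = ke: Bateman function degenerate")

    @property
    def t_max(self) -> float:
        return float(np.log(self.ka / self.ke) / (self.ka - self.ke))


def conc_bateman(t, params: BatemanParams):
    """C(t) = A*(exp(-ke*t) - exp(-ka*t))."""
    t = np.asarray(t, dtype=float)
    return params.A * (np.exp(-params.ke * t) - np.exp(-params.ka * t))


def bateman_auc(params: BatemanParams) -> float:
    """Closed-form AUC = A*(ka - ke)/(ka*ke)."""
    return params.A * (params.ka - params.ke) / (params.ka * params.ke)


@dataclass(frozen=True)
class IG1CParams:
    """One-compartment model with a single-IG input.

    ``scale`` is the composite amplitude F*D/V (only the product is
    identifiable from oral data); MT/RD2 parameterise the input density and
    ke is the first-order elimination rate constant.
    """

    scale: float
    MT: float
    RD2: float
    ke: float

    def __post_init__(self) -> None:
        for name in ("scale", "MT", "RD2", "ke"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"IG1C parameter {name} must be > 0, got {v}")

    @property
    def ig(self) -> IGInput:
        return IGInput(MT=self.MT, RD2=self.RD2)


def conc_ig1c_raw(t, scale: float, mt: float, rd2: float, ke: float) -> np.ndarray:
    """Single-IG one-compartment convolution on plain floats (hot path)."""
    brk = (mt, mt + 6.0 * mt * np.sqrt(rd2))
    return _convolve_density_expsum(
        t,
        lambda x: _ig_pdf(x, mt, rd2),
        brk,
        np.array([1.0]),
        np.array([ke]),
        scale,
    )


def conc_ig1c(t, params: IG1CParams):
    """C(t) = scale * integral_0^t f(tau) * exp(-ke*(t-tau)) dtau."""
    out = conc_ig1c_raw(t, params.scale, params.MT, params.RD2, params.ke)
    return out if np.ndim(t) else float(out[0])


def ig1c_auc(params: IG1CParams) -> float:
    """AUC = scale/ke (one-compartment F*D/CL with CL = ke*V)."""
    return params.scale / params.ke


@dataclass(frozen=True)
class GammaParams:
    """Empirical gamma curve C(t) = A*t**(a-1)*exp(-b*t), a > 1."""

    A: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.A > 0 and np.isfinite(self.A)):
            raise ValueError(f"gamma amplitude A must be > 0, got {self.A}")
        if not self.a > 1:
            raise ValueError(f"gamma shape a must be > 1, got {self.a}")
        if not (self.b > 0 and np.isfinite(self.b)):
            raise ValueError(f"gamma rate b must be > 0, got {self.b}")

    @property
    def t_max(self) -> float:
        return (self.a - 1.0) / self.b


def conc_gamma(t, params: GammaParams):
    """C(t) = A*t**(a-1)*exp(-b*t); 0 at t = 0 since a > 1."""
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        out = params.A * np.where(t > 0, t, 0.0) ** (params.a - 1.0) * np.exp(-params.b * t)
    return np.where(t > 0, out, 0.0)


def gamma_auc(params: GammaParams) -> float:
    """Closed-form AUC = A*Gamma(a)/b**a."""
    return params.A * gamma_fn(params.a) / params.b**params.a
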
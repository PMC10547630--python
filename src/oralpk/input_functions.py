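"""Inverse-Gaussian absorption input functions.

The oral drug input rate into the central compartment is modelled as a
mixture of two inverse-Gaussian (IG) densities scaled by the bioavailable
dose,

    I(t) = D*F * (p*f1(t) + (1-p)*f2(t)),      0 < p < 1,

where each component density

    f_i(t) = sqrt(MT_i / (2*pi*RD2_i*t^3)) * exp(-(t-MT_i)^2 / (2*RD2_i*MT_i*t))

is an IG distribution parameterised by its mean time ``MT`` (h) and its
squared relative dispersion ``RD2`` (dimensionless shape).  In the standard
(mu, lambda) parameterisation of the inverse Gaussian this corresponds to
mu = MT and lambda = MT / RD2.

The mean absorption time of the mixture is exact:

    MAT = p*MT1 + (1-p)*MT2.

The time-dependent fractional absorption rate (the hazard rate of the
input-time distribution) follows from first-order mass balance at the
absorption site, dA_gi/dt = -k_a(t)*A_gi(t):

    k_a(t) = I(t) / A_gi(t),

which is constant only for a mono-exponential input (classical first-order
absorption).  All times are in hours; amounts carry the units of the dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "IGInput",
    "AbsorptionInput",
    "ig_density",
    "ig_cdf",
    "ig_survival",
    "input_rate",
    "unabsorbed_amount",
    "ka_of_t",
]

# densities are defined on t > 0; below this floor they are taken as 0
_T_FLOOR = 1e-12
# exponent cap guards exp() overflow for t far inside the left tail
_EXP_CAP = 700.0


@dataclass(frozen=True)
class IGInput:
    """One inverse-Gaussian input component.

    Parameters
    ----------
    MT : float
        Mean time of the component (h), strictly positive.
    RD2 : float
        Squared relative dispersion (shape), strictly positive.
    """

    MT: float
    RD2: float

    def __post_init__(self) -> None:
        if not (self.MT > 0 and np.isfinite(self.MT)):
            raise ValueError(f"MT must be a positive finite number, got {self.MT}")
        if not (self.RD2 > 0 and np.isfinite(self.RD2)):
            raise ValueError(f"RD2 must be a positive finite number, got {self.RD2}")

    @property
    def _frozen_dist(self):
        # scipy parameterisation: invgauss(m, scale) has mean m*scale and
        # shape lambda = scale; here mean = MT, lambda = MT/RD2.
        return stats.invgauss(self.RD2, scale=self.MT / self.RD2)


@dataclass(frozen=True)
class AbsorptionInput:
    """Dose-scaled two-component IG mixture input.

    ``D`` is the administered dose, ``F`` the bioavailability fraction and
    ``p`` the mixture weight of the first component.  The total amount
    entering the circulation is D*F.
    """

    D: float
    F: float
    p: float
    ig1: IGInput
    ig2: IGInput

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"dose D must be > 0, got {self.D}")
        if not 0 < self.F <= 1:
            raise ValueError(f"bioavailability F must be in (0, 1], got {self.F}")
        if not 0 < self.p < 1:
            raise ValueError(f"mixture weight p must be in (0, 1), got {self.p}")

    @property
    def mat(self) -> float:
        """Mean absorption time p*MT1 + (1-p)*MT2 (h)."""
        return self.p * self.ig1.MT + (1 - self.p) * self.ig2.MT

    def mixture_density(self, t):
        """Input-time probability density p*f1 + (1-p)*f2."""
        return self.p * ig_density(t, self.ig1) + (1 - self.p) * ig_density(t, self.ig2)

    def mixture_cdf(self, t):
        return self.p * ig_cdf(t, self.ig1) + (1 - self.p) * ig_cdf(t, self.ig2)


def _ig_pdf(t: np.ndarray, mt: float, rd2: float) -> np.ndarray:
    """IG density on a float array, no parameter object (hot path)."""
    out = np.zeros_like(t)
    pos = t > _T_FLOOR
    tp = t[pos]
    pref = np.sqrt(mt / (2.0 * np.pi * rd2 * tp**3))
    expo = -((tp - mt) ** 2) / (2.0 * rd2 * mt * tp)
    out[pos] = pref * np.exp(np.maximum(expo, -_EXP_CAP))
    return out


def ig_density(t, ig: IGInput):
    """IG density f(t); 0 at t = 0 (continuous limit) and for t < 0 floor.

    Vectorised over ``t``.
    """
    out = _ig_pdf(np.asarray(t, dtype=float), ig.MT, ig.RD2)
    return out if out.ndim else float(out)


def ig_cdf(t, ig: IGInput):
    """IG cumulative distribution via the closed two-Gaussian-CDF form."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > _T_FLOOR
    out[pos] = ig._frozen_dist.cdf(t[pos])
    return out if out.ndim else float(out)


def ig_survival(t, ig: IGInput):
    """IG survival function S(t) = 1 - F(t)."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    pos = t > _T_FLOOR
    out[pos] = ig._frozen_dist.sf(t[pos])
    return out if out.ndim else float(out)


def input_rate(t, absorption: AbsorptionInput):
    """Drug input rate I(t) = D*F*(p*f1(t) + (1-p)*f2(t)), in mass/h."""
    return absorption.D * absorption.F * absorption.mixture_density(t)


def unabsorbed_amount(t, absorption: AbsorptionInput):
    """Amount still at the absorption site, A_gi(t) = D*F*(1 - F_mix(t))."""
    a = absorption
    surv = a.p * ig_survival(t, a.ig1) + (1 - a.p) * ig_survival(t, a.ig2)
    return a.D * a.F * surv


def ka_of_t(t, absorption: AbsorptionInput, floor: float = 1e-300):
    """Fractional absorption rate k_a(t) = I(t)/A_gi(t) (1/h).

    Computed in log space (log-pdf minus log-survival of the mixture) so the
    deep right tail, where both numerator and denominator underflow, stays
    accurate.  Where the mixture survival falls below ``floor`` (drug
    essentially fully absorbed) the rate is undefined and NaN is returned.
    """
    t = np.asarray(t, dtype=float)
    a = absorption
    d1, d2 = a.ig1._frozen_dist, a.ig2._frozen_dist
    out = np.zeros_like(t)
    pos = t > _T_FLOOR
    tp = t[pos]
    with np.errstate(divide="ignore"):
        logw = np.log([a.p, 1.0 - a.p])
        logpdf = logsumexp(
            np.stack([logw[0] + d1.logpdf(tp), logw[1] + d2.logpdf(tp)]), axis=0
        )
        logsf = logsumexp(
            np.stack([logw[0] + d1.logsf(tp), logw[1] + d2.logsf(tp)]), axis=0
        )
    haz = np.exp(logpdf - logsf)
    haz[logsf < np.log(floor)] = np.nan
    out[pos] = haz
    return out if out.ndim else float(out)
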
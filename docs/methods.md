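# Methods

## The question the package addresses

After an oral dose, the plasma concentration curve is the convolution of two
processes: drug *input* into the systemic circulation (absorption) and
*disposition* (distribution + elimination). When intravenous reference data
exist, the disposition kinetics can be fixed independently and the input
function estimated from the oral data; without iv data, simple empirical
models — above all the one-compartment model with first-order absorption
(the Bateman function) — are fitted to the oral curve alone. This package
quantifies, by simulation, what that simplification does to the two
model-independent parameters of interest: the exposure AUC and the mean
absorption time MAT.

## Reference ("true") model: 2IG3C

The input rate is a dose-scaled mixture of two inverse-Gaussian (IG)
densities,

    I(t) = D·F·[p·f1(t) + (1−p)·f2(t)],  0 < p < 1,
    f_i(t) = sqrt(MT_i / (2π·RD²_i·t³)) · exp(−(t−MT_i)² / (2·RD²_i·MT_i·t)),

with mean time `MT_i` (h) and squared relative dispersion `RD²_i` per
component, so that MAT = p·MT1 + (1−p)·MT2 exactly. (Published statements of
this model contain an obvious misprint repeating f1 in the second mixture
term; the mixture form above is the only one consistent with the MAT
identity.) The IG corresponds to the standard (μ, λ) parameterisation via
μ = MT, λ = MT/RD²; densities, CDFs and survival functions go through
`scipy.stats.invgauss`.

Disposition is a mammillary three-compartment model in clearance/volume form
(V1, CL, CLd2, V2, CLd3, V3). Its unit-bolus central-compartment response is
tri-exponential, `h(t) = Σ C_i·exp(−λ_i t)`, obtained by eigen-decomposition
of the 3×3 first-order rate matrix with `numpy.linalg.eig` (equivalent to
solving the characteristic cubic; the tests pin it to a matrix-exponential
oracle at 1e−9 relative). Useful identities: Σ C_i = 1/V1, ∫h = 1/CL,
V_ss = V1+V2+V3, MDRT = V_ss/CL.

The oral curve is C(t) = ∫₀ᵗ I(τ)·h(t−τ) dτ, with AUC = F·D/CL.

The time-dependent fractional absorption rate is the hazard of the
input-time distribution, k_a(t) = I(t)/A_gi(t), where A_gi is the unabsorbed
amount; it is computed from log-pdf and log-survival differences
(`logsumexp`) so the right tail stays accurate, and reported as undefined
(NaN) once the mixture survival underflows.

### Numerical convolution

The convolution integrand is a smooth but possibly sharply peaked density
times a sum of exponentials. It is integrated with fixed 32-node
Gauss–Legendre panels on [0, t], with panel edges at each component's mean
and at mean + 6·SD (SD = MT·√RD²) so narrow components are resolved; the
scheme is vectorised over all evaluation times (~0.2 ms for a 24-point
curve) and agrees with adaptive quadrature to ~1e−8 relative in the tested
parameter ranges. Population fitting evaluates the model ~10⁵ times, which
is why a fixed-node scheme is used instead of per-point adaptive quadrature.

## Candidate models fitted to oral data alone

* **ka1C (Bateman)**: C(t) = A·(e^(−ke·t) − e^(−ka·t)); AUC =
  A(ka−ke)/(ka·ke); MAT = 1/ka; MBRT = 1/ka + 1/ke. ka = ke is rejected
  (the closed-form AUC is undefined at the confluent limit).
* **IG1C**: one compartment with a single IG input; only the composite
  amplitude scale = F·D/V is identifiable from oral data; AUC = scale/ke;
  MAT = MT.
* **gamma**: C(t) = A·t^(a−1)·e^(−bt) with a > 1; AUC = A·Γ(a)/bᵃ;
  MBRT = a/b; *no* MAT estimate exists. The shape is estimated as a−1 on
  the log scale so the a > 1 constraint is honoured by construction.

## Moment analysis

`moments_numeric` integrates any curve on [0, T] by adaptive quadrature and
corrects for the tail by log-linear extrapolation of the terminal slope
(fitted to the last three evaluation points), the usual non-compartmental
convention; when no horizon is given, a first pass estimates MBRT and the
horizon is reset once to 10×MBRT. MAT follows by moment subtraction,
MAT = MBRT − MDRT, which requires iv information (MDRT = V_ss/CL); a
negative MAT from a misspecified fit is returned with a warning, never
clipped, because the bias analysis needs the signed value.

## Estimation

Residual error is additive Gaussian with SD linear in the predicted
concentration, SD(C) = a + b·C. Individual fits maximise this likelihood
with all structural parameters on the log scale (Nelder–Mead, 5 jittered
starts with log-scale SD 0.6, best likelihood kept). When no error model is
supplied, (a, b) are estimated jointly.

The population layer assumes log-normal individual parameters with diagonal
covariance and offers:

* **two_stage** — independent individual fits, then the log-scale
  mean/variance across subjects. Fast; used for smoke tests, AIC grids and
  as EM initialisation. Its "population likelihood" is the sum of the
  individual maxima.
* **em** — importance-sampling EM. Per subject, parameters are drawn from a
  Gaussian (in log space) proposal centred at the current conditional means
  with SD re-estimated each iteration from the previous weighted posterior
  spread (inflated 2×, clipped to at most twice the population SD);
  importance weights combine the data likelihood with the prior/proposal
  ratio. Common random numbers are reused across iterations so the EM map is
  deterministic and convergence (relative marginal-loglik change < 1e−5) is
  meaningful. The M-step updates the population mean/variance from the
  conditional moments, floors each variance at CV 2% (flagged), and
  re-estimates (a, b) from the cached weighted residuals. The marginal
  log-likelihood is the importance-sampling estimate log·mean_k p(y|θ_k).
  Default 400 samples, ≤60 iterations. Adaptive proposals are essential:
  with rich designs (14–24 samples/subject) the conditional distributions
  are far narrower than the population distribution and population-wide
  proposals give effective sample sizes near 1.

AIC = −2·loglik + 2·m with m = 2·(number of structural parameters) + 2
(a mean and a variance per parameter, plus the two error parameters).
Comparisons across models always use fits produced with the same method.

The 2IG3C model is fitted with the six disposition parameters fixed (F is
then estimable because CL is known); the three simple models are fitted to
the oral data alone and never report F. Mixture label switching is resolved
by the convention MT1 ≤ MT2; the mixture weight is estimated log-normally
with a hard cap at p = 0.995.

## Synthetic studies

No raw clinical datasets of this design are publicly deposited, so the
package generates virtual studies whose *structure* matches published rich
single-dose designs for three slowly absorbed drugs/formulations:

| preset            | n  | samples | dose  | MAT  | MDRT | MAT/MDRT | F    |
|-------------------|----|---------|-------|------|------|----------|------|
| trospium_like     | 12 | 24      | 30 mg | 9 h  | 15 h | 0.6      | 0.10 |
| propiverine_like  | 10 | 16      | 45 mg | 11 h | 11 h | 1.0      | 0.50 |
| ketamine_like     | 15 | 14      | 80 mg | 12 h | 20 h | 0.6      | 0.15 |

All absorption parameters carry 25% between-subject CV (10% for p) as
log-normal variability with the population value as geometric mean;
disposition is shared by all subjects (it plays the role of iv-derived
truth). Sampling grids are geometric, dense early, ending at 4×MBRT.
Residual noise is 10% proportional plus an additive floor of 2% of the
population peak concentration; negative simulated observations are truncated
at zero and counted. The preset parameter values are *synthetic*: chosen
once to satisfy the published design constraints (subject/sample counts, the
8–13 h MAT range, MAT/MDRT ratios of ≈0.6/≈1, low-F ketamine-like
first-pass character), not fitted to any clinical data.

What the generator does **not** emulate: real formulation-specific input
shapes beyond two IG components, between-subject variability in disposition,
iv arms, below-quantification censoring rules, dropout, or covariate
effects. Passing tests therefore demonstrate properties of the estimation
machinery under the stated statistical model, not conclusions about any real
drug.

## Design choices and degenerate inputs

* Times are hours; concentrations are dose-units per litre; nothing is
  enforced beyond positivity.
* Densities return 0 below t = 1e−12 h; exponent arguments are capped to
  avoid overflow; residual SDs are floored at 1e−10.
* Repeated disposition eigenvalues (a measure-zero configuration) raise a
  degenerate-model error rather than switching to a confluent form.
* A subject must carry at least (number of parameters + 1) observations.
* The "population AUC/MAT" of a fit propagates the geometric-mean parameter
  set through the model's closed form; because that map is nonlinear the
  arithmetic mean of the individual metrics is also reported
  (`auc_mean_of_individuals`) and is the better-behaved summary for the
  Bateman model, whose closed-form AUC is violently nonlinear near ka ≈ ke.
* Two-stage fits of weakly identified parameters (the mixture's internal
  decomposition: p, RD²_1, RD²_2) are noticeably biased at n≈12 with 10%
  noise even though the fitted curves and the functionals AUC, F and MAT are
  accurate; the EM estimates are closer but the late component's RD²
  remains the hardest parameter. This is a genuine identifiability limit of
  the mixture at these study sizes, not an optimizer artefact (noise-free
  fits recover all parameters to <0.1%, and the ML solutions dominate the
  truth in likelihood).

## Problem sizes used in the shipped analyses

The packaged tests and the acceptance script run the three presets at their
published design sizes (12×24, 10×16, 15×14), two-stage fits of all four
models, and EM fits where the population layer itself is under test. These
sizes keep a full replication run in the minutes range on one CPU.

## Known limitations

* Diagonal random-effects covariance only; no covariates; no FOCE/Laplace
  alternative likelihoods.
* The importance-sampling marginal likelihood is a Monte-Carlo estimate;
  AIC differences of a few units between models of similar fit should not
  be over-interpreted.
* Single oral dose per subject; no infusion or multi-dose records.
* The gamma model's MAT is reported as unavailable rather than imputed.
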
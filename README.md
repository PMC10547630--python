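# oralpk

**How much does the Bateman function lie to you?** `oralpk` is a simulation
and estimation pipeline for quantifying the bias that simple oral-data-only
absorption models introduce into the two model-independent pharmacokinetic
parameters — the exposure `AUC` and the mean absorption time `MAT` — when
the drug actually distributes into several compartments and its absorption
rate is not first-order.

It is aimed at pharmacometricians who fit oral concentration–time data
without intravenous reference information and want to know which of their
numbers to trust.

## The model family

Reference ("true") model, **2IG3C** — drug input into the central
compartment as a dose-scaled mixture of two inverse-Gaussian densities,

```
I(t) = D·F·[p·f₁(t) + (1−p)·f₂(t)],   fᵢ ~ IG(MTᵢ, RD²ᵢ),
MAT  = p·MT₁ + (1−p)·MT₂,
```

convolved with the tri-exponential impulse response of a three-compartment
disposition model whose six parameters (V1, CL, CLd2, V2, CLd3, V3) are
fixed, as if estimated from iv data. `AUC = F·D/CL`, `MDRT = V_ss/CL` and
the time-dependent fractional absorption rate is the input-time hazard
`k_a(t) = I(t)/A_gi(t)`.

Candidate models fitted to the oral data alone:

| model | curve                          | AUC            | MAT  |
|-------|--------------------------------|----------------|------|
| ka1C  | `A(e^(−ke·t) − e^(−ka·t))`     | `A(ka−ke)/(ka·ke)` | `1/ka` |
| IG1C  | single IG input ⊗ `e^(−ke·t)`  | `scale/ke`     | `MT` |
| gamma | `A·t^(a−1)·e^(−bt)`, a > 1     | `A·Γ(a)/bᵃ`    | none |

Fitting is by maximum likelihood with residual SD linear in the predicted
concentration, individually or as a log-normal population model (two-stage
or importance-sampling EM with conditional means); models are compared by
AIC and by percent deviation of AUC/MAT from the simulation truth, at the
population-mean and the per-subject level. Because no raw clinical data of
this kind are deposited, the `synthetic` module generates virtual studies
(three presets with 12×24, 10×16 and 15×14 subjects×samples, MAT between
8 and 13 h, MAT/MDRT ≈ 0.6–1) from the reference model.

## Worked example

```python
import numpy as np
from oralpk import (preset_design, simulate_study, fit_population,
                    build_bias_report, aic_table)
from oralpk.fitting import FitConfig

design = preset_design("trospium_like", seed=1)   # 12 subjects x 24 samples
sim = simulate_study(design)

cfg = FitConfig(method="two_stage", seed=1)
fits = {
    m: fit_population(sim.dataset, m,
                      fixed_disposition=design.disposition if m == "2IG3C" else None,
                      config=cfg)
    for m in ("2IG3C", "ka1C", "IG1C", "gamma")
}
print(aic_table(fits)[["model", "AIC"]].to_string(index=False))
report = build_bias_report(fits, sim.truth)
ka = report.models["ka1C"]
print(f"ka1C AUC population deviation: {ka.population['AUC']:+.1f}%")
print(f"ka1C AUC mean |individual| deviation: {ka.summary['AUC']['mean_abs']:.1f}%")
print(f"ka1C MAT population deviation: {ka.population['MAT']:+.1f}%")
```

prints

```
model          AIC
2IG3C -4077.348144
 IG1C -3910.373770
 ka1C -3534.055917
gamma -3478.818971
ka1C AUC population deviation: +1.5%
ka1C AUC mean |individual| deviation: 6.1%
ka1C MAT population deviation: -87.0%
```

Read: the true model wins the AIC comparison decisively; the Bateman
function still recovers the *population* exposure to within a couple of
percent even though its per-subject AUC estimates are several times more
biased; and its mean absorption time is useless here (1/ka massively
underestimates MAT because the one-compartment approximation absorbs the
distribution kinetics into the "absorption" rate). The same pipeline is
scriptable from the shell:

```
oralpk run --preset trospium_like --seed 1 --method two_stage --outdir results/run1
oralpk report --outdir results/run1
```

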
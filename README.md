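# chromech

Nonlinear mechanics of human mitotic chromosomes: a hierarchical
worm-like-chain (HWLC) simulator and the optical-tweezers analysis pipeline
that goes with it, exercised entirely on synthetic data.

## The problem

When a metaphase chromosome held between two optically trapped beads is
stretched, its force-extension response is linear up to a few tens of pN and
then *stiffens*: the differential stiffness K = dF/dd grows with force as a
power law, K ~ F^γ. Classical homogeneous polymer models cannot produce the
observed exponent. A polymer with finite extensibility diverges as
F ~ (d − d_c)^(−δ), which implies γ = (δ + 1)/δ > 1 — the freely jointed
chain (FJC) gives γ = 2 and the worm-like chain (WLC) gives γ = 3/2 — yet
chromosomes show γ ≈ 0.8, *below* one.

The HWLC model resolves this through heterogeneity: the chromosome is a
series of N worm-like-chain elements whose critical forces f_c,i (the scale
where each element starts to stiffen) are drawn from a broad distribution,
e.g. P(f_c) ∝ f_c^(−β) on [f_min, f_max]. Elements stiffen sequentially —
softest first — and the assembly acquires the emergent exponent

    γ = β + α − 1,         k0,i ∝ f_c,i^α,

which for fixed sub-chain length (α = 1) is simply γ = β and can lie below
1. The assembly's own critical force is the minimum of the N draws, so its
distribution follows from order statistics:
P(F_c ≤ x) = 1 − (1 − P(f_c ≤ x))^N.

The package implements:

* **`chromech.polymer`** — closed-form WLC interpolation and FJC (Langevin)
  force laws, their exact inverses and analytic stiffness;
* **`chromech.distributions` / `chromech.hwlc`** — truncated power-law and
  exponential critical-force distributions, serial assemblies, 500-
  configuration ensemble simulation, the exponent law and the assembly-F_c
  order statistics;
* **`chromech.curves`** — the measurement pipeline (moving-average
  smoothing, numerical differentiation, KDE plateau, stiffening onset and
  length, compliance at 200 pN, log-log piecewise fit, master-curve
  collapse, exponent fit, rupture detection), wrapped in
  `StiffeningModel` / `StiffeningResults`;
* **`chromech.rheology`** — oscillatory microrheology: fixed-frequency
  sinusoid fits and the complex stiffness k = (A_F/A_d)·e^{i(φ_F−φ_d)}
  with storage K′ and loss K″ moduli (`OscillationModel`);
* **`chromech.synthetic`** — generators for chromosome populations, pulling
  curves (noise, drift, rupture events) and oscillation traces, each with a
  ground-truth sidecar;
* **`chromech.cli`** — a `chromech` command with `simulate`, `analyze`,
  `microrheo` and `fixtures` subcommands.

## Worked example

```python
import numpy as np
from chromech import (CriticalForceDistribution, simulate_ensemble,
                      predicted_gamma, StiffeningModel,
                      u2os_like_spec, gen_population_curve)
from chromech.curves import StiffnessCurve, fit_stiffening_exponent

# the published HWLC parameter set: P(f_c) ~ f_c^-0.86 on [5, 500] pN,
# N = 30 sub-chains, L = 3 um, alpha = 1, 500 configurations
dist = CriticalForceDistribution.power_law(0.86, 5.0, 500.0)
ens = simulate_ensemble(dist, N=30, L=3.0, alpha=1.0, n_configs=500, seed=1)
gamma = fit_stiffening_exponent(
    StiffnessCurve(force=ens.force_grid, stiffness=ens.mean_stiffness),
    20.0, 200.0)
print(f"ensemble gamma = {gamma:.3f}  (law predicts {predicted_gamma(dist):.2f})")

# one noisy synthetic chromosome through the measurement pipeline
curve, truth = gen_population_curve(u2os_like_spec(seed=1), 0)
res = StiffeningModel(curve).fit()
print(res.summary())
```

prints

```
ensemble gamma = 0.934  (law predicts 0.86)
Strain-stiffening analysis
==============================================
samples                                   3393
cycle                              extension_3
plateau stiffness [pN/um]                15.72
K0 (piecewise) [pN/um]                   12.96
Fc [pN]                                  8.334
piecewise slope c                       0.9009
gamma (window fit)                      0.9819
stiffening length [um]                    2.24
onset force [pN]                         24.48
compliance@200pN [nm/pN]                 3.911
collapse valid                            True
rupture events                               0
```

The ensemble exponent (0.93 over the 20–200 pN window) sits near the
asymptotic law γ = β = 0.86; the residual offset is the finite-cutoff bias
of the truncated distribution (see `docs/methods.md`). The per-curve report
shows the linear plateau (~16 pN/µm), the critical force where stiffening
sets in, the stiffening length (bead-bead distance at onset, here 2.2 µm),
and the compliance read at 200 pN in nm/pN.

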
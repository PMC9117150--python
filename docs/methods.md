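# Methods

## Model

### Elements

A chromosome is modelled as effective structural elements rather than bare
DNA. Each worm-like-chain element is parametrized by its critical force
f_c (pN) and contour length ℓ (µm); there is no explicit temperature — f_c
absorbs the thermal force scale (k_B·T over persistence length in a literal
polymer). The force law is the standard interpolation form

    F(x) = f_c · [ 1/(4(1 − x/ℓ)²) − 1/4 + x/ℓ ],

which has the three properties the data require: a linear regime with
initial stiffness k0 = (3/2)·f_c/ℓ, a crossover at F ≈ f_c, and asymptotic
stiffening K = dF/dx ∝ F^(3/2). The freely jointed chain uses the Langevin
law x(F) = ℓ·[coth(F/f_c) − f_c/F], with k0 = 3·f_c/ℓ and K ∝ F². Any
finite-extensibility divergence F ~ (d − d_c)^(−δ) implies K ~ F^γ with
γ = (δ + 1)/δ > 1, so exponents below 1 cannot come from a homogeneous
chain.

Inversion of the WLC law is exact: with u = 1 − x/ℓ the law becomes the
cubic u³ + (F/f_c − 3/4)u² − 1/4 = 0, which has exactly one positive root
for every F ≥ 0. The root is taken in closed form (Cardano or the
trigonometric three-root branch) and polished with three Newton steps,
giving machine-precision round trips (verified against bracketed
root-finding in the tests); the closed form is what makes 500-configuration
ensembles and thousands-of-samples synthetic curves cheap.

### Assemblies

N elements in series share the force; extensions and compliances add:

    d(F) = Σ x_i(F),    1/K(F) = Σ 1/k_i(F).

Critical forces are i.i.d. from a truncated density on [f_min, f_max]
(defaults 5 and 500 pN, chosen so assembly critical forces land in the
observed 10–50 pN range while the power-law window 20–200 pN sits inside
the support): either P(f_c) ∝ f_c^(−β) or P(f_c) ∝ exp(−f_c/f_c*).
Sampling is by inverse CDF, so integer seeds reproduce draws exactly.
Element lengths scale as ℓ_i ∝ f_c,i^(1−α) normalised to total contour L,
which enforces k0,i ∝ f_c,i^α; the default α = 1 keeps all sub-chains at
L/N. For the power-law family the assembly stiffens with the emergent
exponent γ = β + α − 1. The assembly critical force is the minimum of the
N draws, with CDF 1 − (1 − P(f_c ≤ x))^N.

**Finite-cutoff bias.** γ = β + α − 1 is asymptotic in f_min ≪ F ≪ f_max.
At the published parameter set (β = 0.86, cutoffs [5, 500] pN) the
ensemble-mean stiffness fitted over the experimental 20–200 pN window gives
γ ≈ 0.93: the slope drifts up toward the single-chain 3/2 as the window
approaches f_max. This is a property of the truncated model, not of the
estimator, and it is why `calibrate_beta_for_gamma` exists: it solves for
the β whose *measured* window slope equals a requested γ (bisection on the
noiseless per-configuration mean slope). Targets γ ≲ 0.5 are unreachable
with f_max = 500 pN and need a wider support (the flat-distribution
populations use f_max = 2000 pN).

## Curve analysis

The pipeline mirrors standard force-spectroscopy practice:

1. **Smoothing** — centered moving average on the force channel, window
   1/15 of the samples. Edge windows shrink *symmetrically* (half-width
   limited by the distance to either end), so linear signals pass unchanged
   everywhere; an asymmetric truncation would bias the endpoints.
2. **Differentiation** — K = dF/dd by centered differences on the
   (nonuniform) distance grid, one-sided at the ends; distance ties are
   collapsed by force averaging.
3. **Edge trim** — derivative samples within half a smoothing window of
   either curve end keep essentially unsmoothed noise and are dropped
   before the statistics (`trim_edges`, default on in `StiffeningModel`).
4. **Plateau** — mode of a Gaussian-KDE (Silverman bandwidth, 512 grid
   points) over stiffness samples below 50 pN. The 50 pN ceiling targets
   chromosomes, whose linear regime ends at 10–50 pN; for a bare element
   the window must sit inside its own linear regime (< 0.05·f_c), otherwise
   the mode picks up the stiffening tail.
5. **Onset** — first sample whose stiffness exceeds plateau + 1 s.d. of
   the below-50 pN stiffnesses; the stiffening length is the bead-bead
   distance there. `StiffeningModel` additionally requires the exceedance
   to persist for one tenth of the smoothing half-window (≈ 10 samples at
   default sampling), which suppresses noise-triggered early onsets without
   shifting the location on noiseless data.
6. **Log-log resampling** — nonpositive (F, K) pairs are discarded; the
   rest are averaged within log-spaced force bins as (mean ln F, mean ln K)
   pairs — exact for any pure power law and averaging noise by the per-bin
   count — then interpolated onto a log-spaced grid (capped at 400 points).
7. **Piecewise fit** — continuous plateau-plus-line model in (ln F, ln K):
   y = ln K0 below ln Fc, slope c above, continuous at the kink. The kink
   is located by an exhaustive vectorised scan over sample positions and
   refined by bounded golden section. Validity for the master-curve
   collapse requires K0, Fc positive and inside the curve's observed
   ranges; rescaling to (F/Fc, K/K0) collapses curve families.
8. **Exponent** — OLS slope of ln K vs ln F over 20–200 pN (the published
   fitting window), configurable.
9. **Compliance** — 1000/K interpolated at 200 pN, reported in nm/pN.
10. **Ruptures** — peak-to-trough force drops ≥ a threshold while distance
    increases. Detection runs on a lightly smoothed copy (5-sample window):
    a rupture's drop is small compared with the force gained across one
    full 1/15 window, so the heavily smoothed curve rises straight through
    it.

Group contrasts use the two-sided Wilcoxon rank-sum test (exact null
distribution for n ≤ 25 per group) via the standard scipy routine.

**Estimator systematics.** The piecewise-fit K0 consistently reads ~20%
above the analytic series k0 because the stiffness already rises below the
kink; the KDE plateau is the unbiased initial-stiffness estimate. Feature
recovery is therefore quantified against the *noiseless-pipeline* features
of the same chromosome (what the measurement returns without noise), which
separates noise robustness from estimator bias. Across seeds, the
stiffening exponent recovers within ±0.01, the stiffening length within
±8% per curve, and K0 within ~2% in the median with a per-curve tail to
~7% for chromosomes whose assembly critical force sits within half a
decade of the lowest observable force (their plateau is barely sampled).
Documented recovery tolerances: γ ±0.1 and stiffening length ±15% per
curve; K0 5% on the population median.

## Microrheology

An oscillation trace holds time, force, trap position and optionally a
tracked bead position around a pre-tension. Both channels are fitted with
A·sin(2πft + φ) + offset + slope·t at the known drive frequency — linear
in the (sin, cos, 1, t) basis, so one least-squares solve detrends
(first order) and fits simultaneously and is exact on noiseless input. The
complex stiffness is k = (A_F/A_d)·e^{i(φ_F − φ_d)}, storage K′ = Re k,
loss K″ = Im k; force leading distance gives K″ > 0 (passive material).
|k| = A_F/A_d holds identically. Fit precision scales as 1/√(samples);
at the default 10 periods × 200 samples/period and few-percent noise, K′
recovers within ~1% and the K″/K′ ratio generated at 1/50 stays inside
the observed 10–100× band.

Above 1 Hz, camera tracking is frame-rate limited and the bead position is
reconstructed as trap − F/k_trap. Integer-sample cross-correlation
synchronization is provided for channels on independent clocks, but
`OscillationModel` does not apply it by default: the passive phase lag is a
fraction of one sample, and quantized alignment of force against distance
would absorb exactly the phase the loss modulus measures.

## Synthetic data

The generator emulates the study conditions: pulling at ≤ 0.2 µm/s sampled
at 100 Hz (≈ 1 nm steps), forces to 300 pN, Gaussian force noise of 0.5 pN
(a declared fixture choice; the instruments publish no explicit floor),
optional linear drift, and rupture events (Poisson count; each is a
permanent contour-length increment placed where the force comfortably
exceeds the drop, giving an abrupt decline with gradual recovery). The
recorded bead-bead distance is a native rest length plus the assembly
extension; the wild-type-like population uses contour 3.0 ± 1.0 µm and
rest length 1.7 ± 0.8 µm so that measured stiffening lengths average
≈ 2.5 µm with a spread of order 1 µm. Chromosome-to-chromosome stiffness
variability enters as a lognormal factor (`K0_scatter`); populations can
alternatively be pinned to a compliance target at 200 pN (contour rescale,
used for the 6 vs 15 nm/pN contrast). Comparison-population experiments
are generated at 0.2 µm/s and 50 Hz (4 nm steps), which leaves the
compliance readout unchanged while keeping 100-replicate power studies
fast. Every generated curve carries a ground-truth sidecar (analytic K0,
assembly F_c, contour, rest length, injected ruptures).

What the generator does *not* emulate: trap-series compliance on pulling
curves (distance is chromosome extension; an optional trap stiffness adds
the bead offset on oscillation traces), hysteresis and retraction, force-
dependent remodelling, imaging channels, and attachment geometry. Passing
tests therefore demonstrate correctness of the analysis chain under the
declared noise model, not robustness to every instrumental artefact in
real recordings.

## Numerical choices

- WLC inversion: closed-form cubic + 3 Newton steps; round-trip relative
  error < 1e-12 (contract: 1e-9).
- Assembly force-at-distance: interpolation on a 300-point log force grid
  followed by 4 Newton steps using the analytic series compliance.
- Onset threshold carries a 1e-9 relative epsilon so float jitter on an
  exactly linear curve does not register as an onset; a curve with no
  crossing returns a no-onset flag, not an error.
- KDE bandwidth: Silverman. Piecewise-kink refinement tolerance 1e-10 in
  ln F. Ensemble summaries use Welford accumulation.
- Default ensemble force grid: 200 log-spaced points over 0.1–1000 pN.
- Exact rank-sum null for group sizes ≤ 25, normal approximation beyond.

## Known limitations

- The 20–200 pN window exponent of the truncated power-law ensemble
  exceeds β + α − 1 by ~0.07 at the published parameter set (cutoff bias,
  see above); wider cutoffs recover the asymptotic law.
- Per-curve K0 recovery degrades for assemblies whose critical force is
  near the smallest observable force; the population median is the robust
  statistic.
- The plateau estimator assumes the analysis window lies inside the linear
  regime; single elements with small f_c need an adjusted window.
- Curves are analysed as extension (pull) segments only; retraction and
  energy dissipation are out of scope.
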
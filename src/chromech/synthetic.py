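"""Synthetic optical-tweezers data with known ground truth.

Generates force-extension curves of hierarchical-WLC chromosomes and
oscillation traces with the statistical structure the analysis pipeline
assumes — linear regime below a few tens of pN, power-law stiffening above
a critical force, stiffening lengths of order 2.5 µm, forces up to 300 pN,
broad chromosome-to-chromosome stiffness variability, optional abrupt
rupture-like force drops, measurement noise and slow drift.  Every
generated dataset is accompanied by a ground-truth record so recovery can
be quantified.

All randomness flows through integer seeds; identical seeds give
byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .distributions import CriticalForceDistribution
from .hwlc import HWLCAssembly, build_assembly
from .curves import (
    ForceExtensionCurve,
    StiffeningModel,
)
from .polymer import WLCElement, FJCElement
from .rheology import ComplexStiffness, OscillationTrace

__all__ = [
    "PopulationSpec",
    "NoiseSpec",
    "GroundTruth",
    "gen_chromosome",
    "gen_force_extension",
    "gen_population_curve",
    "gen_oscillation",
    "gen_comparison_populations",
    "gen_polymer_curve",
    "noiseless_features",
    "calibrate_beta_for_gamma",
    "u2os_like_spec",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement imperfections added to generated data.

    force_noise_sd : pN, i.i.d. Gaussian noise on the force channel
        (the 0.5 pN default is a declared fixture choice; the experiments
        report no explicit noise floor).
    sampling_rate : Hz.
    pulling_velocity : µm/s (kept at or below the 0.2 µm/s used
        experimentally).
    rupture_rate : expected number of rupture events per curve (Poisson).
    rupture_drop : pN, size of each injected force drop.
    drift_slope : pN/s linear drift on the force channel of oscillation
        traces.
    position_noise_sd : µm, Gaussian noise on position channels of
        oscillation traces.
    """

    force_noise_sd: float = 0.5
    sampling_rate: float = 100.0
    pulling_velocity: float = 0.1
    rupture_rate: float = 0.0
    rupture_drop: float = 15.0
    drift_slope: float = 0.0
    position_noise_sd: float = 0.005

    def __post_init__(self):
        if self.pulling_velocity <= 0:
            raise ValueError("pulling_velocity must be > 0")
        for name in (
            "force_noise_sd",
            "sampling_rate",
            "rupture_rate",
            "rupture_drop",
            "position_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """A population of synthetic chromosomes.

    Contour lengths are drawn from a truncated normal (L_mean, L_sd, lower
    bound 0.5 µm); critical forces come from ``distribution``; ``K0_scatter``
    is the relative spread of an extra lognormal stiffness factor across
    chromosomes (emulating the broad observed variability in initial
    stiffness).  When ``compliance_200_target`` (nm/pN) is set, each
    chromosome's contour is rescaled so its noiseless compliance at 200 pN
    equals the target times a lognormal factor of relative sd K0_scatter.
    """

    distribution: CriticalForceDistribution
    N: int = 30
    L_mean: float = 3.0
    L_sd: float = 1.0
    alpha: float = 1.0
    K0_scatter: float = 0.2
    n_chromosomes: int = 1
    seed: int = 0
    compliance_200_target: float | None = None
    rest_length_mean: float = 0.0
    rest_length_sd: float = 0.0

    def __post_init__(self):
        if self.L_mean <= 0 or self.L_sd < 0:
            raise ValueError("need L_mean > 0 and L_sd >= 0")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.rest_length_mean < 0 or self.rest_length_sd < 0:
            raise ValueError("rest length parameters must be >= 0")


def u2os_like_spec(n_chromosomes: int = 44, seed: int = 0) -> PopulationSpec:
    """Population emulating the wild-type measurements.

    Power-law critical forces (β = 0.86 on [5, 500] pN), N = 30 sub-chains,
    contour lengths 3.0 ± 1.0 µm, native rest lengths 1.7 ± 0.8 µm.  The
    bead-bead distance is the rest length plus the HWLC extension; with
    these values the measured stiffening length (distance at stiffening
    onset) has population mean ≈ 2.5 µm with a spread of order 1 µm.
    """
    return PopulationSpec(
        distribution=CriticalForceDistribution.power_law(0.86),
        N=30,
        L_mean=3.0,
        L_sd=1.0,
        alpha=1.0,
        K0_scatter=0.2,
        n_chromosomes=n_chromosomes,
        seed=seed,
        rest_length_mean=1.7,
        rest_length_sd=0.8,
    )


@dataclass
class GroundTruth:
    """Sidecar record of the generator's true parameters for one curve."""

    K0: float
    Fc: float
    L: float
    N: int
    alpha: float
    rest_length: float = 0.0
    stiffening_length: float = float("nan")
    gamma_predicted: float = float("nan")
    compliance_200: float = float("nan")
    n_ruptures: int = 0
    rupture_distances: list = field(default_factory=list)
    seed: int | None = None
    index: int | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _chromosome_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def gen_chromosome(spec: PopulationSpec, index: int) -> HWLCAssembly:
    """Instantiate chromosome ``index`` of the population; deterministic.

    The same (spec.seed, index) pair always yields the identical assembly.
    """
    rng = _chromosome_rng(spec.seed, index)
    if spec.L_sd > 0:
        L = float(max(0.5, rng.normal(spec.L_mean, spec.L_sd)))
    else:
        L = spec.L_mean
    assembly = build_assembly(spec.distribution, spec.N, L, spec.alpha, seed=rng)
    scale = 1.0
    if spec.compliance_200_target is not None:
        # contour rescale: compliance at fixed force is proportional to ell
        current = 1000.0 * assembly.compliance(200.0)  # nm/pN
        target = spec.compliance_200_target
        if spec.K0_scatter > 0:
            target = target * float(
                np.exp(rng.normal(0.0, np.log1p(spec.K0_scatter)))
            )
        scale = target / current
    elif spec.K0_scatter > 0:
        scale = float(np.exp(rng.normal(0.0, np.log1p(spec.K0_scatter))))
    if scale != 1.0:
        assembly = HWLCAssembly(
            f_c=assembly.f_c, ell=assembly.ell * scale, alpha=spec.alpha
        )
    return assembly


def gen_force_extension(
    assembly: HWLCAssembly,
    noise: NoiseSpec | None = None,
    f_max: float = 300.0,
    seed: int = 0,
    cycle_label: str = "extension_3",
    rest_length: float = 0.0,
):
    """Simulate one constant-velocity pulling curve.

    The recorded bead-bead distance is ``rest_length`` (the chromosome's
    native zero-force length) plus the HWLC extension, sampled at
    ``pulling_velocity / sampling_rate`` increments up to the extension at
    ``f_max``; the noiseless force is the exact
    inverse of the assembly's force-extension relation (interpolation
    initialisation plus Newton polish on the analytic series response),
    then rupture drops (Poisson count, permanent contour-length increment
    giving an abrupt drop with gradual force recovery) and i.i.d. Gaussian
    force noise are added.

    Returns
    -------
    (curve, truth) : (ForceExtensionCurve, GroundTruth)
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    d_max = assembly.extension(f_max)
    step = noise.pulling_velocity / noise.sampling_rate
    d = np.arange(0.0, d_max, step)
    if d.size < 30:
        raise ValueError(
            "fewer than 30 samples; reduce pulling_velocity or raise sampling_rate"
        )
    force = assembly.force_at_extension(d, f_max=max(2 * f_max, 10.0))
    time = d / noise.pulling_velocity

    rupture_d: list[float] = []
    if noise.rupture_rate > 0:
        n_events = rng.poisson(noise.rupture_rate)
        if n_events:
            # place events where the force comfortably exceeds the drop, so
            # each produces a genuine force decline rather than clipping at 0
            eligible = np.flatnonzero(
                (force >= 2.0 * noise.rupture_drop) & (force <= 0.9 * f_max)
            )
            if eligible.size == 0:
                n_events = 0
            locs = np.sort(rng.choice(d[eligible], size=n_events)) if n_events else []
            for d0 in locs:
                j0 = int(np.searchsorted(d, d0))
                if j0 >= d.size - 2 or j0 < 2:
                    continue
                k_local = assembly.stiffness(force[j0])
                shift = noise.rupture_drop / k_local
                # permanent contour gain: curve continues as if shifted right
                force[j0:] = np.interp(
                    d[j0:] - shift, d, force, left=0.0, right=force[-1]
                )
                rupture_d.append(float(rest_length + d[j0]))

    if noise.force_noise_sd > 0:
        force = force + rng.normal(0.0, noise.force_noise_sd, force.size)
    keep = force <= f_max
    curve = ForceExtensionCurve(
        distance=rest_length + d[keep],
        force=force[keep],
        time=time[keep],
        cycle_label=cycle_label,
    )
    truth = GroundTruth(
        K0=assembly.k0,
        Fc=assembly.fc_assembly,
        L=assembly.L,
        N=assembly.N,
        alpha=assembly.alpha,
        rest_length=rest_length,
        compliance_200=(
            1000.0 * assembly.compliance(200.0) if f_max >= 200.0 else float("nan")
        ),
        n_ruptures=len(rupture_d),
        rupture_distances=rupture_d,
        seed=seed,
    )
    return curve, truth


def gen_population_curve(
    spec: PopulationSpec,
    index: int,
    noise: NoiseSpec | None = None,
    f_max: float = 300.0,
    cycle_label: str = "extension_3",
):
    """Curve ``index`` of a population: assembly, rest length, noise draw.

    Deterministic per (spec.seed, index).  Returns (curve, truth).
    """
    asm = gen_chromosome(spec, index)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(index), 1]))
    rest = 0.0
    if spec.rest_length_mean > 0:
        rest = float(max(0.0, rng.normal(spec.rest_length_mean, spec.rest_length_sd)))
    curve, truth = gen_force_extension(
        asm,
        noise,
        f_max=f_max,
        seed=int(rng.integers(0, 2**31 - 1)),
        cycle_label=cycle_label,
        rest_length=rest,
    )
    truth.index = index
    truth.seed = spec.seed
    return curve, truth


def noiseless_features(
    assembly: HWLCAssembly,
    noise: NoiseSpec | None = None,
    f_max: float = 300.0,
    rest_length: float = 0.0,
    **model_kwargs,
):
    """Run the analysis pipeline on the noise-free curve of an assembly.

    This defines the generator's self-consistent ground truth for
    measurement-level features (fitted K0/Fc/γ, stiffening length): what the
    pipeline itself returns in the absence of noise.
    """
    base = noise or NoiseSpec()
    quiet = replace(base, force_noise_sd=0.0, rupture_rate=0.0)
    curve, _ = gen_force_extension(
        assembly, quiet, f_max=f_max, seed=0, rest_length=rest_length
    )
    return StiffeningModel(curve, **model_kwargs).fit().features


def gen_polymer_curve(kind: str, f_c: float, ell: float, force_grid) -> ForceExtensionCurve:
    """Noiseless force-extension curve of a single WLC or FJC element.

    Samples the closed-form extension at the given forces (use a log-spaced
    grid to cover several decades) — the entry point for exercising the
    curve pipeline on the classical homogeneous polymer limits.
    """
    f = np.asarray(force_grid, dtype=float)
    if kind == "wlc":
        x = WLCElement(f_c, ell).extension_at_force(f)
    elif kind == "fjc":
        x = FJCElement(f_c, ell).extension_at_force(f)
    else:
        raise ValueError(f"unknown polymer kind {kind!r}")
    return ForceExtensionCurve(distance=x, force=f, cycle_label=f"{kind}_analytic")


def gen_oscillation(
    k_true: ComplexStiffness | complex,
    pre_tension: float,
    frequency: float,
    n_periods: int = 10,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    samples_per_period: int = 200,
    drive_amplitude: float = 0.2,
    trap_stiffness: float | None = None,
) -> OscillationTrace:
    """Simulate one small-amplitude oscillation trace.

    The distance channel oscillates with amplitude ``drive_amplitude``
    (default 0.2 µm trap displacement); the force responds with amplitude
    |k|·A_d and leads by arg(k).  Gaussian noise goes on both channels and
    a linear drift (``noise.drift_slope`` pN/s) on the force.  By default
    the trap series compliance is not simulated (trap position equals the
    bead trajectory); pass ``trap_stiffness`` (pN/µm) to displace the trap
    by F/k_trap from the bead, which makes force-based bead reconstruction
    meaningful.  The true complex stiffness is recoverable from the
    returned trace's attributes.
    """
    if not (2e-3 <= frequency <= 100.0):
        warnings.warn(
            f"drive frequency {frequency} Hz outside the calibrated "
            "2 mHz-100 Hz band",
            stacklevel=2,
        )
    if n_periods < 2:
        raise ValueError("n_periods must be >= 2")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    k = k_true.k if isinstance(k_true, ComplexStiffness) else complex(k_true)
    n = int(n_periods * samples_per_period)
    t = np.arange(n) / (frequency * samples_per_period)
    w = 2.0 * np.pi * frequency * t
    a_d = drive_amplitude
    dist = a_d * np.sin(w)
    force = pre_tension + abs(k) * a_d * np.sin(w + np.angle(k))
    if trap_stiffness is not None:
        trap = dist + force / trap_stiffness
    else:
        trap = dist.copy()  # trap-series compliance not simulated by default
    if noise.position_noise_sd > 0:
        dist = dist + rng.normal(0.0, noise.position_noise_sd, n)
    if noise.force_noise_sd > 0:
        force = force + rng.normal(0.0, noise.force_noise_sd, n)
    if noise.drift_slope:
        force = force + noise.drift_slope * t
    return OscillationTrace(
        time=t,
        force=force,
        trap_position=trap,
        bead_position=dist,
        drive_frequency=frequency,
        pre_tension=pre_tension,
    )


def calibrate_beta_for_gamma(
    gamma_target: float,
    f_min: float = 5.0,
    f_max: float = 500.0,
    N: int = 30,
    L: float = 3.0,
    window: tuple[float, float] = (20.0, 200.0),
    n_configs: int = 100,
    seed: int = 0,
) -> float:
    """Power-law exponent β whose *measured* window slope equals a γ target.

    With finite critical-force cutoffs the log-log slope measured over a
    fixed force window differs from the asymptotic law γ = β + α − 1 (the
    slope drifts toward the single-WLC 3/2 as the window approaches f_max).
    This solves, by bisection on β, for the distribution whose noiseless
    per-configuration mean slope over ``window`` equals ``gamma_target``;
    use a larger ``f_max`` for flat targets (γ ≲ 0.5 is unreachable with
    the default 500 pN cutoff).
    """
    from .curves import StiffnessCurve, fit_stiffening_exponent
    from .polymer import _wlc_reduced_extension

    grid = np.geomspace(window[0] / 2.0, window[1] * 2.0, 60)

    def mean_slope(beta: float) -> float:
        dist = CriticalForceDistribution.power_law(beta, f_min, f_max)
        rng = np.random.default_rng(seed)
        f_c = dist.ppf(rng.random((n_configs, N)))
        ell = L / N
        u = 1.0 - _wlc_reduced_extension(grid[None, :, None] / f_c[:, None, :])
        k = (f_c[:, None, :] / ell) * (0.5 / u**3 + 1.0)
        K = 1.0 / (1.0 / k).sum(axis=-1)
        slopes = [
            fit_stiffening_exponent(StiffnessCurve(force=grid, stiffness=row), *window)
            for row in K
        ]
        return float(np.mean(slopes))

    lo, hi = 0.0, 3.0
    if not mean_slope(lo) <= gamma_target <= mean_slope(hi):
        raise ValueError(
            f"gamma target {gamma_target} unreachable for cutoffs "
            f"[{f_min}, {f_max}] pN; widen f_max for flat targets"
        )
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if mean_slope(mid) < gamma_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_comparison_populations(
    spec_a: PopulationSpec,
    spec_b: PopulationSpec,
    n_each: int,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    f_max: float = 300.0,
):
    """Two labelled curve populations for a group comparison.

    Returns ``(curves_a, curves_b, manifest)`` where each curves list holds
    (ForceExtensionCurve, GroundTruth) pairs and the manifest is a tidy
    DataFrame with one row per curve (label, index, true parameters).
    """
    import pandas as pd

    if n_each < 5:
        raise ValueError("n_each must be >= 5")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    out = []
    rows = []
    for label, spec in (("a", spec_a), ("b", spec_b)):
        pop_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(spec, n_chromosomes=n_each, seed=pop_seed)
        curves = []
        for i in range(n_each):
            curve, truth = gen_population_curve(spec, i, noise, f_max=f_max)
            curves.append((curve, truth))
            rows.append(
                {
                    "group": label,
                    "index": i,
                    "true_K0": truth.K0,
                    "true_Fc": truth.Fc,
                    "true_L": truth.L,
                    "true_compliance_200": truth.compliance_200,
                }
            )
        out.append(curves)
    manifest = pd.DataFrame(rows)
    return out[0], out[1], manifest
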
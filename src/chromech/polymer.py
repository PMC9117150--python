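"""Single-element force-extension laws: worm-like and freely jointed chains.

Package-wide unit convention: forces in piconewton (pN), lengths in
micrometre (µm), stiffnesses in pN/µm; compliances are reported in nm/pN
(``1000 / K``).

Each element is parametrized by a *critical force* ``f_c`` — the force scale
at which it crosses over from its linear low-force regime into strain
stiffening — and a contour length ``ell``.  There is no explicit temperature
parameter: ``f_c`` absorbs the thermal force scale (k_B·T over persistence
length for a literal polymer), which is the natural parametrization for
effective structural elements of a chromosome rather than for bare DNA.

The worm-like chain uses the standard interpolation force law

    F(x) = f_c · [ 1 / (4 (1 − x/ell)²) − 1/4 + x/ell ],

whose initial stiffness is k0 = (3/2)·f_c/ell and whose differential
stiffness grows asymptotically as F^(3/2).  The freely jointed chain uses
the Langevin law x(F) = ell·[coth(F/f_c) − f_c/F], with initial stiffness
3·f_c/ell and asymptotic stiffness growth F².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WLCElement",
    "FJCElement",
    "wlc_force",
    "wlc_extension_at_force",
    "wlc_stiffness",
    "fjc_extension_at_force",
    "fjc_stiffness",
    "gamma_from_delta",
]


# --------------------------------------------------------------------------
# Reduced (dimensionless) WLC law and its inversion
# --------------------------------------------------------------------------

def _wlc_reduced_force(t: np.ndarray) -> np.ndarray:
    """Reduced WLC force φ = F/f_c as a function of t = x/ell ∈ [0, 1)."""
    return 0.25 / (1.0 - t) ** 2 - 0.25 + t


def _wlc_reduced_extension(phi):
    """Invert the reduced WLC interpolation law: t(φ) with φ = F/f_c ≥ 0.

    Substituting u = 1 − t turns φ = 1/(4u²) − 1/4 + (1 − u) into the cubic

        u³ + a·u² − 1/4 = 0,   a = φ − 3/4,

    which has exactly one positive root for every φ ≥ 0.  The root is taken
    in closed form (Cardano for one real root, trigonometric branch for
    three) and polished with three Newton steps, leaving a relative error at
    machine precision — far below the 1e-9 tolerance this operation
    guarantees.  Fully vectorised.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("force must be >= 0 (got a negative value)")
    scalar = phi.ndim == 0
    phi = np.atleast_1d(phi)

    a = (phi - 0.75).ravel()
    p = -(a * a) / 3.0
    q = 2.0 * a**3 / 27.0 - 0.25
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    u = np.empty_like(a)

    # Cardano branch (one real root)
    card = disc >= 0.0
    if np.any(card):
        qc, ac = q[card], a[card]
        sq = np.sqrt(disc[card])
        u[card] = np.cbrt(-qc / 2.0 + sq) + np.cbrt(-qc / 2.0 - sq) - ac / 3.0

    # Trigonometric branch (three real roots; the unique positive one is the
    # largest).  p < 0 whenever disc < 0.
    trig = ~card
    if np.any(trig):
        pt, qt, at = p[trig], q[trig], a[trig]
        m = 2.0 * np.sqrt(-pt / 3.0)
        theta = np.arccos(np.clip(3.0 * qt / (pt * m), -1.0, 1.0))
        u[trig] = np.maximum.reduce(
            [m * np.cos((theta - 2.0 * np.pi * k) / 3.0) - at / 3.0 for k in (0, 1, 2)]
        )

    u = np.clip(u, 1e-300, 1.0)
    # Newton polish: g(u) = u³ + a·u² − 1/4, g'(u) = u(3u + 2a) > 0 at root
    for _ in range(3):
        g = u * u * (u + a) - 0.25
        gp = u * (3.0 * u + 2.0 * a)
        u = np.clip(u - g / gp, 1e-300, 1.0)

    t = (1.0 - u).reshape(phi.shape)
    return (t[0] if scalar else t)


def _fjc_langevin(y):
    """Langevin function L(y) = coth(y) − 1/y, series-protected near 0."""
    y = np.asarray(y, dtype=float)
    yc = np.where(y > 1e-3, y, 1.0)
    exact = 1.0 / np.tanh(yc) - 1.0 / yc
    series = y / 3.0 - y**3 / 45.0 + 2.0 * y**5 / 945.0
    return np.where(y > 1e-3, exact, series)


def _fjc_reduced_compliance(y):
    """d(x/ell)/dy = 1/y² − 1/sinh²(y), series-protected near 0."""
    y = np.asarray(y, dtype=float)
    ylo = np.maximum(y, 0.05)  # keep 1/y² finite off the series branch
    ysh = np.clip(y, 0.05, 350.0)  # sinh overflows beyond ~710
    exact = 1.0 / ylo**2 - np.where(y > 350.0, 0.0, 1.0 / np.sinh(ysh) ** 2)
    series = 1.0 / 3.0 - y**2 / 15.0 + 2.0 * y**4 / 189.0 - y**6 / 675.0
    return np.where(y > 0.05, exact, series)


# --------------------------------------------------------------------------
# Elements
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WLCElement:
    """One effective worm-like-chain sub-unit.

    Parameters
    ----------
    f_c : float
        Critical force in pN; the force scale of the crossover from the
        linear regime into strain stiffening.  Must be > 0.
    ell : float
        Contour length in µm.  Must be > 0.
    """

    f_c: float
    ell: float

    def __post_init__(self):
        if not self.f_c > 0:
            raise ValueError(f"critical force f_c must be > 0, got {self.f_c}")
        if not self.ell > 0:
            raise ValueError(f"contour length ell must be > 0, got {self.ell}")

    @property
    def k0(self) -> float:
        """Initial (zero-force) stiffness, (3/2)·f_c/ell, in pN/µm."""
        return 1.5 * self.f_c / self.ell

    def force(self, extension):
        """Force (pN) at the given extension (µm); requires 0 ≤ x < ell."""
        x = np.asarray(extension, dtype=float)
        if np.any(x < 0):
            raise ValueError("extension must be >= 0")
        if np.any(x >= self.ell):
            raise ValueError(
                f"extension must be < contour length ell = {self.ell} µm"
            )
        return self.f_c * _wlc_reduced_force(x / self.ell)

    def extension_at_force(self, force):
        """Unique extension x ∈ [0, ell) (µm) with F(x) = force (pN)."""
        return self.ell * _wlc_reduced_extension(np.asarray(force, float) / self.f_c)

    def stiffness(self, force):
        """Differential stiffness dF/dx (pN/µm) at the given force.

        Evaluated analytically at the inverted extension:
        K = (f_c/ell)·(1/(2u³) + 1) with u = 1 − x/ell.  Equals k0 at F = 0
        and grows as F^(3/2) at high force.
        """
        t = _wlc_reduced_extension(np.asarray(force, float) / self.f_c)
        u = 1.0 - t
        return (self.f_c / self.ell) * (0.5 / u**3 + 1.0)


@dataclass(frozen=True)
class FJCElement:
    """One freely-jointed-chain element (Langevin elasticity).

    Same (f_c, ell) parametrization as :class:`WLCElement`; the initial
    stiffness is 3·f_c/ell and the high-force stiffening exponent is 2.
    """

    f_c: float
    ell: float

    def __post_init__(self):
        if not self.f_c > 0:
            raise ValueError(f"critical force f_c must be > 0, got {self.f_c}")
        if not self.ell > 0:
            raise ValueError(f"contour length ell must be > 0, got {self.ell}")

    @property
    def k0(self) -> float:
        """Initial stiffness 3·f_c/ell in pN/µm."""
        return 3.0 * self.f_c / self.ell

    def extension_at_force(self, force):
        """Langevin extension x = ell·[coth(F/f_c) − f_c/F] in µm."""
        f = np.asarray(force, dtype=float)
        if np.any(f < 0):
            raise ValueError("force must be >= 0")
        return self.ell * _fjc_langevin(f / self.f_c)

    def stiffness(self, force):
        """Differential stiffness dF/dx (pN/µm); equals 3·f_c/ell at F = 0."""
        f = np.asarray(force, dtype=float)
        if np.any(f < 0):
            raise ValueError("force must be >= 0")
        return (self.f_c / self.ell) / _fjc_reduced_compliance(f / self.f_c)


# --------------------------------------------------------------------------
# Functional interface (thin wrappers over the element methods)
# --------------------------------------------------------------------------

def wlc_force(element: WLCElement, extension):
    """Force (pN) of a WLC element at the given extension (µm)."""
    return element.force(extension)


def wlc_extension_at_force(element: WLCElement, force):
    """Extension (µm) of a WLC element at the given force (pN)."""
    return element.extension_at_force(force)


def wlc_stiffness(element: WLCElement, force):
    """Differential stiffness (pN/µm) of a WLC element at the given force."""
    return element.stiffness(force)


def fjc_extension_at_force(element: FJCElement, force):
    """Extension (µm) of an FJC element at the given force (pN)."""
    return element.extension_at_force(force)


def fjc_stiffness(element: FJCElement, force):
    """Differential stiffness (pN/µm) of an FJC element at the given force."""
    return element.stiffness(force)


def gamma_from_delta(delta):
    """Stiffening exponent γ = (δ + 1)/δ of a finite-extensibility divergence.

    A homogeneous polymer whose force diverges near full extension as
    F ~ (d − d_c)^(−δ) stiffens with K ~ F^γ, γ = (δ + 1)/δ — strictly
    larger than 1 for any finite δ > 0 (δ = 2 gives the WLC value 3/2,
    δ = 1 the FJC value 2).
    """
    d = np.asarray(delta, dtype=float)
    if np.any(d <= 0):
        raise ValueError("delta must be > 0")
    out = (d + 1.0) / d
    return float(out) if out.ndim == 0 else out
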
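"""Truncated critical-force distributions for hierarchical assemblies.

Two families are supported, both normalised on a finite support
[f_min, f_max] (pN):

* ``power_law``:   P(f_c) ∝ f_c^(−β)   with β ≥ 0,
* ``exponential``: P(f_c) ∝ exp(−f_c / f_c*) with f_c* > 0.

Sampling is by inverse-CDF transform of uniform variates, so a fixed seed
reproduces draws exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CriticalForceDistribution", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Invalid distribution or model configuration."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CriticalForceDistribution:
    """Truncated power-law or exponential distribution of element critical forces.

    Use the :meth:`power_law` / :meth:`exponential` constructors; the default
    cutoffs [5, 500] pN place assembly critical forces in the experimentally
    observed 10–50 pN range while spanning the 20–200 pN power-law fitting
    window.
    """

    kind: str
    f_min: float = 5.0
    f_max: float = 500.0
    beta: float | None = None
    f_c_star: float | None = None

    def __post_init__(self):
        if self.kind not in ("power_law", "exponential"):
            raise ConfigurationError(f"unknown distribution kind {self.kind!r}")
        if not (0 < self.f_min < self.f_max):
            raise ConfigurationError(
                f"need 0 < f_min < f_max, got [{self.f_min}, {self.f_max}]"
            )
        if self.kind == "power_law":
            if self.beta is None or self.beta < 0:
                raise ConfigurationError("power_law requires beta >= 0")
        else:
            if self.f_c_star is None or self.f_c_star <= 0:
                raise ConfigurationError("exponential requires f_c_star > 0")

    # -- constructors ------------------------------------------------------

    @classmethod
    def power_law(cls, beta: float, f_min: float = 5.0, f_max: float = 500.0):
        """P(f_c) ∝ f_c^(−beta) truncated to [f_min, f_max]."""
        return cls(kind="power_law", f_min=f_min, f_max=f_max, beta=beta)

    @classmethod
    def exponential(cls, f_c_star: float, f_min: float = 5.0, f_max: float = 500.0):
        """P(f_c) ∝ exp(−f_c/f_c_star) truncated to [f_min, f_max]."""
        return cls(kind="exponential", f_min=f_min, f_max=f_max, f_c_star=f_c_star)

    # -- analytic forms ----------------------------------------------------

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x >= self.f_min) & (x <= self.f_max)
        xc = np.clip(x, self.f_min, self.f_max)
        if self.kind == "power_law":
            b = self.beta
            if abs(b - 1.0) < 1e-12:
                norm = np.log(self.f_max / self.f_min)
            else:
                norm = (self.f_max ** (1 - b) - self.f_min ** (1 - b)) / (1 - b)
            dens = xc ** (-b) / norm
        else:
            s = self.f_c_star
            norm = s * (np.exp(-self.f_min / s) - np.exp(-self.f_max / s))
            dens = np.exp(-xc / s) / norm
        out = np.where(inside, dens, 0.0)
        return float(out) if out.ndim == 0 else out

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.f_min, self.f_max)
        if self.kind == "power_law":
            b = self.beta
            if abs(b - 1.0) < 1e-12:
                c = np.log(xc / self.f_min) / np.log(self.f_max / self.f_min)
            else:
                c = (xc ** (1 - b) - self.f_min ** (1 - b)) / (
                    self.f_max ** (1 - b) - self.f_min ** (1 - b)
                )
        else:
            s = self.f_c_star
            c = (np.exp(-self.f_min / s) - np.exp(-xc / s)) / (
                np.exp(-self.f_min / s) - np.exp(-self.f_max / s)
            )
        c = np.clip(c, 0.0, 1.0)
        return float(c) if c.ndim == 0 else c

    def ppf(self, u):
        """Inverse CDF (quantile function) for u ∈ [0, 1]."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("quantile argument must lie in [0, 1]")
        if self.kind == "power_law":
            b = self.beta
            if abs(b - 1.0) < 1e-12:
                x = self.f_min * (self.f_max / self.f_min) ** u
            else:
                lo = self.f_min ** (1 - b)
                hi = self.f_max ** (1 - b)
                x = ((1 - u) * lo + u * hi) ** (1.0 / (1 - b))
        else:
            s = self.f_c_star
            a = np.exp(-self.f_min / s)
            bb = np.exp(-self.f_max / s)
            x = -s * np.log(a - u * (a - bb))
        x = np.clip(x, self.f_min, self.f_max)
        return float(x) if x.ndim == 0 else x

    def mean(self) -> float:
        """Closed-form mean of the truncated distribution."""
        if self.kind == "power_law":
            b = self.beta
            lo, hi = self.f_min, self.f_max
            if abs(b - 1.0) < 1e-12:
                return (hi - lo) / np.log(hi / lo)
            norm = (hi ** (1 - b) - lo ** (1 - b)) / (1 - b)
            if abs(b - 2.0) < 1e-12:
                return np.log(hi / lo) / norm
            return (hi ** (2 - b) - lo ** (2 - b)) / ((2 - b) * norm)
        s = self.f_c_star
        a = np.exp(-self.f_min / s)
        bb = np.exp(-self.f_max / s)
        return s + (self.f_min * a - self.f_max * bb) / (a - bb)

    # -- sampling ----------------------------------------------------------

    def sample(self, n: int, seed) -> np.ndarray:
        """Draw ``n`` i.i.d. critical forces by inverse-CDF sampling.

        ``seed`` may be an integer or a ``numpy.random.Generator``;
        identical integer seeds reproduce draws exactly.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = _as_rng(seed)
        return self.ppf(rng.random(int(n)))
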
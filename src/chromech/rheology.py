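"""Oscillatory microrheology: complex stiffness from small oscillations.

A chromosome held at a fixed pre-tension F is driven with a small sinusoidal
distance oscillation at frequency ω.  Detrended force and distance channels
are each fitted with a fixed-frequency sinusoid A·sin(2πft + φ) + offset
(a linear least-squares problem in a sin/cos basis); the complex stiffness
is then

    k = (A_F / A_d) · exp(i (φ_F − φ_d)),

whose real part K' (storage modulus) measures elastically stored energy and
imaginary part K'' (loss modulus) the viscously dissipated energy per
cycle.  Sign convention: force leading distance (φ_F > φ_d) gives K'' > 0,
as required for a passive material.

Above 1 Hz, camera-based bead tracking is frame-rate limited; there the
bead position is reconstructed from the trap position and the measured
force (bead = trap − F/k_trap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OscillationTrace",
    "ComplexStiffness",
    "OscillationModel",
    "ComplexStiffnessResults",
    "reconstruct_bead_position",
    "synchronize",
    "fit_oscillation",
    "complex_stiffness",
    "frequency_sweep",
    "BEAD_TRACKING_MAX_HZ",
]

#: Above this drive frequency the bead position is reconstructed from force
#: and trap position instead of camera tracking.
BEAD_TRACKING_MAX_HZ = 1.0


@dataclass
class OscillationTrace:
    """One oscillation recording around a pre-tension.

    Sampling must be uniform (timestamp jitter below 1 % of the mean step)
    and at least two full drive periods must be recorded (five or more are
    recommended and generated by default).
    """

    time: np.ndarray
    force: np.ndarray
    trap_position: np.ndarray
    drive_frequency: float
    pre_tension: float
    bead_position: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.force, dtype=float)
        x = np.asarray(self.trap_position, dtype=float)
        if not (t.shape == f.shape == x.shape) or t.ndim != 1:
            raise ValueError("time, force and trap_position must match in length")
        dt = np.diff(t)
        if t.size < 4 or np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - dt.mean())) > 0.01 * dt.mean():
            raise ValueError("sampling jitter exceeds 1% of the mean time step")
        if self.drive_frequency <= 0:
            raise ValueError("drive_frequency must be > 0")
        n_periods = (t[-1] - t[0]) * self.drive_frequency
        if n_periods < 2:
            raise ValueError(
                f"only {n_periods:.2f} drive periods recorded; need at least 2"
            )
        self.time, self.force, self.trap_position = t, f, x
        if self.bead_position is not None:
            b = np.asarray(self.bead_position, dtype=float)
            if b.shape != t.shape:
                raise ValueError("bead_position length must match time")
            self.bead_position = b

    @property
    def n_periods(self) -> float:
        return float((self.time[-1] - self.time[0]) * self.drive_frequency)


@dataclass
class ComplexStiffness:
    """Storage/loss moduli with the underlying amplitudes and phases."""

    storage: float  # K' (pN/µm)
    loss: float  # K'' (pN/µm)
    frequency: float  # Hz
    pre_tension: float  # pN
    amplitude_force: float = float("nan")  # A_F (pN)
    amplitude_distance: float = float("nan")  # A_d (µm)
    phase_force: float = float("nan")  # φ_F (rad)
    phase_distance: float = float("nan")  # φ_d (rad)

    @property
    def k(self) -> complex:
        return complex(self.storage, self.loss)

    @property
    def magnitude(self) -> float:
        """|k| = A_F / A_d (pN/µm)."""
        return float(np.hypot(self.storage, self.loss))

    @property
    def phase_lag(self) -> float:
        """φ_F − φ_d (rad), wrapped to (−π, π]."""
        return float(np.angle(self.k))


def reconstruct_bead_position(trap_position, force, trap_stiffness: float):
    """Bead position from trap position and force: bead = trap − F/k_trap.

    The optical restoring force is positive toward the trap center, so a
    positive measured force means the bead is displaced by F/k_trap away
    from it.
    """
    if not trap_stiffness > 0:
        raise ValueError("trap_stiffness must be > 0")
    return np.asarray(trap_position, float) - np.asarray(force, float) / trap_stiffness


def synchronize(series_a, series_b) -> int:
    """Lag (samples) maximising the normalized cross-correlation.

    A positive lag means ``series_b`` is delayed relative to ``series_a``;
    shifting ``series_b`` forward by the returned lag aligns the two.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    a = a - a.mean()
    b = b - b.mean()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("cannot synchronize a zero-variance series")
    corr = np.correlate(a, b, mode="full")
    return int((a.size - 1) - np.argmax(corr))


def fit_oscillation(series, drive_frequency: float, time):
    """Fixed-frequency sinusoid fit after linear detrending.

    The model A·sin(2πft + φ) + offset + slope·t with f fixed is linear in
    the (sin, cos, 1, t) basis, so a single least-squares solve detrends
    (first-order) and fits simultaneously and always converges on
    non-degenerate input; fitting the trend inside the basis rather than
    pre-subtracting it keeps a pure sinusoid's amplitude and phase exact.

    Returns
    -------
    (A, phi, offset) : tuple of float
        Amplitude (A ≥ 0), phase in (−π, π], and offset (series level at
        the mid-time of the window).
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(time, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("series and time must be 1-D of equal length")
    if (t[-1] - t[0]) * drive_frequency < 2:
        raise ValueError("need at least 2 drive periods for a sinusoid fit")
    w = 2.0 * np.pi * drive_frequency * t
    basis = np.column_stack([np.sin(w), np.cos(w), np.ones_like(t), t - t.mean()])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    a_sin, a_cos, offset, _slope = coef
    amp = float(np.hypot(a_sin, a_cos))
    phi = float(np.arctan2(a_cos, a_sin))  # a·sin + b·cos = A·sin(wt + phi)
    return amp, phi, float(offset)


def complex_stiffness(
    amplitude_force: float,
    phase_force: float,
    amplitude_distance: float,
    phase_distance: float,
    frequency: float = float("nan"),
    pre_tension: float = float("nan"),
) -> ComplexStiffness:
    """Complex stiffness k = (A_F/A_d)·exp(i(φ_F − φ_d)).

    K' = |k|·cos(Δφ) and K'' = |k|·sin(Δφ); the magnitude equals A_F/A_d
    identically.
    """
    if not amplitude_distance > 0:
        raise ValueError("no distance oscillation: A_d must be > 0")
    if not amplitude_force > 0:
        raise ValueError("A_F must be > 0")
    ratio = amplitude_force / amplitude_distance
    dphi = np.angle(np.exp(1j * (phase_force - phase_distance)))
    return ComplexStiffness(
        storage=float(ratio * np.cos(dphi)),
        loss=float(ratio * np.sin(dphi)),
        frequency=frequency,
        pre_tension=pre_tension,
        amplitude_force=float(amplitude_force),
        amplitude_distance=float(amplitude_distance),
        phase_force=float(phase_force),
        phase_distance=float(phase_distance),
    )


class OscillationModel:
    """Complex-stiffness analysis of one oscillation trace.

    Chooses the distance channel (tracked bead position at or below 1 Hz,
    force-based reconstruction above — requires ``trap_stiffness``), fits
    both channels with a fixed-frequency sinusoid and forms the complex
    stiffness.

    ``synchronize_channels`` applies the integer-sample cross-correlation
    alignment before fitting.  It is off by default: the viscoelastic phase
    lag of a nearly elastic material is a small fraction of one sample, so
    sample-quantized alignment of force against distance would absorb the
    very phase that the loss modulus measures.  Enable it only for traces
    whose force and distance channels come from independent clocks (e.g.
    camera-tracked bead positions), where the offset is many samples.
    """

    def __init__(
        self,
        trace: OscillationTrace,
        trap_stiffness: float | None = None,
        *,
        synchronize_channels: bool = False,
    ):
        self.trace = trace
        self.trap_stiffness = trap_stiffness
        self.synchronize_channels = synchronize_channels

    def _distance_channel(self) -> np.ndarray:
        tr = self.trace
        use_tracking = (
            tr.bead_position is not None
            and tr.drive_frequency <= BEAD_TRACKING_MAX_HZ
        )
        if use_tracking:
            return tr.bead_position
        if self.trap_stiffness is None:
            if tr.bead_position is not None:
                return tr.bead_position
            raise ValueError(
                "no bead tracking available; trap_stiffness is required to "
                "reconstruct the bead position from force and trap position"
            )
        return reconstruct_bead_position(tr.trap_position, tr.force, self.trap_stiffness)

    def fit(self) -> "ComplexStiffnessResults":
        tr = self.trace
        dist = self._distance_channel()
        lag = 0
        if self.synchronize_channels:
            try:
                lag = synchronize(tr.force, dist)
            except ValueError:
                lag = 0
        if lag != 0:
            # align by trimming; restrict to the overlapping window
            if lag > 0:
                f_al, d_al, t_al = tr.force[lag:], dist[:-lag], tr.time[lag:]
            else:
                f_al, d_al, t_al = tr.force[:lag], dist[-lag:], tr.time[:lag]
        else:
            f_al, d_al, t_al = tr.force, dist, tr.time
        a_f, phi_f, off_f = fit_oscillation(f_al, tr.drive_frequency, t_al)
        a_d, phi_d, _ = fit_oscillation(d_al, tr.drive_frequency, t_al)
        cs = complex_stiffness(
            a_f, phi_f, a_d, phi_d, tr.drive_frequency, tr.pre_tension
        )
        return ComplexStiffnessResults(
            model=self, stiffness=cs, lag_samples=lag, force_offset=off_f
        )


@dataclass
class ComplexStiffnessResults:
    """Fit output of :class:`OscillationModel`."""

    model: OscillationModel
    stiffness: ComplexStiffness
    lag_samples: int
    force_offset: float

    def summary(self) -> str:
        cs = self.stiffness
        lines = [
            "Oscillation analysis",
            "=" * 46,
            f"{'frequency [Hz]':<28}{cs.frequency:>18.4g}",
            f"{'pre-tension [pN]':<28}{cs.pre_tension:>18.4g}",
            f"{'storage K-prime [pN/um]':<28}{cs.storage:>18.4g}",
            f"{'loss K-doubleprime [pN/um]':<28}{cs.loss:>18.4g}",
            f"{'|k| = A_F/A_d [pN/um]':<28}{cs.magnitude:>18.4g}",
            f"{'phase lag [rad]':<28}{cs.phase_lag:>18.4g}",
            f"{'A_F [pN]':<28}{cs.amplitude_force:>18.4g}",
            f"{'A_d [um]':<28}{cs.amplitude_distance:>18.4g}",
            f"{'sync lag [samples]':<28}{self.lag_samples:>18d}",
        ]
        return "\n".join(lines)


def frequency_sweep(traces, trap_stiffness: float | None = None):
    """Analyse a list of traces; returns a tidy DataFrame keyed by frequency.

    Per-trace failures are recorded in the ``error`` column and do not stop
    the sweep.
    """
    import pandas as pd

    rows = []
    for i, tr in enumerate(traces):
        row = {
            "frequency_Hz": getattr(tr, "drive_frequency", float("nan")),
            "pretension_pN": getattr(tr, "pre_tension", float("nan")),
            "K_storage": float("nan"),
            "K_loss": float("nan"),
            "A_F": float("nan"),
            "A_d": float("nan"),
            "phase_lag_rad": float("nan"),
            "error": "",
        }
        try:
            res = OscillationModel(tr, trap_stiffness).fit()
            cs = res.stiffness
            row.update(
                K_storage=cs.storage,
                K_loss=cs.loss,
                A_F=cs.amplitude_force,
                A_d=cs.amplitude_distance,
                phase_lag_rad=cs.phase_lag,
            )
        except (ValueError, RuntimeError) as err:
            row["error"] = str(err)
        rows.append(row)
    cols = [
        "frequency_Hz",
        "pretension_pN",
        "K_storage",
        "K_loss",
        "A_F",
        "A_d",
        "phase_lag_rad",
        "error",
    ]
    return pd.DataFrame(rows, columns=cols)
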
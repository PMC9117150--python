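"""Force-extension curve analysis: differential stiffness and stiffening fits.

This is the measurement pipeline applied to optical-tweezers pulling data:

1. smooth the force channel with a centered moving average (window 1/15 of
   the samples),
2. differentiate force with respect to bead-bead distance to obtain the
   differential stiffness K(F),
3. estimate the low-force plateau stiffness (KDE mode below 50 pN), the
   stiffening onset (first K above plateau + 1 s.d.) and the stiffening
   length (the distance there),
4. resample to a log-spaced force grid, fit the continuous plateau-plus-line
   model ln K = ln K0 for ln F ≤ ln Fc and ln K = ln K0 + c·(ln F − ln Fc)
   above, and rescale by (K0, Fc) for the master-curve collapse,
5. fit the stiffening exponent γ as the log-log slope over a force window
   (default 20–200 pN) and read the compliance (nm/pN) at 200 pN.

The object-oriented entry point is :class:`StiffeningModel`, whose
``fit()`` returns a :class:`StiffeningResults` carrying a
:class:`CurveFeatures` record, diagnostics and a ``summary()`` table; the
individual steps are also exposed as plain functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ForceExtensionCurve",
    "StiffnessCurve",
    "CurveFeatures",
    "OnsetResult",
    "StiffeningModel",
    "StiffeningResults",
    "smooth_curve",
    "differential_stiffness",
    "plateau_stiffness",
    "stiffening_onset",
    "compliance_at",
    "loglog_prepare",
    "fit_piecewise_loglog",
    "collapse_valid",
    "normalize_curve",
    "fit_stiffening_exponent",
    "detect_ruptures",
    "rank_sum_test",
    "GroupComparison",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class ForceExtensionCurve:
    """A sampled pulling curve: bead-bead distance (µm) vs force (pN).

    On construction the samples are sorted by distance; at least 30 samples
    are required, values must be finite, and at most 5 % of force samples
    may be negative (noise floor around zero force).
    """

    distance: np.ndarray
    force: np.ndarray
    time: np.ndarray | None = None
    cycle_label: str = ""

    def __post_init__(self):
        d = np.asarray(self.distance, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.ndim != 1 or d.shape != f.shape:
            raise ValueError("distance and force must be 1-D arrays of equal length")
        if d.size < 30:
            raise ValueError(f"need at least 30 samples, got {d.size}")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(f))):
            raise ValueError("curve contains non-finite values")
        if np.mean(f < 0) > 0.05:
            raise ValueError("more than 5% of force samples are negative")
        t = None if self.time is None else np.asarray(self.time, dtype=float)
        order = np.argsort(d, kind="stable")
        self.distance = d[order]
        self.force = f[order]
        self.time = None if t is None else t[order]

    def __len__(self):
        return self.distance.size

    @classmethod
    def from_dataframe(cls, df, cycle_label: str = ""):
        """Build from a frame with columns distance_um, force_pN[, time_s]."""
        time = df["time_s"].to_numpy() if "time_s" in df.columns else None
        return cls(
            distance=df["distance_um"].to_numpy(),
            force=df["force_pN"].to_numpy(),
            time=time,
            cycle_label=cycle_label,
        )


@dataclass
class StiffnessCurve:
    """Differential stiffness K (pN/µm) paired with force F (pN).

    ``distance`` keeps the sample's distance coordinate when the curve was
    obtained by differentiating a pulling curve (needed for the stiffening
    length).
    """

    force: np.ndarray
    stiffness: np.ndarray
    distance: np.ndarray | None = None

    def __post_init__(self):
        f = np.asarray(self.force, dtype=float)
        k = np.asarray(self.stiffness, dtype=float)
        if f.shape != k.shape:
            raise ValueError("force and stiffness must have equal length")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(k))):
            raise ValueError("stiffness curve contains non-finite values")
        self.force = f
        self.stiffness = k
        if self.distance is not None:
            self.distance = np.asarray(self.distance, dtype=float)

    def __len__(self):
        return self.force.size


@dataclass
class OnsetResult:
    """Stiffening onset: found flag, onset force (pN), stiffening length (µm)."""

    found: bool
    force: float = float("nan")
    length: float = float("nan")


@dataclass
class CurveFeatures:
    """Per-curve analysis output (units: pN, µm, pN/µm, nm/pN)."""

    K0: float = float("nan")
    Fc: float = float("nan")
    c: float = float("nan")
    gamma: float = float("nan")
    stiffening_length: float = float("nan")
    onset_force: float = float("nan")
    plateau_stiffness: float = float("nan")
    compliance_200: float = float("nan")
    collapse_valid: bool = False
    n_ruptures: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# Pipeline steps
# --------------------------------------------------------------------------

def _sym_moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with symmetrically shrinking edge windows.

    The half-width at sample i is min(window//2, i, n-1-i), so the window is
    always symmetric about its center and linear signals pass unchanged at
    every point, including the edges.  Output length equals input length.
    """
    n = y.size
    h = window // 2
    if h < 1:
        return y.copy()
    idx = np.arange(n)
    hi = np.minimum(h, np.minimum(idx, n - 1 - idx))
    cs = np.concatenate([[0.0], np.cumsum(y)])
    return (cs[idx + hi + 1] - cs[idx - hi]) / (2 * hi + 1)


def smooth_curve(curve: ForceExtensionCurve, window_fraction: float = 1 / 15):
    """Moving-average smoothing of the force channel.

    The window is ``max(1, round(n * window_fraction))`` samples; distance is
    untouched and the output has the same length.  If the curve is too short
    for the requested fraction the window degenerates to 1 (identity) with a
    logged warning.
    """
    if not (0 < window_fraction <= 1):
        raise ValueError("window_fraction must lie in (0, 1]")
    n = len(curve)
    w = max(1, round(n * window_fraction))
    if w == 1 and n * window_fraction < 1:
        logger.warning(
            "curve of %d samples too short for window fraction %.3g; "
            "smoothing is the identity",
            n,
            window_fraction,
        )
    return ForceExtensionCurve(
        distance=curve.distance.copy(),
        force=_sym_moving_average(curve.force, w),
        time=None if curve.time is None else curve.time.copy(),
        cycle_label=curve.cycle_label,
    )


def differential_stiffness(curve: ForceExtensionCurve) -> StiffnessCurve:
    """Numerical derivative K = dF/dd on the (possibly nonuniform) grid.

    Distance ties are collapsed by averaging the force; centered differences
    are used in the interior and one-sided differences at the endpoints
    (``numpy.gradient``).
    """
    d, inverse = np.unique(curve.distance, return_inverse=True)
    if d.size < 3:
        raise ValueError("need at least 3 distinct distance values")
    f = np.bincount(inverse, weights=curve.force) / np.bincount(inverse)
    k = np.gradient(f, d)
    return StiffnessCurve(force=f, stiffness=k, distance=d)


def plateau_stiffness(
    sc: StiffnessCurve, force_max: float = 50.0, n_kde: int = 512
) -> float:
    """Most likely stiffness below ``force_max`` (KDE mode).

    A Gaussian kernel density estimate (Silverman bandwidth) is evaluated on
    ``n_kde`` points spanning the low-force stiffness range; the location of
    its maximum is returned.  The mode — not the mean — is what survives a
    rising stiffness tail inside the window.
    """
    vals = sc.stiffness[sc.force < force_max]
    if vals.size < 10:
        raise ValueError(
            f"only {vals.size} stiffness samples below {force_max} pN; "
            "pass a larger force_max explicitly"
        )
    if np.std(vals) < 1e-12 * max(1.0, abs(np.mean(vals))):
        return float(np.mean(vals))
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min(), vals.max(), n_kde)
    return float(grid[np.argmax(kde(grid))])


def stiffening_onset(
    curve: ForceExtensionCurve,
    sc: StiffnessCurve,
    threshold_sd: float = 1.0,
    force_max: float = 50.0,
    min_run: int = 1,
) -> OnsetResult:
    """Onset of stiffening: first sample with K > plateau + threshold_sd·σ.

    σ is the standard deviation of all stiffness samples below ``force_max``.
    Samples are scanned in increasing distance; the stiffening length is the
    distance coordinate of the crossing.  ``min_run`` requires the
    exceedance to be sustained over that many consecutive samples before it
    counts (noise robustification; 1 reproduces the bare first-crossing
    rule).  A curve that never crosses (purely linear) yields
    ``OnsetResult(found=False)`` rather than an error.
    """
    plateau = plateau_stiffness(sc, force_max=force_max)
    sd = float(np.std(sc.stiffness[sc.force < force_max]))
    # the relative epsilon keeps float jitter on an exactly constant
    # stiffness from registering as an onset
    thresh = plateau + threshold_sd * sd + 1e-9 * abs(plateau)
    d = sc.distance if sc.distance is not None else curve.distance
    above = sc.stiffness > thresh
    min_run = max(1, int(min_run))
    if min_run > 1 and above.size >= min_run:
        run = np.convolve(above.astype(int), np.ones(min_run, dtype=int), "valid")
        hits = np.flatnonzero(run == min_run)
        if hits.size == 0:
            return OnsetResult(found=False)
        j = int(hits[0])
    else:
        if not np.any(above):
            return OnsetResult(found=False)
        j = int(np.argmax(above))
    return OnsetResult(found=True, force=float(sc.force[j]), length=float(d[j]))


def compliance_at(sc: StiffnessCurve, probe_force: float = 200.0) -> float:
    """Compliance 1000/K(probe) in nm/pN, K interpolated linearly in force."""
    order = np.argsort(sc.force, kind="stable")
    f, k = sc.force[order], sc.stiffness[order]
    if not (f[0] <= probe_force <= f[-1]):
        raise ValueError(
            f"probe force {probe_force} pN outside the curve's range "
            f"[{f[0]:.3g}, {f[-1]:.3g}] pN"
        )
    return 1000.0 / float(np.interp(probe_force, f, k))


def loglog_prepare(sc: StiffnessCurve, n_points: int | None = None) -> StiffnessCurve:
    """Resample to a log-spaced force grid for log-log fitting.

    Nonpositive forces or stiffnesses are discarded; the surviving samples
    (at least 10 required) are averaged within log-spaced force bins — each
    occupied bin contributes the pair (mean ln F, mean ln K) of its samples,
    which reproduces any pure power law exactly and averages measurement
    noise down by the per-bin sample count — and the bin values are then
    interpolated, linearly in (ln F, ln K), onto a log-spaced grid spanning
    the retained force range.
    """
    keep = (sc.force > 0) & (sc.stiffness > 0)
    f, k = sc.force[keep], sc.stiffness[keep]
    if f.size < 10:
        raise ValueError(f"only {f.size} positive (F, K) pairs; need at least 10")
    lnf, lnk = np.log(f), np.log(k)
    n = n_points if n_points is not None else min(f.size, 400)
    lo, hi = lnf.min(), lnf.max()
    edges = np.linspace(lo, hi, n + 1)
    idx = np.clip(np.searchsorted(edges, lnf, side="right") - 1, 0, n - 1)
    counts = np.bincount(idx, minlength=n)
    occupied = counts > 0
    with np.errstate(invalid="ignore"):
        bin_lnf = np.bincount(idx, weights=lnf, minlength=n)[occupied] / counts[occupied]
        bin_lnk = np.bincount(idx, weights=lnk, minlength=n)[occupied] / counts[occupied]
    order = np.argsort(bin_lnf, kind="stable")
    bin_lnf, bin_lnk = bin_lnf[order], bin_lnk[order]
    grid = np.linspace(lo, hi, n)
    lnk_grid = np.interp(grid, bin_lnf, bin_lnk)
    # linear extrapolation past the outermost bin centers (np.interp clamps)
    if bin_lnf.size >= 2:
        left = grid < bin_lnf[0]
        right = grid > bin_lnf[-1]
        sl = (bin_lnk[1] - bin_lnk[0]) / (bin_lnf[1] - bin_lnf[0])
        sr = (bin_lnk[-1] - bin_lnk[-2]) / (bin_lnf[-1] - bin_lnf[-2])
        lnk_grid[left] = bin_lnk[0] + sl * (grid[left] - bin_lnf[0])
        lnk_grid[right] = bin_lnk[-1] + sr * (grid[right] - bin_lnf[-1])
    return StiffnessCurve(force=np.exp(grid), stiffness=np.exp(lnk_grid))


def _piecewise_ols(x, y, x0):
    """OLS of y on [1, relu(x - x0)]; returns (intercept, slope, sse)."""
    z = np.maximum(0.0, x - x0)
    n = x.size
    szz = np.dot(z, z) - z.sum() ** 2 / n
    if szz <= 0:
        return np.mean(y), 0.0, float(np.sum((y - np.mean(y)) ** 2))
    szy = np.dot(z, y) - z.sum() * y.sum() / n
    c = szy / szz
    b = (y.sum() - c * z.sum()) / n
    resid = y - b - c * z
    return b, c, float(np.dot(resid, resid))


def fit_piecewise_loglog(sc_log: StiffnessCurve):
    """Fit the continuous plateau-plus-line model in (ln F, ln K).

    The model is y = ln K0 for x ≤ ln Fc and y = ln K0 + c·(x − ln Fc)
    above; continuity at the kink is built in.  The kink is located by an
    exhaustive scan over the sample positions (vectorised via suffix sums)
    followed by bounded golden-section refinement.

    Returns
    -------
    (K0, Fc, c) : tuple of float
        Plateau stiffness (pN/µm), critical force (pN), log-log slope.
    """
    x = np.log(sc_log.force)
    y = np.log(sc_log.stiffness)
    n = x.size
    if n < 6:
        raise ValueError("need at least 6 log-prepared points for a piecewise fit")

    # suffix sums over i > k for every candidate kink k
    rx = np.cumsum(x[::-1])[::-1]
    rx2 = np.cumsum((x * x)[::-1])[::-1]
    ry = np.cumsum(y[::-1])[::-1]
    rxy = np.cumsum((x * y)[::-1])[::-1]
    ks = np.arange(1, n - 3)  # at least 2 points left, 3 right
    cnt = n - 1 - ks
    t1 = rx[ks + 1]
    t2 = rx2[ks + 1]
    ty = ry[ks + 1]
    txy = rxy[ks + 1]
    xk = x[ks]
    sz = t1 - cnt * xk
    szz = t2 - 2 * xk * t1 + cnt * xk**2
    szy = txy - xk * ty
    sy = y.sum()
    syy = np.dot(y, y)
    szz_c = szz - sz**2 / n
    szy_c = szy - sz * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        c_all = np.where(szz_c > 1e-30, szy_c / szz_c, 0.0)
    sse = syy - sy**2 / n - c_all**2 * szz_c
    best = int(np.argmin(sse))
    k = ks[best]

    lo = x[max(k - 1, 0)]
    hi = x[min(k + 1, n - 1)]
    res = optimize.minimize_scalar(
        lambda x0: _piecewise_ols(x, y, x0)[2],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:  # pragma: no cover - bounded golden section converges
        raise RuntimeError(f"piecewise fit failed: {res.message}; sse grid {sse[best]:.3g}")
    x0 = float(res.x)
    b, c, _ = _piecewise_ols(x, y, x0)
    return float(np.exp(b)), float(np.exp(x0)), float(c)


def collapse_valid(K0: float, Fc: float, sc: StiffnessCurve) -> bool:
    """Whether fitted (K0, Fc) qualify the curve for the master collapse.

    True iff both are positive and lie within the observed force and
    stiffness ranges of the curve.
    """
    if not (np.isfinite(K0) and np.isfinite(Fc) and K0 > 0 and Fc > 0):
        return False
    fmin, fmax = float(sc.force.min()), float(sc.force.max())
    kmin, kmax = float(sc.stiffness.min()), float(sc.stiffness.max())
    return (fmin <= Fc <= fmax) and (kmin <= K0 <= kmax)


def normalize_curve(sc: StiffnessCurve, K0: float, Fc: float) -> StiffnessCurve:
    """Rescale to (F/Fc, K/K0) for the master-curve collapse."""
    if not (K0 > 0 and Fc > 0):
        raise ValueError("K0 and Fc must be > 0")
    return StiffnessCurve(force=sc.force / Fc, stiffness=sc.stiffness / K0)


def fit_stiffening_exponent(
    sc_log: StiffnessCurve, f_lo: float = 20.0, f_hi: float = 200.0
) -> float:
    """OLS slope of ln K vs ln F over the force window [f_lo, f_hi]."""
    m = (sc_log.force >= f_lo) & (sc_log.force <= f_hi)
    if np.count_nonzero(m) < 5:
        raise ValueError(
            f"fewer than 5 grid points inside [{f_lo}, {f_hi}] pN"
        )
    slope, _ = np.polyfit(np.log(sc_log.force[m]), np.log(sc_log.stiffness[m]), 1)
    return float(slope)


def detect_ruptures(curve: ForceExtensionCurve, min_drop: float):
    """Locate abrupt force drops of at least ``min_drop`` pN.

    Returns a list of (distance_um, force_drop_pN) tuples, one per event:
    the distance of the preceding force peak and the peak-to-trough drop.
    Monotonically nondecreasing force yields an empty list.
    """
    f, d = curve.force, curve.distance
    events: list[tuple[float, float]] = []
    peak_f, peak_d = f[0], d[0]
    trough: float | None = None
    for fi, di in zip(f[1:], d[1:]):
        if trough is None:
            if fi >= peak_f:
                peak_f, peak_d = fi, di
            elif peak_f - fi >= min_drop:
                trough = fi
        else:
            if fi < trough:
                trough = fi
            elif fi >= peak_f:
                events.append((float(peak_d), float(peak_f - trough)))
                peak_f, peak_d = fi, di
                trough = None
    if trough is not None:
        events.append((float(peak_d), float(peak_f - trough)))
    return events


# --------------------------------------------------------------------------
# Group comparison (standard rank-sum routine, invoked not reimplemented)
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def highly_significant(self) -> bool:
        return self.p_value < 0.01


def rank_sum_test(a, b) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison of two groups.

    Exact null distribution for small samples (n ≤ 25 per group), normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    method = "exact" if max(a.size, b.size) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


# --------------------------------------------------------------------------
# Model / Results objects
# --------------------------------------------------------------------------

class StiffeningModel:
    """Strain-stiffening analysis of one force-extension curve.

    Parameters
    ----------
    curve : ForceExtensionCurve
        The pulling curve (extension segment) to analyse.
    window_fraction : float
        Moving-average window as a fraction of the sample count.
    plateau_force_max : float
        Force ceiling (pN) for the plateau/onset statistics.
    onset_threshold_sd : float
        Onset threshold in units of the low-force stiffness s.d.
    gamma_window : (float, float)
        Force window (pN) for the stiffening-exponent fit.
    compliance_probe : float
        Probe force (pN) for the compliance readout.
    rupture_min_drop : float
        Minimum force drop (pN) counted as a rupture event.
    n_loglog : int or None
        Number of log-grid points (None: matched to the data, capped at 400).
    trim_edges : bool
        Drop stiffness samples within half a smoothing window of either end
        of the curve before the statistics.  The moving average cannot
        suppress noise there (its window shrinks), so derivative estimates
        at the edges are disproportionately noisy and would otherwise
        trigger spurious onsets.  Default True.

    Examples
    --------
    >>> res = StiffeningModel(curve).fit()          # doctest: +SKIP
    >>> res.features.gamma                          # doctest: +SKIP
    """

    def __init__(
        self,
        curve: ForceExtensionCurve,
        *,
        window_fraction: float = 1 / 15,
        plateau_force_max: float = 50.0,
        onset_threshold_sd: float = 1.0,
        gamma_window: tuple[float, float] = (20.0, 200.0),
        compliance_probe: float = 200.0,
        rupture_min_drop: float = 10.0,
        n_loglog: int | None = None,
        trim_edges: bool = True,
    ):
        self.curve = curve
        self.window_fraction = window_fraction
        self.plateau_force_max = plateau_force_max
        self.onset_threshold_sd = onset_threshold_sd
        self.gamma_window = gamma_window
        self.compliance_probe = compliance_probe
        self.rupture_min_drop = rupture_min_drop
        self.n_loglog = n_loglog
        self.trim_edges = trim_edges

    @classmethod
    def from_dataframe(cls, df, cycle_label: str = "", **kwargs):
        return cls(ForceExtensionCurve.from_dataframe(df, cycle_label), **kwargs)

    def fit(self) -> "StiffeningResults":
        notes: list[str] = []
        smoothed = smooth_curve(self.curve, self.window_fraction)
        sc_raw = differential_stiffness(smoothed)

        def _trim(sc_in: StiffnessCurve, margin: int) -> StiffnessCurve:
            if not self.trim_edges or len(sc_in) <= 2 * margin + 10 or margin < 1:
                return sc_in
            sl = slice(margin, -margin)
            return StiffnessCurve(
                force=sc_in.force[sl],
                stiffness=sc_in.stiffness[sl],
                distance=None if sc_in.distance is None else sc_in.distance[sl],
            )

        half = max(1, round(len(self.curve) * self.window_fraction) // 2)
        sc = _trim(sc_raw, half)
        feats = CurveFeatures()

        try:
            feats.plateau_stiffness = plateau_stiffness(sc, self.plateau_force_max)
            onset = stiffening_onset(
                self.curve,
                sc,
                self.onset_threshold_sd,
                self.plateau_force_max,
                min_run=max(1, half // 10),
            )
        except ValueError as err:
            notes.append(f"plateau/onset: {err}")
            onset = OnsetResult(found=False)
        if onset.found:
            feats.onset_force = onset.force
            feats.stiffening_length = onset.length

        try:
            feats.compliance_200 = compliance_at(sc, self.compliance_probe)
        except ValueError as err:
            notes.append(f"compliance: {err}")

        sc_log = None
        try:
            sc_log = loglog_prepare(sc, self.n_loglog)
            feats.K0, feats.Fc, feats.c = fit_piecewise_loglog(sc_log)
            feats.collapse_valid = collapse_valid(feats.K0, feats.Fc, sc_log)
            feats.gamma = fit_stiffening_exponent(sc_log, *self.gamma_window)
        except (ValueError, RuntimeError) as err:
            notes.append(f"log-log fit: {err}")

        # A rupture's force drop is sharp but small compared with the force
        # gained across one full smoothing window, so the 1/15-window curve
        # rises monotonically straight through it; detection therefore runs
        # on a lightly smoothed copy (5-sample window, enough to suppress
        # the sample-to-sample noise floor).
        light = smooth_curve(self.curve, min(1.0, 5.0 / len(self.curve)))
        ruptures = detect_ruptures(light, self.rupture_min_drop)
        feats.n_ruptures = len(ruptures)
        return StiffeningResults(
            model=self,
            smoothed=smoothed,
            stiffness_curve=sc,
            loglog_curve=sc_log,
            features=feats,
            onset=onset,
            ruptures=ruptures,
            notes=notes,
        )


@dataclass
class StiffeningResults:
    """Fit output of :class:`StiffeningModel`."""

    model: StiffeningModel
    smoothed: ForceExtensionCurve
    stiffness_curve: StiffnessCurve
    loglog_curve: StiffnessCurve | None
    features: CurveFeatures
    onset: OnsetResult
    ruptures: list
    notes: list = field(default_factory=list)

    def normalized(self) -> StiffnessCurve:
        """The curve rescaled by its own (K0, Fc) for the master collapse."""
        if self.loglog_curve is None or not np.isfinite(self.features.K0):
            raise ValueError("no valid piecewise fit; cannot normalise")
        return normalize_curve(self.loglog_curve, self.features.K0, self.features.Fc)

    def summary(self) -> str:
        f = self.features
        lines = [
            "Strain-stiffening analysis",
            "=" * 46,
            f"{'samples':<28}{len(self.model.curve):>18d}",
            f"{'cycle':<28}{self.model.curve.cycle_label or '-':>18}",
            f"{'plateau stiffness [pN/um]':<28}{f.plateau_stiffness:>18.4g}",
            f"{'K0 (piecewise) [pN/um]':<28}{f.K0:>18.4g}",
            f"{'Fc [pN]':<28}{f.Fc:>18.4g}",
            f"{'piecewise slope c':<28}{f.c:>18.4g}",
            f"{'gamma (window fit)':<28}{f.gamma:>18.4g}",
            f"{'stiffening length [um]':<28}{f.stiffening_length:>18.4g}",
            f"{'onset force [pN]':<28}{f.onset_force:>18.4g}",
            f"{'compliance@200pN [nm/pN]':<28}{f.compliance_200:>18.4g}",
            f"{'collapse valid':<28}{str(f.collapse_valid):>18}",
            f"{'rupture events':<28}{f.n_ruptures:>18d}",
        ]
        if self.notes:
            lines.append("notes: " + "; ".join(self.notes))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Log-log stiffness-force data with the fitted piecewise model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sc = self.stiffness_curve
        keep = (sc.force > 0) & (sc.stiffness > 0)
        ax.loglog(sc.force[keep], sc.stiffness[keep], ".", ms=2, label="data")
        f = self.features
        if np.isfinite(f.K0) and np.isfinite(f.Fc):
            fg = np.geomspace(sc.force[keep].min(), sc.force[keep].max(), 200)
            kg = np.where(fg <= f.Fc, f.K0, f.K0 * (fg / f.Fc) ** f.c)
            ax.loglog(fg, kg, "-", label=f"piecewise fit (c={f.c:.2f})")
        ax.set_xlabel("force (pN)")
        ax.set_ylabel("stiffness (pN/µm)")
        ax.legend()
        return ax
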
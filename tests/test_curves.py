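"""Curve-analysis pipeline: smoothing, stiffness, fits, collapse, ruptures."""

import numpy as np
import pytest

from chromech import StiffeningModel, WLCElement
from chromech.curves import (
    CurveFeatures,
    ForceExtensionCurve,
    StiffnessCurve,
    collapse_valid,
    compliance_at,
    detect_ruptures,
    differential_stiffness,
    fit_piecewise_loglog,
    fit_stiffening_exponent,
    loglog_prepare,
    normalize_curve,
    plateau_stiffness,
    rank_sum_test,
    smooth_curve,
    stiffening_onset,
)
from chromech.synthetic import gen_polymer_curve


def _linear_curve(n=150, slope=5.0, noise=None, seed=0):
    d = np.linspace(0.0, 3.0, n)
    f = slope * d
    if noise:
        f = f + np.random.default_rng(seed).normal(0.0, noise, n)
    return ForceExtensionCurve(distance=d, force=f)


def _wlc_curve(f_c=10.0, ell=3.0, n=600):
    return gen_polymer_curve("wlc", f_c, ell, np.geomspace(1e-3, 1e3, n))


class TestContainers:
    def test_sorts_by_distance(self):
        d = np.array([0.3, 0.1, 0.2] * 10 + [0.4] * 5)
        f = d * 2
        c = ForceExtensionCurve(distance=d, force=f)
        assert np.all(np.diff(c.distance) >= 0)
        np.testing.assert_allclose(c.force, 2 * c.distance)

    def test_rejects_short_or_negative_curves(self):
        with pytest.raises(ValueError):
            ForceExtensionCurve(distance=np.arange(10.0), force=np.arange(10.0))
        d = np.linspace(0, 1, 100)
        with pytest.raises(ValueError):
            ForceExtensionCurve(distance=d, force=np.full(100, -1.0))


class TestSmoothing:
    def test_linear_signal_unchanged_everywhere(self):
        c = _linear_curve()
        out = smooth_curve(c, 1 / 15)
        np.testing.assert_allclose(out.force, c.force, atol=1e-12)
        np.testing.assert_array_equal(out.distance, c.distance)

    def test_window_is_one_fifteenth_of_samples(self):
        # n = 150 -> window 10 -> interior half-width 5
        c = _linear_curve(n=150, noise=1.0)
        out = smooth_curve(c, 1 / 15)
        w = 2 * (10 // 2) + 1
        i = 75
        np.testing.assert_allclose(
            out.force[i], c.force[i - 5 : i + 6].mean(), rtol=1e-12
        )
        assert len(out) == len(c)
        assert w == 11

    def test_noise_reduced_by_sqrt_window(self):
        rng = np.random.default_rng(5)
        n, sigma = 3000, 1.0
        d = np.linspace(0, 1, n)
        f = 10.0 + rng.normal(0, sigma, n)
        out = smooth_curve(ForceExtensionCurve(distance=d, force=f), 1 / 15)
        w = 2 * (round(n / 15) // 2) + 1
        interior = out.force[300:-300]
        assert np.std(interior) == pytest.approx(sigma / np.sqrt(w), rel=0.35)

    def test_too_short_for_window_falls_back_to_identity(self):
        c = _linear_curve(n=30, noise=0.5)
        out = smooth_curve(c, 1 / 45)
        np.testing.assert_array_equal(out.force, c.force)


class TestDifferentialStiffness:
    def test_linear_curve_constant_stiffness(self):
        sc = differential_stiffness(_linear_curve(slope=5.0))
        np.testing.assert_allclose(sc.stiffness, 5.0, rtol=1e-9)

    def test_matches_analytic_wlc_stiffness(self):
        el = WLCElement(10.0, 3.0)
        sc = differential_stiffness(_wlc_curve())
        ref = el.stiffness(sc.force)
        interior = slice(5, -5)
        np.testing.assert_allclose(
            sc.stiffness[interior], ref[interior], rtol=0.01
        )

    def test_plateau_then_rise_shape(self, power_dist):
        from chromech.hwlc import build_assembly
        from chromech.synthetic import NoiseSpec, gen_force_extension

        asm = build_assembly(power_dist, 30, 3.0, seed=8)
        curve, _ = gen_force_extension(asm, NoiseSpec(force_noise_sd=0.0), seed=0)
        sc = differential_stiffness(smooth_curve(curve))
        low = sc.stiffness[(sc.force > 0.5) & (sc.force < 2.0)]
        high = sc.stiffness[sc.force > 200]
        assert high.mean() > 5 * low.mean()

    def test_requires_three_points(self):
        c = _linear_curve(n=40)
        c.distance[:] = 1.0  # collapse all distances
        with pytest.raises(ValueError):
            differential_stiffness(c)


class TestPlateauAndOnset:
    def test_constant_stiffness_plateau(self):
        sc = StiffnessCurve(force=np.linspace(1, 40, 50), stiffness=np.full(50, 7.0))
        assert plateau_stiffness(sc) == pytest.approx(7.0, rel=1e-9)

    def test_mode_not_mean_for_bimodal(self):
        rng = np.random.default_rng(0)
        k = np.concatenate([10 + 0.1 * rng.normal(size=80), 30 + 0.1 * rng.normal(size=8)])
        sc = StiffnessCurve(force=np.linspace(1, 40, 88), stiffness=k)
        assert plateau_stiffness(sc) == pytest.approx(10.0, abs=1.0)

    def test_insufficient_low_force_samples(self):
        sc = StiffnessCurve(force=np.linspace(60, 100, 30), stiffness=np.ones(30))
        with pytest.raises(ValueError, match="force_max"):
            plateau_stiffness(sc)

    def test_purely_linear_curve_has_no_onset(self):
        c = _linear_curve(n=200)
        sc = differential_stiffness(c)
        onset = stiffening_onset(c, sc)
        assert not onset.found

    def test_piecewise_fixture_onset_location(self):
        # K = 10 (sd 1) below d = 4 um, then a steep ramp; the ramp leaves
        # the below-50-pN window almost immediately, so the low-force sd
        # stays ~1 and the onset lands at the kink
        rng = np.random.default_rng(3)
        d = np.linspace(0, 4.5, 450)
        k = np.where(d < 4.0, 10.0, 10.0 + 200.0 * (d - 4.0))
        k = k + rng.normal(0, 1.0, 450)
        f = np.concatenate([[0], np.cumsum(np.maximum(k[1:], 0) * np.diff(d))])
        c = ForceExtensionCurve(distance=d, force=f)
        sc = StiffnessCurve(force=f, stiffness=k, distance=d)
        onset = stiffening_onset(c, sc)
        assert onset.found
        assert onset.length == pytest.approx(4.0, abs=0.25)

    def test_raising_threshold_never_shortens_length(self):
        c = _wlc_curve()
        sc = differential_stiffness(smooth_curve(c))
        lengths = []
        for thr in (0.5, 1.0, 2.0, 4.0):
            onset = stiffening_onset(c, sc, threshold_sd=thr)
            assert onset.found
            lengths.append(onset.length)
        assert np.all(np.diff(lengths) >= 0)


class TestComplianceAndNormalize:
    def test_unit_conversion(self):
        sc = StiffnessCurve(
            force=np.linspace(100, 300, 30), stiffness=np.full(30, 100.0)
        )
        assert compliance_at(sc, 200.0) == pytest.approx(10.0, rel=1e-12)

    def test_analytic_wlc_value(self):
        el = WLCElement(10.0, 3.0)
        sc = differential_stiffness(_wlc_curve())
        assert compliance_at(sc, 200.0) == pytest.approx(
            1000.0 / el.stiffness(200.0), rel=0.01
        )

    def test_probe_outside_range_names_range(self):
        sc = StiffnessCurve(force=np.linspace(1, 50, 30), stiffness=np.ones(30))
        with pytest.raises(ValueError, match="range"):
            compliance_at(sc, 200.0)

    def test_normalize_identity_scaling(self):
        sc = StiffnessCurve(force=np.geomspace(1, 100, 40), stiffness=np.geomspace(10, 60, 40))
        out = normalize_curve(sc, K0=10.0, Fc=20.0)
        np.testing.assert_allclose(out.force, sc.force / 20.0)
        np.testing.assert_allclose(out.stiffness, sc.stiffness / 10.0)


class TestLogLogPrepare:
    def test_grid_spans_positive_range(self):
        sc = StiffnessCurve(force=np.geomspace(0.5, 200, 300), stiffness=np.geomspace(5, 500, 300))
        out = loglog_prepare(sc)
        assert out.force[0] == pytest.approx(0.5, rel=1e-9)
        assert out.force[-1] == pytest.approx(200, rel=1e-9)
        assert np.all(np.diff(np.log(out.force)) > 0)

    def test_nonpositive_rows_discarded(self):
        f = np.concatenate([[-5.0, 0.0], np.geomspace(1, 100, 50)])
        k = np.concatenate([[10.0, 10.0], np.geomspace(10, 100, 50)])
        out = loglog_prepare(StiffnessCurve(force=f, stiffness=k))
        assert out.force.min() >= 1.0

    def test_power_law_resampled_within_half_percent(self):
        f = np.geomspace(1, 1000, 500)
        sc = StiffnessCurve(force=f, stiffness=f**0.8)
        out = loglog_prepare(sc)
        np.testing.assert_allclose(out.stiffness, out.force**0.8, rtol=0.005)

    def test_too_few_positive_pairs(self):
        sc = StiffnessCurve(force=-np.ones(30), stiffness=np.ones(30))
        with pytest.raises(ValueError):
            loglog_prepare(sc)


class TestPiecewiseFit:
    def test_recovers_its_own_model_exactly(self):
        f = np.geomspace(1, 1000, 300)
        k = np.where(f <= 20.0, 50.0, 50.0 * (f / 20.0) ** 0.8)
        K0, Fc, c = fit_piecewise_loglog(StiffnessCurve(force=f, stiffness=k))
        assert K0 == pytest.approx(50.0, rel=1e-5)
        assert Fc == pytest.approx(20.0, rel=1e-3)
        assert c == pytest.approx(0.8, rel=1e-4)

    def test_single_wlc_slope_near_three_halves(self):
        sc = loglog_prepare(differential_stiffness(smooth_curve(_wlc_curve())))
        K0, Fc, c = fit_piecewise_loglog(sc)
        assert c == pytest.approx(1.5, abs=0.15)
        assert 0.5 * 10.0 <= Fc <= 2.0 * 10.0  # within a factor ~2 of f_c

    def test_collapse_validity_semantics(self):
        f = np.geomspace(1, 1000, 100)
        sc = StiffnessCurve(force=f, stiffness=np.geomspace(10, 1000, 100))
        assert collapse_valid(50.0, 30.0, sc)
        assert not collapse_valid(50.0, 0.5, sc)  # Fc below force range
        assert not collapse_valid(-1.0, 30.0, sc)
        assert not collapse_valid(float("nan"), 30.0, sc)


class TestExponentFit:
    def test_pure_power_law_exact(self):
        f = np.geomspace(1, 1000, 200)
        sc = StiffnessCurve(force=f, stiffness=3.0 * f**0.82)
        assert fit_stiffening_exponent(sc, 20, 200) == pytest.approx(0.82, rel=1e-10)

    def test_single_wlc_low_fc_gives_three_halves(self):
        curve = gen_polymer_curve("wlc", 1.0, 3.0, np.geomspace(1e-3, 1e3, 600))
        sc = loglog_prepare(differential_stiffness(smooth_curve(curve)))
        gamma = fit_stiffening_exponent(sc, 20.0, 200.0)
        assert gamma == pytest.approx(1.5, abs=0.05)

    def test_empty_window_rejected(self):
        sc = StiffnessCurve(force=np.geomspace(1, 10, 50), stiffness=np.ones(50))
        with pytest.raises(ValueError):
            fit_stiffening_exponent(sc, 100, 1000)


class TestCollapse:
    def test_family_recollapses_onto_master_curve(self):
        # exact piecewise curves with shared slope, scattered (K0, Fc)
        rng = np.random.default_rng(12)
        f = np.geomspace(0.5, 2000, 400)
        masters = []
        for _ in range(6):
            K0 = 10 ** rng.uniform(0.5, 2.0)
            Fc = 10 ** rng.uniform(0.8, 1.8)
            k = np.where(f <= Fc, K0, K0 * (f / Fc) ** 0.8)
            fit = fit_piecewise_loglog(StiffnessCurve(force=f, stiffness=k))
            norm = normalize_curve(StiffnessCurve(force=f, stiffness=k), fit[0], fit[1])
            masters.append(norm)
        # evaluate each normalized curve on a common reduced-force grid
        ref = np.geomspace(0.1, 10, 50)
        vals = [
            np.interp(np.log(ref), np.log(m.force), np.log(m.stiffness))
            for m in masters
        ]
        spread = np.ptp(np.array(vals), axis=0)
        assert spread.max() < 1e-6


class TestRuptures:
    def test_monotone_force_gives_no_events(self):
        assert detect_ruptures(_linear_curve(), 5.0) == []

    def test_injected_drop_detected_at_location(self):
        d = np.linspace(0, 6, 600)
        f = 20.0 * d
        f[d > 3.0] -= 15.0
        c = ForceExtensionCurve(distance=d, force=f)
        events = detect_ruptures(c, 10.0)
        assert len(events) == 1
        loc, drop = events[0]
        assert loc == pytest.approx(3.0, abs=0.05)
        assert drop == pytest.approx(15.0, abs=1.0)

    def test_subthreshold_drop_ignored(self):
        d = np.linspace(0, 6, 600)
        f = 20.0 * d
        f[d > 2.0] -= 15.0
        f[d > 4.0] -= 5.0  # second, below threshold
        c = ForceExtensionCurve(distance=d, force=f)
        assert len(detect_ruptures(c, 10.0)) == 1


class TestScaleEquivariance:
    def test_force_and_distance_rescaling(self):
        # the force-unit thresholds (plateau ceiling, exponent window,
        # compliance probe) are rescaled along with the force axis
        base = _wlc_curve()
        res = StiffeningModel(base).fit().features
        s = 3.0
        f_scaled = ForceExtensionCurve(distance=base.distance, force=base.force * s)
        rf = StiffeningModel(
            f_scaled,
            plateau_force_max=50.0 * s,
            gamma_window=(20.0 * s, 200.0 * s),
            compliance_probe=200.0 * s,
        ).fit().features
        assert rf.K0 == pytest.approx(s * res.K0, rel=1e-6)
        assert rf.Fc == pytest.approx(s * res.Fc, rel=1e-6)
        assert rf.plateau_stiffness == pytest.approx(s * res.plateau_stiffness, rel=1e-6)
        assert rf.onset_force == pytest.approx(s * res.onset_force, rel=1e-6)
        assert rf.gamma == pytest.approx(res.gamma, abs=1e-9)
        d_scaled = ForceExtensionCurve(distance=base.distance * s, force=base.force)
        rd = StiffeningModel(d_scaled).fit().features
        assert rd.K0 == pytest.approx(res.K0 / s, rel=1e-6)
        assert rd.gamma == pytest.approx(res.gamma, abs=1e-9)
        assert rd.stiffening_length == pytest.approx(s * res.stiffening_length, rel=1e-6)


class TestModelResults:
    def test_full_pipeline_on_noiseless_wlc(self):
        # exponent window in the top force decade (asymptotic regime) and
        # plateau window inside the element's own linear regime (< 0.05 f_c;
        # the 50 pN default targets chromosomes, whose plateau ends there)
        el = WLCElement(10.0, 3.0)
        res = StiffeningModel(
            _wlc_curve(), gamma_window=(100.0, 1000.0), plateau_force_max=0.5
        ).fit()
        f = res.features
        assert f.gamma == pytest.approx(1.5, abs=0.05)
        # the KDE plateau is the unbiased initial-stiffness estimate; the
        # piecewise-fit K0 carries a known systematic from the stiffness
        # already rising below the kink
        assert f.plateau_stiffness == pytest.approx(el.k0, rel=0.05)
        assert f.K0 == pytest.approx(el.k0, rel=0.25)
        assert f.collapse_valid
        assert f.n_ruptures == 0

    def test_summary_contains_key_fields(self):
        res = StiffeningModel(_wlc_curve()).fit()
        text = res.summary()
        for token in ("K0", "Fc", "gamma", "stiffening length", "compliance"):
            assert token in text

    def test_features_dict_round_trip(self):
        d = CurveFeatures(K0=1.0, Fc=2.0).as_dict()
        assert d["K0"] == 1.0 and "collapse_valid" in d


class TestRankSum:
    def test_detects_clear_difference(self):
        a = np.full(10, 6.0) + 0.1 * np.arange(10)
        b = np.full(10, 15.0) + 0.1 * np.arange(10)
        res = rank_sum_test(a, b)
        assert res.p_value < 0.01 and res.highly_significant

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 10)
        b = rng.normal(10, 1, 10)
        assert rank_sum_test(a, b).p_value > 0.05
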
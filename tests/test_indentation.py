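"""Oliver-Pharr chain: closed forms, own-model recovery, synthetic oracle."""

import math

import numpy as np
import pytest

from osteoquant.indentation import (
    IndentCurve, InsufficientDataError, ProbeGeometry, SegmentationError,
    StiffnessStrategy, analyze_indent, contact_area, hardness,
    reduced_modulus, segment_curve, unloading_stiffness)
from osteoquant.simulate import generate_indent_curve


def trapezoid_curve(n_ramp=100, n_hold=100, pmax=1000.0, noise=0.0, seed=0):
    """Programmed trapezoidal load profile with a plausible displacement."""
    p = np.concatenate([np.linspace(0, pmax, n_ramp, endpoint=False),
                        np.full(n_hold, pmax),
                        np.linspace(pmax, 0, n_ramp + 1)[1:]])
    if noise:
        rng = np.random.default_rng(seed)
        p = p + noise * pmax * rng.standard_normal(p.size)
    t = np.arange(p.size, dtype=float) * 0.1
    h = np.concatenate([np.linspace(0, 300, n_ramp, endpoint=False),
                        np.linspace(300, 320, n_hold),
                        np.linspace(320, 100, n_ramp)])
    return IndentCurve(time_s=t, load_uN=p, disp_nm=h), n_ramp, n_ramp + n_hold - 1


class TestSegmentation:
    def test_exact_corners_on_clean_trapezoid(self):
        c, load_corner, hold_corner = trapezoid_curve()
        seg = segment_curve(c, hold_tolerance=1e-6)
        assert seg.load_end == load_corner
        assert seg.hold_end == hold_corner

    def test_corners_within_two_samples_under_load_noise(self):
        misses = 0
        for seed in range(100):
            c, load_corner, hold_corner = trapezoid_curve(noise=0.01, seed=seed)
            seg = segment_curve(c, hold_tolerance=0.01)
            if abs(seg.load_end - load_corner) > 2 or \
                    abs(seg.hold_end - hold_corner) > 2:
                misses += 1
        assert misses == 0

    def test_monotone_ramp_has_no_hold(self):
        t = np.arange(100, dtype=float)
        p = np.linspace(0, 1000, 100)
        h = np.linspace(0, 300, 100)
        with pytest.raises(SegmentationError):
            segment_curve(IndentCurve(t, p, h), hold_tolerance=1e-6)

    def test_too_short_curve(self):
        t = np.arange(10, dtype=float)
        with pytest.raises(SegmentationError):
            segment_curve(IndentCurve(t, t, t))


def synthetic_unload(alpha, h_f, m, pmax=1000.0):
    """Ramp + hold + power-law unload with known unloading parameters."""
    hmax = h_f + (pmax / alpha) ** (1 / m)
    n = 120
    p_load = np.linspace(0, pmax, 60, endpoint=False)
    h_load = np.linspace(0, hmax, 60, endpoint=False)
    p_hold = np.full(20, pmax)
    h_hold = np.full(20, hmax)
    p_unl = np.linspace(pmax, 0, n)
    h_unl = h_f + (p_unl / alpha) ** (1 / m)
    t = np.arange(60 + 20 + n, dtype=float)
    return IndentCurve(t, np.concatenate([p_load, p_hold, p_unl]),
                       np.concatenate([h_load, h_hold, h_unl])), hmax


class TestUnloadingStiffness:
    def test_exact_power_law_recovery(self):
        alpha, h_f, m = 2.0, 120.0, 1.7
        c, hmax = synthetic_unload(alpha, h_f, m)
        seg = segment_curve(c, hold_tolerance=1e-6)
        S, hm, pm, m_hat, warn = unloading_stiffness(seg)
        expected = alpha * m * (hmax - h_f) ** (m - 1)
        assert S == pytest.approx(expected, rel=1e-3)
        assert m_hat == pytest.approx(m, rel=1e-3)
        assert not warn

    def test_linear_unload_recovers_slope(self):
        S0, h_f = 5.0, 100.0
        c, hmax = synthetic_unload(S0, h_f, 1.0)
        seg = segment_curve(c, hold_tolerance=1e-6)
        S, *_ = unloading_stiffness(seg)
        assert S == pytest.approx(S0, rel=1e-3)

    def test_stiffness_matches_inverted_modulus_relation(self, probe):
        # oracle: solve Er = (1/beta)(sqrt(pi)/2) S/sqrt(A) for S using the
        # analysis' own contact area
        er_true = 20.0
        c = generate_indent_curve(er_true, 0.6, probe, noise=0.0, seed=0)
        res = analyze_indent(c, probe)
        s_expected = probe.beta * (2 / math.sqrt(math.pi)) * \
            (er_true * 1000.0) * math.sqrt(res.A_um2) / 1000.0  # μN/nm
        assert res.S_uN_per_nm == pytest.approx(s_expected, rel=0.02)

    def test_insufficient_unloading_range(self):
        alpha, h_f, m = 2.0, 120.0, 1.7
        c, hmax = synthetic_unload(alpha, h_f, m)
        truncated = IndentCurve(c.time_s[:100], c.load_uN[:100],
                                c.disp_nm[:100])
        seg = segment_curve(truncated, hold_tolerance=1e-6)
        with pytest.raises(InsufficientDataError):
            unloading_stiffness(seg)

    def test_secant_strategy_on_linear_unload(self):
        S0, h_f = 5.0, 100.0
        c, _ = synthetic_unload(S0, h_f, 1.0)
        seg = segment_curve(c, hold_tolerance=1e-6)
        S, *_ = unloading_stiffness(seg, strategy=StiffnessStrategy.SECANT)
        assert S == pytest.approx(S0, rel=1e-6)


class TestContactMechanics:
    def test_spherical_area_with_reference_probe(self, probe):
        # R = 1.03 μm, hc = 0.1 μm -> pi (0.206 - 0.01)
        assert contact_area(100.0, probe) == pytest.approx(
            math.pi * (2 * 1.03 * 0.1 - 0.01), rel=1e-12)

    def test_area_limits(self, probe):
        assert contact_area(1e-6, probe) < 1e-8
        r_nm = probe.radius_um * 1000
        assert contact_area(r_nm, probe) == pytest.approx(
            math.pi * probe.radius_um ** 2, rel=1e-12)
        with pytest.raises(ValueError):
            contact_area(2 * r_nm, probe)

    def test_reduced_modulus_closed_form(self):
        # beta=1, A=pi μm², S=2000 μN/μm  ->  Er = 1 GPa exactly
        probe = ProbeGeometry(beta=1.0)
        er = reduced_modulus(2000.0 / 1000.0, math.pi, probe)
        assert er == pytest.approx(1.0, rel=1e-12)

    def test_modulus_homogeneity(self, probe):
        base = reduced_modulus(2.0, 1.0, probe)
        assert reduced_modulus(4.0, 1.0, probe) == pytest.approx(
            2 * base, rel=1e-12)
        assert reduced_modulus(2.0, 4.0, probe) == pytest.approx(
            base / 2, rel=1e-12)

    def test_hardness_closed_forms(self):
        assert hardness(1000.0, 2.0) == pytest.approx(0.5, rel=1e-12)
        assert hardness(1.0, 1.0) == pytest.approx(0.001, rel=1e-12)
        with pytest.raises(ValueError):
            hardness(1000.0, 0.0)


class TestAnalyzeIndent:
    def test_noiseless_roundtrip(self, probe):
        c = generate_indent_curve(20.0, 0.6, probe, noise=0.0, seed=0)
        res = analyze_indent(c, probe)
        assert res.Er_GPa == pytest.approx(20.0, rel=0.02)
        assert res.H_GPa == pytest.approx(0.6, rel=0.02)

    def test_hardness_times_area_is_peak_load(self, probe):
        for er, h in [(10, 0.4), (20, 0.8), (30, 1.2)]:
            c = generate_indent_curve(er, h, probe, noise=0.003, seed=er)
            res = analyze_indent(c, probe)
            assert res.H_GPa * res.A_um2 * 1000.0 == pytest.approx(
                res.Pmax_uN, rel=1e-12)

    def test_contact_depth_identity(self, probe):
        c = generate_indent_curve(20.0, 0.6, probe, noise=0.0, seed=0)
        res = analyze_indent(c, probe)
        assert res.hc_nm == pytest.approx(
            res.hmax_nm - probe.epsilon * res.Pmax_uN / res.S_uN_per_nm,
            abs=1e-9)

    def test_hertzian_loading_scale_invariance(self, probe):
        # scaling h by 2 and P by 2^1.5 leaves the Hertz modulus estimate
        # 3P/(4 sqrt(R) h^1.5) unchanged
        c = generate_indent_curve(20.0, 0.6, probe, noise=0.0, seed=0)
        load = slice(5, 900)  # loading branch, away from P=0

        def hertz_er(curve, scale_h=1.0, scale_p=1.0):
            p = scale_p * curve.load_uN[load]
            h_um = scale_h * curve.disp_nm[load] / 1000.0
            return np.median(3 * p / (4 * np.sqrt(probe.radius_um) * h_um ** 1.5))

        assert hertz_er(c, 2.0, 2 ** 1.5) == pytest.approx(hertz_er(c),
                                                           rel=1e-9)

    def test_loading_branch_is_hertzian(self, probe):
        c = generate_indent_curve(25.0, 0.8, probe, noise=0.0, seed=0)
        seg = segment_curve(c)
        p = c.load_uN[10:seg.load_end]
        h = c.disp_nm[10:seg.load_end]
        slope = np.polyfit(np.log(h), np.log(p), 1)[0]
        assert slope == pytest.approx(1.5, abs=0.01)

    def test_unit_conversion_invariance(self, probe):
        c = generate_indent_curve(20.0, 0.6, probe, noise=0.002, seed=1)
        disp_um = c.disp_nm / 1000.0  # export in μm, re-import in nm
        c2 = IndentCurve(c.time_s, c.load_uN, disp_um * 1000.0)
        r1, r2 = analyze_indent(c, probe), analyze_indent(c2, probe)
        assert r2.Er_GPa == pytest.approx(r1.Er_GPa, rel=1e-6)
        assert r2.H_GPa == pytest.approx(r1.H_GPa, rel=1e-6)

    def test_noisy_recovery_grid(self, probe):
        errs = []
        for er in (10.0, 20.0, 30.0):
            for h in (0.4, 0.8, 1.2):
                for seed in range(10):
                    c = generate_indent_curve(er, h, probe, noise=0.005,
                                              seed=seed)
                    res = analyze_indent(c, probe)
                    errs.append([abs(res.Er_GPa / er - 1),
                                 abs(res.H_GPa / h - 1)])
        med = np.median(np.asarray(errs), axis=0)
        assert med[0] < 0.05 and med[1] < 0.05
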
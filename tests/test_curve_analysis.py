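"""Guinier/cross-section fits, P(r) transform, extrapolation, differences."""

import numpy as np
import pytest

import flexsas as fx
from flexsas.curve_analysis import pr_transform
from flexsas.curves import ScatteringCurve

from conftest import exact_cylinder_curve, exact_sphere_curve


class TestGuinier:
    def test_exact_guinier_law_recovered_to_machine_precision(self):
        q = np.linspace(0.13, 0.30, 80)
        for rg, i0 in [(5.0, 7.0), (5.96, 1.0), (2.0, 3.3)]:
            c = ScatteringCurve(q, i0 * np.exp(-(rg * q) ** 2 / 3))
            g = fx.guinier_fit(c, window=(0.13, 0.30), qrg_limit=10)
            assert g.rg == pytest.approx(rg, rel=1e-10)
            assert g.i0 == pytest.approx(i0, rel=1e-10)

    def test_solid_sphere_guinier_radius(self):
        """Rg of a uniform sphere is sqrt(3/5) R.

        The sphere's ln I picks up a negative quartic term, so the fit
        sits in the low-Q.Rg part of the validity range.
        """
        r = 5.0
        rg_true = np.sqrt(3.0 / 5.0) * r
        c = exact_sphere_curve(radius=r)
        g = fx.guinier_fit(c, window=(0.05, 0.65 / rg_true))
        assert g.rg == pytest.approx(rg_true, rel=0.01)
        assert g.valid

    def test_low_q_upturn_raises(self):
        q = np.linspace(0.13, 0.3, 30)
        c = ScatteringCurve(q, 1.0 + 5 * q**2)
        with pytest.raises(ValueError, match="aggregation"):
            fx.guinier_fit(c, window=(0.13, 0.3))

    def test_nonpositive_points_dropped_with_warning(self):
        q = np.linspace(0.13, 0.3, 30)
        i = np.exp(-25 * q**2 / 3)
        i[5] = -1e-6
        with pytest.warns(UserWarning, match="non-positive"):
            g = fx.guinier_fit(ScatteringCurve(q, i), window=(0.13, 0.3))
        assert g.n_points == 29

    def test_qrg_limit_flag(self):
        c = exact_sphere_curve(radius=5.0)
        g = fx.guinier_fit(c, window=(0.05, 1.0), qrg_limit=1.5)
        assert not g.valid  # Q.Rg reaches 3.9 in this window


class TestCrossSection:
    def test_exact_cross_section_law(self):
        rxs = 2.46
        q = np.linspace(0.28, 0.51, 60)
        c = ScatteringCurve(q, np.exp(-(rxs * q) ** 2 / 2) / q)
        r = fx.cross_section_fit(c, "xs-1", window=(0.28, 0.51))
        assert r.rxs == pytest.approx(rxs, rel=1e-10)

    def test_long_cylinder_rxs_is_rc_over_sqrt2(self):
        rc = 2.0
        c = exact_cylinder_curve(rc=rc)
        r = fx.cross_section_fit(c, "xs-1", window=(0.15, 0.5))
        assert r.rxs == pytest.approx(rc / np.sqrt(2), rel=0.02)

    def test_scaling_invariance(self):
        c = exact_cylinder_curve(rc=2.0)
        r1 = fx.cross_section_fit(c, "xs-1", window=(0.15, 0.5))
        r2 = fx.cross_section_fit(c.scaled(37.0), "xs-1", window=(0.15, 0.5))
        assert r1.rxs == pytest.approx(r2.rxs, rel=1e-12)

    def test_inner_region_steeper_than_outer(self):
        # two-component cross-section, the antibody-like pattern: a steep
        # inner region and a flatter outer one
        q = np.linspace(0.2, 1.1, 300)
        iq = np.exp(-(2.46 * q) ** 2 / 2) + 0.25 * np.exp(-(1.0 * q) ** 2 / 2)
        c = ScatteringCurve(q, iq / q)
        r1 = fx.cross_section_fit(c, "xs-1", window=(0.28, 0.51))
        r2 = fx.cross_section_fit(c, "xs-2", window=(0.56, 1.01))
        assert r1.rxs > r2.rxs

    def test_window_outside_range_rejected(self):
        c = exact_cylinder_curve(rc=2.0, qmax=1.0)
        with pytest.raises(ValueError, match="range"):
            fx.cross_section_fit(c, "xs-2", window=(0.56, 1.5))


class TestPrTransform:
    def test_sphere_dmax_and_single_peak(self):
        r = 5.0
        c = exact_sphere_curve(radius=r, qmax=3.0, n=500)
        pr = pr_transform(c, dmax=13.0)
        assert pr.length == pytest.approx(2 * r, rel=0.05)
        assert len(pr.peaks) == 1

    def test_two_point_scatterers_peak_at_separation(self):
        d = 8.0
        q = np.linspace(0.05, 3.0, 400)
        i = 0.5 * (1.0 + np.sin(q * d) / (q * d))
        pr = pr_transform(ScatteringCurve(q, i), dmax=12.0)
        assert pr.peaks[-1] == pytest.approx(d, abs=0.4)

    def test_forward_transform_consistency_and_rg_agreement(self):
        """P(r) fit reproduces I(Q); Rg from P(r) matches Guinier Rg."""
        c = exact_sphere_curve(radius=5.0, qmax=2.5, n=400)
        pr = pr_transform(c, dmax=12.0)
        resid = np.abs(pr.fitted_i - c.i)
        assert resid.max() < 0.02 * c.i.max()
        g = fx.guinier_fit(c, window=(0.05, 1.5 / 3.873))
        assert pr.rg == pytest.approx(g.rg, rel=0.03)

    def test_pr_nonnegative_with_endpoints_zero(self):
        c = exact_sphere_curve(radius=5.0)
        pr = pr_transform(c, dmax=12.0)
        assert pr.pr.min() >= 0
        assert pr.pr[0] == 0 and pr.pr[-1] == 0

    def test_insufficient_q_range_rejected(self):
        q = np.linspace(0.05, 0.2, 30)
        c = ScatteringCurve(q, np.exp(-q**2))
        with pytest.raises(ValueError, match="resolve"):
            pr_transform(c, dmax=10.0)


class TestExtrapolation:
    def test_identity_on_concentration_independent_series(self):
        q = np.linspace(0.13, 2.0, 200)
        base = np.exp(-(5.9 * q) ** 2 / 3)
        series = [
            ScatteringCurve(q, c * base, concentration=c)
            for c in (0.25, 0.5, 1.0)
        ]
        ex = fx.extrapolate_to_zero_concentration(series)
        assert np.allclose(ex.i, base, rtol=1e-10)

    def test_dimer_series_recovers_monomer(self, toy_dataset):
        """Rg drifts up with c; extrapolation lands on the pure monomer."""
        spec, model, curves, truth = toy_dataset
        rgs = [fx.guinier_fit(c).rg for c in curves]
        assert rgs[-1] > rgs[0]
        ex = fx.extrapolate_to_zero_concentration(curves)
        rg_extrap = fx.guinier_fit(ex).rg
        rg_true = fx.guinier_fit(truth.monomer_curve).rg
        assert rg_extrap == pytest.approx(rg_true, rel=0.01)
        assert rg_extrap < rgs[-1]

    def test_too_few_concentrations_rejected(self):
        q = np.linspace(0.13, 1.0, 50)
        series = [ScatteringCurve(q, q * 0 + 1, concentration=c)
                  for c in (0.3, 0.6)]
        with pytest.raises(ValueError, match=">= 3"):
            fx.extrapolate_to_zero_concentration(series)

    def test_mismatched_grids_need_resample(self):
        qa = np.linspace(0.13, 1.0, 50)
        qb = np.linspace(0.14, 1.0, 60)
        series = [
            ScatteringCurve(qa, 0.3 * np.ones(50), concentration=0.3),
            ScatteringCurve(qb, 0.6 * np.ones(60), concentration=0.6),
            ScatteringCurve(qa, 0.9 * np.ones(50), concentration=0.9),
        ]
        with pytest.raises(ValueError, match="resample"):
            fx.extrapolate_to_zero_concentration(series)
        ex = fx.extrapolate_to_zero_concentration(series, resample=True)
        assert np.allclose(ex.i, 1.0, atol=1e-9)


class TestDifferenceCurve:
    def test_self_difference_is_zero(self, toy_dataset):
        _, _, curves, _ = toy_dataset
        d = fx.difference_curve(curves[0], curves[0])
        assert np.allclose(d.i, 0.0)

    def test_same_structure_different_noise_consistent_with_zero(self):
        spec_a = fx.SyntheticSpec(seed=11)
        spec_b = fx.SyntheticSpec(seed=12)
        model, _ = fx.make_toy_antibody(spec_a)
        ca, _ = fx.simulate_curve_series(model, spec_a)
        cb, _ = fx.simulate_curve_series(model, spec_b)
        d = fx.difference_curve(ca[0], cb[0])
        frac = np.mean(np.abs(d.i) <= 2.0 * d.sigma)
        assert frac > 0.93

    def test_distinct_conformations_differ_in_contiguous_band(self):
        spec = fx.SyntheticSpec(seed=5, noise_a=1e-4)
        m1, _ = fx.make_toy_antibody(spec)
        spec2 = fx.SyntheticSpec(seed=5, noise_a=1e-4, arm_angle=25.0)
        m2, _ = fx.make_toy_antibody(spec2)
        c1, _ = fx.simulate_curve_series(m1, spec)
        c2, _ = fx.simulate_curve_series(m2, spec2)
        d = fx.difference_curve(c1[0], c2[0])
        sig = np.abs(d.i) > 2.0 * d.sigma
        # longest contiguous significant run
        runs, cur = 0, 0
        for flag in sig:
            cur = cur + 1 if flag else 0
            runs = max(runs, cur)
        assert runs >= 20

    def test_grid_mismatch_rejected(self):
        qa = np.linspace(0.13, 1.0, 50)
        qb = np.linspace(0.14, 1.0, 50)
        with pytest.raises(ValueError, match="grid"):
            fx.difference_curve(
                ScatteringCurve(qa, np.ones(50)),
                ScatteringCurve(qb, np.ones(50)),
            )
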
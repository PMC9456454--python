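"""Tensile and bending curve analysis against closed-form oracles."""

import numpy as np
import pytest

from osteospec import synth
from osteospec.biomech import (
    BendingCurve,
    BiomechError,
    TensileCurve,
    analyze_bending,
    analyze_tensile,
    bending_stiffness,
    cross_sectional_area,
    detect_failure,
    elastic_modulus,
    final_ramp,
    post_yield_displacement,
    to_stress_strain,
    toughness,
    ultimate_point,
    work_to_fracture,
    yield_point,
)
from osteospec.synth import MechRecipe, synth_bending, synth_tensile


class TestCSA:
    def test_identity_and_arithmetic(self):
        assert cross_sectional_area(1.12 * 5.0, 5.0, 1.12) == pytest.approx(1.0)
        assert cross_sectional_area(1.45, 5.5, 1.12) == pytest.approx(1.45 / (1.12 * 5.5))

    def test_linear_in_mass(self):
        one = cross_sectional_area(1.0, 5.0)
        assert cross_sectional_area(2.0, 5.0) == pytest.approx(2 * one)

    def test_rejects_nonpositive(self):
        with pytest.raises(BiomechError):
            cross_sectional_area(0.0, 5.0)


class TestStressStrain:
    def test_units(self):
        c = TensileCurve(displacement=np.linspace(0, 5, 50), force=np.full(50, 1.0),
                         mass=1.12 * 5.0 * 0.5, length=5.0)  # CSA = 0.5 mm^2
        strain, stress = to_stress_strain(c)
        assert stress[0] == pytest.approx(2.0)
        assert strain[-1] == pytest.approx(100.0)  # displacement == length

    def test_final_ramp_segmentation(self):
        # load/hold/unload cycle followed by the terminal ramp
        d = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0.2, 30),
                            np.linspace(0.2, 3, 100)])
        start = final_ramp(d)
        assert d[start] == pytest.approx(0.2)  # analysis starts at the unload end
        assert np.all(np.diff(d[start:]) >= 0)

    def test_generator_round_trip(self):
        r = MechRecipe(kind="tensile", elastic_slope=250, yield_y=15, ultimate_y=20,
                       ultimate_x=0.12, toe_x=0.02, mass=1.45, length=5.5)
        curve, truth = synth_tensile(r, 0)
        strain, stress = to_stress_strain(curve)
        k = np.argmax(stress)
        assert stress[k] == pytest.approx(truth["ultimate_y"], rel=1e-9)
        assert strain[k] / 100 == pytest.approx(truth["ultimate_x"], rel=1e-9)


class TestElasticModulus:
    def test_pure_linear(self):
        strain = np.linspace(0, 20, 200)  # percent
        stress = 50 * strain / 100
        stress[-3:] = 0  # fracture tail so failure detection fires
        assert elastic_modulus(strain, stress) == pytest.approx(50, rel=1e-6)

    def test_bilinear_toe_then_linear(self):
        r = MechRecipe(kind="tensile", elastic_slope=50, yield_y=4.0, ultimate_y=4.5,
                       ultimate_x=0.25, toe_x=0.05, mass=1.0, length=5.0)
        curve, _ = synth_tensile(r, 0)
        strain, stress = to_stress_strain(curve)
        assert elastic_modulus(strain, stress) == pytest.approx(50, rel=0.01)

    def test_noise_robustness_vs_clean_oracle(self):
        r = MechRecipe(kind="tensile", elastic_slope=250, yield_y=15, ultimate_y=20,
                       ultimate_x=0.12, toe_x=0.02, mass=1.45, length=5.5)
        clean, _ = synth_tensile(r, 0)
        noisy, _ = synth_tensile(
            MechRecipe(**{**r.__dict__, "noise_sd": 0.005}), 5
        )
        e_clean = elastic_modulus(*to_stress_strain(clean))
        e_noisy = elastic_modulus(*to_stress_strain(noisy))
        assert abs(e_noisy - e_clean) / e_clean < 0.03

    def test_too_few_points(self):
        with pytest.raises(BiomechError):
            elastic_modulus(np.linspace(0, 1, 30), np.r_[np.linspace(0, 1, 15), np.zeros(15)])


class TestUltimateAndToughness:
    def test_triangle(self):
        strain = np.linspace(0, 15, 150)
        stress = np.where(strain <= 12, strain * 10 / 12, 0.0)
        u_stress, u_strain, detected = ultimate_point(strain, stress)
        assert (u_stress, u_strain) == (pytest.approx(10.0, rel=0.01), pytest.approx(12.0, rel=0.01))
        assert detected

    def test_plateau_then_drop(self):
        strain = np.linspace(0, 20, 200)
        stress = np.clip(strain, 0, 10)
        stress[strain > 15] = 0.0
        u_stress, _, _ = ultimate_point(strain, stress)
        assert u_stress == pytest.approx(10.0)

    def test_right_triangle_area(self):
        strain = np.linspace(0, 20, 1000)  # percent
        stress = np.where(strain <= 20, strain * 10 / 20, 0.0)
        # integral of stress over fractional strain: 1/2 * 0.2 * 10 = 1.0
        assert toughness(strain, stress) == pytest.approx(1.0, rel=0.01)

    def test_generator_closed_form(self):
        r = MechRecipe(kind="tensile", elastic_slope=250, yield_y=15, ultimate_y=20,
                       ultimate_x=0.12, toe_x=0.02, step=1.2e-4, mass=1.45, length=5.5)
        curve, truth = synth_tensile(r, 0)
        strain, stress = to_stress_strain(curve)
        assert toughness(strain, stress) == pytest.approx(truth["area_to_fracture"], rel=0.005)


class TestBending:
    def _recipe(self, **kw):
        base = dict(kind="bending", elastic_slope=60.0, yield_y=7.0, ultimate_y=10.0,
                    ultimate_x=0.4917, toe_x=0.05, step=5e-4)
        base.update(kw)
        return MechRecipe(**base)

    def test_linear_stiffness(self):
        d = np.linspace(1e-3, 1.0, 300)
        load = np.r_[120 * d[:-3], 0, 0, 0]
        c = BendingCurve(displacement=d, load=load)
        assert bending_stiffness(c) == pytest.approx(120, rel=0.01)

    def test_bilinear_stiffness_and_scale_invariance(self):
        curve, truth = synth_bending(self._recipe(), 0)
        k = bending_stiffness(curve)
        assert k == pytest.approx(60.0, rel=0.01)
        doubled = BendingCurve(displacement=2 * curve.displacement, load=2 * curve.load)
        assert bending_stiffness(doubled) == pytest.approx(k, rel=1e-6)

    def test_yield_secant_matches_analytic_crossing(self):
        r = self._recipe()
        curve, truth = synth_bending(r, 0)
        k = bending_stiffness(curve)
        y_load, y_disp, brittle = yield_point(curve, k)
        assert not brittle
        # analytic: toe-corrected origin d0 = toe/2 (elastic line intercept);
        # secant from d0 equals 0.9k where (Fy + kp*(d-dy))/(d-d0) = 0.9k
        d0, kp = r.toe_x / 2.0, r.post_yield_slope
        dy = r.yield_x
        d_star = (r.yield_y - kp * dy + 0.9 * r.elastic_slope * d0) / (0.9 * r.elastic_slope - kp)
        assert y_disp == pytest.approx(d_star, abs=2 * r.step)
        assert y_load == pytest.approx(r.evaluate(np.array([d_star]))[0], rel=0.01)

    def test_perfectly_linear_brittle(self):
        d = np.linspace(1e-3, 0.5, 200)
        load = np.r_[60 * d[:-3], 0, 0, 0]
        c = BendingCurve(displacement=d, load=load)
        res = analyze_bending(c)
        assert res.brittle
        assert res.yield_load == pytest.approx(res.ultimate_load, rel=1e-6)
        assert res.post_yield_displacement == pytest.approx(0.0, abs=2 * (d[1] - d[0]))

    def test_criteria_agree_on_smooth_curve(self):
        curve, _ = synth_bending(self._recipe(), 0)
        k = bending_stiffness(curve)
        y1, d1, _ = yield_point(curve, k, "secant10")
        y2, d2, _ = yield_point(curve, k, "offset")
        assert abs(y1 - y2) / y1 < 0.10


class TestFailureAndWork:
    def test_instant_drop_peak_index(self):
        v = np.r_[np.linspace(0, 10, 100), 0.0, 0.0, 0.0]
        idx, detected = detect_failure(v)
        assert detected and idx == 99

    def test_monotone_no_failure(self):
        v = np.linspace(0, 10, 100)
        idx, detected = detect_failure(v)
        assert not detected and idx == 99

    def test_generator_truth_index(self):
        curve, truth = synth_bending(
            MechRecipe(kind="bending", elastic_slope=60, yield_y=7, ultimate_y=10,
                       ultimate_x=0.49, toe_x=0.05, step=5e-4), 0)
        idx, detected = detect_failure(curve.load)
        assert detected
        assert curve.displacement[idx] == pytest.approx(truth["ultimate_x"], abs=2 * 5e-4)

    def test_rectangle_work(self):
        d = np.linspace(0, 2.0, 200)
        load = np.full_like(d, 5.0)
        c = BendingCurve(displacement=d, load=load)
        assert work_to_fracture(c, len(d) - 1) == pytest.approx(10.0, rel=1e-9)

    def test_bilinear_closed_form_work(self):
        r = MechRecipe(kind="bending", elastic_slope=60, yield_y=7, ultimate_y=10,
                       ultimate_x=0.4917, toe_x=0.05, step=2e-4)
        curve, truth = synth_bending(r, 0)
        idx, _ = detect_failure(curve.load)
        assert work_to_fracture(curve, idx) == pytest.approx(truth["area_to_fracture"], rel=0.005)

    def test_brittle_pyd_zero(self):
        c = BendingCurve(displacement=np.linspace(0, 1, 100), load=np.linspace(0, 5, 100))
        assert post_yield_displacement(c, 1.0, 50) == 0.0


class TestInvariants:
    def test_work_bound_and_yield_order(self):
        curve, _ = synth_bending(
            MechRecipe(kind="bending", elastic_slope=60, yield_y=7, ultimate_y=10,
                       ultimate_x=0.4917, toe_x=0.05, step=5e-4), 3)
        res = analyze_bending(curve)
        assert res.ultimate_load >= res.yield_load
        assert res.work_to_fracture >= 0.5 * res.yield_load * res.yield_displacement * 0.99

    def test_resampling_stability(self):
        r = MechRecipe(kind="tensile", elastic_slope=250, yield_y=15, ultimate_y=20,
                       ultimate_x=0.12, toe_x=0.02, step=1e-4, mass=1.45, length=5.5)
        fine, _ = synth_tensile(r, 0)
        coarse, _ = synth_tensile(MechRecipe(**{**r.__dict__, "step": 2e-4}), 0)
        rf = analyze_tensile(fine)
        rc = analyze_tensile(coarse)
        assert rc.elastic_modulus == pytest.approx(rf.elastic_modulus, rel=0.01)
        assert rc.toughness == pytest.approx(rf.toughness, rel=0.01)
        assert rc.ultimate_stress == pytest.approx(rf.ultimate_stress, rel=0.01)

    def test_tensile_cohort_recovery(self, tensile_cohort):
        from osteospec import pipeline

        specs, truth = tensile_cohort
        df = pipeline.run_tensile_cohort(specs)
        rec = pipeline.recovered_effects(df, ["elastic_modulus_MPa", "ultimate_stress_MPa"])
        tru = pipeline.recovered_effects(truth, ["elastic_modulus", "ultimate_stress"])
        assert rec["elastic_modulus_MPa"] == pytest.approx(tru["elastic_modulus"], abs=1.0)
        assert rec["ultimate_stress_MPa"] == pytest.approx(tru["ultimate_stress"], abs=1.0)
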
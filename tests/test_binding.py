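"""Co-sedimentation, charge matching, SPR processing and fitting."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pmbind as pb
from pmbind.binding import (association_response, dissociation_response,
                            langmuir_isotherm)
from pmbind.exceptions import FitError
from pmbind.synthetic import SensorgramParams


def _lane(sup, pel, lane_id="x"):
    return pb.GelLane(lane_id=lane_id, supernatant=sup, pellet=pel)


class TestPercentBinding:
    def test_everything_in_pellet_is_100(self):
        assert pb.percent_binding(_lane(0.0, 500.0)) == pytest.approx(100.0)

    def test_equal_bands_give_50(self):
        assert pb.percent_binding(_lane(320.0, 320.0)) == pytest.approx(50.0)

    def test_generator_metric_round_trip(self):
        lane = pb.simulate_gel_lane(1000.0, bound_fraction=0.25)
        assert pb.percent_binding(lane) == pytest.approx(25.0)

    def test_control_subtraction_floors_at_zero(self):
        active = _lane(900.0, 100.0)   # 10 %
        control = _lane(750.0, 250.0)  # 25 %
        assert pb.percent_binding(active, control) == 0.0
        assert pb.percent_binding(control, active) == pytest.approx(15.0)

    def test_zero_total_density_rejected(self):
        with pytest.raises(ValueError):
            pb.percent_binding(_lane(0.0, 0.0))

    @settings(deadline=None, max_examples=25)
    @given(sup=st.floats(0.0, 1e4), pel=st.floats(1e-3, 1e4),
           scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, sup, pel, scale):
        a = pb.percent_binding(_lane(sup, pel))
        b = pb.percent_binding(_lane(sup * scale, pel * scale))
        assert b == pytest.approx(a, rel=1e-9)


class TestChargeMatchedMolpercent:
    def test_bis_5_maps_to_tris_3p3(self):
        assert pb.charge_matched_molpercent("bis", 5.0, "tris") == 3.3

    def test_same_class_is_identity(self):
        assert pb.charge_matched_molpercent("bis", 5.0, "bis") == 5.0

    def test_mono_5_maps_to_tris_1p7(self):
        assert pb.charge_matched_molpercent("mono", 5.0, "tris") == 1.7

    @pytest.mark.parametrize("a,b", [("mono", "bis"), ("bis", "tris"),
                                     ("mono", "tris")])
    def test_involution_up_to_rounding(self, a, b):
        fwd = pb.charge_matched_molpercent(a, 5.0, b)
        back = pb.charge_matched_molpercent(b, fwd, a)
        assert back == pytest.approx(5.0, abs=0.1)

    def test_unknown_class_rejected(self):
        with pytest.raises(KeyError):
            pb.charge_matched_molpercent("tetra", 5.0, "bis")

    def test_alternative_charge_table(self):
        got = pb.charge_matched_molpercent(
            "bis", 5.0, "tris", charge_table=pb.PHYSIOLOGICAL_CHARGE)
        assert got == pytest.approx(round(5.0 * 4 / 6, 1))


class TestLipidComposition:
    def test_mol_percent_must_sum_to_100(self):
        with pytest.raises(ValueError):
            pb.LipidComposition({"POPC": 80.0, "POPE": 25.0})

    def test_standard_mixes(self):
        control = pb.make_pip_composition()
        assert control.species == {"POPC": 80.0, "POPE": 20.0}
        active = pb.make_pip_composition("PI(4,5)P2", 5.0)
        assert active.species["POPC"] == 75.0
        ps_mix = pb.make_pip_composition("PI(4,5)P2", 5.0, ps_molpct=20.0)
        assert ps_mix.species == {"POPC": 55.0, "POPE": 20.0, "POPS": 20.0,
                                  "PI(4,5)P2": 5.0}


class TestSubtractControl:
    def _sg(self, resp, t=None, conc=1e-7):
        t = np.arange(len(resp), dtype=float) if t is None else t
        phase = np.array(["association"] * len(resp), dtype=object)
        return pb.Sensorgram(t, np.asarray(resp, float), phase, conc)

    def test_identical_channels_cancel(self):
        sg = self._sg([1.0, 2.0, 3.0, 4.0])
        out = pb.subtract_control(sg, sg)
        assert np.allclose(out.response, 0.0)

    def test_constant_offset_is_removed(self):
        active = self._sg([10.0, 11.0, 12.0])
        control = self._sg([3.0, 3.0, 3.0])
        out = pb.subtract_control(active, control)
        assert np.allclose(out.response, [7.0, 8.0, 9.0])

    def test_staggered_grid_matches_analytic_difference(self):
        """Control on a shifted grid: interpolated subtraction equals the
        difference of the two generating closed forms on the active grid."""
        t_active = np.linspace(0.0, 50.0, 101)
        t_control = np.linspace(-0.3, 50.3, 173)
        f_active = lambda t: 80.0 * (1 - np.exp(-0.05 * t))
        f_control = lambda t: 0.02 * t + 1.5
        active = self._sg(f_active(t_active), t=t_active)
        control = self._sg(f_control(t_control), t=t_control)
        out = pb.subtract_control(active, control)
        expected = f_active(t_active) - f_control(t_active)
        assert np.allclose(out.response, expected, atol=1e-9)

    def test_non_overlapping_ranges_rejected(self):
        active = self._sg([1.0, 2.0], t=np.array([10.0, 11.0]))
        control = self._sg([1.0, 2.0], t=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            pb.subtract_control(active, control)


class TestExtractReq:
    def test_saturated_curve_recovers_asymptote_within_1_percent(self):
        p = SensorgramParams(k_a=1e5, k_d=0.01, R_max=100.0,
                             analyte_conc=1e-6, t_assoc=3000.0, noise_sd=0.0)
        sg = pb.simulate_sensorgram(p)
        Req = p.R_max * p.analyte_conc / (p.analyte_conc + p.k_d / p.k_a)
        assert pb.extract_Req(sg) == pytest.approx(Req, rel=0.01)

    def test_constant_response_returns_it(self):
        t = np.arange(100, dtype=float)
        phase = np.array(["association"] * 100, dtype=object)
        sg = pb.Sensorgram(t, np.full(100, 42.0), phase, 1e-7)
        assert pb.extract_Req(sg) == pytest.approx(42.0)

    def test_full_phase_window_on_rising_curve_is_biased_low(self):
        p = SensorgramParams(k_a=1e5, k_d=0.01, analyte_conc=1e-7,
                             t_assoc=50.0, noise_sd=0.0)
        sg = pb.simulate_sensorgram(p)
        asymptote = sg.select("association").response[-1]
        mean_all = pb.extract_Req(sg, window=50.0)
        assert mean_all < asymptote

    def test_window_longer_than_phase_rejected(self):
        sg = pb.simulate_sensorgram(SensorgramParams(t_assoc=100.0))
        with pytest.raises(ValueError):
            pb.extract_Req(sg, window=200.0)


class TestFitIsotherm:
    def test_noiseless_round_trip_250nM(self):
        concs = np.geomspace(20e-9, 3000e-9, 8)
        data = pb.simulate_isotherm(250e-9, 80.0, concs)
        fit = pb.fit_isotherm(data)
        assert fit.Kd == pytest.approx(250e-9, rel=1e-6)
        assert fit.Rmax == pytest.approx(80.0, rel=1e-6)

    def test_fixed_Rmax_Kd_equals_conc_at_half_response(self):
        conc_half = 400e-9
        concs = np.array([50e-9, conc_half, 2000e-9])
        Req = langmuir_isotherm(concs, conc_half, 60.0)
        assert Req[1] == pytest.approx(30.0)
        fit = pb.fit_isotherm(pb.IsothermData(concs, Req), fix_Rmax=60.0)
        assert fit.Kd == pytest.approx(conc_half, rel=1e-6)

    def test_reported_pip2_affinity_round_trip(self):
        """340 nM generating Kd over the 10-3000 nM range is recovered."""
        concs = np.geomspace(10e-9, 3000e-9, 8)
        data = pb.simulate_isotherm(340e-9, 100.0, concs)
        fit = pb.fit_isotherm(data)
        assert fit.Kd == pytest.approx(340e-9, rel=1e-6)

    def test_model_identity_half_response_at_fitted_Kd(self):
        concs = np.geomspace(10e-9, 3000e-9, 10)
        data = pb.simulate_isotherm(500e-9, 90.0, concs, noise_sd=2.0, seed=4)
        fit = pb.fit_isotherm(data)
        assert fit.predict([fit.Kd])[0] == pytest.approx(fit.Rmax / 2, rel=1e-9)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(FitError):
            pb.fit_isotherm(pb.IsothermData(np.array([1e-7, 2e-7]),
                                            np.array([10.0, 20.0])))

    def test_not_spanning_Kd_warns_ill_conditioned(self):
        concs = np.linspace(1e-9, 10e-9, 5)  # far below the true Kd
        data = pb.simulate_isotherm(1e-6, 100.0, concs)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            pb.fit_isotherm(data)


class TestFitKinetics:
    def _sensorgrams(self, ka=1e5, kd=0.034, concs=(1.0, 2.0, 4.0)):
        Kd = kd / ka
        return [pb.simulate_sensorgram(SensorgramParams(
            k_a=ka, k_d=kd, analyte_conc=c * Kd, t_assoc=300.0,
            t_dissoc=150.0, noise_sd=0.0)) for c in concs]

    def test_pure_exponential_decay_recovers_kd(self):
        t = np.arange(0.0, 150.0, 1.0)
        resp = dissociation_response(t, 50.0, 0.01)
        phase = np.array(["dissociation"] * len(t), dtype=object)
        sg_d = pb.Sensorgram(t, resp, phase, 1e-7)
        from pmbind.binding import _fit_dissociation
        assert _fit_dissociation(sg_d) == pytest.approx(0.01, rel=1e-9)

    def test_noiseless_round_trip(self):
        kin = pb.fit_kinetics(self._sensorgrams())
        assert kin.k_a == pytest.approx(1e5, rel=1e-4)
        assert kin.k_d == pytest.approx(0.034, rel=1e-4)

    def test_kobs_regression_intercept_matches_kd(self):
        kin = pb.fit_kinetics(self._sensorgrams())
        assert kin.k_obs_intercept == pytest.approx(kin.k_d, rel=1e-3)

    def test_kobs_is_linear_in_concentration(self):
        kin = pb.fit_kinetics(self._sensorgrams())
        for conc, kobs in kin.k_obs.items():
            assert kobs == pytest.approx(1e5 * conc + 0.034, rel=1e-4)

    def test_kinetic_equilibrium_consistency(self):
        """k_d/k_a from kinetics equals the isotherm Kd on noiseless data."""
        ka, kd = 1e5, 0.034
        kin = pb.fit_kinetics(self._sensorgrams(ka=ka, kd=kd))
        concs = np.geomspace(10e-9, 3000e-9, 8)
        fit = pb.fit_isotherm(pb.simulate_isotherm(kd / ka, 100.0, concs))
        assert kin.Kd_kinetic == pytest.approx(fit.Kd, rel=1e-3)

    def test_single_concentration_rejected(self):
        with pytest.raises(FitError):
            pb.fit_kinetics(self._sensorgrams(concs=(2.0,)))
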
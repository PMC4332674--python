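"""Voltage-clamp integration, half-times and protocol analyses."""

import math

import numpy as np
import pytest

from kvmech import MSModulation, get_scheme, measure_shift, stationary_distribution
from kvmech.kinetics_engine import (
    Segment,
    VoltageProtocol,
    finite_pulse_gv,
    halftimes,
    integrate,
    onset_halftime,
    step_response,
    tail_gv_family,
    tail_halftime,
)


class TestIntegrate:
    def test_occupancy_conserved_along_trace(self, scheme3_wt):
        proto = VoltageProtocol(
            (Segment(0.02, -100.0), Segment(0.1, 40.0), Segment(0.05, -100.0))
        )
        tr = integrate(scheme3_wt, None, proto)
        assert np.abs(tr.occupancy.sum(axis=1) - 1.0).max() < 1e-8
        assert np.all(tr.popen >= -1e-12) and np.all(tr.popen <= 1.0 + 1e-12)

    def test_long_time_limit_matches_stationary(self, scheme1, rng):
        for v in rng.uniform(-100.0, 60.0, 5):
            p0 = np.zeros(scheme1.n_states)
            p0[0] = 1.0
            proto = VoltageProtocol((Segment(5.0, v),), initial_condition=p0)
            tr = integrate(scheme1, None, proto)
            assert np.abs(
                tr.occupancy[-1] - stationary_distribution(scheme1, v)
            ).max() < 1e-6

    def test_expm_and_bdf_agree(self, scheme3_wt):
        proto = VoltageProtocol((Segment(0.02, -100.0), Segment(0.05, 20.0)))
        a = integrate(scheme3_wt, None, proto, method="expm")
        b = integrate(scheme3_wt, None, proto, method="bdf")
        assert np.abs(a.occupancy - b.occupancy).max() < 1e-6

    def test_recovery_from_inactivation_single_exponential(self, scheme2):
        # all channels slow-inactivated, held at -100 mV: the available
        # fraction after 240 s follows 1 - exp(-recov * t)
        proto = VoltageProtocol(
            (Segment(240.0, -100.0),), initial_condition="all_inactivated"
        )
        tr = integrate(scheme2, None, proto)
        available = 1.0 - tr.occupancy[-1, scheme2.inactivated_index]
        assert available == pytest.approx(1.0 - math.exp(-0.005 * 240.0), abs=0.005)

    def test_sigmoidal_onset_after_strong_step(self, scheme1):
        tr = step_response(scheme1, None, -100.0, 60.0, 0.01)
        # multi-state delay: the steepest rise is not at the step itself
        assert int(np.argmax(np.diff(tr.popen))) > 10
        plateau = stationary_distribution(scheme1, 60.0)[scheme1.open_index]
        assert tr.popen[-1] == pytest.approx(plateau, abs=1e-4)

    def test_invalid_protocols_rejected(self, scheme1):
        with pytest.raises(ValueError):
            Segment(0.0, -100.0)
        proto = VoltageProtocol(
            (Segment(0.1, 0.0),), initial_condition="all_inactivated"
        )
        with pytest.raises(ValueError):
            integrate(scheme1, None, proto)


class TestHalftimes:
    def test_lms_slows_tails_by_sqrt_m(self, scheme3_wt):
        # at strongly hyperpolarized voltages the tail rate tracks k_c,
        # which the symmetric split divides by sqrt(m)
        m = 14.4 / 4.0
        control = tail_halftime(scheme3_wt, None, 40.0, -120.0)
        stretch = tail_halftime(scheme3_wt, MSModulation.lms(m), 40.0, -120.0)
        assert stretch / control == pytest.approx(math.sqrt(m), rel=0.10)

    def test_vms_tails_stretch_insensitive(self, scheme3_wt):
        control = tail_halftime(scheme3_wt, None, 40.0, -120.0)
        stretch = tail_halftime(
            scheme3_wt, MSModulation.vms_concerted(15.6 / 5.0), 40.0, -120.0
        )
        assert abs(stretch - control) / control < 0.05

    def test_crossover_voltages_reported(self, scheme3_wt):
        rep_vms = halftimes(scheme3_wt, None, MSModulation.vms_concerted(15.6 / 5.0))
        rep_lms = halftimes(scheme3_wt, None, MSModulation.lms(14.4 / 4.0))
        assert rep_vms.crossover_voltage is not None
        assert rep_lms.crossover_voltage is not None
        # stretch-acceleration of onset starts at more hyperpolarized
        # voltages for the vMS mechanism
        assert rep_vms.crossover_voltage < rep_lms.crossover_voltage
        assert rep_lms.tail_stretch > 1.5 * rep_lms.tail_control
        assert rep_vms.tail_stretch == pytest.approx(rep_vms.tail_control, rel=0.05)

    def test_expanded_barrier_accelerates_onset_demo(self, scheme_hh_l1):
        # transition state nearly at the expanded conformation: the forward
        # thermal rate scales by m^0.95, a ~49-fold jump for m = 60 -- and
        # onset accelerates at every voltage, unlike any observed stretch
        # response
        from kvmech.ms_modulation import apply_modulation

        mod = MSModulation.lms(60.0, barrier_position=0.95)
        s = apply_modulation(scheme_hh_l1, mod)
        (t,) = s.transitions_of_kind("thermal")
        assert t.forward.prefactor / 100.0 == pytest.approx(
            60.0**0.95, rel=1e-12
        )
        assert 60.0**0.95 == pytest.approx(48.9, abs=0.1)
        for v in (0.0, 60.0):
            assert onset_halftime(scheme_hh_l1, mod, -100.0, v) < 0.5 * (
                onset_halftime(scheme_hh_l1, None, -100.0, v)
            )


class TestTailFamilies:
    def test_recovering_system_grows_across_runs(self, scheme2):
        curves = tail_gv_family(scheme2)
        assert len(curves) == 4
        above_foot = curves[0].voltage >= -20.0
        for early, late in zip(curves, curves[1:]):
            assert np.all(
                late.popen[above_foot] > early.popen[above_foot]
            )

    def test_first_run_has_inclined_plateau(self, scheme2):
        curves = tail_gv_family(scheme2)

        def plateau_slope(c):
            hi = c.popen[c.voltage >= 20.0]
            return (hi[-1] - hi[0]) / hi[-1]

        assert plateau_slope(curves[0]) > 5 * plateau_slope(curves[-1])
        assert plateau_slope(curves[0]) > 0.05

    def test_equilibrated_start_gives_near_identical_runs(self, scheme2):
        # from the holding-potential equilibrium the four runs coincide up
        # to the slight slow inactivation the acquisition itself causes,
        # an order of magnitude below the recovery-driven growth
        p0 = stationary_distribution(scheme2, -100.0)
        curves = tail_gv_family(scheme2, start=p0)
        drift = max(
            np.abs(c.popen - curves[0].popen).max() for c in curves[1:]
        )
        assert drift < 0.03
        recovering = tail_gv_family(scheme2)
        growth = np.abs(recovering[-1].popen - recovering[0].popen).max()
        assert growth > 5 * drift

    def test_missing_inactivated_state_rejected(self, scheme1):
        with pytest.raises(ValueError):
            tail_gv_family(scheme1)


class TestFinitePulse:
    def test_long_pulse_recovers_equilibrium(self, scheme3_wt):
        from kvmech.equilibrium_analysis import gv_curve

        grid = np.arange(-80.0, 61.0, 10.0)
        pulsed = finite_pulse_gv(scheme3_wt, pulse=5.0, test_voltages=grid)
        eq = gv_curve(scheme3_wt, voltages=grid)
        assert np.abs(pulsed.popen - eq.popen).max() < 1e-4

    def test_ilt_pulse_curve_far_right_of_wt(self, scheme3_ilt):
        g = finite_pulse_gv(scheme3_ilt, pulse=0.1)
        assert g.fit.v05 > 40.0

    def test_ilt_stretch_right_shifts_and_slows_onset(self, scheme3_ilt):
        stretch = MSModulation.ilt_vms(0.75)
        rest = finite_pulse_gv(scheme3_ilt, pulse=0.1)
        mod = finite_pulse_gv(scheme3_ilt, stretch, pulse=0.1)
        assert measure_shift(rest, mod) < -2.0  # right-shift
        assert onset_halftime(
            scheme3_ilt, stretch, -100.0, 120.0, duration=2.0
        ) > 1.1 * onset_halftime(scheme3_ilt, None, -100.0, 120.0, duration=2.0)

    def test_ilt_tail_time_course_unchanged_on_trace_timescale(self, scheme3_ilt):
        # over a 50 ms repolarization the Popen trajectories with and
        # without stretch are indistinguishable (closing is rate-limited
        # by the unmodulated thermal step on this timescale)
        stretch = MSModulation.ilt_vms(0.75)
        p_rest = stationary_distribution(scheme3_ilt, 160.0)
        from kvmech.ms_modulation import apply_modulation

        p_mod = stationary_distribution(
            apply_modulation(scheme3_ilt, stretch), 160.0
        )
        proto_r = VoltageProtocol((Segment(0.05, -100.0),), initial_condition=p_rest)
        proto_m = VoltageProtocol((Segment(0.05, -100.0),), initial_condition=p_mod)
        tr_r = integrate(scheme3_ilt, None, proto_r)
        tr_m = integrate(scheme3_ilt, stretch, proto_m)
        assert np.abs(tr_r.popen - tr_m.popen).max() < 0.02
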
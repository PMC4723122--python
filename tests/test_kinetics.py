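"""Forward-simulation contracts: conservation, limits, and oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import rk4_single_pool, rk4_two_pool
from pbutkin.errors import InfeasiblePrescriptionError
from pbutkin.kinetics import (
    CompartmentState,
    PhaseSpec,
    SoluteKinetics,
    initial_state,
    simulate_phase,
    simulate_single_pool,
    total_mass,
)
from pbutkin.study import SOLUTES


def session_phase(kin, quf=0.41, duration=240.0, G=None):
    return PhaseSpec.dialysis(duration, kin.K, quf, kin.G if G is None else G)


class TestEquilibriumAndLimits:
    def test_no_clearance_no_generation_is_fixed_point(self):
        kin = SoluteKinetics("x", K=0.0, K21=100.0, V1_0=10.0, Vtot_0=30.0, G=0.0)
        traj = simulate_phase(kin, PhaseSpec.dialysis(240, 0.0, 0.0, 0.0), initial_state(kin, 50.0))
        assert np.allclose(traj.C1, 50.0) and np.allclose(traj.C2, 50.0)
        assert traj.removal == pytest.approx(0.0, abs=1e-9)

    def test_well_mixed_limit_matches_exponential_decay(self):
        # K21 -> infinity collapses the system to one pool: C(t) = C0 exp(-K t / Vtot)
        kin = SoluteKinetics("x", K=200.0, K21=1e6, V1_0=10.0, Vtot_0=30.0, G=0.0)
        traj = simulate_phase(kin, PhaseSpec.dialysis(240, kin.K, 0.0, 0.0), initial_state(kin, 100.0))
        expected = 100.0 * np.exp(-kin.K / 1000.0 * (traj.time_grid) / kin.Vtot_0)
        assert np.max(np.abs(traj.C1 / expected - 1.0)) < 1e-3

    @pytest.mark.parametrize("k21", [1e3, 1e4, 1e6])
    def test_single_pool_limit_is_approached_monotonically(self, k21):
        kin = SoluteKinetics("x", K=150.0, K21=k21, V1_0=8.0, Vtot_0=25.0, G=0.1)
        phase = session_phase(kin)
        init = initial_state(kin, 40.0)
        two = simulate_phase(kin, phase, init)
        one = simulate_single_pool(kin, phase, init)
        sup = np.max(np.abs(two.C1 - one.C1) / one.C1)
        # distance shrinks roughly like 1/K21; at 1e6 the pools are one
        assert sup < 200.0 / k21

    def test_zero_clearance_single_and_two_pool_agree(self):
        kin = SoluteKinetics("x", K=0.0, K21=85.0, V1_0=4.0, Vtot_0=16.0, G=0.0)
        phase = PhaseSpec.dialysis(240, 0.0, 0.0, 0.0)
        init = initial_state(kin, 15.0)
        two = simulate_phase(kin, phase, init)
        one = simulate_single_pool(kin, phase, init)
        assert np.allclose(two.C1, 15.0) and np.allclose(one.C1, 15.0)


class TestOracleAgreement:
    @pytest.mark.parametrize("solute", SOLUTES)
    def test_adaptive_solver_matches_fine_step_rk4(self, solute, reference_bundles, reference_cpre):
        kin = reference_bundles[solute]
        c0 = reference_cpre[solute]
        quf_lpm = 0.41 / 60.0
        traj = simulate_phase(kin, session_phase(kin), initial_state(kin, c0))
        t_o, c1_o, c2_o, rem_o = rk4_two_pool(
            kin.K, kin.K21, kin.V1_0, kin.V2_0, kin.G, quf_lpm, c0, 240.0, dt=0.01
        )
        idx = np.searchsorted(t_o, traj.time_grid)
        assert np.max(np.abs(traj.C1 / c1_o[idx] - 1.0)) < 1e-3
        assert np.max(np.abs(traj.C2 / c2_o[idx] - 1.0)) < 1e-3
        assert traj.removal == pytest.approx(rem_o[-1], rel=1e-3)

    def test_single_pool_overestimates_early_decline_recovery(self, reference_bundles, reference_cpre):
        # early in the session the one-pool model's concentration stays higher:
        # the whole volume buffers the dialyzer, while the two-pool plasma pool
        # is drained faster than the deep pool can refill it
        kin = reference_bundles["urea"]
        c0 = reference_cpre["urea"]
        quf_lpm = 0.41 / 60.0
        _, c1_two, _, _ = rk4_two_pool(kin.K, kin.K21, kin.V1_0, kin.V2_0, kin.G, quf_lpm, c0, 60.0)
        _, c_one, _ = rk4_single_pool(kin.K, kin.Vtot_0, kin.G, quf_lpm, c0, 60.0)
        assert c_one[-1] > c1_two[-1]
        one = simulate_single_pool(kin, session_phase(kin), initial_state(kin, c0))
        two = simulate_phase(kin, session_phase(kin), initial_state(kin, c0))
        i60 = np.searchsorted(one.time_grid, 60.0)
        assert one.C1[i60] > two.C1[i60]
        assert one.C1[i60] == pytest.approx(c_one[-1], rel=1e-3)


class TestConservationAndVolumes:
    @pytest.mark.parametrize("solute", SOLUTES)
    @pytest.mark.parametrize("kind", ["dialysis", "interdialytic"])
    def test_mass_balance_closes(self, solute, kind, reference_bundles, reference_cpre):
        kin = reference_bundles[solute]
        c0 = reference_cpre[solute]
        if kind == "dialysis":
            phase = session_phase(kin)
        else:
            phase = PhaseSpec.interdialytic(2640.0, -1.64 / 44.0, kin.G)
        traj = simulate_phase(kin, phase, initial_state(kin, c0))
        m0 = total_mass(traj.initial_state)
        mT = total_mass(traj.final_state)
        resid = abs((mT - m0) - (phase.G * phase.duration - traj.removal))
        assert resid / max(m0, 1.0) < 1e-6

    def test_volume_bookkeeping_is_exact(self, reference_bundles):
        kin = reference_bundles["urea"]
        phase = session_phase(kin)
        traj = simulate_phase(kin, phase, initial_state(kin, 950.0))
        tau = traj.time_grid - traj.time_grid[0]
        expected = kin.Vtot_0 - phase.quf_l_per_min * tau
        assert np.allclose(traj.V1 + traj.V2, expected, rtol=1e-12)
        # proportional partition: the volume ratio is constant
        assert np.allclose(traj.V1 / traj.V2, kin.V1_0 / kin.V2_0, rtol=1e-12)

    @pytest.mark.parametrize("solute", SOLUTES)
    def test_deep_pool_declines_slower(self, solute, reference_bundles, reference_cpre):
        kin = reference_bundles[solute]
        traj = simulate_phase(kin, session_phase(kin), initial_state(kin, reference_cpre[solute]))
        assert np.all(traj.C2[1:] >= traj.C1[1:])

    @given(
        k=st.floats(0.0, 300.0),
        k21=st.floats(10.0, 1000.0),
        v1=st.floats(2.0, 15.0),
        v2=st.floats(2.0, 30.0),
        g=st.floats(0.0, 10.0),
        c0=st.floats(1.0, 1000.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conservation_property(self, k, k21, v1, v2, g, c0):
        kin = SoluteKinetics("x", K=k, K21=k21, V1_0=v1, Vtot_0=v1 + v2, G=g)
        phase = PhaseSpec.dialysis(240.0, k, 0.41, g)
        traj = simulate_phase(kin, phase, initial_state(kin, c0))
        m0 = total_mass(traj.initial_state)
        mT = total_mass(traj.final_state)
        assert abs((mT - m0) - (g * 240.0 - traj.removal)) / max(m0, 1.0) < 1e-6


class TestContracts:
    def test_total_mass_hand_values(self):
        assert total_mass(CompartmentState(0, 10.0, 20.0, 1.0, 1.0)) == pytest.approx(30.0)
        assert total_mass(CompartmentState(0, 5.0, 7.0, 0.0, 0.0)) == 0.0
        # predialysis urea: 32.9 L at 950 mg/L in both pools
        st_ = CompartmentState(0, 10.2, 22.7, 950.0, 950.0)
        assert total_mass(st_) == pytest.approx(31255.0)

    def test_overdrawn_ultrafiltration_is_rejected(self):
        kin = SoluteKinetics("x", K=100.0, K21=100.0, V1_0=3.0, Vtot_0=8.0, G=0.0)
        # 2.5 L/h over 4 h removes 10 L from an 8 L distribution volume
        with pytest.raises(InfeasiblePrescriptionError):
            simulate_phase(kin, PhaseSpec.dialysis(240, 100.0, 2.5, 0.0), initial_state(kin, 10.0))

    def test_trajectory_starts_at_initial_state(self, reference_bundles):
        kin = reference_bundles["IS"]
        init = initial_state(kin, 15.1)
        traj = simulate_phase(kin, session_phase(kin), init)
        assert traj.initial_state.C1 == pytest.approx(init.C1)
        assert traj.initial_state.V1 == pytest.approx(init.V1)
        assert np.all(np.diff(traj.time_grid) > 0)
        assert np.all(np.diff(traj.cumulative_removal) >= 0)

    def test_interdialytic_phase_requires_zero_clearance(self):
        with pytest.raises(ValueError):
            PhaseSpec("interdialytic", 100.0, 50.0, 0.0, 0.0)
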
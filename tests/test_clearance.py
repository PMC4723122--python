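"""Pointwise session metrics: clearances, binding, Kt/V, and their domains."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbutkin.clearance import (
    Anthropometrics,
    blood_side_clearance,
    dialysate_side_clearance,
    generation_rate,
    hemoconcentration_factor,
    plasma_volume_floor,
    protein_binding,
    reduction_ratio,
    session_clearance,
    sp_ktv_daugirdas,
)
from pbutkin.errors import (
    InfeasiblePrescriptionError,
    InvalidSampleError,
    MeasurementInconsistencyError,
    MissingDataError,
)
from pbutkin.samples import SamplePoint, SampleSheet, SessionPrescription


class TestBloodSideClearance:
    @pytest.mark.parametrize(
        "c_in,c_out,qb,quf,expected",
        [
            (500.0, 500.0, 300.0, 0.0, 0.0),
            (500.0, 0.0, 300.0, 0.0, 300.0),  # complete extraction
            (1000.0, 300.0, 300.0, 6.83, 212.049),
        ],
    )
    def test_values(self, c_in, c_out, qb, quf, expected):
        assert blood_side_clearance(c_in, c_out, qb, quf) == pytest.approx(expected, abs=0.05)

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidSampleError):
            blood_side_clearance(0.0, 10.0, 300.0, 0.0)
        with pytest.raises(MeasurementInconsistencyError):
            blood_side_clearance(100.0, 120.0, 300.0, 0.0)

    @given(
        c_in=st.floats(10.0, 2000.0),
        ratio=st.floats(0.0, 1.0),
        qb=st.floats(100.0, 400.0),
        quf=st.floats(0.0, 20.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_by_blood_flow(self, c_in, ratio, qb, quf):
        k = blood_side_clearance(c_in, ratio * c_in, qb, quf)
        assert 0.0 <= k <= qb + 1e-9


class TestDialysateSideClearance:
    def test_values(self):
        assert dialysate_side_clearance(0.0, 700.0, 30.0) == 0.0
        assert dialysate_side_clearance(0.9, 700.0, 30.0) == pytest.approx(21.0)

    def test_identity_is_linear_in_dialysate_concentration(self):
        k1 = dialysate_side_clearance(0.45, 700.0, 30.0)
        k2 = dialysate_side_clearance(0.9, 700.0, 30.0)
        assert k2 == pytest.approx(2 * k1)
        # K * C_in = Q_D * C_d exactly
        assert k2 * 30.0 == pytest.approx(700.0 * 0.9)

    def test_rejects_nonpositive_blood_concentration(self):
        with pytest.raises(InvalidSampleError):
            dialysate_side_clearance(0.9, 700.0, 0.0)


def _sheet_for_clearance(k30, k120, qb=300.0, quf_ml=0.0, solute="urea", drop_120=False):
    """Inlet/outlet pairs engineered to yield given 30- and 120-min clearances."""
    pts = []
    for t, k in ((30.0, k30), (120.0, k120)):
        c_in = 1000.0
        c_out = c_in * (qb - k) / (qb - quf_ml)
        pts.append(SamplePoint("P", solute, t, "inlet", c_in))
        if not (drop_120 and t == 120.0):
            pts.append(SamplePoint("P", solute, t, "outlet", c_out))
    return SampleSheet(pts)


class TestSessionClearance:
    def test_mean_of_both_time_points(self):
        rx = SessionPrescription(Q_B=300.0, Q_UF=0.0)
        sheet = _sheet_for_clearance(220.0, 228.0)
        assert session_clearance(sheet, rx, "urea") == pytest.approx(224.0)
        assert session_clearance(_sheet_for_clearance(200.0, 200.0), rx, "urea") == pytest.approx(200.0)

    def test_missing_time_point_raises(self):
        rx = SessionPrescription(Q_B=300.0, Q_UF=0.0)
        with pytest.raises(MissingDataError):
            session_clearance(_sheet_for_clearance(220.0, 228.0, drop_120=True), rx, "urea")


class TestProteinBinding:
    @pytest.mark.parametrize(
        "total,free,expected",
        [(100.0, 100.0, 0.0), (100.0, 5.0, 95.0), (100.0, 87.0, 13.0)],
    )
    def test_values(self, total, free, expected):
        assert protein_binding(total, free) == pytest.approx(expected)

    def test_free_above_total_rejected(self):
        with pytest.raises(InvalidSampleError):
            protein_binding(100.0, 101.0)

    @given(total=st.floats(1.0, 1000.0), frac=st.floats(0.0, 1.0), scale=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, total, frac, scale):
        pb = protein_binding(total, frac * total)
        pb_scaled = protein_binding(scale * total, scale * frac * total)
        assert pb == pytest.approx(pb_scaled, abs=1e-9)


class TestHemoconcentration:
    def test_values(self):
        assert hemoconcentration_factor(61.4, 61.4) == pytest.approx(1.0)
        assert hemoconcentration_factor(61.4, 68.2) == pytest.approx(0.900, abs=5e-4)

    def test_rising_protein_means_factor_below_one(self):
        assert hemoconcentration_factor(61.4, 70.0) < 1.0 < hemoconcentration_factor(61.4, 55.0)


class TestPlasmaVolumeFloor:
    def test_cohort_value(self):
        a = Anthropometrics(body_weight=75.0, hematocrit=0.372)
        assert plasma_volume_floor(a) == pytest.approx(3.62, abs=0.005)

    def test_limits(self):
        nearly_all_cells = Anthropometrics(body_weight=75.0, hematocrit=0.999999)
        assert plasma_volume_floor(nearly_all_cells) == pytest.approx(0.0, abs=1e-4)
        a = Anthropometrics(body_weight=40.0, hematocrit=0.372)
        b = Anthropometrics(body_weight=80.0, hematocrit=0.372)
        assert plasma_volume_floor(b) == pytest.approx(2 * plasma_volume_floor(a))


class TestGenerationRate:
    def test_values(self):
        assert generation_rate(0.0) == 0.0
        # either cycle convention brackets the reference urea value of 9.7 mg/min
        assert generation_rate(28300.0, 2880.0) == pytest.approx(9.83, abs=0.005)
        assert generation_rate(28300.0, 3120.0) == pytest.approx(9.07, abs=0.005)
        assert generation_rate(62.4, 3120.0) == pytest.approx(0.020)

    def test_default_cycle_is_midweek(self):
        assert generation_rate(3120.0) == pytest.approx(1.0)


class TestReductionRatio:
    def test_values(self):
        assert reduction_ratio(500.0, 500.0) == 0.0
        assert reduction_ratio(500.0, 0.0) == 100.0
        assert reduction_ratio(1130.0, 250.0) == pytest.approx(77.876, abs=0.001)

    @given(pre=st.floats(1.0, 1000.0), frac=st.floats(0.0, 1.0), scale=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, pre, frac, scale):
        assert reduction_ratio(pre, frac * pre) == pytest.approx(
            reduction_ratio(scale * pre, scale * frac * pre), abs=1e-9
        )


class TestDaugirdasKtV:
    def test_hand_value(self):
        assert sp_ktv_daugirdas(1000.0, 300.0, 4.0, 1.6, 75.0) == pytest.approx(1.380, abs=0.001)

    def test_limit_no_removal_no_uf(self):
        v = sp_ktv_daugirdas(1000.0, 999.9, 4.0, 0.0, 75.0)
        assert 0.0 < v < 0.04  # -> -ln(1 - 0.008 t) as R -> 1

    def test_cohort_plausibility(self):
        # a typical session: 70% urea reduction, 4 h, 1.6 L removed, 75 kg
        v = sp_ktv_daugirdas(950.0, 285.0, 4.0, 1.6, 75.0)
        assert 1.2 < v < 2.2

    def test_log_domain_violation(self):
        with pytest.raises(InfeasiblePrescriptionError):
            sp_ktv_daugirdas(1000.0, 25.0, 4.0, 1.6, 75.0)


def test_reference_clearance_ordering(reference_bundles):
    ks = {s: k.K for s, k in reference_bundles.items()}
    order = sorted(ks, key=ks.get, reverse=True)
    assert order == ["urea", "PCG", "HA", "IAA", "IS", "PCS"]
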
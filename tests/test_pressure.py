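import math

import numpy as np
import pytest

from scinject import (
    ConfigurationError,
    InjectionProtocol,
    InvalidInputError,
    Numerics,
    SkinModel,
    apparent_viscosity,
    gliding_force,
    needle_removal,
    phase12_pressure,
    pressure_factor,
    relaxation_flow,
    residual_pressure,
    simulate_pressure,
    stressed_volume,
)
from scinject.pressure import dead_volume, phase3_pressure

ETA_IF_PIG = 1.66  # mPa·s, healthy-human-average / pig validation value

FAST = Numerics(dt_injection=5e-3, dt_post=0.02, dt_leak=1e-4, horizon=None)


def protocol(**kw):
    base = dict(v_inj=500.0, q_inj=6000.0)
    base.update(kw)
    return InjectionProtocol(**base)


class TestGlidingForce:
    def test_reference_device(self, saline_protocol):
        assert gliding_force(saline_protocol) == pytest.approx(0.27, abs=0.01)

    def test_linear_in_viscosity_and_rate(self, saline_protocol):
        base = gliding_force(saline_protocol)
        double_eta = saline_protocol.model_copy(update={"formulation_viscosity": 2.0})
        half_q = saline_protocol.model_copy(update={"q_inj": 3000.0})
        assert gliding_force(double_eta) == pytest.approx(2 * base)
        assert gliding_force(half_q) == pytest.approx(base / 2)


class TestPressureFactor:
    def test_reference_scenario(self):
        assert pressure_factor(6000.0, 0.5) == pytest.approx(2 * math.log(24000) + 5, rel=1e-12)
        assert pressure_factor(6000.0, 0.5) == pytest.approx(25.2, abs=0.1)

    def test_floor_at_zero(self):
        v = 0.5
        q_boundary = v**2 * math.exp(-2.5)
        assert pressure_factor(q_boundary, v) == pytest.approx(0.0, abs=1e-12)
        assert pressure_factor(q_boundary / 2, v) == 0.0

    def test_monotone_in_rate(self):
        vals = [pressure_factor(q, 0.5) for q in (100, 1000, 6000, 12000)]
        assert vals == sorted(vals)


class TestApparentViscosity:
    def test_identity_when_equal(self):
        assert apparent_viscosity(2.5, 2.5) == pytest.approx(2.5)

    def test_ninety_ten_blend(self):
        assert apparent_viscosity(1.0, 2.08) == pytest.approx(1.972)

    def test_order_sensitive(self):
        assert apparent_viscosity(1.0, 3.0) != apparent_viscosity(3.0, 1.0)


class TestPhase12:
    def test_zero_at_injection_start(self, saline_protocol):
        assert phase12_pressure(0.0, saline_protocol, ETA_IF_PIG) == 0.0

    def test_linear_in_apparent_viscosity(self, saline_protocol):
        # doubling η_app (via a formulation/IF pair with exactly twice the
        # blend) doubles the Darcy pressure
        p1 = phase12_pressure(5.0, saline_protocol, eta_if=1.0)
        eta_if2 = (2 * apparent_viscosity(1.0, 1.0) - 0.1 * 1.0) / 0.9
        p2 = phase12_pressure(5.0, saline_protocol, eta_if=eta_if2)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_rejects_bad_conductivity(self, saline_protocol):
        with pytest.raises(InvalidInputError):
            phase12_pressure(1.0, saline_protocol, ETA_IF_PIG, k=0.0)

    def test_plateaus_after_elongation_onset(self, saline_protocol):
        # once the depot elongates, vertical growth (and hence the pressure)
        # nearly halts: < 3% rise over the last 40% of the injection
        p3 = phase12_pressure(3.0, saline_protocol, ETA_IF_PIG)
        p5 = phase12_pressure(5.0, saline_protocol, ETA_IF_PIG)
        assert p5 / p3 < 1.03


class TestStressedVolume:
    def test_fraction_of_injected(self):
        assert stressed_volume(2000.0) == pytest.approx(50.0)
        assert stressed_volume(0.0) == 0.0

    def test_epsilon_cancels(self):
        # 0.025 · (4/3)π ε WFH² WFV = 0.025 · V_injected for any ε
        from scinject import waterfronts

        for eps in (0.05, 0.13, 0.3):
            wfv, wfh = waterfronts(0.5, eps, 1.4)
            v_stress = 0.025 * 4.0 / 3.0 * math.pi * eps * wfh**2 * wfv
            assert v_stress == pytest.approx(stressed_volume(500.0), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            stressed_volume(-1.0)


class TestRelaxationFlow:
    def test_sphere_reduces_to_radius_squared(self):
        # with WFH = WFV = R the ellipsoid surface term is exactly R²
        p, eta, f, k, r = 10.0, 1.5, 20.0, 5.67e-17, 8.0
        q = relaxation_flow(p, r, r, eta, f, k)
        expected = k * p * 1000.0 / (f * eta * 1e-3 * 4 * math.pi * (r * 1e-3) ** 2) * 1e9
        assert q == pytest.approx(expected, rel=1e-12)

    def test_zero_pressure_zero_flow(self):
        assert relaxation_flow(0.0, 5.0, 8.0, 1.5, 20.0) == 0.0

    def test_zero_geometry_zero_flow(self):
        assert relaxation_flow(5.0, 0.0, 0.0, 1.5, 20.0) == 0.0


class TestPhase3:
    def test_initial_value(self):
        assert phase3_pressure(10.0, 0.0, 50.0, 1.5) == pytest.approx(11.5)

    def test_floor_at_bleb_pressure(self):
        assert phase3_pressure(10.0, 50.0, 50.0, 1.5) == pytest.approx(1.5)
        assert phase3_pressure(10.0, 80.0, 50.0, 1.5) == pytest.approx(1.5)

    def test_trace_monotone_non_increasing(self, saline_protocol):
        proto = saline_protocol.model_copy(update={"t_removal": 15.0})
        tr = simulate_pressure(proto, ETA_IF_PIG, numerics=FAST)
        sel = tr.phase == 3
        assert (np.diff(tr.p_tissue[sel]) <= 1e-12).all()

    def test_two_ml_injection_relaxes_within_seconds(self):
        # tissue component of a 2 mL / 120 mL/h injection decays below 3 kPa
        # within a few seconds of the end of injection
        proto = protocol(v_inj=2000.0, q_inj=2000.0, t_removal=70.0)
        tr = simulate_pressure(proto, ETA_IF_PIG, numerics=FAST)
        t_end = proto.t_end
        assert np.interp(t_end, tr.t, tr.p_tissue) > 10.0
        assert np.interp(t_end + 8.0, tr.t, tr.p_tissue) < 3.0


class TestNeedleRemoval:
    def test_dead_volume_reference_needle(self, saline_protocol):
        assert dead_volume(saline_protocol) == pytest.approx(1.82, abs=0.01)

    def test_loss_equals_dead_volume_when_depressurised(self):
        # long hold + zero skin stiffness: nothing drives the leak
        proto = protocol(t_removal=120.0)
        bf, _ = needle_removal(
            120.0, protocol(), 1.0, skin=SkinModel(stiffness=0.0), numerics=FAST
        )
        assert bf.v_loss == pytest.approx(bf.v_dead, rel=1e-6)
        assert bf.percent_dose_loss == pytest.approx(bf.v_dead / 500.0 * 100.0)

    def test_loss_never_below_dead_volume(self):
        for t_rem in (2.0, 5.0, 10.0, 60.0):
            bf, _ = needle_removal(t_rem, protocol(), ETA_IF_PIG, numerics=FAST)
            assert bf.v_loss >= bf.v_dead
            assert 0.0 <= bf.percent_dose_loss <= 100.0

    def test_removal_during_injection_adds_device_volume(self):
        bf, tr = needle_removal(2.5, protocol(), ETA_IF_PIG, numerics=FAST)
        # half the dose is still in the device
        assert bf.percent_dose_loss >= 50.0
        assert 4 in set(tr.phase.tolist())

    def test_backflow_invariant_to_joint_viscosity_scaling(self):
        # pressure scales with η_app while the Poiseuille leak resistance
        # scales with η_form: scaling both viscosities by 2 (a power of two,
        # with no bleb term) cancels exactly, bit for bit
        skin = SkinModel(stiffness=0.0)
        bf1, _ = needle_removal(
            10.0, protocol(formulation_viscosity=1.0), 1.0, skin=skin, numerics=FAST
        )
        bf2, _ = needle_removal(
            10.0, protocol(formulation_viscosity=2.0), 2.0, skin=skin, numerics=FAST
        )
        assert bf1.v_loss == bf2.v_loss

    def test_backflow_weakly_dependent_on_formulation_viscosity(self):
        # doubling the formulation viscosity alone raises the pressure and
        # the leak resistance together, leaving the loss nearly unchanged
        bf1, _ = needle_removal(
            10.0, protocol(formulation_viscosity=5.0), ETA_IF_PIG, numerics=FAST
        )
        bf2, _ = needle_removal(
            10.0, protocol(formulation_viscosity=10.0), ETA_IF_PIG, numerics=FAST
        )
        assert bf2.v_loss == pytest.approx(bf1.v_loss, rel=0.35)


class TestResidualPressure:
    SKIN = SkinModel()

    def test_zero_bleb_zero_pressure(self):
        assert residual_pressure(0.0, self.SKIN) == 0.0

    def test_monotone_in_bleb_volume(self):
        vols = [100.0, 500.0, 1000.0, 2000.0]
        ps = [residual_pressure(v, self.SKIN) for v in vols]
        assert ps == sorted(ps)

    def test_two_ml_bleb_calibration(self):
        # default stiffness tuned so a 2 mL abdominal bleb exerts ≈3 kPa
        assert residual_pressure(2000.0, self.SKIN) == pytest.approx(3.0, abs=0.15)


class TestSimulatePressure:
    def test_phases_ordered_and_all_present(self, saline_protocol):
        proto = saline_protocol.model_copy(update={"t_removal": 15.0})
        tr = simulate_pressure(proto, ETA_IF_PIG, numerics=FAST)
        assert (np.diff(tr.phase) >= 0).all()
        assert set(tr.phase.tolist()) == {1, 2, 3, 4, 5}

    def test_total_pressure_never_negative(self, saline_protocol):
        proto = saline_protocol.model_copy(update={"t_removal": 15.0})
        tr = simulate_pressure(proto, ETA_IF_PIG, numerics=FAST)
        assert (tr.p_total >= 0).all()

    def test_volume_accounting_closes(self, saline_protocol):
        proto = saline_protocol.model_copy(update={"t_removal": 15.0})
        tr = simulate_pressure(proto, ETA_IF_PIG, numerics=FAST)
        closure = tr.v_delivered - (tr.v_in_tissue + tr.v_out + tr.v_leak)
        assert np.abs(closure).max() <= 1e-6 * proto.v_inj

    def test_peak_increases_with_rate_at_fixed_volume(self):
        peaks = [
            simulate_pressure(protocol(q_inj=q, t_removal=10.0), ETA_IF_PIG,
                              numerics=FAST).peak_pressure
            for q in (1000.0, 3000.0, 6000.0)
        ]
        assert peaks == sorted(peaks)

    def test_leakage_decreases_with_rate_at_fixed_volume(self):
        losses = []
        for q in (500.0, 2000.0, 6000.0):
            t_end = 2000.0 / (q / 60.0)
            proto = protocol(v_inj=2000.0, q_inj=q, t_removal=t_end + 10.0)
            tr = simulate_pressure(proto, ETA_IF_PIG, numerics=FAST)
            losses.append(tr.backflow.v_loss)
        assert losses[0] > losses[1] > losses[2]

    def test_dt_larger_than_leak_window_rejected(self, saline_protocol):
        proto = saline_protocol.model_copy(update={"t_removal": 10.0})
        with pytest.raises(ConfigurationError):
            simulate_pressure(proto, ETA_IF_PIG, numerics=Numerics(dt_leak=0.1))

    def test_viscous_high_rate_warns(self):
        proto = protocol(formulation_viscosity=20.0, q_inj=6000.0, t_removal=10.0)
        with pytest.warns(UserWarning, match="overpredicted"):
            simulate_pressure(proto, ETA_IF_PIG, numerics=FAST)

    def test_trace_frame_columns(self, saline_protocol):
        proto = saline_protocol.model_copy(update={"t_removal": 15.0})
        df = simulate_pressure(proto, ETA_IF_PIG, numerics=FAST).to_frame()
        assert list(df.columns) == [
            "t_s", "p_tissue_kPa", "p_bleb_kPa", "p_total_kPa",
            "phase", "v_out_uL", "v_loss_uL",
        ]
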
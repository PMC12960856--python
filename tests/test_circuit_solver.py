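import dataclasses

import numpy as np
import pytest

from ecmoflow import (
    CircuitDefinition,
    OperatingPoint,
    QuadraticCurve,
    apply_bed_height,
    hydrostatic_offset_mmhg,
    predict_circuit,
    solve_operating_point,
    total_passive_curve,
    walk_pressures,
)
from ecmoflow.circuit_solver import _stable_positive_root
from ecmoflow.errors import (
    AmbiguousOperatingPointError,
    ConsistencyError,
    InvalidComponentError,
    MissingTapError,
    NoOperatingPointError,
)
from ecmoflow.workbench_io import DEFAULT_GRID, build_circuit

from conftest import grid_scan_operating_flow, passive, pump, random_circuit


class TestTotalPassiveCurve:
    def test_coefficientwise_sum(self, toy_circuit):
        assert total_passive_curve(toy_circuit).as_tuple() == pytest.approx(
            (3.0, 0.0, 0.0)
        )

    def test_single_component_identity(self):
        c = CircuitDefinition(
            drainage_side=(passive("only", 4.0, 0.0),),
            pump=pump(-1, 0, 100), rpm=3000, return_side=(),
        )
        assert total_passive_curve(c).as_tuple() == (4.0, 0.0, 0.0)

    def test_six_unit_components(self):
        comps = tuple(passive(f"c{i}", 1.0, 0.0) for i in range(6))
        c = CircuitDefinition(
            drainage_side=comps[:3], pump=pump(-1, 0, 100), rpm=3000,
            return_side=comps[3:],
        )
        assert total_passive_curve(c).as_tuple() == (6.0, 0.0, 0.0)

    def test_empty_circuit_rejected(self):
        with pytest.raises(InvalidComponentError):
            CircuitDefinition(
                drainage_side=(), pump=pump(-1, 0, 100), rpm=3000,
                return_side=(),
            )


class TestSolveOperatingPoint:
    def test_closed_form_toy_circuit(self, toy_circuit):
        """3q^2 = 100 - q^2 has the unique positive solution q = 5."""
        op = solve_operating_point(toy_circuit)
        assert op.q == pytest.approx(5.0, abs=1e-12)
        assert op.pump_head == pytest.approx(75.0, abs=1e-12)

    def test_negative_discriminant_is_no_operating_point(self):
        # pump minus circuit = -2q^2 - 40: never zero
        with pytest.raises(NoOperatingPointError):
            _stable_positive_root(-2.0, 0.0, -40.0, q_max=10.0)

    def test_tangency_is_ambiguous(self):
        with pytest.raises(AmbiguousOperatingPointError) as exc:
            _stable_positive_root(-1.0, 4.0, -4.0, q_max=10.0)  # -(q-2)^2
        assert exc.value.candidates == (2.0, 2.0)

    def test_root_beyond_q_max_is_no_operating_point(self):
        # weak circuit: q* = sqrt(600/4) > 10
        c = CircuitDefinition(
            drainage_side=(passive("weak", 1.0, 0.0),),
            pump=pump(-3.0, 0.0, 600.0), rpm=3000, return_side=(),
        )
        with pytest.raises(NoOperatingPointError):
            solve_operating_point(c)

    def test_matches_grid_scan_oracle(self):
        """Closed-form root agrees with a 1e-4-step brute-force scan."""
        rng = np.random.default_rng(7)
        solved = 0
        while solved < 50:
            circuit = random_circuit(rng)
            try:
                op = solve_operating_point(circuit)
            except NoOperatingPointError:
                continue
            assert op.q == pytest.approx(
                grid_scan_operating_flow(circuit), abs=1e-3
            )
            solved += 1

    def test_energy_balance_at_operating_point(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            circuit = random_circuit(rng)
            try:
                op = solve_operating_point(circuit)
            except NoOperatingPointError:
                continue
            drop = total_passive_curve(circuit)(op.q)
            assert abs(op.pump_head - drop) < 1e-9


class TestWalkPressures:
    def test_hand_bookkeeping(self, toy_circuit):
        """Drops at q*=5: drain 10, tube1 2, tube2 3, oxy 20, tube3 3,
        return 37; head 75 => P1=-12, P2=60, P3=40, closure at 0."""
        op = solve_operating_point(toy_circuit)
        prof = walk_pressures(toy_circuit, op)
        assert prof.p1 == pytest.approx(-12.0, abs=1e-9)
        assert prof.p2 == pytest.approx(60.0, abs=1e-9)
        assert prof.p3 == pytest.approx(40.0, abs=1e-9)
        assert prof.node_pressures[0] == ("drainage_bath", 0.0)
        assert prof.node_pressures[-1][1] == pytest.approx(0.0, abs=1e-9)

    def test_identity_walk_all_drops_zero(self):
        """Zero-resistance circuit at the pump's zero-head flow: every
        node sits at the CVP."""
        c = CircuitDefinition(
            drainage_side=(passive("wire1", 0.0, 0.0),),
            pump=pump(-1.0, 0.0, 25.0), rpm=3000,
            return_side=(passive("oxy", 0.0, 0.0, kind="oxygenator"),),
            cvp=7.0,
        )
        op = solve_operating_point(c)
        assert op.q == pytest.approx(5.0)
        prof = walk_pressures(c, op)
        for _, p in prof.node_pressures:
            assert p == pytest.approx(7.0, abs=1e-9)

    def test_cvp_shift_propagates_additively(self, toy_circuit):
        op = solve_operating_point(toy_circuit)
        base = walk_pressures(toy_circuit, op)
        shifted_circuit = dataclasses.replace(toy_circuit, cvp=toy_circuit.cvp + 5)
        op2 = solve_operating_point(shifted_circuit)
        assert op2.q == pytest.approx(op.q, abs=1e-12)
        shifted = walk_pressures(shifted_circuit, op2)
        for (_, p0), (_, p1) in zip(base.node_pressures, shifted.node_pressures):
            assert p1 - p0 == pytest.approx(5.0, abs=1e-9)

    def test_inconsistent_operating_point_rejected(self, toy_circuit):
        with pytest.raises(ConsistencyError):
            walk_pressures(toy_circuit, OperatingPoint(q=5.0, pump_head=80.0))

    def test_loop_closure_on_random_circuits(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 50:
            circuit = random_circuit(rng)
            try:
                op = solve_operating_point(circuit)
            except NoOperatingPointError:
                continue
            prof = walk_pressures(circuit, op)
            assert abs(prof.node_pressures[-1][1] - circuit.cvp) < 1e-9
            checked += 1


class TestApplyBedHeight:
    def test_40cm_adds_29_4_mmhg(self, toy_circuit):
        """40 cmH2O / 1.36 = 29.4 mmHg on each pump-level tap."""
        prof = walk_pressures(toy_circuit, solve_operating_point(toy_circuit))
        raised = apply_bed_height(prof, 40.0)
        for before, after in ((prof.p1, raised.p1), (prof.p2, raised.p2),
                              (prof.p3, raised.p3)):
            assert round(after - before, 1) == 29.4

    def test_zero_height_is_identity(self, toy_circuit):
        prof = walk_pressures(toy_circuit, solve_operating_point(toy_circuit))
        same = apply_bed_height(prof, 0.0)
        assert same.node_pressures == prof.node_pressures
        assert (same.p1, same.p2, same.p3) == (prof.p1, prof.p2, prof.p3)

    def test_80cm_offset(self, toy_circuit):
        prof = walk_pressures(toy_circuit, solve_operating_point(toy_circuit))
        raised = apply_bed_height(prof, 80.0)
        assert raised.p2 - prof.p2 == pytest.approx(80.0 / 1.36)
        assert raised.p2 - prof.p2 == pytest.approx(58.8, abs=0.05)

    def test_bath_endpoints_unchanged(self, toy_circuit):
        prof = walk_pressures(toy_circuit, solve_operating_point(toy_circuit))
        raised = apply_bed_height(prof, 40.0)
        assert raised.node_pressures[0] == prof.node_pressures[0]
        assert raised.node_pressures[-1] == prof.node_pressures[-1]
        for (_, p0), (_, p1) in zip(prof.node_pressures[1:-1],
                                    raised.node_pressures[1:-1]):
            assert p1 - p0 == pytest.approx(40.0 / 1.36)

    def test_specific_gravity_scales_offset(self):
        assert hydrostatic_offset_mmhg(40.0, include_specific_gravity=True) \
            == pytest.approx(40.0 / 1.36 * 1.05)

    def test_negative_height_rejected(self, toy_circuit):
        prof = walk_pressures(toy_circuit, solve_operating_point(toy_circuit))
        with pytest.raises(InvalidComponentError):
            apply_bed_height(prof, -10.0)


class TestPredictCircuit:
    def test_composed_pipeline_on_toy_circuit(self, toy_circuit):
        res = predict_circuit(toy_circuit)
        assert res.q == pytest.approx(5.0, abs=1e-12)
        assert (res.p1, res.p2, res.p3) == pytest.approx((-12.0, 60.0, 40.0))

    def test_flow_invariant_to_bed_height(self, toy_circuit):
        qs = {
            h: predict_circuit(
                dataclasses.replace(toy_circuit, bed_height_cm=h)
            ).q
            for h in (0.0, 40.0, 80.0)
        }
        assert qs[40.0] == qs[0.0] and qs[80.0] == qs[0.0]

    def test_higher_pump_speed_signature(self, library):
        """More rpm: flow up, P1 down (more suction), P2 and P3 up."""
        res = {
            rpm: predict_circuit(build_circuit(
                DEFAULT_GRID, library, "drain_18fr", "return_14fr", rpm, 0.0
            ))
            for rpm in (2500, 3500)
        }
        assert res[3500].q > res[2500].q
        assert res[3500].p1 < res[2500].p1
        assert res[3500].p2 > res[2500].p2
        assert res[3500].p3 > res[2500].p3

    def test_larger_cannula_never_decreases_flow(self):
        """Pointwise-smaller component curve => operating flow >=."""
        rng = np.random.default_rng(37)
        checked = 0
        while checked < 30:
            circuit = random_circuit(rng)
            try:
                q0 = solve_operating_point(circuit).q
            except NoOperatingPointError:
                continue
            comp = circuit.drainage_side[0]
            bigger = dataclasses.replace(
                comp, curve=QuadraticCurve(comp.curve.k1 * 0.5,
                                           comp.curve.k2 * 0.5, 0.0)
            )
            relaxed = dataclasses.replace(
                circuit, drainage_side=(bigger,) + circuit.drainage_side[1:]
            )
            assert solve_operating_point(relaxed).q >= q0 - 1e-12
            checked += 1

    def test_cannula_enlargement_pressure_signature(self, library):
        """On the 18/22 Fr drain x 14/18 Fr return grid: a larger drainage
        cannula raises P1/P2/P3; a larger return cannula lowers them."""
        res = {
            (d, r): predict_circuit(build_circuit(
                DEFAULT_GRID, library, d, r, 3000, 0.0
            ))
            for d in ("drain_18fr", "drain_22fr")
            for r in ("return_14fr", "return_18fr")
        }
        for r in ("return_14fr", "return_18fr"):
            small, big = res[("drain_18fr", r)], res[("drain_22fr", r)]
            assert big.p1 > small.p1 and big.p2 > small.p2 and big.p3 > small.p3
        for d in ("drain_18fr", "drain_22fr"):
            small, big = res[(d, "return_14fr")], res[(d, "return_18fr")]
            assert big.p1 < small.p1 and big.p2 < small.p2 and big.p3 < small.p3

    def test_circuit_without_oxygenator_has_no_p2_p3(self):
        c = CircuitDefinition(
            drainage_side=(passive("drain", 1.0, 0.0, kind="drainage_cannula"),),
            pump=pump(-1, 0, 100), rpm=3000,
            return_side=(passive("return", 2.0, 0.0, kind="return_cannula"),),
        )
        with pytest.raises(MissingTapError):
            predict_circuit(c)
        prof = walk_pressures(c, solve_operating_point(c))
        with pytest.raises(MissingTapError):
            prof.tap("P2")
        assert prof.tap("P1") == prof.p1
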
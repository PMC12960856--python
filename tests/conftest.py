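import numpy as np
import pytest

from ecmoflow import (
    CircuitDefinition,
    PassiveComponent,
    PumpModel,
    QuadraticCurve,
    default_library,
    total_passive_curve,
)


def passive(name, k1, k2, kind="connecting_tube", **kw):
    return PassiveComponent(
        name=name, kind=kind, curve=QuadraticCurve(k1, k2, 0.0), **kw
    )


def pump(k1, k2, k3, rpm=3000, name="pump"):
    return PumpModel(name=name, curves_by_rpm={rpm: QuadraticCurve(k1, k2, k3)})


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture
def toy_circuit():
    """Hand-checkable circuit: total passive curve (3,0,0), pump (-1,0,100).

    Operating point q*=5 L/min, head 75 mmHg; component drops at q*=5 are
    drain 10, tube1 2, tube2 3, oxygenator 20, tube3 3, return 37.
    """
    return CircuitDefinition(
        drainage_side=(
            passive("drain", 0.4, 0.0, kind="drainage_cannula"),
            passive("tube1", 0.08, 0.0),
        ),
        pump=pump(-1.0, 0.0, 100.0),
        rpm=3000,
        return_side=(
            passive("tube2", 0.12, 0.0),
            passive("oxy", 0.8, 0.0, kind="oxygenator"),
            passive("tube3", 0.12, 0.0),
            passive("return", 1.48, 0.0, kind="return_cannula"),
        ),
        cvp=0.0,
    )


def random_circuit(rng: np.random.Generator) -> CircuitDefinition:
    """A random physically plausible series circuit with an oxygenator."""
    def rand_passive(name, kind):
        return passive(name, rng.uniform(0.3, 6.0), rng.uniform(0.0, 4.0),
                       kind=kind)

    return CircuitDefinition(
        drainage_side=(
            rand_passive("drain", "drainage_cannula"),
            rand_passive("tube1", "connecting_tube"),
        ),
        pump=pump(rng.uniform(-8.0, -1.0), rng.uniform(-10.0, 0.0),
                  rng.uniform(100.0, 600.0)),
        rpm=3000,
        return_side=(
            rand_passive("tube2", "connecting_tube"),
            rand_passive("oxy", "oxygenator"),
            rand_passive("tube3", "connecting_tube"),
            rand_passive("return", "return_cannula"),
        ),
        cvp=rng.uniform(-5.0, 15.0),
        bed_height_cm=float(rng.choice([0.0, 40.0, 80.0])),
    )


def grid_scan_operating_flow(circuit: CircuitDefinition, step: float = 1e-4) -> float:
    """Brute-force oracle: argmin |circuit(q) - pump(q)| over a fine grid."""
    q = np.arange(step, circuit.q_max + step / 2, step)
    circuit_curve = total_passive_curve(circuit)
    pump_curve = circuit.pump.curve_at(circuit.rpm)
    gap = np.abs(circuit_curve(q) - pump_curve(q))
    return float(q[np.argmin(gap)])
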
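"""Operating-point solution and pressure walk for a series ECMO circuit.

The circuit is a single loop: drainage cannula and tube(s) from the
patient (or bath) to the pump, then tube, oxygenator, tube and return
cannula back.  Three things are computed:

1. The *operating point*: the flow Q* at which the head supplied by the
   pump equals the summed pressure drop of every passive component.  Both
   sides are quadratics in Q, so Q* comes from the quadratic formula.
2. The *pressure profile*: starting from the central venous pressure
   (CVP), each component's drop is subtracted (and the pump's head added)
   walking around the loop; the named taps P1 (pre-pump), P2
   (pre-oxygenator) and P3 (post-oxygenator) are read off the walk.
3. The *bed-height correction*: raising the patient/bath by h cm above
   the pump level adds h/1.36 mmHg of hydrostatic pressure to every
   pump-level node (P1, P2, P3 included) without changing the flow.  The
   1.36 factor converts cmH2O to mmHg; the ~1.05 specific gravity of
   blood is omitted by default, matching the usual bedside simplification,
   but can be switched on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .component_model import (
    PassiveComponent,
    PumpModel,
    QuadraticCurve,
    component_pressure_drop,
    pump_head_at,
)
from .errors import (
    AmbiguousOperatingPointError,
    ConsistencyError,
    EcmoflowError,
    InvalidComponentError,
    MissingTapError,
    NoOperatingPointError,
)

logger = logging.getLogger(__name__)

#: cmH2O per mmHg: dividing a height in cm by this yields mmHg.
CMH2O_PER_MMHG = 1.36

#: Specific gravity of blood, applied only on request.
BLOOD_SPECIFIC_GRAVITY = 1.05

#: Energy-balance / loop-closure tolerance for the analytic pipeline.
BALANCE_TOL = 1e-9

#: Tolerance for rejecting an externally supplied operating point.
CONSISTENCY_TOL = 1e-6


@dataclass(frozen=True)
class CircuitDefinition:
    """A complete series circuit: who is plumbed where, and at what speed.

    ``drainage_side`` runs from the patient to the pump inlet (typically
    drainage cannula, connecting tube 1); ``return_side`` from the pump
    outlet back to the patient (typically connecting tube 2, oxygenator,
    connecting tube 3, return cannula).  P1 sits after the last
    drainage-side component, P2 just before the oxygenator, P3 just after
    it.
    """

    drainage_side: tuple[PassiveComponent, ...]
    pump: PumpModel
    rpm: int
    return_side: tuple[PassiveComponent, ...]
    cvp: float = 0.0
    bed_height_cm: float = 0.0
    q_max: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "drainage_side", tuple(self.drainage_side))
        object.__setattr__(self, "return_side", tuple(self.return_side))
        if not self.drainage_side and not self.return_side:
            raise InvalidComponentError("circuit has no passive components")
        if self.bed_height_cm < 0:
            raise InvalidComponentError(
                f"bed height must be >= 0 cm (got {self.bed_height_cm})"
            )
        if self.q_max is None:
            object.__setattr__(self, "q_max", self.pump.q_max)

    @property
    def components(self) -> tuple[PassiveComponent, ...]:
        return self.drainage_side + self.return_side

    @property
    def oxygenator_index(self) -> int | None:
        """Index of the oxygenator within return_side, or None."""
        for i, c in enumerate(self.return_side):
            if c.kind == "oxygenator":
                return i
        return None


@dataclass(frozen=True)
class OperatingPoint:
    """The solved intersection of circuit and pump curves."""

    q: float            # flow rate, L/min
    pump_head: float    # head supplied at q, mmHg


@dataclass(frozen=True)
class PressureProfile:
    """Node pressures around the loop, bath to bath.

    ``node_pressures`` is ordered from the drainage bath back to the
    return bath; the first and last entries sit at bath (CVP) level, all
    interior nodes at pump level.  ``p2``/``p3`` are ``None`` for circuits
    without an oxygenator; use :meth:`tap` for checked access.
    """

    node_pressures: tuple[tuple[str, float], ...]
    p1: float
    p2: float | None
    p3: float | None
    bed_height_cm: float = 0.0

    def tap(self, name: str) -> float:
        value = {"P1": self.p1, "P2": self.p2, "P3": self.p3}.get(name)
        if name not in ("P1", "P2", "P3"):
            raise MissingTapError(f"unknown tap {name!r}; expected P1, P2 or P3")
        if value is None:
            raise MissingTapError(
                f"tap {name} is undefined: circuit has no oxygenator"
            )
        return value


def total_passive_curve(circuit: CircuitDefinition) -> QuadraticCurve:
    """Coefficient-wise sum of every passive component's curve.

    This is the whole circuit's pressure-flow characteristic; its
    intercept is zero because every summand's is.
    """
    total = QuadraticCurve(0.0, 0.0, 0.0)
    for comp in circuit.components:
        total = total + comp.curve
    return total


def _stable_positive_root(diff_a: float, diff_b: float, diff_c: float,
                          q_max: float) -> float:
    """Root of a*q^2 + b*q + c = 0 where the difference crosses + to -.

    The difference is pump head minus circuit drop; the stable operating
    point is where it changes sign from positive (pump wins, flow
    accelerates) to negative (circuit wins, flow decelerates).
    """
    if abs(diff_a) < 1e-300:
        # linear difference
        if diff_b == 0:
            raise NoOperatingPointError(
                "pump and circuit curves are parallel; no intersection"
            )
        root = -diff_c / diff_b
        if diff_b < 0 and 0 < root <= q_max:
            return root
        raise NoOperatingPointError(
            f"no stable operating point in (0, {q_max}] L/min"
        )
    disc = diff_b * diff_b - 4 * diff_a * diff_c
    if disc < 0:
        raise NoOperatingPointError(
            "pump cannot drive this circuit: curves do not intersect "
            "(negative discriminant)"
        )
    sq = math.sqrt(disc)
    r1 = (-diff_b - sq) / (2 * diff_a)
    r2 = (-diff_b + sq) / (2 * diff_a)
    roots = sorted((r1, r2))
    if disc == 0:
        raise AmbiguousOperatingPointError(
            "curves are tangent; the crossing direction is undefined",
            candidates=tuple(roots),
        )
    # derivative of the difference at each root identifies the crossing:
    # d'(r) < 0  <=>  + to - crossing (stable)
    stable = [r for r in roots if 0 < r <= q_max and 2 * diff_a * r + diff_b < 0]
    if len(stable) == 1:
        return stable[0]
    if not stable:
        raise NoOperatingPointError(
            f"no stable operating point in (0, {q_max}] L/min "
            f"(roots: {roots})"
        )
    raise AmbiguousOperatingPointError(
        "multiple stable crossings", candidates=tuple(stable)
    )


def solve_operating_point(circuit: CircuitDefinition) -> OperatingPoint:
    """Closed-form flow at which pump head equals total circuit drop.

    Solves pump(q) - circuit(q) = 0 with the quadratic formula and picks
    the stable crossing in (0, q_max].
    """
    circuit_curve = total_passive_curve(circuit)
    pump_curve = circuit.pump.curve_at(circuit.rpm)
    a = pump_curve.k1 - circuit_curve.k1
    b = pump_curve.k2 - circuit_curve.k2
    c = pump_curve.k3 - circuit_curve.k3
    q = _stable_positive_root(a, b, c, circuit.q_max)
    head = pump_head_at(circuit.pump, circuit.rpm, q)
    logger.debug(
        "operating point: q=%.6f L/min, head=%.6f mmHg (circuit %s, pump %s "
        "@ %d rpm)", q, head, circuit_curve.as_tuple(), pump_curve.as_tuple(),
        circuit.rpm,
    )
    return OperatingPoint(q=q, pump_head=head)


def walk_pressures(circuit: CircuitDefinition, op: OperatingPoint) -> PressureProfile:
    """Sequential pressure bookkeeping from the drainage side.

    Starting at the CVP, each drainage-side drop is subtracted (the last
    such node is P1), the pump head is added, then each return-side drop
    is subtracted; P2 is the node just before the oxygenator and P3 the
    node just after.  The final node must land back on the CVP -- the
    loop-closure check -- which holds exactly when ``op`` balances this
    circuit.
    """
    drops = [component_pressure_drop(c, op.q) for c in circuit.components]
    imbalance = op.pump_head - sum(drops)
    if abs(imbalance) > CONSISTENCY_TOL:
        raise ConsistencyError(
            f"operating point (q={op.q} L/min, head={op.pump_head} mmHg) "
            f"does not balance this circuit: residual {imbalance:.3g} mmHg"
        )

    nodes: list[tuple[str, float]] = [("drainage_bath", circuit.cvp)]
    p = circuit.cvp
    for comp, drop in zip(circuit.drainage_side, drops):
        p -= drop
        nodes.append((f"after {comp.name}", p))
    p1 = p
    p += op.pump_head
    nodes.append(("after pump", p))

    oxy_i = circuit.oxygenator_index
    p2 = p3 = None
    n_drain = len(circuit.drainage_side)
    for i, comp in enumerate(circuit.return_side):
        if oxy_i is not None and i == oxy_i:
            p2 = p
        p -= drops[n_drain + i]
        nodes.append((f"after {comp.name}", p))
        if oxy_i is not None and i == oxy_i:
            p3 = p
    nodes[-1] = ("return_bath", nodes[-1][1])
    return PressureProfile(
        node_pressures=tuple(nodes), p1=p1, p2=p2, p3=p3,
        bed_height_cm=0.0,
    )


def hydrostatic_offset_mmhg(
    bed_height_cm: float, include_specific_gravity: bool = False
) -> float:
    """Pressure added at pump level by raising the bed ``bed_height_cm``.

    h cmH2O / 1.36 = mmHg; optionally scaled by blood's specific gravity
    (1.05), which is omitted by default as its effect is minimal.
    """
    if bed_height_cm < 0:
        raise InvalidComponentError(
            f"bed height must be >= 0 cm (got {bed_height_cm})"
        )
    offset = bed_height_cm / CMH2O_PER_MMHG
    if include_specific_gravity:
        offset *= BLOOD_SPECIFIC_GRAVITY
    return offset


def apply_bed_height(
    profile: PressureProfile,
    bed_height_cm: float,
    include_specific_gravity: bool = False,
) -> PressureProfile:
    """Shift every pump-level node by the hydrostatic offset.

    The bath endpoints (first and last nodes, at bed level) are unchanged;
    all interior nodes -- including the P1/P2/P3 taps -- gain
    h/1.36 mmHg.  Flow is unaffected by construction.
    """
    offset = hydrostatic_offset_mmhg(bed_height_cm, include_specific_gravity)
    if offset == 0.0:
        return replace(profile, bed_height_cm=bed_height_cm)
    nodes = list(profile.node_pressures)
    shifted = (
        [nodes[0]]
        + [(label, p + offset) for label, p in nodes[1:-1]]
        + [nodes[-1]]
    )
    return PressureProfile(
        node_pressures=tuple(shifted),
        p1=profile.p1 + offset,
        p2=None if profile.p2 is None else profile.p2 + offset,
        p3=None if profile.p3 is None else profile.p3 + offset,
        bed_height_cm=bed_height_cm,
    )


@dataclass(frozen=True)
class PredictionResult:
    """Headline outputs of the four-step prediction."""

    q: float
    p1: float
    p2: float
    p3: float
    operating_point: OperatingPoint
    profile: PressureProfile


def predict_circuit(
    circuit: CircuitDefinition, include_specific_gravity: bool = False
) -> PredictionResult:
    """Full pipeline: operating point -> pressure walk -> bed-height offset."""
    try:
        op = solve_operating_point(circuit)
    except EcmoflowError as e:
        e.add_note("during the operating-point step")
        raise
    try:
        profile = walk_pressures(circuit, op)
    except EcmoflowError as e:
        e.add_note("during the pressure-walk step")
        raise
    try:
        profile = apply_bed_height(
            profile, circuit.bed_height_cm, include_specific_gravity
        )
    except EcmoflowError as e:
        e.add_note("during the bed-height step")
        raise
    if profile.p2 is None or profile.p3 is None:
        raise MissingTapError(
            "circuit has no oxygenator; P2/P3 are undefined"
        )
    return PredictionResult(
        q=op.q, p1=profile.p1, p2=profile.p2, p3=profile.p3,
        operating_point=op, profile=profile,
    )
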
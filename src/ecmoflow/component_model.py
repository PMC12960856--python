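"""Quadratic pressure-flow characteristics of ECMO circuit components.

Every element of an extracorporeal circuit -- cannulas, connecting tubes,
the oxygenator, and the centrifugal pump at each rotational speed -- is
summarised by a quadratic curve

    P(Q) = k1 * Q**2 + k2 * Q + k3

with P in mmHg and Q in L/min.  For passive components P is the pressure
*drop* across the element and k3 is pinned to zero (no flow, no drop); the
quadratic term is dominated by inertial (density) losses and the linear
term by viscous ones.  For a centrifugal pump P is the *head* supplied,
the curve opens downward, and k3 is the shut-off head: the maximum
pressure the pump develops against a fully obstructed circuit.

Curves are fitted to (flow, pressure) points digitised from manufacturer
catalogs by ordinary least squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    FittingDegeneracyError,
    InvalidComponentError,
    NegativeFlowError,
    UntabulatedRpmError,
)

logger = logging.getLogger(__name__)

#: Default upper end of the modelled flow range (L/min).  Evaluation beyond
#: this is permitted but logged as extrapolation.
DEFAULT_Q_MAX = 10.0

#: Quadratic loss coefficient of 3/8-inch connecting tube, per metre
#: (mmHg * min^2 / L^2 / m).  Calibrated so that 1 m of tubing drops
#: 100 mmHg at 5 L/min, the figure quoted in the Alfred ECMO guideline:
#: 4 * 1 * 5**2 = 100.
TUBE_K1_PER_METRE = 4.0

PASSIVE_KINDS = frozenset(
    {"drainage_cannula", "return_cannula", "connecting_tube", "oxygenator"}
)


@dataclass(frozen=True)
class QuadraticCurve:
    """Coefficients of P(Q) = k1*Q**2 + k2*Q + k3.

    Units: k1 in mmHg*min^2/L^2, k2 in mmHg*min/L, k3 in mmHg.
    """

    k1: float
    k2: float
    k3: float = 0.0

    def __post_init__(self):
        for name in ("k1", "k2", "k3"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidComponentError(f"curve coefficient {name}={v} is not finite")

    def __call__(self, q):
        """Evaluate the curve at flow ``q`` (scalar or array, L/min)."""
        q = np.asarray(q, dtype=float)
        out = self.k1 * q * q + self.k2 * q + self.k3
        return float(out) if out.ndim == 0 else out

    def __add__(self, other: "QuadraticCurve") -> "QuadraticCurve":
        return QuadraticCurve(self.k1 + other.k1, self.k2 + other.k2, self.k3 + other.k3)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k1, self.k2, self.k3)


@dataclass(frozen=True)
class CatalogPointSet:
    """(flow, pressure) pairs digitised from a product catalog.

    ``source_label`` names the component or pump-rpm block the points came
    from; it is echoed in fitting-degeneracy errors.
    """

    points: tuple[tuple[float, float], ...]
    source_label: str = ""

    def __post_init__(self):
        pts = tuple((float(q), float(p)) for q, p in self.points)
        object.__setattr__(self, "points", pts)
        for q, _p in pts:
            if q < 0:
                raise InvalidComponentError(
                    f"negative catalog flow {q} in {self.source_label!r}"
                )

    @property
    def flows(self) -> np.ndarray:
        return np.array([q for q, _ in self.points])

    @property
    def pressures(self) -> np.ndarray:
        return np.array([p for _, p in self.points])

    def __len__(self) -> int:
        return len(self.points)


def fit_quadratic_curve(
    points: CatalogPointSet, constrain_zero_intercept: bool = False
) -> QuadraticCurve:
    """Least-squares quadratic fit to catalog points.

    With ``constrain_zero_intercept`` the intercept k3 is fixed at zero and
    only (k1, k2) are estimated -- the appropriate model for passive
    components, which drop no pressure at zero flow.  With exactly as many
    points as free parameters the fit interpolates the points exactly.

    Raises
    ------
    FittingDegeneracyError
        Fewer points than free parameters, or a singular design (e.g. all
        flows identical).
    """
    n_free = 2 if constrain_zero_intercept else 3
    if len(points) < n_free:
        raise FittingDegeneracyError(
            f"{points.source_label!r}: need at least {n_free} points for "
            f"{'constrained' if constrain_zero_intercept else 'unconstrained'} "
            f"fit, got {len(points)}",
            source_label=points.source_label,
        )
    q = points.flows
    p = points.pressures
    if constrain_zero_intercept:
        design = np.column_stack([q**2, q])
    else:
        design = np.column_stack([q**2, q, np.ones_like(q)])
    if np.linalg.matrix_rank(design) < n_free:
        raise FittingDegeneracyError(
            f"{points.source_label!r}: singular design matrix (degenerate "
            f"flow values) for quadratic fit",
            source_label=points.source_label,
        )
    coef, *_ = np.linalg.lstsq(design, p, rcond=None)
    if constrain_zero_intercept:
        curve = QuadraticCurve(float(coef[0]), float(coef[1]), 0.0)
    else:
        curve = QuadraticCurve(float(coef[0]), float(coef[1]), float(coef[2]))
    logger.debug(
        "fitted %s: k1=%.6g k2=%.6g k3=%.6g (%d points, constrained=%s)",
        points.source_label, curve.k1, curve.k2, curve.k3, len(points),
        constrain_zero_intercept,
    )
    return curve


@dataclass(frozen=True)
class PassiveComponent:
    """A flow-resisting circuit element: cannula, tube or oxygenator.

    The curve's intercept must be exactly zero and the pressure drop must
    be non-negative over the valid flow range [0, q_max].
    """

    name: str
    kind: str
    curve: QuadraticCurve
    size_fr: float | None = None
    length_m: float | None = None
    q_max: float = DEFAULT_Q_MAX

    def __post_init__(self):
        if self.kind not in PASSIVE_KINDS:
            raise InvalidComponentError(
                f"{self.name!r}: unknown component kind {self.kind!r}; "
                f"expected one of {sorted(PASSIVE_KINDS)}"
            )
        if self.curve.k3 != 0.0:
            raise InvalidComponentError(
                f"{self.name!r}: passive component must have k3=0 "
                f"(got {self.curve.k3}); a passive element drops no pressure "
                f"at zero flow"
            )
        # non-negativity of k1*q^2 + k2*q on [0, q_max]: check endpoints and
        # the interior stationary point of the quadratic
        qs = [0.0, self.q_max]
        if self.curve.k1 != 0:
            q_vertex = -self.curve.k2 / (2 * self.curve.k1)
            if 0 < q_vertex < self.q_max:
                qs.append(q_vertex)
        if min(self.curve(q) for q in qs) < -1e-12:
            raise InvalidComponentError(
                f"{self.name!r}: pressure drop is negative somewhere on "
                f"[0, {self.q_max}] L/min"
            )


def component_pressure_drop(component: PassiveComponent, q: float) -> float:
    """Pressure drop (mmHg) across ``component`` at flow ``q`` (L/min).

    Zero at zero flow.  Negative (retrograde) flow is rejected.  Flows
    beyond the component's modelled range are evaluated but logged as
    extrapolation.
    """
    if q < 0:
        raise NegativeFlowError(
            f"{component.name!r}: retrograde flow q={q} L/min is outside "
            f"the model domain"
        )
    if q > component.q_max:
        logger.warning(
            "%r: evaluating at q=%.3f L/min beyond modelled range "
            "[0, %.3f] (extrapolation)", component.name, q, component.q_max,
        )
    return float(component.curve(q))


def connecting_tube(
    name: str,
    length_m: float,
    k1_per_m: float = TUBE_K1_PER_METRE,
    k2_per_m: float = 0.0,
    q_max: float = DEFAULT_Q_MAX,
) -> PassiveComponent:
    """Build a connecting tube from its length.

    The default model is a pure quadratic loss, dP = 4 * L * Q**2, which
    puts 100 mmHg across 1 m of 3/8-inch tubing at 5 L/min.  The split
    between quadratic and linear losses is configurable per tube.
    """
    if length_m <= 0:
        raise InvalidComponentError(f"{name!r}: tube length must be positive")
    curve = QuadraticCurve(k1_per_m * length_m, k2_per_m * length_m, 0.0)
    return PassiveComponent(
        name=name, kind="connecting_tube", curve=curve, length_m=length_m,
        q_max=q_max,
    )


@dataclass(frozen=True)
class PumpModel:
    """A centrifugal pump characterised at discrete rotational speeds.

    ``curves_by_rpm`` maps each tabulated speed to its head-vs-flow curve.
    Each curve must have a positive shut-off head (k3 > 0) and
    non-increasing head over [0, q_max]; higher speeds shift the curve
    upward.  Speeds between tabulated values are *not* interpolated.
    """

    name: str
    curves_by_rpm: Mapping[int, QuadraticCurve]
    q_max: float = DEFAULT_Q_MAX

    def __post_init__(self):
        curves = {int(rpm): c for rpm, c in self.curves_by_rpm.items()}
        object.__setattr__(self, "curves_by_rpm", curves)
        if not curves:
            raise InvalidComponentError(f"{self.name!r}: pump has no tabulated curves")
        for rpm, c in curves.items():
            if c.k3 <= 0:
                raise InvalidComponentError(
                    f"{self.name!r} @ {rpm} rpm: shut-off head k3 must be "
                    f"positive (got {c.k3})"
                )
            # head non-increasing: dP/dQ = 2*k1*q + k2 <= 0 at both ends of
            # the range (the derivative is monotone, so endpoints suffice)
            if c.k2 > 1e-12 or 2 * c.k1 * self.q_max + c.k2 > 1e-12:
                raise InvalidComponentError(
                    f"{self.name!r} @ {rpm} rpm: pump head must be "
                    f"non-increasing in flow over [0, {self.q_max}] L/min"
                )

    @property
    def rpms(self) -> tuple[int, ...]:
        return tuple(sorted(self.curves_by_rpm))

    def curve_at(self, rpm: int) -> QuadraticCurve:
        try:
            return self.curves_by_rpm[int(rpm)]
        except KeyError:
            raise UntabulatedRpmError(rpm, self.rpms) from None


def pump_head_at(pump: PumpModel, rpm: int, q: float) -> float:
    """Head (mmHg) supplied by ``pump`` at speed ``rpm`` and flow ``q``.

    At q=0 this is exactly the shut-off head k3 of the rpm's curve.
    Untabulated speeds raise :class:`UntabulatedRpmError` listing the
    available speeds.
    """
    if q < 0:
        raise NegativeFlowError(
            f"{pump.name!r}: retrograde flow q={q} L/min is outside the "
            f"model domain"
        )
    return float(pump.curve_at(rpm)(q))
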
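# Methods

## Model

The circuit is treated as a single incompressible, steady-state series
loop. Each passive component (cannula, tube, oxygenator) imposes a
pressure drop

    ΔP(Q) = K1·Q² + K2·Q,     Q ≥ 0,

where the quadratic term captures inertial (density-driven) losses and
the linear term viscous ones. The intercept is pinned to zero as a
physical constraint — a passive element drops no pressure at zero flow —
which also makes the pressure walk close exactly. The centrifugal pump at
a tabulated speed supplies a head

    H(Q) = K1·Q² + K2·Q + K3,     K1 < 0 region, K3 > 0,

with K3 the shut-off head. Pump curves are validated to be non-increasing
over the modelled flow range; passive curves to be non-negative there.

**Operating point.** At steady state the head supplied equals the sum of
all drops. Because both sides are quadratics, the difference
d(Q) = H(Q) − ΣΔP(Q) is a quadratic solved in closed form. Among its real
roots in (0, q_max], the solver returns the *stable* crossing — the root
at which d changes sign from + to − (d′ < 0), i.e. where a perturbation
to higher flow is pushed back by the circuit. For a quadratic there is at
most one such crossing; a tangency (zero discriminant, no sign change)
raises an explicit ambiguity error carrying both candidate roots, and a
negative discriminant or an out-of-range root raises a
no-operating-point error.

**Pressure walk.** Starting from the CVP at the drainage bath, each
drainage-side drop (evaluated at Q*) is subtracted — the node after the
last drainage component is P1 — then the pump head is added, then each
return-side drop subtracted; P2 is the node entering the oxygenator and
P3 the node leaving it. The final node must return to the CVP; this
closure is exact (≤1e-9 mmHg) whenever the supplied operating point
balances the circuit, and a supplied operating point with residual above
1e-6 mmHg is rejected as inconsistent.

**Bed height.** Raising the bath h cm above the pump level converts
potential to pressure energy at pump level: every interior node
(including P1, P2, P3) gains h/1.36 mmHg, the cmH₂O→mmHg conversion.
The two bath endpoints stay at CVP, and the flow is untouched — the
offset cancels around the loop. Blood's specific gravity (≈1.05) can be
multiplied in via a flag; the default omits it, the usual bedside
simplification, which underestimates the offset by 5%.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| tube loss coefficient | 4·L (pure Q² term) | mmHg·min²/L² | 1 m of 3/8-inch tubing drops 100 mmHg at 5 L/min, the Alfred ECMO guideline anchor; the K1/K2 split is configurable per tube |
| q_max | 10 | L/min | upper bound of adult VV-ECMO flows; evaluation beyond logs an extrapolation warning |
| CVP | 0 | mmHg | open-bath bench emulation (cannulas submerged at bed level); clinical use passes a measured CVP |
| closure / energy tolerance | 1e-9 | mmHg | analytic pipeline; anything larger indicates a bug, not roundoff |
| consistency tolerance | 1e-6 | mmHg | rejecting externally supplied operating points |
| bench noise | 0.1 L/min flow, 5 mmHg pressure | — | typical ultrasonic flow-probe and transducer scatter |

Curve fitting is ordinary least squares on the catalog points (numpy
lstsq on the [Q², Q] or [Q², Q, 1] design). With exactly as many points
as free parameters this interpolates exactly; with fewer, or with all
flows identical, it raises a degeneracy error naming the offending
catalog block. Pump speeds between tabulated curves are *not*
interpolated — a speed off the table is an explicit error listing the
available speeds — because affinity-law scaling is deliberately out of
scope.

## Validation statistics

For each predicted/measured series (flow, P1, P2, P3): bias is
predicted − measured; relative error is (measured − predicted)/measured
× 100 (signed, so a model that under-reads shows negative bias and
positive relative error); RMSD is the root mean squared bias. Medians
and quartiles use linear interpolation between order statistics (numpy's
default, R's type 7). The headline R² is the squared Pearson correlation
of the observed-on-predicted OLS regression; an identity-line variant
1 − SS(meas−pred)/SS(meas−mean) is reported alongside as `r2_identity`
because the two differ whenever the regression line is far from y = x.
Exact agreement short-circuits R² to exactly 1 so perfect pipelines do
not report 0.9999999999999998.

## Synthetic bench

The generator runs the factorial sweep (drain × return × rpm × height,
row order fixed by that nested loop) and perturbs each prediction with
iid Gaussian noise, seeded so output is byte-identical per seed. It
emulates only measurement scatter. It does **not** emulate the ways a
real bench deviates from the model — non-Newtonian rheology, tubing
compliance, suction-limited drainage, transducer height offsets, or
coefficient error in the component curves themselves. Passing
parameter-recovery tests therefore demonstrates the pipeline's internal
consistency (prediction, noise, statistics, I/O round trips), not the
model's fidelity to a physical circuit.

The shipped component set mirrors a realistic adult grid — 18/22 Fr
drainage, 14/18 Fr return cannulas, three tubes (0.5/0.5/1.0 m), an
oxygenator and a pump at 2500/3000/3500 rpm — but its coefficients are
invented, chosen once to produce flows of roughly 3.5–5.5 L/min and the
expected qualitative signatures (steeper curves for smaller cannulas;
higher speed raising flow, P2 and P3 while deepening P1; drainage
enlargement raising all three taps, return enlargement lowering them).

## Design choices

- **Zero-intercept passive fits.** Catalog digitisation could fit a free
  intercept, but a nonzero intercept breaks loop closure and is
  unphysical at Q = 0; the constraint costs nothing on well-behaved
  catalog data.
- **Single height datum.** The pump, tube 2 and oxygenator are treated
  as one level and the bath as another; per-component heights are not
  modelled, so the hydrostatic correction is one uniform offset applied
  to all interior nodes.
- **Taps are positions, not components.** P1/P2/P3 are read off the walk
  by the component order; a circuit without an oxygenator has no P2/P3
  and requesting them is an error rather than a silent NaN.
- **CLI rounding.** Human-readable output rounds pressures to 0.1 mmHg;
  files keep full precision (`%.10g`).

## Limitations

Steady-state only; no pulsatility, compliance or inertance. Retrograde
flow is out of domain (rejected, not modelled). Coefficients are assumed
constant with viscosity and hematocrit. Venous collapse at strongly
negative P1 is reported as a number, not simulated as a dynamic. The
grid-scan oracle used in the test suite resolves flow to its 1e-4 L/min
step, so closed-form/oracle agreement is asserted at 1e-3 L/min.
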
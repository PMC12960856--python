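# ecmoflow

Predict the operating flow rate and circuit pressures of a venovenous
ECMO (extracorporeal membrane oxygenation) circuit from nothing but the
pressure–flow characteristics of its parts.

Selecting cannulas and pump speed for ECMO is often done by empirical
judgment, yet those choices determine whether the circuit reaches its
target flow and whether pressures stay in a safe range (excessively
negative pre-pump pressure risks cavitation and hemolysis). `ecmoflow`
implements a simple lumped-parameter hydraulic model for clinicians,
perfusionists and device engineers who want those numbers *before*
assembling a circuit.

## The model

Every component — drainage cannula, connecting tubes, oxygenator, return
cannula — is summarised by a quadratic pressure-drop curve fitted to
manufacturer catalog points by ordinary least squares:

    P(Q) = K1·Q² + K2·Q + K3        [P in mmHg, Q in L/min]

with K3 ≡ 0 for passive components (no flow, no drop). The centrifugal
pump, at each tabulated speed, has a downward-opening head curve whose
intercept K3 > 0 is the shut-off head. Prediction is four steps:

1. **Fit** each component's curve from catalog (flow, pressure) pairs.
2. **Intersect**: sum the passive curves coefficient-wise and solve
   circuit(Q) = pump(Q) with the quadratic formula; the stable crossing
   is the operating flow Q*.
3. **Walk**: starting from the central venous pressure (CVP), subtract
   each drainage-side drop, add the pump head, subtract each return-side
   drop. The taps P1 (pre-pump), P2 (pre-oxygenator) and P3
   (post-oxygenator) are read off the walk, which closes back on the CVP.
4. **Bed height**: raising the patient h cm above the pump level adds
   h/1.36 mmHg (cmH₂O → mmHg) to every pump-level pressure without
   changing the flow.

A validation module computes the usual predicted-vs-measured agreement
statistics (R², RMSD, bias median/IQR, signed median relative error, and
the observed-on-predicted regression line), and a synthetic bench
generator produces seeded noisy "measurements" for end-to-end testing.

The component set shipped with the package (18/22 Fr drainage ×
14/18 Fr return cannulas, oxygenator, three tubes, one pump at
2500/3000/3500 rpm) is *synthetic*: the sizes and layout mirror a typical
adult bench grid, but the coefficients are invented shape-plausible
values, not manufacturer data. The default connecting-tube model is
ΔP = 4·L·Q² (mmHg, L in m), calibrated so 1 m of 3/8-inch tubing drops
100 mmHg at 5 L/min.

## Worked example

Predict the shipped example circuit (18 Fr drain, 14 Fr return,
3000 rpm) with the bed raised 40 cm:

```bash
ecmoflow predict --circuit src/ecmoflow/data/default_circuit.yaml --bed-height 40
```

```
q_l_min,p1_mmhg,p2_mmhg,p3_mmhg
4.33,-82.4,285.4,253.0

drainage_bath          0.0 mmHg
after drain_18fr     -44.9 mmHg
after tube1          -82.4 mmHg
after pump           322.9 mmHg
after tube2          285.4 mmHg
after oxygenator     253.0 mmHg
after tube3          178.0 mmHg
return_bath           -0.0 mmHg
```

The circuit runs at 4.33 L/min; the pre-pump pressure P1 is −82.4 mmHg
(suction side), the pump lifts the pressure by its head at Q*, and each
subsequent component drops it until the walk closes at the bath. All
interior pressures include the +29.4 mmHg hydrostatic offset from the
40 cm bed height; rerunning with `--bed-height 0` gives the same
4.33 L/min flow with every interior pressure exactly 29.4 mmHg lower.

A full factorial sweep and a synthetic validation round trip:

```bash
ecmoflow sweep --out sweep.csv                  # 36 combinations
ecmoflow synth-bench --seed 3 --out meas.csv    # predictions + noise
ecmoflow validate --pred sweep.csv --meas meas.csv --out report.csv
```

```
flow: R2=0.967 RMSD=0.107 bias median 0.02 (IQR -0.06, 0.04) rel err -0.46% slope 0.9910 intercept 0.0497
  P1: R2=0.982 RMSD=5.534 bias median 0.07 (IQR -3.05, 4.67) rel err 0.81% slope 0.9995 intercept -1.3455
  P2: R2=0.995 RMSD=4.616 bias median -0.32 (IQR -3.76, 3.39) rel err 0.11% slope 0.9960 intercept 1.1845
  P3: R2=0.990 RMSD=5.926 bias median -0.95 (IQR -5.47, 3.16) rel err 0.52% slope 0.9826 intercept 5.2855
```

With the default noise levels (0.1 L/min on flow, 5 mmHg on pressures)
the recovered statistics sit where a well-matched bench comparison
should: R² near 1, regression slope near 1, intercept near 0.

## Scope

Steady, Newtonian, rigid-tube flow in a single series loop. No pulsatile
effects, no venous-collapse dynamics, no viscosity/hematocrit scaling,
and no interpolation between tabulated pump speeds. See
`docs/methods.md` for the model's assumptions, numerical choices and
limitations.
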
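# Synthetic demonstration component set.
#
# The sizes (18/22 Fr drainage, 14/18 Fr return), the three pump speeds and
# the circuit layout mirror a typical adult VV-ECMO bench grid, but every
# coefficient value here is invented to be shape-plausible (steeper curves
# for smaller cannulas, downward-opening pump curves with positive shut-off
# head); they are NOT manufacturer data.  Connecting tubes without explicit
# coefficients use the default 4*L*Q^2 model (100 mmHg across 1 m of
# 3/8-inch tubing at 5 L/min).
components:
  - {name: drain_18fr, kind: drainage_cannula, size_fr: 18, k1: 3.5, k2: 2.0, k3: 0.0}
  - {name: drain_22fr, kind: drainage_cannula, size_fr: 22, k1: 1.6, k2: 1.2, k3: 0.0}
  - {name: return_14fr, kind: return_cannula, size_fr: 14, k1: 7.0, k2: 4.0, k3: 0.0}
  - {name: return_18fr, kind: return_cannula, size_fr: 18, k1: 3.0, k2: 2.5, k3: 0.0}
  - {name: oxygenator, kind: oxygenator, k1: 0.8, k2: 4.0, k3: 0.0}
  - {name: tube1, kind: connecting_tube, length_m: 0.5}
  - {name: tube2, kind: connecting_tube, length_m: 0.5}
  - {name: tube3, kind: connecting_tube, length_m: 1.0}
pumps:
  - name: pump
    curves:
      2500: {k1: -4.0, k2: -6.0, k3: 380.0}
      3000: {k1: -4.5, k2: -7.0, k3: 520.0}
      3500: {k1: -5.0, k2: -8.0, k3: 680.0}
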
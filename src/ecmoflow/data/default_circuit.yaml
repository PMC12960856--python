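# Example circuit definition resolving against default_library.yaml:
# drainage cannula -> tube 1 -> pump -> tube 2 -> oxygenator -> tube 3 ->
# return cannula, at 3000 rpm, bath-level bed, open bath (CVP 0).
drainage_side: [drain_18fr, tube1]
pump: pump
rpm: 3000
return_side: [tube2, oxygenator, tube3, return_14fr]
cvp_mmhg: 0.0
bed_height_cm: 0.0
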
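name: fig2
description: >
  Threshold current, firing frequency and spike width at the 0.2 / 0.4 nA
  probe currents as a function of the specific membrane capacitance, scaled
  everywhere and on the soma + proximal dendrites only.
fi: {di: 0.01, i_cap: 1.0, threshold_resolution: 0.001}
probes: [0.2, 0.4]
axes:
  - axis: cm
    regions: [all, sprx]
    values: [0.5, 0.75, 1.0, 1.25, 1.5]
    threshold: true
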
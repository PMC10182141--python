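name: fig3
description: >
  Full f-I curves for selected capacitance scalings (soma + proximal
  dendrites), with the relative firing-rate difference between each curve
  and baseline evaluated at the largest common sustained current.
fi: {di: 0.01, i_cap: 1.0}
probes: []
axes:
  - axis: cm
    regions: [sprx]
    values: [0.5, 0.75, 1.0, 1.25, 1.5]
    threshold: false
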
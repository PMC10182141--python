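name: fig5
description: >
  f-I curves with each maximal conductance scaled one-by-one over
  0.3x .. 10x of its default.  The maximal current of the sweep is 0.8 nA
  (printed once as pA; context fixes the unit as nA).
fi: {di: 0.01, i_cap: 0.8}
probes: []
axes:
  - {axis: "conductance:Ca_HVA", values: [0.3, 0.5, 1.0, 3.0, 7.0, 10.0], threshold: false}
  - {axis: "conductance:Ca_LVA", values: [0.3, 0.5, 1.0, 3.0, 7.0, 10.0], threshold: false}
  - {axis: "conductance:NaV", values: [0.3, 0.5, 1.0, 3.0, 7.0, 10.0], threshold: false}
  - {axis: "conductance:Kv3_1", values: [0.3, 0.5, 1.0, 3.0, 7.0, 10.0], threshold: false}
  - {axis: "conductance:Kv2like", values: [0.3, 0.5, 1.0, 3.0, 7.0, 10.0], threshold: false}
  - {axis: "conductance:SK", values: [0.3, 0.5, 1.0, 3.0, 7.0, 10.0], threshold: false}
  - {axis: "conductance:Kd", values: [0.3, 0.5, 1.0, 3.0, 7.0, 10.0], threshold: false}
  - {axis: "conductance:Im_v2", values: [0.3, 0.5, 1.0, 3.0, 7.0, 10.0], threshold: false}
  - {axis: "conductance:K_T", values: [0.3, 0.5, 1.0, 3.0, 7.0, 10.0], threshold: false}
  - {axis: "conductance:Ih", values: [0.3, 0.5, 1.0, 3.0, 7.0, 10.0], threshold: false}
  - {axis: "conductance:leak", values: [0.3, 0.5, 1.0, 3.0, 7.0, 10.0], threshold: false}
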
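name: fig4
description: >
  f-I curves under +-20 mV shifts of each ionic reversal potential, one ion
  at a time.  The calcium shift moves E_Ca(t=0) via the fixed extracellular
  concentration.  Step size between -20 and +20 mV is a 10 mV design choice.
fi: {di: 0.01, i_cap: 1.0}
probes: []
axes:
  - axis: reversal:na
    values: [-20, -10, 0, 10, 20]
    threshold: false
  - axis: reversal:k
    values: [-20, -10, 0, 10, 20]
    threshold: false
  - axis: reversal:leak
    values: [-20, -10, 0, 10, 20]
    threshold: false
  - axis: reversal:ca
    values: [-20, -10, 0, 10, 20]
    threshold: false
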
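name: fig6
description: >
  Combinatorial candidate-mechanism scenarios: capacitance x1.5 on the soma
  and proximal dendrites combined with E_Na +10 mV (53 -> 63 mV), a tenfold
  extracellular-calcium increase (E_Ca(0) 131.06 -> 161.53 mV) and joint
  Kv2like/SK conductance scalings between 1.5x and 4x.  The relative firing
  difference vs default is evaluated at the largest common sustained current.
fi: {di: 0.01, i_cap: 0.8}
scenarios:
  - {label: A-ENa-Kv2-SK-1.5, cm_factor: 1.5, cm_region: sprx, reversals: {na: 10}, conductances: {Kv2like: 1.5, SK: 1.5}}
  - {label: A-ENa-Kv2-SK-2, cm_factor: 1.5, cm_region: sprx, reversals: {na: 10}, conductances: {Kv2like: 2, SK: 2}}
  - {label: A-ENa-Kv2-SK-3, cm_factor: 1.5, cm_region: sprx, reversals: {na: 10}, conductances: {Kv2like: 3, SK: 3}}
  - {label: A-ENa-Kv2-SK-4, cm_factor: 1.5, cm_region: sprx, reversals: {na: 10}, conductances: {Kv2like: 4, SK: 4}}
  - {label: B-ECa-SK-1.5, cm_factor: 1.5, cm_region: sprx, ca_out_factor: 10.0, conductances: {SK: 1.5}}
  - {label: B-ECa-SK-4, cm_factor: 1.5, cm_region: sprx, ca_out_factor: 10.0, conductances: {SK: 4}}
  - {label: C-ECa-Kv2-SK-1.5, cm_factor: 1.5, cm_region: sprx, ca_out_factor: 10.0, conductances: {Kv2like: 1.5, SK: 1.5}}
  - {label: C-ECa-Kv2-SK-4, cm_factor: 1.5, cm_region: sprx, ca_out_factor: 10.0, conductances: {Kv2like: 4, SK: 4}}
  - {label: D-Kv2-SK-1.5, cm_factor: 1.5, cm_region: sprx, conductances: {Kv2like: 1.5, SK: 1.5}}
  - {label: D-Kv2-SK-4, cm_factor: 1.5, cm_region: sprx, conductances: {Kv2like: 4, SK: 4}}
  - {label: E-ECa-ENa-Kv2-SK-1.5, cm_factor: 1.5, cm_region: sprx, ca_out_factor: 10.0, reversals: {na: 10}, conductances: {Kv2like: 1.5, SK: 1.5}}
  - {label: E-ECa-ENa-Kv2-SK-4, cm_factor: 1.5, cm_region: sprx, ca_out_factor: 10.0, reversals: {na: 10}, conductances: {Kv2like: 4, SK: 4}}
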
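# firesweep

Conductance-based compartmental neuron simulation and firing-rate parameter
sweeps: how changes in specific membrane capacitance, maximal ion-channel
conductances and ionic reversal potentials reshape the f–I curves of
fast-spiking interneuron models.

The package implements the full pipeline:

* **morphology** — SWC parsing, parametric morphologies, equal-length
  compartmentalization, path distances, and the soma + proximal-dendrite
  ("sprx", < 3.5 soma lengths) region mask.
* **mechanisms** — data-driven channel definitions (YAML rate expressions),
  Hodgkin–Huxley-style gates, calcium-activated (Hill) gates, Markov schemes,
  single-shell calcium pools and the Nernst reversal relation.
* **cable_solver** — theta-method (Crank–Nicolson by default, backward Euler
  at `theta=1`) integration of the branched cable equation with staggered
  exact-exponential gate updates, direct Hines tree solve, dynamic calcium
  reversal, at the study's fixed `dt = 0.0078125 ms` with a 600 ms settle.
  Numba-accelerated when available, pure-Python fallback otherwise.
* **model_library** — the one-compartment (OC) and ball-and-stick (BAS)
  squid-kinetics models, perisomatic multicompartment models built from
  parameter bundles (SWC + JSON), and a reproducible synthetic-fixture
  generator so everything runs without downloads.
* **protocols** — spike detection (strict local maxima above −20 mV),
  sustained-firing frequencies, f–I sweeps with depolarization-block
  termination, 0.001 nA threshold search, spike width at −40 mV.
* **perturbations** — capacitance scaling (whole-cell or sprx-restricted),
  conductance factors (0.3–10×), reversal shifts (±20 mV; calcium via the
  fixed extracellular concentration), scan/scenario drivers and the
  relative-difference-at-max-common-current statistic, with bundled
  `fig2`…`fig6` study-design configs.

## CLI

```bash
firesweep fi OC --out out/                    # f-I curve
firesweep threshold BAS --out out/            # rheobase on the 0.001 nA grid
firesweep scan OC fig2 --out out/             # bundled study-design config
firesweep scenarios synthetic:1 fig6 --out out/
firesweep make-fixture --seed 7 --out bundle/ # synthetic parameter bundle
firesweep fi bundle/ --out out/               # run a bundle directory
```

Model references are `OC`, `BAS`, `synthetic:<seed>` or a parameter-bundle
directory (`morphology.swc` + `parameters.json`; see
`firesweep.model_library` for the schema). Every command writes a
`*.manifest.json` with the command, model/config hashes, dt, seed and output
list; deterministic runs reproduce byte-for-byte.

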
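"""Model construction: the study's named configurations plus synthetic cells.

The library builds the one-compartment (OC) and ball-and-stick (BAS)
squid-kinetics models exactly as parameterized, constructs perisomatic
multicompartment models from external parameter bundles, and generates
reproducible random branched fixtures ("synthetic" models) so that every
pipeline stage runs without downloads.

A *parameter bundle* is a directory holding ``morphology.swc`` and
``parameters.json`` with keys::

    {"name": ..., "v_init": mV, "celsius": C, "ra": Ohm cm, "cm": uF/cm^2,
     "conductances": {"NaV": S/cm^2, ... all eleven mechanisms ...},
     "erev": {"na": mV, "k": mV},            # optional overrides
     "ca": {"ca_out": mM, "decay": ms, "gamma": ..., "depth_um": ...}}
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mechanisms import (
    ALLEN_MECHANISMS,
    FARADAY,
    CalciumPool,
    MechanismSpec,
    NernstParams,
    bundled_mechanisms,
)
from .morphology import (
    AXON,
    DENDRITE,
    SOMA,
    CompartmentalizedCell,
    Morphology,
    Section,
    discretize,
    load_swc,
)

#: stimulus duration rules (ms)
HH_STIM_DURATION = 1000.0
ALLEN_STIM_DURATION = 2000.0


class BundleError(ValueError):
    pass


@dataclass
class Placement:
    """One mechanism inserted on a set of segments with a conductance."""

    mech: MechanismSpec
    mask: np.ndarray  # bool per segment
    gbar: float  # S/cm^2 (authoritative; may be perturbed per model)


@dataclass
class CaConfig:
    """Calcium pool plus the Nernst parameters for the dynamic reversal."""

    pool: CalciumPool
    nernst: NernstParams


@dataclass(eq=False)
class ModelSpec:
    """A runnable model: discretized cell, mechanism placements, protocol
    defaults.  ``rate_window`` is the interval (ms, relative to stimulus
    onset) over which firing frequencies are measured."""

    name: str
    cell: CompartmentalizedCell
    placements: list[Placement]
    temperature: float  # deg C
    v_init: float
    stim_duration: float
    rate_window: tuple[float, float]
    ca: CaConfig | None = None
    settle: float = 600.0
    source: dict = field(default_factory=dict)

    def copy(self) -> "ModelSpec":
        import copy as _copy

        return _copy.deepcopy(self)

    def mechanism_names(self) -> list[str]:
        return [pl.mech.name for pl in self.placements]

    def placement(self, mech_name: str) -> Placement:
        for pl in self.placements:
            if pl.mech.name == mech_name:
                return pl
        raise KeyError(mech_name)

    def equals(self, other: "ModelSpec") -> bool:
        if self.name != other.name or len(self.placements) != len(other.placements):
            return False
        if not np.allclose(self.cell.cm, other.cell.cm):
            return False
        for a, b in zip(self.placements, other.placements):
            if a.mech.name != b.mech.name or a.gbar != b.gbar:
                return False
            if (a.mech.erev is None) != (b.mech.erev is None):
                return False
            if a.mech.erev is not None and a.mech.erev != b.mech.erev:
                return False
            if not np.array_equal(a.mask, b.mask):
                return False
        if (self.ca is None) != (other.ca is None):
            return False
        if self.ca is not None and self.ca.pool.ca_out != other.ca.pool.ca_out:
            return False
        return True


def _soma_morphology(length: float, diam: float) -> Morphology:
    return Morphology(
        sections=[Section(id=0, stype=SOMA, length=length, diam=diam)], name="soma"
    )


def build_oc() -> ModelSpec:
    """One-compartment 10 um x 10 um soma with the squid Na/K/leak trio."""
    morph = _soma_morphology(10.0, 10.0)
    cell = discretize(morph, nseg_overrides={0: 1})
    cell.name = "OC"
    mechs = bundled_mechanisms("hh")
    soma = cell.region_mask("soma")
    placements = [Placement(mech=mechs[m].copy(), mask=soma, gbar=mechs[m].gbar)
                  for m in ("na_hh", "k_hh", "leak")]
    return ModelSpec(
        name="OC",
        cell=cell,
        placements=placements,
        temperature=6.3,
        v_init=-65.0,
        stim_duration=HH_STIM_DURATION,
        rate_window=(0.0, HH_STIM_DURATION),
    )


def build_bas() -> ModelSpec:
    """Ball-and-stick: 10 um soma (active) + 1000 um x 1 um passive dendrite
    in 5 um segments; dendritic leak -65 mV at 0.0003 S/cm^2, Ra 100 Ohm cm."""
    morph = Morphology(
        sections=[
            Section(id=0, stype=SOMA, length=10.0, diam=10.0),
            Section(id=1, stype=DENDRITE, length=1000.0, diam=1.0, parent=0, parent_pos=0.5),
        ],
        name="BAS",
    )
    cell = discretize(morph, max_seg_len=5.0, nseg_overrides={0: 1}, ra=100.0)
    cell.name = "BAS"
    mechs = bundled_mechanisms("hh")
    soma = cell.region_mask("soma")
    dend = np.isin(cell.seg_region, (1, 2))
    placements = [Placement(mech=mechs[m].copy(), mask=soma, gbar=mechs[m].gbar)
                  for m in ("na_hh", "k_hh", "leak")]
    dend_leak = MechanismSpec(name="leak_dend", gbar=0.0003, ion=None, erev=-65.0)
    placements.append(Placement(mech=dend_leak, mask=dend, gbar=0.0003))
    return ModelSpec(
        name="BAS",
        cell=cell,
        placements=placements,
        temperature=6.3,
        v_init=-65.0,
        stim_duration=HH_STIM_DURATION,
        rate_window=(0.0, HH_STIM_DURATION),
    )


def _replace_axon(morph: Morphology) -> Morphology:
    """Drop native axon sections; attach a 60 um x 1 um initial-segment stub
    (two sections, discretized as two segments each)."""
    keep = [s for s in morph.sections if s.stype != AXON]
    kept_ids = {s.id for s in keep}
    for s in keep:
        if s.parent is not None and s.parent not in kept_ids:
            raise BundleError(f"section {s.id} attaches to a removed axon section")
    next_id = max(s.id for s in keep) + 1
    soma_id = next(s.id for s in keep if s.stype == SOMA)
    stub1 = Section(id=next_id, stype=AXON, length=30.0, diam=1.0, parent=soma_id, parent_pos=0.5)
    stub2 = Section(id=next_id + 1, stype=AXON, length=30.0, diam=1.0, parent=next_id)
    return Morphology(sections=keep + [stub1, stub2], name=morph.name)


def build_allen_style(
    bundle, max_seg_len: float = 20.0, mechanisms: dict[str, MechanismSpec] | None = None
) -> ModelSpec:
    """Build a perisomatic model from a parameter bundle (path or dict).

    Active mechanisms are placed on the soma only; the passive leak covers
    every segment.  The native axon is replaced by the standard
    60 um initial-segment stub before discretization.
    """
    if isinstance(bundle, (str, Path)):
        bdir = Path(bundle)
        swc_text = (bdir / "morphology.swc").read_text()
        params = json.loads((bdir / "parameters.json").read_text())
    else:
        swc_text = bundle["swc"]
        params = bundle["parameters"]

    cond = params.get("conductances", {})
    missing = [m for m in ALLEN_MECHANISMS if m not in cond]
    if missing:
        raise BundleError(f"bundle missing conductances for: {', '.join(missing)}")

    mechs = mechanisms or bundled_mechanisms("allen_template")
    morph = _replace_axon(load_swc(swc_text, name=params.get("name", "allen")))
    stub_ids = [s.id for s in morph.sections if s.stype == AXON]
    overrides = {sid: 2 for sid in stub_ids}
    cell = discretize(morph, max_seg_len=max_seg_len, nseg_overrides=overrides,
                      ra=float(params.get("ra", 100.0)))
    cell.cm[:] = float(params.get("cm", 1.0))
    cell.name = params.get("name", "allen")

    erev = params.get("erev", {})
    soma = cell.region_mask("soma")
    everywhere = np.ones(cell.n, dtype=bool)
    placements = []
    for mname in ALLEN_MECHANISMS:
        mech = mechs[mname].copy()
        mech.gbar = float(cond[mname])
        if mech.ion in erev:
            mech.erev = float(erev[mech.ion])
        mask = everywhere if mname == "leak" else soma
        placements.append(Placement(mech=mech, mask=mask, gbar=mech.gbar))

    ca_params = params.get("ca", {})
    gamma = float(ca_params.get("gamma", 0.05))
    depth = float(ca_params.get("depth_um", 0.1))
    pool = CalciumPool(
        ca_rest=float(ca_params.get("ca_rest", 1e-4)),
        tau=float(ca_params.get("decay", 80.0)),
        k=1e4 * gamma / (2 * FARADAY * depth),
        ca_out=float(ca_params.get("ca_out", 2.0)),
    )
    celsius = float(params.get("celsius", 34.0))
    ca = CaConfig(pool=pool, nernst=NernstParams(T=273.15 + celsius, z=2))
    return ModelSpec(
        name=params.get("name", "allen"),
        cell=cell,
        placements=placements,
        temperature=celsius,
        v_init=float(params.get("v_init", -80.0)),
        stim_duration=ALLEN_STIM_DURATION,
        rate_window=(ALLEN_STIM_DURATION - 1000.0, ALLEN_STIM_DURATION),
        ca=ca,
        source={"kind": "bundle"},
    )


#: conductance ranges (S/cm^2) sampled by the synthetic generator
SYNTHETIC_GBAR_RANGES = {
    "NaV": (0.15, 0.3),
    "Kd": (0.03, 0.06),
    "Kv3_1": (0.002, 0.008),
    "Kv2like": (0.0005, 0.002),
    "K_T": (1e-5, 2e-4),
    "Im_v2": (1e-6, 5e-5),
    "Ih": (1e-6, 5e-5),
    "SK": (0.008, 0.02),
    "Ca_HVA": (1e-4, 4e-4),
    "Ca_LVA": (1e-6, 5e-5),
    "leak": (0.0002, 0.0004),
}


def _synthetic_swc(rng: np.random.Generator, n_dendrites: int, depth: int) -> str:
    """Random branched morphology as SWC text (deterministic per rng state)."""
    soma_r = rng.uniform(5.0, 10.0)
    lines = ["# synthetic morphology", f"1 1 0.0000 0.0000 0.0000 {soma_r:.4f} -1"]
    next_id = 2

    def grow(parent_id: int, origin, direction, diam: float, level: int) -> None:
        nonlocal next_id
        length = rng.uniform(20.0, 200.0)
        npts = 3
        pid = parent_id
        pos = np.array(origin, dtype=float)
        for i in range(npts):
            pos = pos + np.asarray(direction) * (length / npts)
            lines.append(
                f"{next_id} 3 {pos[0]:.4f} {pos[1]:.4f} {pos[2]:.4f} {diam / 2:.4f} {pid}"
            )
            pid = next_id
            next_id += 1
        if level < depth:
            for _ in range(2):
                d = np.asarray(direction) + rng.normal(0, 0.4, 3)
                d /= np.linalg.norm(d)
                grow(pid, pos, d, max(0.5, diam * 0.75), level + 1)

    for _ in range(n_dendrites):
        d = rng.normal(0, 1, 3)
        d /= np.linalg.norm(d)
        start = np.asarray(d) * soma_r
        first_diam = rng.uniform(1.0, 2.0)
        grow(1, start, d, first_diam, 1)
    return "\n".join(lines) + "\n"


def generate_synthetic_cell(
    seed: int, n_dendrites: int = 4, depth: int = 2
) -> tuple[ModelSpec, str, dict]:
    """Reproducible random perisomatic fixture.

    Returns ``(model, swc_text, bundle_dict)``; the bundle dict round-trips
    through :func:`build_allen_style` and :func:`write_bundle`.
    """
    if n_dendrites < 1:
        raise ValueError("n_dendrites must be >= 1")
    rng = np.random.default_rng(seed)
    swc_text = _synthetic_swc(rng, n_dendrites, depth)
    cond = {m: float(rng.uniform(*SYNTHETIC_GBAR_RANGES[m])) for m in ALLEN_MECHANISMS}
    params = {
        "name": f"synthetic-{seed}",
        "v_init": -70.0,
        "celsius": 34.0,
        "ra": 100.0,
        "cm": 1.0,
        "conductances": cond,
        "erev": {"na": 53.0, "k": -90.0},
        "ca": {"ca_out": 2.0, "decay": 80.0, "gamma": 0.05, "depth_um": 0.1, "ca_rest": 1e-4},
        "seed": seed,
    }
    bundle = {"swc": swc_text, "parameters": params}
    model = build_allen_style(bundle)
    model.source = {"kind": "synthetic", "seed": seed}
    return model, swc_text, bundle


def write_bundle(bundle: dict, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "morphology.swc").write_text(bundle["swc"])
    (out / "parameters.json").write_text(json.dumps(bundle["parameters"], indent=1))
    return out


def study_configurations(
    bundles: list | None = None, synthetic_seeds: tuple = (1, 2, 3)
) -> list[tuple[ModelSpec, str]]:
    """The nine study configurations: OC, BAS x {all, sprx} and three
    multicompartment models x {all, sprx}.

    The multicompartment slots are filled from ``bundles`` (parameter-bundle
    paths or dicts) when given, otherwise from synthetic stand-ins.
    """
    configs: list[tuple[ModelSpec, str]] = [(build_oc(), "all")]
    bas = build_bas()
    configs += [(bas, "all"), (bas.copy(), "sprx")]
    if bundles:
        multis = [build_allen_style(b) for b in bundles]
    else:
        multis = [generate_synthetic_cell(s)[0] for s in synthetic_seeds]
    for m in multis:
        configs += [(m, "all"), (m.copy(), "sprx")]
    return configs


def resolve_model(ref: str) -> ModelSpec:
    """Resolve a model reference: ``OC``, ``BAS``, ``synthetic:<seed>`` or a
    parameter-bundle directory path."""
    if ref == "OC":
        return build_oc()
    if ref == "BAS":
        return build_bas()
    if ref.startswith("synthetic:"):
        seed = int(ref.split(":", 1)[1])
        return generate_synthetic_cell(seed)[0]
    p = Path(ref)
    if p.is_dir() and (p / "parameters.json").exists():
        return build_allen_style(p)
    raise KeyError(f"cannot resolve model reference {ref!r}")
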
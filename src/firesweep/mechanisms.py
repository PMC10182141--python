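"""Membrane mechanisms: gated channels, leak, calcium pools, Nernst reversals.

Channel kinetics are data, not code: rate expressions live in YAML mechanism
definition files (see ``data/hh.yaml`` for the squid-axon trio and
``data/allen_template.yaml`` for a schema-complete eleven-mechanism set with
simplified fast-spiking kinetics).  The definition schema::

    mechanisms:
      <name>:
        gbar: <S/cm^2>
        ion: na | k | ca | nonspecific | null     # null = leak
        erev: <mV>            # omit for ion: ca (dynamic Nernst reversal)
        gates:                # voltage-dependent gates, any number
          <gate>:
            exponent: <int>
            alpha: "<expr in V, 1/ms>"   # either alpha/beta ...
            beta: "<expr in V, 1/ms>"
            inf: "<expr in V>"           # ... or inf/tau
            tau: "<expr in V, ms>"
            q10: <float>                 # optional temperature scaling
            ref_temp: <deg C>
        ca_activation:        # calcium-activated gate (e.g. SK), instead of
          ca_half: <mM>       # voltage gates: x_inf = 1/(1+(ca_half/ca)^hill)
          hill: <float>
          tau: <ms>
        markov:               # optional Markov scheme, instead of gates
          states: [c, o, ...]
          rates: {"c->o": "<expr in V, 1/ms>", ...}
          conducting: [o]

Rate expressions are evaluated with numpy on a voltage grid; removable
singularities (0/0 points of the linoid form) are repaired by interpolation
from neighbouring grid values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy import constants

GAS_CONSTANT = constants.R  # J/(mol K)
FARADAY = constants.physical_constants["Faraday constant"][0]  # C/mol

#: voltage grid used to tabulate gate rate functions (mV)
TABLE_VMIN = -150.0
TABLE_VMAX = 100.0
TABLE_DV = 0.05

#: lower bound on intracellular calcium so the Nernst term stays defined (mM)
CA_FLOOR = 1e-10

HH_MECHANISMS = ("na_hh", "k_hh", "leak")
ALLEN_MECHANISMS = (
    "Ih",
    "NaV",
    "Kd",
    "Kv2like",
    "K_T",
    "Kv3_1",
    "Im_v2",
    "SK",
    "Ca_HVA",
    "Ca_LVA",
    "leak",
)


class MechanismSchemaError(ValueError):
    """Raised when a mechanism definition violates the schema."""


class DomainError(ValueError):
    pass


@dataclass
class NernstParams:
    """Physical constants for the Nernst relation."""

    T: float  # K
    z: int
    R: float = GAS_CONSTANT
    F: float = FARADAY

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise DomainError("temperature must be positive")
        if self.z == 0:
            raise DomainError("valence must be nonzero")


def nernst(params: NernstParams, c_out: float, c_in: float) -> float:
    """Reversal potential (mV): ``(R T / z F) ln(c_out / c_in)``."""
    if c_out <= 0 or c_in <= 0:
        raise DomainError("concentrations must be positive")
    return 1e3 * params.R * params.T / (params.z * params.F) * math.log(c_out / c_in)


def _eval_rate(expr: str, v: np.ndarray) -> np.ndarray:
    ns = {
        "V": v,
        "exp": np.exp,
        "log": np.log,
        "log10": np.log10,
        "sqrt": np.sqrt,
        "tanh": np.tanh,
        "abs": np.abs,
        "where": np.where,
        "pi": np.pi,
    }
    try:
        with np.errstate(all="ignore"):
            out = eval(expr, {"__builtins__": {}}, ns)  # noqa: S307 - trusted data files
    except Exception as exc:
        raise MechanismSchemaError(f"cannot evaluate rate expression {expr!r}: {exc}") from exc
    out = np.asarray(out, dtype=float)
    if out.shape != v.shape:
        out = np.full_like(v, float(out))
    bad = ~np.isfinite(out)
    if bad.any():
        if bad.all():
            raise MechanismSchemaError(f"rate expression {expr!r} is nowhere finite")
        out[bad] = np.interp(v[bad], v[~bad], out[~bad])
    return out


@dataclass
class GateSpec:
    """One gating variable: exponent plus voltage (or calcium) rate laws."""

    name: str
    exponent: int
    alpha: str | None = None
    beta: str | None = None
    inf: str | None = None
    tau: str | None = None
    q10: float | None = None
    ref_temp: float | None = None
    # calcium-activated form (Hill function of [Ca]_in)
    ca_half: float | None = None
    hill: float | None = None
    ca_tau: float | None = None

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise MechanismSchemaError(f"gate {self.name}: exponent must be >= 0")
        has_ab = self.alpha is not None and self.beta is not None
        has_it = self.inf is not None and self.tau is not None
        has_ca = self.ca_half is not None
        if sum((has_ab, has_it, has_ca)) != 1:
            raise MechanismSchemaError(
                f"gate {self.name}: exactly one of alpha/beta, inf/tau or "
                "calcium activation must be given"
            )

    @property
    def is_calcium_gate(self) -> bool:
        return self.ca_half is not None

    def q10_factor(self, temperature: float) -> float:
        """Rate speed-up at ``temperature`` (deg C); divides tau."""
        if self.q10 is None or self.ref_temp is None:
            return 1.0
        return float(self.q10 ** ((temperature - self.ref_temp) / 10.0))

    def inf_tau(self, v, temperature: float = 6.3):
        """Steady state and time constant on a voltage array (voltage gates)."""
        if self.is_calcium_gate:
            raise MechanismSchemaError(f"gate {self.name} is calcium-activated, not voltage gated")
        v = np.atleast_1d(np.asarray(v, dtype=float))
        if self.alpha is not None:
            a = _eval_rate(self.alpha, v)
            b = _eval_rate(self.beta, v)
            inf = a / (a + b)
            tau = 1.0 / (a + b)
        else:
            inf = _eval_rate(self.inf, v)
            tau = _eval_rate(self.tau, v)
        tau = tau / self.q10_factor(temperature)
        if np.any(tau <= 0):
            raise MechanismSchemaError(f"gate {self.name}: tau <= 0 on the voltage grid")
        return inf, tau

    def ca_inf_tau(self, ca: float):
        """Steady state and time constant for calcium-activated gates."""
        ca = max(float(ca), CA_FLOOR)
        inf = 1.0 / (1.0 + (self.ca_half / ca) ** self.hill)
        return inf, self.ca_tau


def gate_derivative(gate: GateSpec, x: float, v: float, temperature: float = 6.3) -> float:
    """``dx/dt = (inf(V) - x) / tau(V)`` in 1/ms."""
    if not (-1e-9 <= x <= 1 + 1e-9):
        raise ValueError(f"gate value {x} outside [0, 1]")
    inf, tau = gate.inf_tau(np.array([v]), temperature)
    return float((inf[0] - x) / tau[0])


@dataclass
class MarkovScheme:
    """Voltage-dependent Markov scheme with named states."""

    states: list[str]
    rates: dict[str, str]  # "from->to" -> rate expression (1/ms)
    conducting: list[str]

    def __post_init__(self) -> None:
        for key in self.rates:
            src, _, dst = key.partition("->")
            if src not in self.states or dst not in self.states:
                raise MechanismSchemaError(f"markov rate {key!r} names unknown state")
        for c in self.conducting:
            if c not in self.states:
                raise MechanismSchemaError(f"conducting state {c!r} unknown")

    def generator(self, v: float) -> np.ndarray:
        """Generator matrix Q at voltage ``v``: occ' = occ @ Q."""
        n = len(self.states)
        idx = {s: i for i, s in enumerate(self.states)}
        q = np.zeros((n, n))
        for key, expr in self.rates.items():
            src, _, dst = key.partition("->")
            rate = float(_eval_rate(expr, np.array([float(v)]))[0])
            if rate < 0:
                raise MechanismSchemaError(f"negative markov rate for {key!r} at V={v}")
            q[idx[src], idx[dst]] += rate
        q[np.diag_indices(n)] -= q.sum(axis=1)
        return q

    def open_fraction(self, occupancies: np.ndarray) -> float:
        idx = {s: i for i, s in enumerate(self.states)}
        return float(sum(occupancies[idx[c]] for c in self.conducting))


def markov_step(scheme: MarkovScheme, occupancies: np.ndarray, v: float, dt: float) -> np.ndarray:
    """Advance occupancies one step by the exact exponential ``occ @ e^{Q dt}``.

    Uses an eigendecomposition of the generator (independent of the
    ``scipy.linalg.expm`` oracle used in the tests), falling back to a scaled
    Taylor series for defective matrices.
    """
    occ = np.asarray(occupancies, dtype=float)
    if abs(occ.sum() - 1.0) > 1e-6 or np.any(occ < -1e-9):
        raise ValueError("occupancies must be a probability vector")
    q = scheme.generator(v)
    try:
        w, vecs = np.linalg.eig(q.T)
        prop = (vecs @ np.diag(np.exp(w * dt)) @ np.linalg.inv(vecs)).T
        if not np.all(np.isfinite(prop)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        m = q * dt
        prop = np.eye(len(occ))
        term = np.eye(len(occ))
        for k in range(1, 30):
            term = term @ m / k
            prop = prop + term
    out = occ @ np.real(prop)
    out = np.clip(out, 0.0, None)
    return out / out.sum()


@dataclass
class CalciumPool:
    """Single-shell intracellular calcium pool (exponential-decay model).

    ``d[Ca]/dt = -k i_Ca - ([Ca] - [Ca]_rest) / tau`` with ``i_Ca`` in
    mA/cm^2 (inward negative), ``k`` in mM cm^2 / (mA ms).  Defaults follow
    the perisomatic-model convention: a 0.1 um shell collecting 5% of the
    calcium current, 80 ms decay, 1e-4 mM resting level.
    """

    ca_rest: float = 1e-4  # mM
    tau: float = 80.0  # ms
    k: float = 1e4 * 0.05 / (2 * FARADAY * 0.1)  # mM cm^2/(mA ms)
    ca_out: float = 2.0  # mM, fixed
    ca_min: float = CA_FLOOR
    ca_in: float = None  # mM, state

    def __post_init__(self) -> None:
        if self.ca_in is None:
            self.ca_in = self.ca_rest
        if self.tau <= 0 or self.ca_rest <= 0 or self.ca_out <= 0:
            raise DomainError("calcium pool parameters must be positive")


def calcium_derivative(pool: CalciumPool, i_ca: float) -> float:
    """``d[Ca]_in/dt`` (mM/ms) for a calcium current density in mA/cm^2."""
    return -pool.k * i_ca - (pool.ca_in - pool.ca_rest) / pool.tau


@dataclass
class MechanismSpec:
    """A channel definition: maximal conductance, reversal linkage, gating."""

    name: str
    gbar: float  # S/cm^2
    ion: str | None = None  # na | k | ca | nonspecific | None (leak)
    erev: float | None = None  # mV; None for dynamic-calcium reversal
    gates: list[GateSpec] = field(default_factory=list)
    markov: MarkovScheme | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.gbar < 0:
            problems.append(f"gbar={self.gbar} (must be >= 0)")
        if self.ion == "ca":
            if self.erev is not None:
                problems.append("erev given for a calcium mechanism (reversal is dynamic)")
        elif self.erev is None:
            problems.append("missing erev/ion binding")
        if self.markov is not None and self.gates:
            problems.append("both gates and a markov scheme given")
        if problems:
            raise MechanismSchemaError(f"mechanism {self.name}: " + "; ".join(problems))

    @property
    def writes_calcium(self) -> bool:
        return self.ion == "ca"

    def copy(self) -> "MechanismSpec":
        import copy as _copy

        return _copy.deepcopy(self)


def channel_current(mech: MechanismSpec, gate_values, v: float, e_x: float) -> float:
    """Ohmic channel current density ``gbar * prod(x_i^exp_i) * (V - E)``.

    Units: gbar in S/cm^2 and V in mV give mA/cm^2.  For Markov mechanisms
    pass the state occupancies; the open fraction replaces the gate product.
    """
    if mech.markov is not None:
        occ = np.asarray(gate_values, dtype=float)
        if abs(occ.sum() - 1.0) > 1e-6:
            raise ValueError("markov occupancies must sum to 1")
        openf = mech.markov.open_fraction(occ)
        return mech.gbar * openf * (v - e_x)
    prod = 1.0
    for gate, x in zip(mech.gates, np.atleast_1d(gate_values)):
        if not (-1e-9 <= x <= 1 + 1e-9):
            raise ValueError(f"gate {gate.name} value {x} outside [0, 1]")
        prod *= float(x) ** gate.exponent
    return mech.gbar * prod * (v - e_x)


def _parse_gate(name: str, raw: dict) -> GateSpec:
    if not isinstance(raw, dict):
        raise MechanismSchemaError(f"gate {name}: expected a mapping")
    return GateSpec(
        name=name,
        exponent=int(raw.get("exponent", 1)),
        alpha=raw.get("alpha"),
        beta=raw.get("beta"),
        inf=raw.get("inf"),
        tau=raw.get("tau"),
        q10=raw.get("q10"),
        ref_temp=raw.get("ref_temp"),
    )


def _parse_mechanism(name: str, raw: dict) -> MechanismSpec:
    unknown = set(raw) - {"gbar", "ion", "erev", "gates", "ca_activation", "markov", "notes"}
    if unknown:
        raise MechanismSchemaError(f"mechanism {name}: unknown fields {sorted(unknown)}")
    if "gbar" not in raw:
        raise MechanismSchemaError(f"mechanism {name}: missing gbar")
    gates = [_parse_gate(gn, g) for gn, g in (raw.get("gates") or {}).items()]
    ca_act = raw.get("ca_activation")
    if ca_act is not None:
        missing = {"ca_half", "hill", "tau"} - set(ca_act)
        if missing:
            raise MechanismSchemaError(f"mechanism {name}: ca_activation missing {sorted(missing)}")
        if gates:
            raise MechanismSchemaError(f"mechanism {name}: both gates and ca_activation given")
        gates = [
            GateSpec(
                name="z",
                exponent=int(ca_act.get("exponent", 1)),
                ca_half=float(ca_act["ca_half"]),
                hill=float(ca_act["hill"]),
                ca_tau=float(ca_act["tau"]),
            )
        ]
    markov = None
    if raw.get("markov") is not None:
        m = raw["markov"]
        markov = MarkovScheme(
            states=list(m["states"]), rates=dict(m["rates"]), conducting=list(m["conducting"])
        )
    return MechanismSpec(
        name=name,
        gbar=float(raw["gbar"]),
        ion=raw.get("ion"),
        erev=None if raw.get("erev") is None else float(raw["erev"]),
        gates=gates,
        markov=markov,
    )


def load_mechanism_set(source: str) -> dict[str, MechanismSpec]:
    """Load mechanism definitions from YAML text or a file path."""
    text = source
    if "\n" not in source and source.endswith((".yaml", ".yml")):
        with open(source) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "mechanisms" not in doc:
        raise MechanismSchemaError("definition file must contain a 'mechanisms' mapping")
    out = {}
    for name, raw in doc["mechanisms"].items():
        out[name] = _parse_mechanism(name, raw)
    return out


def bundled_mechanisms(which: str) -> dict[str, MechanismSpec]:
    """Load a bundled definition set: ``"hh"`` or ``"allen_template"``."""
    text = resources.files("firesweep.data").joinpath(f"{which}.yaml").read_text()
    return load_mechanism_set(text)
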
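"""Implicit integration of the branched cable equation.

Per compartment ``j``::

    c_m,j dV_j/dt = -i_L,j - sum_X i_X,j + I_stim,j / A_j + (axial currents) / A_j

The voltage step is a theta-method solve (theta = 1: backward Euler,
theta = 0.5: Crank-Nicolson, the default) of the linearized membrane plus
axial system on the compartment tree (direct Hines elimination, no
iteration).  Gating variables are advanced by the exact exponential update of
their linear ODE at the start-of-step voltage, staggered with the voltage
solve; calcium pools use the same exact update and the calcium reversal is
recomputed from the Nernst relation every step.

Units: mV, ms, nA, uF/cm^2; conductance densities are converted to mS/cm^2
internally so that ``g * V`` is in uA/cm^2, matching ``c_m dV/dt``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .mechanisms import (
    CA_FLOOR,
    TABLE_DV,
    TABLE_VMAX,
    TABLE_VMIN,
    MechanismSpec,
    NernstParams,
    nernst,
)
from .morphology import CompartmentalizedCell

try:  # numba is optional; the pure-python fallback is identical but slow
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


#: the fixed simulation time step used throughout the study (ms)
DEFAULT_DT = 0.0078125
#: settling time before the recording starts (ms)
DEFAULT_SETTLE = 600.0


class NumericalBlowupError(RuntimeError):
    pass


class TopologyError(ValueError):
    pass


@dataclass
class StimulusProtocol:
    """Constant-current step injected into one segment (default: soma)."""

    amplitude: float  # nA
    duration: float  # ms
    onset: float = 0.0  # ms relative to the recorded window
    settle: float = DEFAULT_SETTLE  # ms simulated before recording
    segment: int | None = None  # defaults to the soma segment

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.settle < 0:
            raise ValueError("settle must be >= 0")


@dataclass
class VoltageTrace:
    """Somatic potential on a uniform time grid covering the stimulus window."""

    dt: float
    v: np.ndarray  # mV
    t0: float = 0.0  # absolute time of the first sample (= settle + dt)

    @property
    def t(self) -> np.ndarray:
        """Time (ms) relative to stimulus onset; first sample at ``dt``."""
        return (np.arange(len(self.v)) + 1) * self.dt

    def to_csv(self, path, meta: dict | None = None) -> None:
        arr = np.column_stack([self.t, self.v])
        np.savetxt(path, arr, delimiter=",", header="t_ms,v_mV", comments="")
        if meta is not None:
            with open(str(path) + ".json", "w") as fh:
                json.dump({"dt": self.dt, "t0": self.t0, **meta}, fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "VoltageTrace":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        dt = float(arr[1, 0] - arr[0, 0])
        return cls(dt=dt, v=arr[:, 1])


def assemble_axial_conductances(cell: CompartmentalizedCell) -> dict[tuple[int, int], float]:
    """Axial coupling conductances in uS, keyed symmetrically by segment pair.

    ``g_jk = 1 / (r_j/2 + r_k/2)`` with ``r_i = 4 R_a l_i / (pi d_i^2)`` the
    full-segment axial resistance.
    """
    if cell.n > 1:
        reachable = np.zeros(cell.n, dtype=bool)
        reachable[0] = True
        for s in range(1, cell.n):
            p = cell.parent_seg[s]
            if p < 0 or not reachable[p]:
                raise TopologyError(f"segment {s} is disconnected from the root")
            reachable[s] = True
    table: dict[tuple[int, int], float] = {}
    g = _axial_g_us(cell)
    for s in range(1, cell.n):
        p = int(cell.parent_seg[s])
        table[(s, p)] = g[s]
        table[(p, s)] = g[s]
    return table


def _axial_g_us(cell: CompartmentalizedCell) -> np.ndarray:
    """Per-segment coupling conductance to the parent (uS); entry 0 unused."""
    l_cm = cell.seg_len * 1e-4
    d_cm = cell.seg_diam * 1e-4
    r_full = 4.0 * cell.ra * l_cm / (np.pi * d_cm**2)  # Ohm
    g = np.zeros(cell.n)
    for s in range(1, cell.n):
        p = cell.parent_seg[s]
        g[s] = 1e6 / (0.5 * r_full[s] + 0.5 * r_full[p])
    return g


@njit(cache=True)
def _simulate(
    n_steps,
    dt,
    theta,
    V,
    parent,
    gax,
    area,
    cm_dens,
    pt_seg,
    pt_g,
    pt_e,
    pt_edyn,
    pt_wca,
    pt_goff,
    pt_gn,
    gs_kind,
    gs_tab,
    gs_exp,
    gs_h1,
    gs_h2,
    gs_h3,
    x,
    inf_tab,
    tau_tab,
    vmin,
    dv,
    pool_of_seg,
    ca,
    eca,
    ca_rest,
    ca_tau,
    ca_k,
    ca_min,
    nernst_fac,
    ca_out,
    stim_seg,
    stim_amp,
    stim_i0,
    stim_i1,
    rec_seg,
    rec_i0,
    out,
):
    n = V.shape[0]
    P = pt_seg.shape[0]
    nv = inf_tab.shape[1]
    npool = ca.shape[0]
    G = np.zeros(n)
    GE = np.zeros(n)
    diag = np.zeros(n)
    rhs = np.zeros(n)
    off_sp = np.zeros(n)
    off_ps = np.zeros(n)
    ica = np.zeros(npool if npool > 0 else 1)
    for it in range(n_steps):
        # --- gating variables: exact exponential at V(t), staggered ---
        for i in range(P):
            s = pt_seg[i]
            for k in range(pt_goff[i], pt_goff[i] + pt_gn[i]):
                if gs_kind[k] == 0:
                    v = V[s]
                    if v < vmin:
                        v = vmin
                    fidx = (v - vmin) / dv
                    j = int(fidx)
                    if j >= nv - 1:
                        j = nv - 2
                    w = fidx - j
                    if w < 0.0:
                        w = 0.0
                    elif w > 1.0:
                        w = 1.0
                    row = gs_tab[k]
                    xinf = inf_tab[row, j] * (1.0 - w) + inf_tab[row, j + 1] * w
                    xtau = tau_tab[row, j] * (1.0 - w) + tau_tab[row, j + 1] * w
                else:
                    c = ca[pool_of_seg[s]]
                    if c < ca_min:
                        c = ca_min
                    xinf = 1.0 / (1.0 + (gs_h1[k] / c) ** gs_h2[k])
                    xtau = gs_h3[k]
                x[k] = xinf + (x[k] - xinf) * np.exp(-dt / xtau)
        # --- channel conductances (mS/cm^2) ---
        for s in range(n):
            G[s] = 0.0
            GE[s] = 0.0
        for i in range(P):
            s = pt_seg[i]
            gp = pt_g[i]
            for k in range(pt_goff[i], pt_goff[i] + pt_gn[i]):
                xv = x[k]
                for _ in range(gs_exp[k]):
                    gp *= xv
            if pt_edyn[i] == 1:
                e = eca[pool_of_seg[s]]
            else:
                e = pt_e[i]
            G[s] += gp
            GE[s] += gp * e
        # --- theta-method voltage solve on the tree ---
        for s in range(n):
            diag[s] = cm_dens[s] / dt + theta * G[s]
            rhs[s] = cm_dens[s] / dt * V[s] - (1.0 - theta) * (G[s] * V[s] - GE[s]) + theta * GE[s]
        if stim_i0 <= it < stim_i1:
            rhs[stim_seg] += stim_amp * 1e-3 / area[stim_seg]  # nA -> uA/cm^2
        for s in range(1, n):
            p = parent[s]
            g_s = gax[s] * 1e-3 / area[s]
            g_p = gax[s] * 1e-3 / area[p]
            diag[s] += theta * g_s
            diag[p] += theta * g_p
            off_sp[s] = -theta * g_s
            off_ps[s] = -theta * g_p
            rhs[s] += (1.0 - theta) * g_s * (V[p] - V[s])
            rhs[p] += (1.0 - theta) * g_p * (V[s] - V[p])
        for s in range(n - 1, 0, -1):
            p = parent[s]
            f = off_ps[s] / diag[s]
            diag[p] -= f * off_sp[s]
            rhs[p] -= f * rhs[s]
        V[0] = rhs[0] / diag[0]
        for s in range(1, n):
            V[s] = (rhs[s] - off_sp[s] * V[parent[s]]) / diag[s]
        if not np.isfinite(V[0]):
            return it
        # --- calcium pools and dynamic reversal ---
        if npool > 0:
            for q in range(npool):
                ica[q] = 0.0
            for i in range(P):
                if pt_wca[i] == 1:
                    s = pt_seg[i]
                    gp = pt_g[i]
                    for k in range(pt_goff[i], pt_goff[i] + pt_gn[i]):
                        xv = x[k]
                        for _ in range(gs_exp[k]):
                            gp *= xv
                    q = pool_of_seg[s]
                    ica[q] += gp * (V[s] - eca[q]) * 1e-3  # mA/cm^2
            for q in range(npool):
                cinf = ca_rest - ca_k * ca_tau * ica[q]
                c = cinf + (ca[q] - cinf) * np.exp(-dt / ca_tau)
                if c < ca_min:
                    c = ca_min
                ca[q] = c
                eca[q] = nernst_fac * np.log(ca_out / c)
        if it >= rec_i0:
            out[it - rec_i0] = V[rec_seg]
    return -1


@dataclass
class CompiledModel:
    """Array (structure-of-arrays) form of a model, ready for the kernel."""

    n: int
    parent: np.ndarray
    gax: np.ndarray  # uS to parent
    area: np.ndarray  # cm^2
    cm_dens: np.ndarray  # uF/cm^2
    pt_seg: np.ndarray
    pt_g: np.ndarray  # mS/cm^2
    pt_e: np.ndarray
    pt_edyn: np.ndarray
    pt_wca: np.ndarray
    pt_goff: np.ndarray
    pt_gn: np.ndarray
    gs_kind: np.ndarray
    gs_tab: np.ndarray
    gs_exp: np.ndarray
    gs_h1: np.ndarray
    gs_h2: np.ndarray
    gs_h3: np.ndarray
    inf_tab: np.ndarray
    tau_tab: np.ndarray
    pool_of_seg: np.ndarray
    n_pools: int
    ca_rest: float
    ca_tau: float
    ca_k: float
    ca_out: float
    nernst_fac: float  # mV
    v_init: float
    soma_seg: int
    gate_names: list = field(default_factory=list)

    @classmethod
    def from_model(cls, model) -> "CompiledModel":
        cell: CompartmentalizedCell = model.cell
        n = cell.n
        gax = _axial_g_us(cell)
        area = cell.seg_area * 1e-8  # um^2 -> cm^2
        cm_dens = cell.cm.astype(float)

        temp = model.temperature
        grid = np.arange(TABLE_VMIN, TABLE_VMAX + TABLE_DV / 2, TABLE_DV)
        tables: dict[tuple[str, str], int] = {}
        inf_rows: list[np.ndarray] = []
        tau_rows: list[np.ndarray] = []

        pt_seg, pt_g, pt_e, pt_edyn, pt_wca, pt_goff, pt_gn = [], [], [], [], [], [], []
        gs_kind, gs_tab, gs_exp, gs_h1, gs_h2, gs_h3 = [], [], [], [], [], []
        gate_names = []
        has_ca_mech = False

        for pl in model.placements:
            mech: MechanismSpec = pl.mech
            if mech.markov is not None:
                raise NotImplementedError(
                    "the fast kernel integrates gate/Hill mechanisms; Markov "
                    "schemes are supported at the mechanism level only"
                )
            segs = np.flatnonzero(pl.mask)
            if segs.size == 0:
                continue
            if mech.writes_calcium:
                has_ca_mech = True
            gate_meta = []
            for gate in mech.gates:
                if gate.is_calcium_gate:
                    gate_meta.append((1, -1, gate.exponent, gate.ca_half, gate.hill, gate.ca_tau))
                else:
                    key = (mech.name, gate.name)
                    if key not in tables:
                        inf, tau = gate.inf_tau(grid, temp)
                        tables[key] = len(inf_rows)
                        inf_rows.append(inf)
                        tau_rows.append(tau)
                    gate_meta.append((0, tables[key], gate.exponent, 0.0, 0.0, 0.0))
            for s in segs:
                pt_seg.append(s)
                pt_g.append(pl.gbar * 1e3)  # S/cm^2 -> mS/cm^2
                if mech.writes_calcium:
                    pt_e.append(0.0)
                    pt_edyn.append(1)
                    pt_wca.append(1)
                else:
                    pt_e.append(mech.erev)
                    pt_edyn.append(0)
                    pt_wca.append(0)
                pt_goff.append(len(gs_kind))
                pt_gn.append(len(gate_meta))
                for gm, gate in zip(gate_meta, mech.gates):
                    gs_kind.append(gm[0])
                    gs_tab.append(gm[1])
                    gs_exp.append(gm[2])
                    gs_h1.append(gm[3])
                    gs_h2.append(gm[4])
                    gs_h3.append(gm[5])
                    gate_names.append((mech.name, gate.name, int(s)))

        uses_ca = model.ca is not None and (
            has_ca_mech or any(k == 1 for k in gs_kind)
        )
        pool_of_seg = np.full(n, -1, dtype=np.int64)
        n_pools = 0
        if uses_ca:
            pool_segs = sorted(
                {int(pt_seg[i]) for i in range(len(pt_seg)) if pt_wca[i] or
                 any(gs_kind[k] == 1 for k in range(pt_goff[i], pt_goff[i] + pt_gn[i]))}
            )
            for q, s in enumerate(pool_segs):
                pool_of_seg[s] = q
            n_pools = len(pool_segs)

        if inf_rows:
            inf_tab = np.vstack(inf_rows)
            tau_tab = np.vstack(tau_rows)
        else:
            inf_tab = np.zeros((1, len(grid)))
            tau_tab = np.ones((1, len(grid)))

        if uses_ca:
            ca_cfg = model.ca
            nernst_fac = (
                1e3 * ca_cfg.nernst.R * ca_cfg.nernst.T / (ca_cfg.nernst.z * ca_cfg.nernst.F)
            )
            ca_rest, ca_tau, ca_k, ca_out = (
                ca_cfg.pool.ca_rest,
                ca_cfg.pool.tau,
                ca_cfg.pool.k,
                ca_cfg.pool.ca_out,
            )
        else:
            nernst_fac, ca_rest, ca_tau, ca_k, ca_out = 13.0, 1e-4, 80.0, 0.0, 2.0

        return cls(
            n=n,
            parent=cell.parent_seg.astype(np.int64),
            gax=gax,
            area=area,
            cm_dens=cm_dens,
            pt_seg=np.asarray(pt_seg, dtype=np.int64),
            pt_g=np.asarray(pt_g, dtype=float),
            pt_e=np.asarray(pt_e, dtype=float),
            pt_edyn=np.asarray(pt_edyn, dtype=np.int64),
            pt_wca=np.asarray(pt_wca, dtype=np.int64),
            pt_goff=np.asarray(pt_goff, dtype=np.int64),
            pt_gn=np.asarray(pt_gn, dtype=np.int64),
            gs_kind=np.asarray(gs_kind, dtype=np.int64),
            gs_tab=np.asarray(gs_tab, dtype=np.int64),
            gs_exp=np.asarray(gs_exp, dtype=np.int64),
            gs_h1=np.asarray(gs_h1, dtype=float),
            gs_h2=np.asarray(gs_h2, dtype=float),
            gs_h3=np.asarray(gs_h3, dtype=float),
            inf_tab=inf_tab,
            tau_tab=tau_tab,
            pool_of_seg=pool_of_seg,
            n_pools=n_pools,
            ca_rest=ca_rest,
            ca_tau=ca_tau,
            ca_k=ca_k,
            ca_out=ca_out,
            nernst_fac=nernst_fac,
            v_init=model.v_init,
            soma_seg=int(cell.soma_segments[0]),
            gate_names=gate_names,
        )


@dataclass
class SimulationState:
    """Mutable per-segment state at one instant."""

    t: float
    v: np.ndarray
    gates: np.ndarray  # flat gate-slot values, see CompiledModel.gate_names
    ca: np.ndarray  # mM per pool
    eca: np.ndarray  # mV per pool
    compiled: CompiledModel

    def check(self) -> None:
        if not np.all(np.isfinite(self.v)):
            raise NumericalBlowupError(f"non-finite voltage at t={self.t}")
        if np.any(self.gates < -1e-9) or np.any(self.gates > 1 + 1e-9):
            raise ValueError("gate value outside [0, 1]")


def init_state(compiled: CompiledModel) -> SimulationState:
    """State at V_init with gates at steady state and calcium at rest."""
    v = np.full(compiled.n, compiled.v_init, dtype=float)
    gates = np.zeros(len(compiled.gs_kind))
    grid_idx = (compiled.v_init - TABLE_VMIN) / TABLE_DV
    j = int(grid_idx)
    w = grid_idx - j
    for k in range(len(gates)):
        if compiled.gs_kind[k] == 0:
            row = compiled.gs_tab[k]
            gates[k] = compiled.inf_tab[row, j] * (1 - w) + compiled.inf_tab[row, j + 1] * w
        else:
            ca = compiled.ca_rest
            gates[k] = 1.0 / (1.0 + (compiled.gs_h1[k] / ca) ** compiled.gs_h2[k])
    ca = np.full(compiled.n_pools, compiled.ca_rest)
    eca = np.full(compiled.n_pools, compiled.nernst_fac * np.log(compiled.ca_out / compiled.ca_rest))
    return SimulationState(t=0.0, v=v, gates=gates, ca=ca, eca=eca, compiled=compiled)


def step(
    state: SimulationState,
    dt: float,
    stim_amp: float = 0.0,
    stim_seg: int | None = None,
    theta: float = 0.5,
    n_steps: int = 1,
) -> SimulationState:
    """Advance the state by ``n_steps`` steps of ``dt`` in place."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    c = state.compiled
    out = np.empty(n_steps)
    bad = _simulate(
        n_steps,
        dt,
        theta,
        state.v,
        c.parent,
        c.gax,
        c.area,
        c.cm_dens,
        c.pt_seg,
        c.pt_g,
        c.pt_e,
        c.pt_edyn,
        c.pt_wca,
        c.pt_goff,
        c.pt_gn,
        c.gs_kind,
        c.gs_tab,
        c.gs_exp,
        c.gs_h1,
        c.gs_h2,
        c.gs_h3,
        state.gates,
        c.inf_tab,
        c.tau_tab,
        TABLE_VMIN,
        TABLE_DV,
        c.pool_of_seg,
        state.ca,
        state.eca,
        c.ca_rest,
        c.ca_tau,
        c.ca_k,
        CA_FLOOR,
        c.nernst_fac,
        c.ca_out,
        c.soma_seg if stim_seg is None else stim_seg,
        stim_amp,
        0 if stim_amp != 0.0 else n_steps,
        n_steps if stim_amp != 0.0 else n_steps,
        c.soma_seg,
        0,
        out,
    )
    if bad >= 0:
        raise NumericalBlowupError(f"non-finite voltage at t={state.t + bad * dt} ms")
    state.t += n_steps * dt
    state.check()
    return state


def run(
    model,
    protocol: StimulusProtocol,
    dt: float = DEFAULT_DT,
    theta: float = 0.5,
    compiled: CompiledModel | None = None,
) -> VoltageTrace:
    """Simulate settle + stimulus window; return the somatic trace of the
    stimulus window only."""
    c = compiled if compiled is not None else CompiledModel.from_model(model)
    state = init_state(c)
    settle_steps = int(round(protocol.settle / dt))
    onset_steps = int(round(protocol.onset / dt))
    dur_steps = int(round(protocol.duration / dt))
    n_steps = settle_steps + onset_steps + dur_steps
    rec_i0 = settle_steps
    out = np.empty(n_steps - rec_i0)
    stim_seg = c.soma_seg if protocol.segment is None else protocol.segment
    bad = _simulate(
        n_steps,
        dt,
        theta,
        state.v,
        c.parent,
        c.gax,
        c.area,
        c.cm_dens,
        c.pt_seg,
        c.pt_g,
        c.pt_e,
        c.pt_edyn,
        c.pt_wca,
        c.pt_goff,
        c.pt_gn,
        c.gs_kind,
        c.gs_tab,
        c.gs_exp,
        c.gs_h1,
        c.gs_h2,
        c.gs_h3,
        state.gates,
        c.inf_tab,
        c.tau_tab,
        TABLE_VMIN,
        TABLE_DV,
        c.pool_of_seg,
        state.ca,
        state.eca,
        c.ca_rest,
        c.ca_tau,
        c.ca_k,
        CA_FLOOR,
        c.nernst_fac,
        c.ca_out,
        stim_seg,
        protocol.amplitude,
        settle_steps + onset_steps,
        n_steps,
        c.soma_seg,
        rec_i0,
        out,
    )
    if bad >= 0:
        raise NumericalBlowupError(
            f"non-finite voltage at t={bad * dt:.4f} ms "
            f"(model={getattr(model, 'name', '?')}, I={protocol.amplitude} nA)"
        )
    return VoltageTrace(dt=dt, v=out, t0=protocol.settle + dt)


def build_linear_system(
    compiled: CompiledModel,
    state: SimulationState,
    dt: float,
    theta: float = 0.5,
    stim_amp: float = 0.0,
    stim_seg: int | None = None,
    gates_updated: np.ndarray | None = None,
):
    """Dense (A, b) of the voltage solve for residual checks (tests only).

    ``gates_updated`` must hold the gate values *after* the staggered gate
    update for the step being verified.
    """
    c = compiled
    n = c.n
    x = state.gates if gates_updated is None else gates_updated
    G = np.zeros(n)
    GE = np.zeros(n)
    for i in range(len(c.pt_seg)):
        s = c.pt_seg[i]
        gp = c.pt_g[i]
        for k in range(c.pt_goff[i], c.pt_goff[i] + c.pt_gn[i]):
            gp *= x[k] ** c.gs_exp[k]
        e = state.eca[c.pool_of_seg[s]] if c.pt_edyn[i] == 1 else c.pt_e[i]
        G[s] += gp
        GE[s] += gp * e
    A = np.zeros((n, n))
    b = np.zeros(n)
    V = state.v
    for s in range(n):
        A[s, s] = c.cm_dens[s] / dt + theta * G[s]
        b[s] = c.cm_dens[s] / dt * V[s] - (1 - theta) * (G[s] * V[s] - GE[s]) + theta * GE[s]
    if stim_amp != 0.0:
        tseg = c.soma_seg if stim_seg is None else stim_seg
        b[tseg] += stim_amp * 1e-3 / c.area[tseg]
    for s in range(1, n):
        p = c.parent[s]
        g_s = c.gax[s] * 1e-3 / c.area[s]
        g_p = c.gax[s] * 1e-3 / c.area[p]
        A[s, s] += theta * g_s
        A[p, p] += theta * g_p
        A[s, p] -= theta * g_s
        A[p, s] -= theta * g_p
        b[s] += (1 - theta) * g_s * (V[p] - V[s])
        b[p] += (1 - theta) * g_p * (V[s] - V[p])
    return A, b


def model_hash(model) -> str:
    """Stable short hash of the compiled arrays, for run manifests."""
    c = CompiledModel.from_model(model)
    h = hashlib.sha256()
    for arr in (
        c.parent,
        c.gax,
        c.area,
        c.cm_dens,
        c.pt_seg,
        c.pt_g,
        c.pt_e,
        c.inf_tab,
        c.tau_tab,
    ):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update(str((c.ca_rest, c.ca_tau, c.ca_k, c.ca_out, c.nernst_fac, c.v_init)).encode())
    return h.hexdigest()[:16]
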
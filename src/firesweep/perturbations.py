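"""Parameter perturbations and comparison statistics.

A :class:`PerturbationSpec` scales the specific membrane capacitance (on the
whole cell or on the soma + proximal dendrites only), multiplies maximal
conductances, and shifts ionic reversal potentials.  Fixed reversals (Na, K,
leak) shift additively; the dynamic calcium reversal is shifted by replacing
the fixed extracellular concentration with
``ca_out * exp(z F dE / (R T))`` so that E_Ca(t=0) moves by exactly ``dE``
while remaining concentration-determined thereafter.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .mechanisms import nernst
from .model_library import ModelSpec
from .morphology import proximal_mask
from .protocols import DEFAULT_DI, DEFAULT_I_CAP, FICurve, THRESHOLD_RESOLUTION, fi_curve
from .cable_solver import DEFAULT_DT

logger = logging.getLogger(__name__)

CONDUCTANCE_FACTOR_RANGE = (0.3, 10.0)
REVERSAL_SHIFT_RANGE = (-20.0, 20.0)


class PerturbationError(ValueError):
    pass


class StatisticUndefinedError(ValueError):
    pass


@dataclass
class PerturbationSpec:
    """One parameter manipulation applied to a model.

    ``reversal_shifts`` maps an ion ('na', 'k', 'leak') to an additive shift
    in mV; calcium is expressed either as ``delta_e_ca`` (mV shift of
    E_Ca(t=0)) or directly as ``ca_out_factor``.
    """

    cm_factor: float = 1.0
    cm_region: str = "all"  # 'all' | 'sprx'
    conductance_factors: dict[str, float] = field(default_factory=dict)
    reversal_shifts: dict[str, float] = field(default_factory=dict)
    delta_e_ca: float | None = None
    ca_out_factor: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.cm_factor <= 0:
            raise PerturbationError("cm_factor must be positive")
        if self.cm_region not in ("all", "sprx"):
            raise PerturbationError(f"unknown cm_region {self.cm_region!r}")
        lo, hi = CONDUCTANCE_FACTOR_RANGE
        for name, fac in self.conductance_factors.items():
            if not (lo <= fac <= hi):
                raise PerturbationError(
                    f"conductance factor {fac} for {name} outside [{lo}, {hi}]"
                )
        lo, hi = REVERSAL_SHIFT_RANGE
        for ion, shift in self.reversal_shifts.items():
            if ion not in ("na", "k", "leak"):
                raise PerturbationError(f"unknown ion {ion!r} in reversal_shifts")
            if not (lo <= shift <= hi):
                raise PerturbationError(f"reversal shift {shift} mV outside [{lo}, {hi}]")
        if self.delta_e_ca is not None and self.ca_out_factor is not None:
            raise PerturbationError("give either delta_e_ca or ca_out_factor, not both")
        if self.ca_out_factor is not None and self.ca_out_factor <= 0:
            raise PerturbationError("ca_out_factor must be positive")
        if not self.label:
            self.label = self._default_label()

    def _default_label(self) -> str:
        parts = []
        if self.cm_factor != 1.0:
            parts.append(f"cm{self.cm_factor:g}x{self.cm_region}")
        parts += [f"{k}x{v:g}" for k, v in sorted(self.conductance_factors.items())]
        parts += [f"E{k}{v:+g}mV" for k, v in sorted(self.reversal_shifts.items())]
        if self.delta_e_ca is not None:
            parts.append(f"ECa{self.delta_e_ca:+g}mV")
        if self.ca_out_factor is not None:
            parts.append(f"CaOutx{self.ca_out_factor:g}")
        return "+".join(parts) if parts else "identity"

    def validate_for(self, model: ModelSpec) -> None:
        present = set(model.mechanism_names())
        for name in self.conductance_factors:
            if name not in present:
                raise PerturbationError(
                    f"mechanism {name!r} not present in model {model.name} "
                    f"(has: {sorted(present)})"
                )
        if (self.delta_e_ca is not None or self.ca_out_factor is not None) and model.ca is None:
            raise PerturbationError(f"model {model.name} has no calcium reversal to shift")


def apply(model: ModelSpec, p: PerturbationSpec) -> ModelSpec:
    """Return a derived model with the perturbation applied; the input model
    is never mutated."""
    p.validate_for(model)
    out = model.copy()
    out.source = {**model.source, "perturbation": p.label}

    if p.cm_factor != 1.0:
        if p.cm_region == "all":
            out.cell.cm *= p.cm_factor
        else:
            mask = proximal_mask(out.cell)
            out.cell.cm[mask] *= p.cm_factor

    for name, fac in p.conductance_factors.items():
        pl = out.placement(name)
        pl.gbar *= fac
        pl.mech.gbar = pl.gbar

    for ion, shift in p.reversal_shifts.items():
        hit = False
        for pl in out.placements:
            mech_ion = pl.mech.ion
            if (ion == "leak" and mech_ion is None) or mech_ion == ion:
                pl.mech.erev += shift
                hit = True
        if not hit:
            raise PerturbationError(f"no mechanism carries ion {ion!r} in model {model.name}")

    factor = p.ca_out_factor
    if p.delta_e_ca is not None:
        np_ = model.ca.nernst
        factor = math.exp(np_.z * np_.F * p.delta_e_ca * 1e-3 / (np_.R * np_.T))
    if factor is not None:
        out.ca.pool.ca_out *= factor
    return out


def initial_e_ca(model: ModelSpec) -> float:
    """E_Ca at t = 0 (mV) from the model's calcium configuration."""
    if model.ca is None:
        raise PerturbationError(f"model {model.name} has no calcium configuration")
    return nernst(model.ca.nernst, model.ca.pool.ca_out, model.ca.pool.ca_rest)


def relative_difference_at_max_common(curve_a: FICurve, curve_b: FICurve) -> float:
    """``(f_a - f_b)/f_a`` at the largest current with sustained firing in both.

    Curve grids must share their increment; currents are matched by value.
    """
    if abs(curve_a.di - curve_b.di) > 1e-12:
        raise StatisticUndefinedError("curves do not share a grid increment")
    fa = {round(i / curve_a.di): f for i, f in zip(curve_a.currents, curve_a.freqs) if f > 0}
    fb = {round(i / curve_b.di): f for i, f in zip(curve_b.currents, curve_b.freqs) if f > 0}
    common = set(fa) & set(fb)
    if not common:
        raise StatisticUndefinedError("no common sustained-firing current")
    k = max(common)
    return (fa[k] - fb[k]) / fa[k]


@dataclass
class ScanResult:
    """Baseline f-I curve plus perturbed curves and derived statistics."""

    model: str
    baseline: FICurve
    curves: dict[str, FICurve] = field(default_factory=dict)
    stats: dict[str, dict] = field(default_factory=dict)
    gaps: list[str] = field(default_factory=list)

    def tidy(self) -> pd.DataFrame:
        rows = []
        for label, curve in [("baseline", self.baseline)] + list(self.curves.items()):
            st = self.stats.get(label, {})
            for i, f in zip(curve.currents, curve.freqs):
                rows.append(
                    {
                        "model": self.model,
                        "label": label,
                        "axis": st.get("axis", ""),
                        "value": st.get("value", np.nan),
                        "I_nA": i,
                        "f_Hz": f,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, csv_path, stats_path=None) -> None:
        self.tidy().to_csv(csv_path, index=False)
        if stats_path is not None:
            with open(stats_path, "w") as fh:
                json.dump({"model": self.model, "stats": self.stats, "gaps": self.gaps},
                          fh, indent=1, default=float)


def _curve_stats(model: ModelSpec, curve: FICurve, probes, threshold_kw) -> dict:
    from .protocols import (
        StimulusProtocol,
        detect_spikes,
        find_threshold,
        mean_spike_width,
        measure_frequency,
        NoThresholdError,
        WidthUndefinedError,
    )

    st: dict = {"onset_f_Hz": curve.onset_frequency, "termination": curve.termination}
    if threshold_kw is not None:
        try:
            st["threshold_nA"] = find_threshold(model, **threshold_kw)
        except NoThresholdError:
            st["threshold_nA"] = None
    for probe in probes:
        f, trace, spikes = measure_frequency(model, probe, return_trace=True)
        key = f"{probe:g}nA"
        st[f"f_{key}_Hz"] = f
        try:
            st[f"width_{key}_ms"] = mean_spike_width(trace, spikes) if len(spikes) else None
        except WidthUndefinedError:
            st[f"width_{key}_ms"] = None
    return st


def scan(
    model: ModelSpec,
    axis: str,
    values,
    cm_region: str = "all",
    di: float = DEFAULT_DI,
    i_cap: float = DEFAULT_I_CAP,
    probes: tuple = (0.2, 0.4),
    with_threshold: bool = True,
    threshold_resolution: float = THRESHOLD_RESOLUTION,
    dt: float = DEFAULT_DT,
) -> ScanResult:
    """Sweep one perturbation axis (``cm``, ``conductance:X`` or
    ``reversal:k``) and compute an f-I curve plus summary statistics per value.

    Per-point protocol failures are recorded as gaps, not raised.
    """
    specs = []
    for v in values:
        if axis == "cm":
            specs.append(PerturbationSpec(cm_factor=v, cm_region=cm_region))
        elif axis.startswith("conductance:"):
            specs.append(PerturbationSpec(conductance_factors={axis.split(":", 1)[1]: v}))
        elif axis.startswith("reversal:"):
            ion = axis.split(":", 1)[1]
            if ion == "ca":
                specs.append(PerturbationSpec(delta_e_ca=v))
            else:
                specs.append(PerturbationSpec(reversal_shifts={ion: v}))
        else:
            raise PerturbationError(f"unknown scan axis {axis!r}")

    threshold_kw = (
        {"resolution": threshold_resolution, "coarse": max(di, 0.01), "i_cap": i_cap, "dt": dt}
        if with_threshold
        else None
    )
    baseline = fi_curve(model, di=di, i_cap=i_cap, dt=dt, label="baseline")
    result = ScanResult(model=model.name, baseline=baseline)
    result.stats["baseline"] = {"axis": axis, "value": None,
                               **_curve_stats(model, baseline, probes, threshold_kw)}
    for spec, v in zip(specs, values):
        try:
            perturbed = apply(model, spec)
            curve = fi_curve(perturbed, di=di, i_cap=i_cap, dt=dt, label=spec.label)
            st = {"axis": axis, "value": v,
                  **_curve_stats(perturbed, curve, probes, threshold_kw)}
            try:
                st["rel_diff_vs_baseline"] = relative_difference_at_max_common(baseline, curve)
            except StatisticUndefinedError:
                st["rel_diff_vs_baseline"] = None
            result.curves[spec.label] = curve
            result.stats[spec.label] = st
        except Exception as exc:  # per-point failure: log a gap, keep scanning
            logger.warning("scan point %s=%s failed: %s", axis, v, exc)
            result.gaps.append(f"{axis}={v}: {exc}")
    return result


def run_scenarios(
    model: ModelSpec,
    scenarios: list[PerturbationSpec],
    di: float = DEFAULT_DI,
    i_cap: float = DEFAULT_I_CAP,
    dt: float = DEFAULT_DT,
) -> ScanResult:
    """Evaluate combinatorial perturbations and report the relative firing
    difference vs baseline at the largest common sustained current."""
    baseline = fi_curve(model, di=di, i_cap=i_cap, dt=dt, label="baseline")
    result = ScanResult(model=model.name, baseline=baseline)
    result.stats["baseline"] = {"axis": "scenario", "value": None,
                                "onset_f_Hz": baseline.onset_frequency}
    for spec in scenarios:
        try:
            perturbed = apply(model, spec)
            curve = fi_curve(perturbed, di=di, i_cap=i_cap, dt=dt, label=spec.label)
            st = {"axis": "scenario", "value": spec.label,
                  "onset_f_Hz": curve.onset_frequency}
            try:
                st["rel_diff_vs_baseline"] = relative_difference_at_max_common(baseline, curve)
            except StatisticUndefinedError:
                st["rel_diff_vs_baseline"] = None
            if model.ca is not None:
                st["e_ca0_mV"] = initial_e_ca(perturbed)
            result.curves[spec.label] = curve
            result.stats[spec.label] = st
        except Exception as exc:
            logger.warning("scenario %s failed: %s", spec.label, exc)
            result.gaps.append(f"{spec.label}: {exc}")
    return result


def _spec_from_config(raw: dict) -> PerturbationSpec:
    return PerturbationSpec(
        cm_factor=float(raw.get("cm_factor", 1.0)),
        cm_region=raw.get("cm_region", "all"),
        conductance_factors={k: float(v) for k, v in (raw.get("conductances") or {}).items()},
        reversal_shifts={k: float(v) for k, v in (raw.get("reversals") or {}).items()},
        delta_e_ca=raw.get("delta_e_ca"),
        ca_out_factor=raw.get("ca_out_factor"),
        label=raw.get("label", ""),
    )


def load_scan_config(source: str) -> dict:
    """Load a scan/scenario configuration from YAML text, a file path, or the
    name of a bundled config (``fig2`` ... ``fig6``)."""
    if "\n" not in source:
        bundled = resources.files("firesweep.data.configs").joinpath(f"{source}.yaml")
        if source.endswith((".yaml", ".yml")):
            with open(source) as fh:
                text = fh.read()
        elif bundled.is_file():
            text = bundled.read_text()
        else:
            raise FileNotFoundError(f"no config file or bundled config named {source!r}")
    else:
        text = source
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "name" not in cfg:
        raise PerturbationError("config must be a mapping with at least a 'name'")
    unknown = set(cfg) - {"name", "description", "fi", "axes", "scenarios", "probes"}
    if unknown:
        raise PerturbationError(f"config {cfg['name']}: unknown fields {sorted(unknown)}")
    return cfg


def run_config(model: ModelSpec, cfg: dict, overrides: dict | None = None) -> list[ScanResult]:
    """Execute a study-design config against one model.

    Axes naming mechanisms or ions the model lacks are skipped with a
    recorded gap.  ``overrides`` may coarsen ``di``, ``i_cap``,
    ``threshold_resolution`` or ``probes`` for smoke runs.
    """
    fi_cfg = dict(cfg.get("fi", {}))
    fi_cfg.update(overrides or {})
    di = float(fi_cfg.get("di", DEFAULT_DI))
    i_cap = float(fi_cfg.get("i_cap", DEFAULT_I_CAP))
    tres = float(fi_cfg.get("threshold_resolution", THRESHOLD_RESOLUTION))
    probes = tuple(fi_cfg.get("probes", cfg.get("probes", (0.2, 0.4))))
    max_values = fi_cfg.get("max_values_per_axis")
    no_thresholds = bool(fi_cfg.get("disable_thresholds", False))
    present = set(model.mechanism_names())
    results = []
    for ax in cfg.get("axes", []):
        axis = ax["axis"]
        skip = None
        if axis.startswith("conductance:") and axis.split(":", 1)[1] not in present:
            skip = f"mechanism {axis.split(':', 1)[1]} absent"
        if axis.startswith("reversal:"):
            ion = axis.split(":", 1)[1]
            if ion == "ca" and model.ca is None:
                skip = "no calcium reversal in model"
            elif ion != "ca" and not any(
                (pl.mech.ion == ion) or (ion == "leak" and pl.mech.ion is None)
                for pl in model.placements
            ):
                skip = f"no {ion} reversal in model"
        if skip is not None:
            res = ScanResult(model=model.name,
                             baseline=FICurve(currents=[0.0], freqs=[0.0], di=di))
            res.gaps.append(f"axis {axis} skipped: {skip}")
            results.append(res)
            continue
        values = list(ax["values"])
        if max_values is not None and len(values) > int(max_values):
            idx = np.linspace(0, len(values) - 1, int(max_values)).round().astype(int)
            values = [values[i] for i in sorted(set(idx))]
        for region in ax.get("regions", ["all"]):
            results.append(
                scan(model, axis, values, cm_region=region, di=di, i_cap=i_cap,
                     probes=probes,
                     with_threshold=ax.get("threshold", True) and not no_thresholds,
                     threshold_resolution=tres)
            )
    if cfg.get("scenarios"):
        specs = []
        for raw in cfg["scenarios"]:
            spec = _spec_from_config(raw)
            unknown_mech = set(spec.conductance_factors) - present
            if unknown_mech or ((spec.delta_e_ca is not None or spec.ca_out_factor is not None)
                                and model.ca is None):
                res = ScanResult(model=model.name,
                                 baseline=FICurve(currents=[0.0], freqs=[0.0], di=di))
                res.gaps.append(f"scenario {spec.label} skipped: inapplicable to {model.name}")
                results.append(res)
                continue
            specs.append(spec)
        if specs:
            results.append(run_scenarios(model, specs, di=di, i_cap=i_cap))
    return results
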
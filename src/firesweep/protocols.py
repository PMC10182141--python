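"""Measurement protocols: spike detection, sustained frequency, f-I curves,
threshold search and spike width.

A spike is a sample strictly greater than both neighbours and above the
detection level (-20 mV); firing only counts as *sustained* if at least one
spike falls in the latter half of the stimulation interval.  f-I sweeps step
the current in 0.01 nA increments until the model is driven into
depolarization block (frequency back to zero after having been positive,
confirmed one grid point further on).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .cable_solver import DEFAULT_DT, CompiledModel, StimulusProtocol, VoltageTrace, run

logger = logging.getLogger(__name__)

SPIKE_LEVEL = -20.0  # mV
WIDTH_LEVEL = -40.0  # mV
DEFAULT_DI = 0.01  # nA
DEFAULT_I_CAP = 1.0  # nA
THRESHOLD_RESOLUTION = 0.001  # nA


class NoThresholdError(RuntimeError):
    pass


class WidthUndefinedError(ValueError):
    pass


@dataclass
class SpikeTrain:
    """Detected spike times (ms, relative to stimulus onset)."""

    times: np.ndarray
    level: float = SPIKE_LEVEL
    indices: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.asarray(self.times)[:, None], delimiter=",",
                   header="spike_time_ms", comments="")


def detect_spikes(trace: VoltageTrace, level: float = SPIKE_LEVEL) -> SpikeTrain:
    """Strict local maxima above ``level``; first/last samples never count."""
    v = trace.v
    if len(v) < 3:
        raise ValueError("trace must have at least 3 samples")
    mid = v[1:-1]
    is_spike = (mid > v[:-2]) & (mid > v[2:]) & (mid > level)
    idx = np.flatnonzero(is_spike) + 1
    return SpikeTrain(times=trace.t[idx], level=level, indices=idx)


def sustained_frequency(
    spikes: SpikeTrain,
    stim_window: tuple[float, float],
    rate_window: tuple[float, float] | None = None,
) -> float:
    """Firing rate (Hz) under the sustained-firing rule.

    Returns 0 unless at least one spike falls in the latter half of
    ``stim_window``; otherwise the spike count inside ``rate_window``
    divided by the window length.
    """
    if rate_window is None:
        rate_window = stim_window
    t0, t1 = stim_window
    r0, r1 = rate_window
    if not (t0 <= r0 <= r1 <= t1):
        raise ValueError("rate_window must lie inside stim_window")
    times = np.asarray(spikes.times)
    half = t0 + (t1 - t0) / 2.0
    if not np.any(times >= half):
        return 0.0
    count = int(np.count_nonzero((times >= r0) & (times <= r1)))
    return count / ((r1 - r0) * 1e-3)


def measure_frequency(
    model, amplitude: float, dt: float = DEFAULT_DT, theta: float = 0.5,
    compiled: CompiledModel | None = None, return_trace: bool = False,
):
    """Run one current step and apply the sustained-firing rule."""
    protocol = StimulusProtocol(amplitude=amplitude, duration=model.stim_duration,
                                settle=model.settle)
    trace = run(model, protocol, dt=dt, theta=theta, compiled=compiled)
    spikes = detect_spikes(trace)
    f = sustained_frequency(spikes, (0.0, model.stim_duration), model.rate_window)
    if return_trace:
        return f, trace, spikes
    return f


@dataclass
class FICurve:
    """Frequency vs injected current on a uniform current grid."""

    currents: np.ndarray  # nA, strictly increasing
    freqs: np.ndarray  # Hz
    di: float = DEFAULT_DI
    termination: str = "current_cap"  # or "depolarization_block"
    label: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.currents) > 1 and not np.all(np.diff(self.currents) > 0):
            raise ValueError("currents must be strictly increasing")
        if np.any(self.freqs < 0):
            raise ValueError("frequencies must be non-negative")

    def interp(self, current: float) -> float:
        idx = int(round((current - self.currents[0]) / self.di))
        if not (0 <= idx < len(self.currents)) or abs(
            self.currents[idx] - current
        ) > 1e-9 + self.di * 1e-6:
            raise KeyError(f"current {current} nA not on the curve grid")
        return float(self.freqs[idx])

    @property
    def onset_frequency(self) -> float:
        """Frequency at the first sustained-firing grid point (0 if none)."""
        pos = np.flatnonzero(self.freqs > 0)
        return float(self.freqs[pos[0]]) if pos.size else 0.0

    def to_csv(self, path, meta: dict | None = None) -> None:
        np.savetxt(path, np.column_stack([self.currents, self.freqs]), delimiter=",",
                   header="I_nA,f_Hz", comments="", fmt="%.6g")
        if meta is not None:
            with open(str(path) + ".json", "w") as fh:
                json.dump({"di": self.di, "termination": self.termination,
                           "label": self.label, "model": self.model, **meta}, fh, indent=1)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "FICurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        di = float(arr[1, 0] - arr[0, 0]) if len(arr) > 1 else DEFAULT_DI
        return cls(currents=arr[:, 0], freqs=arr[:, 1], di=di, **kwargs)


def fi_curve(
    model,
    di: float = DEFAULT_DI,
    i_cap: float = DEFAULT_I_CAP,
    dt: float = DEFAULT_DT,
    theta: float = 0.5,
    label: str = "",
) -> FICurve:
    """Sweep the injected current from 0 in ``di`` steps until depolarization
    block (confirmed at one extra grid point) or ``i_cap``."""
    compiled = CompiledModel.from_model(model)
    currents: list[float] = []
    freqs: list[float] = []
    fired = False
    termination = "current_cap"
    i = 0
    while True:
        amp = i * di
        if amp > i_cap + 1e-12:
            break
        f = measure_frequency(model, amp, dt=dt, theta=theta, compiled=compiled)
        currents.append(amp)
        freqs.append(f)
        if fired and f == 0.0:
            # confirm block at one further grid point to avoid single-point dropouts
            amp2 = (i + 1) * di
            if amp2 <= i_cap + 1e-12:
                f2 = measure_frequency(model, amp2, dt=dt, theta=theta, compiled=compiled)
                currents.append(amp2)
                freqs.append(f2)
                if f2 == 0.0:
                    termination = "depolarization_block"
                    break
                i += 1  # spurious dropout; keep sweeping
            else:
                termination = "depolarization_block"
                break
        if f > 0:
            fired = True
        i += 1
    return FICurve(currents=np.asarray(currents), freqs=np.asarray(freqs), di=di,
                   termination=termination, label=label, model=getattr(model, "name", ""))


def find_threshold(
    model,
    resolution: float = THRESHOLD_RESOLUTION,
    coarse: float = DEFAULT_DI,
    i_cap: float = DEFAULT_I_CAP,
    dt: float = DEFAULT_DT,
    theta: float = 0.5,
) -> float:
    """Smallest current on the ``resolution`` grid with sustained firing.

    Coarse sweep to bracket the onset, then bisection on the fine grid;
    guarantees ``f(threshold) > 0`` and ``f(threshold - resolution) = 0``.
    """
    compiled = CompiledModel.from_model(model)

    def f_at(amp: float) -> float:
        return measure_frequency(model, amp, dt=dt, theta=theta, compiled=compiled)

    hi = None
    i = 0
    while i * coarse <= i_cap + 1e-12:
        if f_at(i * coarse) > 0:
            hi = i * coarse
            break
        i += 1
    if hi is None:
        raise NoThresholdError(f"model {getattr(model, 'name', '?')} never fires up to {i_cap} nA")
    lo = hi - coarse
    if lo < 0:
        lo = 0.0
    # bisect on integer multiples of the resolution
    lo_n = int(round(lo / resolution))
    hi_n = int(round(hi / resolution))
    while hi_n - lo_n > 1:
        mid_n = (lo_n + hi_n) // 2
        if f_at(mid_n * resolution) > 0:
            hi_n = mid_n
        else:
            lo_n = mid_n
    return hi_n * resolution


def spike_width(
    trace: VoltageTrace, spike_index: int, level: float = WIDTH_LEVEL
) -> float:
    """Width (ms) of one spike at ``level``: the time between the upward and
    downward crossings bracketing the apex, linearly interpolated."""
    v = trace.v
    t = trace.t
    if not (0 < spike_index < len(v) - 1):
        raise WidthUndefinedError("spike index out of range")
    if v[spike_index] <= level:
        raise WidthUndefinedError(
            f"spike apex {v[spike_index]:.2f} mV is not above the {level} mV level"
        )
    i = spike_index
    while i > 0 and v[i - 1] > level:
        i -= 1
    if i == 0:
        raise WidthUndefinedError("trace starts above the width level")
    t_up = t[i - 1] + (t[i] - t[i - 1]) * (level - v[i - 1]) / (v[i] - v[i - 1])
    j = spike_index
    while j < len(v) - 1 and v[j + 1] > level:
        j += 1
    if j == len(v) - 1:
        raise WidthUndefinedError("trace ends above the width level")
    t_dn = t[j] + (t[j + 1] - t[j]) * (level - v[j]) / (v[j + 1] - v[j])
    return float(t_dn - t_up)


def mean_spike_width(trace: VoltageTrace, spikes: SpikeTrain, level: float = WIDTH_LEVEL) -> float:
    """Mean width over all detected spikes whose apex exceeds ``level``."""
    widths = []
    for idx in spikes.indices:
        try:
            widths.append(spike_width(trace, int(idx), level))
        except WidthUndefinedError:
            continue
    if not widths:
        raise WidthUndefinedError("no spike in the trace rises above the width level")
    return float(np.mean(widths))
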
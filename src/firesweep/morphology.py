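"""Neuron morphologies: SWC parsing, compartmentalization, path distances.

A :class:`Morphology` is a tree of unbranched sections (soma, dendrites,
axon).  :func:`discretize` chops each section into equal-length segments and
computes cylinder-side membrane areas, producing a
:class:`CompartmentalizedCell` whose segments are topologically ordered
(every parent index precedes its children) so that the cable solver can use
direct tree elimination.

Conventions
-----------
* The soma is a single cylinder.  Built from parameters its length equals
  its diameter; built from SWC its length is the span of the soma samples
  (a single sample gives length = diameter = 2r).
* Segment membrane area is the lateral cylinder area ``pi * d * l`` (no end
  caps).
* Path distance is measured from the soma attachment point to segment
  midpoints; soma segments are at distance 0.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SOMA = "soma"
DENDRITE = "dendrite"
AXON = "axon"

#: SWC type codes: 1 soma, 2 axon, 3 basal / 4 apical dendrite.
SWC_TYPE_MAP = {1: SOMA, 2: AXON, 3: DENDRITE, 4: DENDRITE}

REGION_SOMA = 0
REGION_PROXIMAL = 1
REGION_DISTAL = 2
REGION_AXON = 3
REGION_NAMES = {
    REGION_SOMA: "soma",
    REGION_PROXIMAL: "proximal_dendrite",
    REGION_DISTAL: "distal_dendrite",
    REGION_AXON: "axon",
}


class SWCParseError(ValueError):
    """Raised when SWC text is malformed (e.g. a dangling parent id)."""


class MorphologyError(ValueError):
    """Raised when a morphology violates its structural invariants."""


@dataclass
class Section:
    """One unbranched neurite section.

    ``parent`` is the id of the parent section (``None`` for the root) and
    ``parent_pos`` the normalized attachment position along the parent
    (1.0 = distal end; the soma attaches children at its center).
    """

    id: int
    stype: str
    length: float  # um
    diam: float  # um
    parent: int | None = None
    parent_pos: float = 1.0

    def __post_init__(self) -> None:
        if self.stype not in (SOMA, DENDRITE, AXON):
            raise MorphologyError(f"unknown section type {self.stype!r}")
        if not (self.length > 0 and self.diam > 0):
            raise MorphologyError(
                f"section {self.id}: length and diameter must be positive "
                f"(got L={self.length}, d={self.diam})"
            )


@dataclass
class Morphology:
    """A tree of sections with exactly one root."""

    sections: list[Section]
    name: str = "morphology"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_id = {s.id: s for s in self.sections}
        if len(by_id) != len(self.sections):
            raise MorphologyError("duplicate section ids")
        roots = [s for s in self.sections if s.parent is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root section, found {len(roots)}")
        # cycle / dangling check via walk to root
        for s in self.sections:
            seen = set()
            cur = s
            while cur.parent is not None:
                if cur.id in seen:
                    raise MorphologyError(f"cycle detected at section {cur.id}")
                seen.add(cur.id)
                if cur.parent not in by_id:
                    raise MorphologyError(f"section {cur.id} references missing parent {cur.parent}")
                cur = by_id[cur.parent]

    @property
    def root(self) -> Section:
        return next(s for s in self.sections if s.parent is None)

    def section(self, sid: int) -> Section:
        for s in self.sections:
            if s.id == sid:
                return s
        raise KeyError(sid)

    @property
    def soma_length(self) -> float:
        soma = [s for s in self.sections if s.stype == SOMA]
        if not soma:
            raise MorphologyError("morphology has no soma section")
        return sum(s.length for s in soma)

    def summary_json(self) -> str:
        """Per-section summary (type, length, diameter, parent) as JSON."""
        rows = [
            {
                "id": s.id,
                "type": s.stype,
                "length_um": s.length,
                "diam_um": s.diam,
                "parent": s.parent,
            }
            for s in self.sections
        ]
        return json.dumps({"name": self.name, "sections": rows}, indent=1)


def _dist(a, b) -> float:
    return math.dist(a[:3], b[:3])


def load_swc(swc_text: str, name: str = "swc") -> Morphology:
    """Parse standard 7-column SWC text into a :class:`Morphology`.

    All soma samples are merged into a single soma section; consecutive
    point-to-point 3D distances accumulate into section lengths.  The span
    from a soma sample to its first attached neurite sample is treated as
    attachment, not neurite length.
    """
    samples: dict[int, tuple] = {}
    for lineno, raw in enumerate(swc_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(cols)}")
        try:
            sid = int(cols[0])
            stype = int(cols[1])
            x, y, z, r = (float(c) for c in cols[2:6])
            parent = int(cols[6])
        except ValueError as exc:
            raise SWCParseError(f"line {lineno}: {exc}") from exc
        if r <= 0:
            raise MorphologyError(f"line {lineno}: non-positive radius {r}")
        if sid in samples:
            raise SWCParseError(f"line {lineno}: duplicate sample id {sid}")
        samples[sid] = (stype, x, y, z, r, parent, lineno)
    if not samples:
        raise SWCParseError("no samples in SWC input")
    for sid, (_, _, _, _, _, parent, lineno) in samples.items():
        if parent != -1 and parent not in samples:
            raise SWCParseError(f"line {lineno}: sample {sid} references missing parent {parent}")

    def swc_type(code: int) -> str:
        if code not in SWC_TYPE_MAP:
            logger.warning("unknown SWC type code %d mapped to dendrite", code)
            return DENDRITE
        return SWC_TYPE_MAP[code]

    soma_ids = [sid for sid, s in samples.items() if swc_type(s[0]) == SOMA]
    if not soma_ids:
        raise MorphologyError("SWC input has no soma samples")

    # soma: merged into one cylinder
    soma_pts = [samples[i][1:5] for i in sorted(soma_ids)]
    soma_len = sum(_dist(soma_pts[i], soma_pts[i + 1]) for i in range(len(soma_pts) - 1))
    soma_diam = 2.0 * float(np.mean([p[3] for p in soma_pts]))
    if soma_len <= 0:
        soma_len = soma_diam  # single-sample soma: sphere -> equivalent cylinder
    sections = [Section(id=0, stype=SOMA, length=soma_len, diam=soma_diam, parent=None)]

    children: dict[int, list[int]] = {}
    for sid in sorted(samples):
        parent = samples[sid][5]
        children.setdefault(parent, []).append(sid)
    soma_set = set(soma_ids)

    def is_break(sid: int) -> bool:
        """A sample starts a new section if its parent is soma/root, a branch
        point, or of a different type."""
        parent = samples[sid][5]
        if parent == -1 or parent in soma_set:
            return True
        if len(children.get(parent, [])) > 1:
            return True
        if swc_type(samples[parent][0]) != swc_type(samples[sid][0]):
            return True
        return False

    sample_section: dict[int, int] = {sid: 0 for sid in soma_ids}
    next_id = 1
    starts = [sid for sid in sorted(samples) if sid not in soma_set and is_break(sid)]
    for start in starts:
        chain = [start]
        cur = start
        while True:
            kids = [
                k
                for k in children.get(cur, [])
                if k not in soma_set and not is_break(k)
            ]
            if len(kids) != 1:
                break
            cur = kids[0]
            chain.append(cur)
        stype = swc_type(samples[start][0])
        parent_sample = samples[start][5]
        pts = [samples[i][1:5] for i in chain]
        if parent_sample != -1 and parent_sample not in soma_set:
            pts.insert(0, samples[parent_sample][1:5])
        length = sum(_dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1))
        if length <= 0:
            raise MorphologyError(f"section starting at sample {start} has zero length")
        diam = 2.0 * float(np.mean([samples[i][4] for i in chain]))
        if parent_sample == -1:
            parent_sec, ppos = 0, 0.5
        elif parent_sample in soma_set:
            parent_sec, ppos = 0, 0.5
        else:
            parent_sec, ppos = sample_section[parent_sample], 1.0
        sections.append(
            Section(
                id=next_id,
                stype=stype,
                length=length,
                diam=diam,
                parent=parent_sec,
                parent_pos=ppos,
            )
        )
        for sid in chain:
            sample_section[sid] = next_id
        next_id += 1

    return Morphology(sections=sections, name=name)


@dataclass
class CompartmentalizedCell:
    """Discretized morphology with per-segment geometry and passive state.

    Segment arrays are topologically ordered: ``parent_seg[i] < i`` for every
    non-root segment.  ``cm`` holds the per-segment specific capacitance
    (uF/cm^2) so that region-restricted capacitance changes stay local.
    """

    seg_section: np.ndarray  # int, section id per segment
    seg_index: np.ndarray  # int, index within section
    seg_len: np.ndarray  # um
    seg_diam: np.ndarray  # um
    seg_area: np.ndarray  # um^2, lateral cylinder area
    seg_region: np.ndarray  # int region codes
    seg_path: np.ndarray  # um, path distance soma attachment -> midpoint
    parent_seg: np.ndarray  # int, -1 for root
    ra: float = 100.0  # axial resistivity, Ohm*cm
    cm: np.ndarray = field(default=None)  # uF/cm^2 per segment
    soma_length: float = 0.0  # um
    name: str = "cell"

    def __post_init__(self) -> None:
        if self.cm is None:
            self.cm = np.ones(self.n)
        if not np.all(self.seg_area > 0):
            raise MorphologyError("non-positive segment membrane area")
        if self.n > 1 and not np.all(self.parent_seg[1:] < np.arange(1, self.n)):
            raise MorphologyError("segments are not topologically ordered")

    @property
    def n(self) -> int:
        return len(self.seg_len)

    def copy(self) -> "CompartmentalizedCell":
        return CompartmentalizedCell(
            seg_section=self.seg_section.copy(),
            seg_index=self.seg_index.copy(),
            seg_len=self.seg_len.copy(),
            seg_diam=self.seg_diam.copy(),
            seg_area=self.seg_area.copy(),
            seg_region=self.seg_region.copy(),
            seg_path=self.seg_path.copy(),
            parent_seg=self.parent_seg.copy(),
            ra=self.ra,
            cm=self.cm.copy(),
            soma_length=self.soma_length,
            name=self.name,
        )

    def region_mask(self, *regions: str) -> np.ndarray:
        codes = [code for code, nm in REGION_NAMES.items() if nm in regions]
        if SOMA in regions:
            codes.append(REGION_SOMA)
        return np.isin(self.seg_region, sorted(set(codes)))

    @property
    def soma_segments(self) -> np.ndarray:
        return np.flatnonzero(self.seg_region == REGION_SOMA)


def discretize(
    morph: Morphology,
    max_seg_len: float = 5.0,
    nseg_overrides: dict[int, int] | None = None,
    ra: float = 100.0,
    proximal_factor: float = 3.5,
) -> CompartmentalizedCell:
    """Split every section into ``ceil(length / max_seg_len)`` equal segments.

    ``nseg_overrides`` maps section id to an explicit segment count.  Dendrite
    segments are labelled proximal/distal using ``proximal_factor`` soma
    lengths of path distance (midpoint convention).
    """
    if max_seg_len <= 0:
        raise ValueError("max_seg_len must be positive")
    nseg_overrides = nseg_overrides or {}

    order: list[Section] = []
    remaining = list(morph.sections)
    placed: set[int] = set()
    while remaining:
        progressed = False
        for s in list(remaining):
            if s.parent is None or s.parent in placed:
                order.append(s)
                placed.add(s.id)
                remaining.remove(s)
                progressed = True
        if not progressed:
            raise MorphologyError("section graph is not a tree")

    soma_length = morph.soma_length

    sec_first: dict[int, int] = {}
    sec_nseg: dict[int, int] = {}
    sec_start_path: dict[int, float] = {}
    seg_section, seg_index, seg_len, seg_diam = [], [], [], []
    seg_region, seg_path, parent_seg = [], [], []

    for sec in order:
        n = nseg_overrides.get(sec.id, max(1, math.ceil(sec.length / max_seg_len - 1e-12)))
        ls = sec.length / n
        sec_first[sec.id] = len(seg_len)
        sec_nseg[sec.id] = n
        if sec.parent is None or morph.section(sec.parent).stype == SOMA:
            start = 0.0
        else:
            start = sec_start_path[sec.parent] + sec.parent_pos * morph.section(sec.parent).length
        sec_start_path[sec.id] = start
        for i in range(n):
            seg_section.append(sec.id)
            seg_index.append(i)
            seg_len.append(ls)
            seg_diam.append(sec.diam)
            if sec.stype == SOMA:
                seg_region.append(REGION_SOMA)
                seg_path.append(0.0)
            else:
                mid = start + (i + 0.5) * ls
                seg_path.append(mid)
                if sec.stype == AXON:
                    seg_region.append(REGION_AXON)
                elif mid < proximal_factor * soma_length:
                    seg_region.append(REGION_PROXIMAL)
                else:
                    seg_region.append(REGION_DISTAL)
            if i > 0:
                parent_seg.append(len(seg_len) - 2)
            elif sec.parent is None:
                parent_seg.append(-1)
            else:
                pfirst = sec_first[sec.parent]
                pn = sec_nseg[sec.parent]
                pidx = min(pn - 1, int(sec.parent_pos * pn))
                parent_seg.append(pfirst + pidx)

    seg_len = np.asarray(seg_len, dtype=float)
    seg_diam = np.asarray(seg_diam, dtype=float)
    return CompartmentalizedCell(
        seg_section=np.asarray(seg_section, dtype=np.int64),
        seg_index=np.asarray(seg_index, dtype=np.int64),
        seg_len=seg_len,
        seg_diam=seg_diam,
        seg_area=np.pi * seg_diam * seg_len,
        seg_region=np.asarray(seg_region, dtype=np.int64),
        seg_path=np.asarray(seg_path, dtype=float),
        parent_seg=np.asarray(parent_seg, dtype=np.int64),
        ra=ra,
        soma_length=soma_length,
        name=morph.name,
    )


def path_distance(cell: CompartmentalizedCell, segment: int) -> float:
    """Path distance (um) from the soma attachment to a segment midpoint."""
    if not (0 <= segment < cell.n):
        raise KeyError(f"segment {segment} not in cell with {cell.n} segments")
    return float(cell.seg_path[segment])


def proximal_mask(
    cell: CompartmentalizedCell, soma_length: float | None = None, factor: float = 3.5
) -> np.ndarray:
    """Boolean mask of soma plus dendrite segments within ``factor`` soma
    lengths (path distance, midpoint convention).  Axon segments are never
    included."""
    if soma_length is None:
        soma_length = cell.soma_length
    if soma_length <= 0:
        raise ValueError("soma_length must be positive")
    is_dend = np.isin(cell.seg_region, (REGION_PROXIMAL, REGION_DISTAL))
    mask = cell.seg_region == REGION_SOMA
    return mask | (is_dend & (cell.seg_path < factor * soma_length))
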
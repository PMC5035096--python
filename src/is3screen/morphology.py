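"""Branched neuronal morphologies: SWC ingestion, trimming, discretization, morphometrics.

A :class:`Morphology` is a tree of :class:`Section` objects, each an ordered
polyline of 3D points with diameters.  Exactly one root section (the soma)
has no parent.  Sections are discretized into isopotential
:class:`Compartment` spans by :func:`compartmentalize`, which also computes
trapezoidal surface areas, half axial resistances, and path distances from
the soma midpoint -- the geometric quantities the cable solver and the
distance-dependent conductance rules consume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "MorphPoint",
    "Section",
    "Morphology",
    "Compartment",
    "CompartmentalModel",
    "TreeStats",
    "SWCParseError",
    "MorphologyError",
    "read_swc",
    "write_swc",
    "trim_axon",
    "compartmentalize",
    "tree_stats",
    "path_distance",
]


class SWCParseError(ValueError):
    """Malformed SWC content (carries the offending line number)."""


class MorphologyError(ValueError):
    """Structural problem in a morphology (orphans, cycles, empty trees)."""


REGIONS = ("soma", "axon", "dendrite")

# SWC type codes -> region. Apical (4) and unresolved custom codes map to dendrite.
_SWC_REGION = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}
_REGION_SWC = {"soma": 1, "axon": 2, "dendrite": 3}


@dataclass(frozen=True)
class MorphPoint:
    """A sample point of a neurite: position in um and local diameter in um."""

    x: float
    y: float
    z: float
    diameter: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z, self.diameter)):
            raise MorphologyError("non-finite coordinate or diameter")
        if self.diameter <= 0:
            raise MorphologyError(f"diameter must be > 0, got {self.diameter}")

    def dist(self, other: "MorphPoint") -> float:
        return math.dist((self.x, self.y, self.z), (other.x, other.y, other.z))


@dataclass
class Section:
    """An unbranched run of points; ``parent`` is ``(section_id, arc fraction)``."""

    id: int
    region: str
    tree_label: str
    points: list[MorphPoint]
    parent: Optional[tuple[int, float]] = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise MorphologyError(f"unknown region {self.region!r}")
        if len(self.points) < 2:
            raise MorphologyError(f"section {self.id} needs >= 2 points")
        if self.parent is not None and not (0.0 <= self.parent[1] <= 1.0):
            raise MorphologyError("parent attachment fraction outside [0, 1]")

    @property
    def arclengths(self) -> np.ndarray:
        """Cumulative arc length (um) at each point, starting at 0."""
        pts = self.points
        out = np.zeros(len(pts))
        for i in range(1, len(pts)):
            out[i] = out[i - 1] + pts[i].dist(pts[i - 1])
        return out

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])

    def interp(self, frac: float) -> tuple[MorphPoint, float]:
        """Point and arc position (um) at arc fraction ``frac`` of the section."""
        if not 0.0 <= frac <= 1.0:
            raise MorphologyError(f"arc fraction {frac} outside [0, 1]")
        arcs = self.arclengths
        s = frac * arcs[-1]
        i = int(np.searchsorted(arcs, s, side="right")) - 1
        i = min(max(i, 0), len(arcs) - 2)
        seg = arcs[i + 1] - arcs[i]
        w = 0.0 if seg == 0 else (s - arcs[i]) / seg
        p0, p1 = self.points[i], self.points[i + 1]
        return (
            MorphPoint(
                p0.x + w * (p1.x - p0.x),
                p0.y + w * (p1.y - p0.y),
                p0.z + w * (p1.z - p0.z),
                p0.diameter + w * (p1.diameter - p0.diameter),
            ),
            float(s),
        )

    def surface_area(self, a: float = 0.0, b: float = 1.0) -> float:
        """Trapezoidal lateral area (um^2) of the arc interval [a, b]."""
        return _integrate_section(self, a, b)[0]


def _integrate_section(sec: Section, a: float, b: float) -> tuple[float, float, float]:
    """(surface area um^2, length um, axial resistance factor um^-1) on [a, b].

    The axial factor is the integral of 4 / (pi d(s)^2) ds; multiply by the
    axial resistivity (converted to MOhm um) to get resistance.  Diameters
    interpolate linearly between points, so each slice is a frustum:
    area = pi * mean(d) * L, resistance = 4 L / (pi d1 d2).
    """
    if not (0.0 <= a <= b <= 1.0):
        raise MorphologyError(f"bad arc interval [{a}, {b}]")
    arcs = sec.arclengths
    total = arcs[-1]
    sa, sb = a * total, b * total
    # breakpoints: existing points inside the interval, plus the two ends
    cuts = [sa] + [float(s) for s in arcs if sa < s < sb] + [sb]
    area = 0.0
    rfac = 0.0
    for s0, s1 in zip(cuts[:-1], cuts[1:]):
        if s1 <= s0:
            continue
        d0 = sec.interp(s0 / total if total else 0.0)[0].diameter
        d1 = sec.interp(s1 / total if total else 0.0)[0].diameter
        L = s1 - s0
        area += math.pi * 0.5 * (d0 + d1) * L
        rfac += 4.0 * L / (math.pi * d0 * d1)
    return area, sb - sa, rfac


@dataclass
class Morphology:
    """A connected tree of sections; exactly one root (the soma)."""

    sections: list[Section]
    name: str = "morphology"

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise MorphologyError("duplicate section ids")
        by_id = {s.id: s for s in self.sections}
        roots = [s for s in self.sections if s.parent is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly 1 root section, got {len(roots)}")
        if roots[0].region != "soma":
            raise MorphologyError("root section must be the soma")
        for s in self.sections:
            if s.parent is not None and s.parent[0] not in by_id:
                raise MorphologyError(f"section {s.id} references missing parent {s.parent[0]}")
        # acyclicity: walking up from every section must reach the root
        for s in self.sections:
            seen = set()
            cur = s
            while cur.parent is not None:
                if cur.id in seen:
                    raise MorphologyError("cycle in parent graph")
                seen.add(cur.id)
                cur = by_id[cur.parent[0]]

    def section(self, sec_id: int) -> Section:
        for s in self.sections:
            if s.id == sec_id:
                return s
        raise MorphologyError(f"no section with id {sec_id}")

    @property
    def root(self) -> Section:
        return next(s for s in self.sections if s.parent is None)

    def children(self, sec_id: int) -> list[Section]:
        return [s for s in self.sections if s.parent is not None and s.parent[0] == sec_id]

    def total_surface_area(self) -> float:
        return sum(s.surface_area() for s in self.sections)

    def topological_order(self) -> list[Section]:
        """Sections ordered root-first (every parent precedes its children)."""
        out: list[Section] = []
        stack = [self.root]
        while stack:
            sec = stack.pop()
            out.append(sec)
            kids = sorted(self.children(sec.id), key=lambda s: s.id)
            stack.extend(reversed(kids))
        if len(out) != len(self.sections):
            raise MorphologyError("morphology is not connected")
        return out


# ---------------------------------------------------------------------------
# SWC input / output


def read_swc(path) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    One :class:`Section` is emitted per unbranched run of same-type samples;
    radii are converted to diameters.  Soma samples (type 1) become a single
    root cylinder-sequence section.
    """
    nodes: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(fields)}")
        try:
            nid = int(fields[0])
            typ = int(fields[1])
            x, y, z, r = (float(v) for v in fields[2:6])
            parent = int(fields[6])
        except ValueError as exc:
            raise SWCParseError(f"line {lineno}: {exc}") from None
        if r <= 0:
            raise SWCParseError(f"line {lineno}: radius must be > 0")
        if nid in nodes:
            raise SWCParseError(f"line {lineno}: duplicate node id {nid}")
        nodes[nid] = (typ, x, y, z, r, parent)
        order.append(nid)
    if not nodes:
        raise SWCParseError("empty SWC file")
    for nid in order:
        parent = nodes[nid][5]
        if parent != -1 and parent not in nodes:
            raise MorphologyError(f"node {nid} references undeclared parent {parent}")

    children: dict[int, list[int]] = {nid: [] for nid in order}
    roots = []
    for nid in order:
        parent = nodes[nid][5]
        if parent == -1:
            roots.append(nid)
        else:
            children[parent].append(nid)
    if len(roots) != 1:
        raise MorphologyError(f"expected a single SWC root node, got {len(roots)}")
    root = roots[0]
    if nodes[root][0] != 1:
        raise MorphologyError("SWC root node must be a soma sample (type 1)")

    def pt(nid: int) -> MorphPoint:
        typ, x, y, z, r, _ = nodes[nid]
        return MorphPoint(x, y, z, 2.0 * r)

    soma_ids = [nid for nid in order if nodes[nid][0] == 1]
    # soma as a cylinder sequence along the chain of type-1 samples
    soma_pts = [pt(nid) for nid in soma_ids]
    if len(soma_pts) == 1:
        # single-sample soma: synthesize a cylinder of length == diameter
        p = soma_pts[0]
        half = p.diameter / 2.0
        soma_pts = [replace(p, x=p.x - half), replace(p, x=p.x + half)]
    sections = [Section(0, "soma", "soma", soma_pts, None)]

    soma_arcs = Section(0, "soma", "soma", soma_pts).arclengths
    soma_total = soma_arcs[-1] if soma_arcs[-1] > 0 else 1.0

    def soma_frac(nid: int) -> float:
        if nid not in soma_ids:
            return 1.0
        return float(soma_arcs[soma_ids.index(nid)] / soma_total) if len(soma_ids) > 1 else 0.5

    # neurite sections: start a section at each node whose parent is soma or a
    # branch point or a type change; follow unbranched same-type runs
    sec_of_node: dict[int, tuple[int, float]] = {}  # node -> (section id, 1.0)
    next_id = 1
    starts: list[int] = []
    for nid in order:
        typ, *_, parent = nodes[nid]
        if typ == 1:
            continue
        if parent in soma_ids:
            starts.append(nid)
        elif nodes[parent][0] != typ or len(children[parent]) >= 2:
            starts.append(nid)
    tree_counter = 0
    tree_of_start: dict[int, str] = {}
    for start in starts:
        parent = nodes[start][5]
        typ = nodes[start][0]
        region = _SWC_REGION.get(typ, "dendrite")
        if parent in soma_ids:
            attach = (0, soma_frac(parent))
            if region == "axon":
                label = "axon"
            else:
                tree_counter += 1
                label = str(tree_counter)
            tree_of_start[start] = label
            first_pt = soma_pts[soma_ids.index(parent)] if parent in soma_ids else pt(parent)
            first_pt = replace(first_pt, diameter=pt(start).diameter)
        else:
            attach_sec, _ = sec_of_node[parent]
            attach = (attach_sec, 1.0)
            label = next(s.tree_label for s in sections if s.id == attach_sec)
            first_pt = pt(parent)
            first_pt = replace(first_pt, diameter=pt(start).diameter) if nodes[parent][0] == 1 else pt(parent)
        run = [start]
        cur = start
        while len(children[cur]) == 1 and nodes[children[cur][0]][0] == typ:
            cur = children[cur][0]
            run.append(cur)
        pts = [first_pt] + [pt(n) for n in run]
        sec = Section(next_id, region, label, pts, attach)
        sections.append(sec)
        for n in run:
            sec_of_node[n] = (next_id, 1.0)
        next_id += 1

    import os

    return Morphology(sections, name=os.path.splitext(os.path.basename(str(path)))[0])


def write_swc(morph: Morphology, path) -> None:
    """Write a morphology back to 7-column SWC (radii = diameter / 2)."""
    lines = ["# generated by is3screen"]
    nid = 0
    last_node_of_sec: dict[int, int] = {}
    soma_node_at: list[tuple[float, int]] = []
    for sec in morph.topological_order():
        arcs = sec.arclengths
        total = arcs[-1] if arcs[-1] > 0 else 1.0
        typ = _REGION_SWC[sec.region]
        if sec.parent is None:
            prev = -1
            for i, p in enumerate(sec.points):
                nid += 1
                lines.append(f"{nid} {typ} {p.x:.6f} {p.y:.6f} {p.z:.6f} {p.diameter / 2:.6f} {prev}")
                soma_node_at.append((float(arcs[i] / total), nid))
                prev = nid
            last_node_of_sec[sec.id] = nid
        else:
            parent_id, frac = sec.parent
            if parent_id == morph.root.id:
                prev = min(soma_node_at, key=lambda t: abs(t[0] - frac))[1]
            else:
                prev = last_node_of_sec[parent_id]
            # the first point duplicates the attachment position; keep it as
            # an explicit node only when its diameter differs from the
            # parent's there (SWC nodes carry a single radius each)
            parent_diam = morph.section(parent_id).interp(frac)[0].diameter
            pts = sec.points if abs(sec.points[0].diameter - parent_diam) > 1e-9 \
                else sec.points[1:]
            for p in pts:
                nid += 1
                lines.append(f"{nid} {typ} {p.x:.6f} {p.y:.6f} {p.z:.6f} {p.diameter / 2:.6f} {prev}")
                prev = nid
            last_node_of_sec[sec.id] = nid
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# editing and measuring


def trim_axon(morph: Morphology, keep_length: float) -> Morphology:
    """Cut the axonal arborization down to ``keep_length`` um of axonal path.

    Distances are measured along the axon from its attachment to the soma.
    Dendrites and soma are untouched.  ``keep_length <= 0`` removes the axon
    entirely (with a warning).
    """
    axon_secs = [s for s in morph.sections if s.region == "axon"]
    if not axon_secs:
        return Morphology([replace(s, points=list(s.points)) for s in morph.sections], morph.name)
    if keep_length <= 0:
        warnings.warn("keep_length <= 0 removes all axon sections", stacklevel=2)

    # axonal path offset of each axon section start, measured from soma attachment
    offset: dict[int, float] = {}
    for sec in morph.topological_order():
        if sec.region != "axon":
            continue
        pid, frac = sec.parent
        parent = morph.section(pid)
        offset[sec.id] = 0.0 if parent.region != "axon" else offset[pid] + frac * parent.length

    kept: list[Section] = []
    for sec in morph.sections:
        if sec.region != "axon":
            kept.append(replace(sec, points=list(sec.points)))
            continue
        start = offset[sec.id]
        if start >= keep_length:
            continue
        if start + sec.length <= keep_length:
            kept.append(replace(sec, points=list(sec.points)))
            continue
        # truncate inside this section
        cut = (keep_length - start) / sec.length
        arcs = sec.arclengths
        s_cut = cut * arcs[-1]
        pts = [p for p, s in zip(sec.points, arcs) if s < s_cut]
        pts.append(sec.interp(cut)[0])
        if len(pts) < 2:
            pts = [sec.points[0], sec.interp(cut)[0]]
        kept.append(replace(sec, points=pts))
    kept_ids = {s.id for s in kept}
    kept = [s for s in kept if s.parent is None or s.parent[0] in kept_ids]
    # drop any axon section whose ancestor was removed
    changed = True
    while changed:
        kept_ids = {s.id for s in kept}
        filtered = [s for s in kept if s.parent is None or s.parent[0] in kept_ids]
        changed = len(filtered) != len(kept)
        kept = filtered
    return Morphology(kept, name=morph.name)


def path_distance(morph: Morphology, location: tuple[int, float]) -> float:
    """Arc length (um) from the soma section midpoint to ``(section, fraction)``.

    The soma half-length is included, so a first-order dendrite of length L
    attached at the distal soma end has its tip at soma_length/2 + L.
    """
    sec_id, frac = location
    sec = morph.section(sec_id)
    if not 0.0 <= frac <= 1.0:
        raise MorphologyError(f"fraction {frac} outside [0, 1]")
    if sec.parent is None:
        mid = 0.5 * sec.length
        return abs(frac * sec.length - mid)
    dist = frac * sec.length
    cur = sec
    while True:
        pid, pfrac = cur.parent
        parent = morph.section(pid)
        if parent.parent is None:
            mid = 0.5 * parent.length
            return dist + abs(pfrac * parent.length - mid)
        # the attachment sits pfrac of the way along the parent section
        dist += pfrac * parent.length
        cur = parent


@dataclass(frozen=True)
class TreeStats:
    """Per-tree morphometrics (branch points, trapezoidal area, lengths)."""

    tree_label: str
    n_branch_points: int
    surface_area: float
    max_distal_length: float
    summed_length: float


def tree_stats(morph: Morphology) -> list[TreeStats]:
    """Morphometrics per tree label (soma excluded; axon reported as 'axon').

    A branch point is a topological node with >= 2 child sections; the soma
    itself is never counted even if several trees attach to it.  Distal
    length is measured from the tree's attachment to the soma.
    """
    labels = sorted({s.tree_label for s in morph.sections if s.region != "soma"})
    out = []
    for label in labels:
        secs = [s for s in morph.sections if s.tree_label == label]
        sec_ids = {s.id for s in secs}
        n_bp = sum(1 for s in secs if len([c for c in morph.children(s.id) if c.id in sec_ids]) >= 2)
        area = sum(s.surface_area() for s in secs)
        total_len = sum(s.length for s in secs)
        # distance of each section start from the tree root attachment
        start: dict[int, float] = {}
        for s in morph.topological_order():
            if s.id not in sec_ids:
                continue
            pid, pfrac = s.parent
            start[s.id] = 0.0 if pid not in sec_ids else start[pid] + pfrac * morph.section(pid).length
        max_dist = max(start[s.id] + s.length for s in secs) if secs else 0.0
        out.append(TreeStats(label, n_bp, area, max_dist, total_len))
    return out


def tree_stats_table(morph: Morphology):
    """Tree stats as a DataFrame with the standard column names."""
    import pandas as pd

    rows = [
        {
            "tree_label": t.tree_label,
            "n_branch_points": t.n_branch_points,
            "surface_area_um2": t.surface_area,
            "max_distal_length_um": t.max_distal_length,
            "summed_length_um": t.summed_length,
        }
        for t in tree_stats(morph)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compartmentalization


@dataclass(frozen=True)
class Compartment:
    """An isopotential span [a, b] of a section's normalized arc."""

    section_id: int
    a: float
    b: float
    length: float
    surface_area: float
    half_r_a: float  # MOhm, from midpoint toward the 'a' end
    half_r_b: float  # MOhm, from midpoint toward the 'b' end
    path_distance: float  # um, soma midpoint to compartment midpoint
    region: str


class CompartmentalModel:
    """A morphology discretized into compartments with tree connectivity.

    Compartments are stored in an order where every parent precedes its
    children (``parent_index[i] < i``), which lets the cable solver run a
    single leaf-to-root elimination sweep.
    """

    def __init__(self, morphology: Morphology, compartments: list[Compartment],
                 parent_index: np.ndarray, axial_g: np.ndarray):
        self.morphology = morphology
        self.compartments = compartments
        self.parent_index = parent_index  # -1 for the root compartment
        self.axial_g = axial_g  # uS coupling between compartment i and its parent
        self._by_section: dict[int, list[int]] = {}
        for i, c in enumerate(compartments):
            self._by_section.setdefault(c.section_id, []).append(i)

    @property
    def n_comp(self) -> int:
        return len(self.compartments)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([c.surface_area for c in self.compartments])

    @property
    def path_distances(self) -> np.ndarray:
        return np.array([c.path_distance for c in self.compartments])

    @property
    def regions(self) -> list[str]:
        return [c.region for c in self.compartments]

    def locate(self, location: tuple[int, float]) -> int:
        """Index of the compartment containing ``(section id, arc fraction)``."""
        sec_id, frac = location
        if sec_id not in self._by_section:
            raise MorphologyError(f"no compartments for section {sec_id}")
        if not 0.0 <= frac <= 1.0:
            raise MorphologyError(f"fraction {frac} outside [0, 1]")
        for i in self._by_section[sec_id]:
            c = self.compartments[i]
            if c.a <= frac <= c.b:
                return i
        return self._by_section[sec_id][-1]

    def soma_index(self) -> int:
        """Compartment at the soma section midpoint."""
        return self.locate((self.morphology.root.id, 0.5))

    def total_surface_area(self) -> float:
        return float(self.areas_um2.sum())


def _ac_length_constant_um(diam_um: float, r_a_ohm_cm: float, c_m_uf_cm2: float,
                           freq_hz: float = 100.0) -> float:
    """AC length constant at ``freq_hz`` for a cylinder, in um.

    lambda_f = 0.5 * sqrt(d / (pi * f * Ra * Cm)) with d in cm, giving cm.
    """
    d_cm = diam_um * 1e-4
    lam_cm = 0.5 * math.sqrt(d_cm / (math.pi * freq_hz * r_a_ohm_cm * c_m_uf_cm2 * 1e-6))
    return lam_cm * 1e4


def compartmentalize(
    morph: Morphology,
    policy: str = "frequency",
    *,
    fraction: float = 0.1,
    max_length: float = 20.0,
    passive=None,
) -> CompartmentalModel:
    """Discretize each section into an odd number of isopotential compartments.

    policy 'frequency': compartment length <= ``fraction`` of the AC length
    constant at 100 Hz (requires ``passive``, a region -> parameters map or a
    single parameter set).  policy 'fixed': compartment length <=
    ``max_length`` um.  Surface areas are trapezoidal integrals over each
    compartment's arc; half axial resistances integrate 4 Ra / (pi d^2).
    """
    if policy not in ("frequency", "fixed"):
        raise MorphologyError(f"unknown policy {policy!r}")

    def passive_for(region: str):
        if passive is None:
            raise MorphologyError("frequency policy requires passive parameters")
        if hasattr(passive, "for_region"):
            return passive.for_region(region)
        if isinstance(passive, dict):
            return passive[region]
        return passive

    comps: list[Compartment] = []
    parent_idx: list[int] = []
    axial_g: list[float] = []
    first_comp_of_sec: dict[int, int] = {}
    comps_of_sec: dict[int, list[int]] = {}

    ordered = morph.topological_order()
    for sec in ordered:
        if any(p.diameter <= 0 for p in sec.points):
            raise MorphologyError(f"zero-diameter point in section {sec.id}")
        mean_diam = float(np.mean([p.diameter for p in sec.points]))
        if policy == "frequency":
            pp = passive_for(sec.region)
            lam = _ac_length_constant_um(mean_diam, pp.R_a, pp.C_m)
            target = fraction * lam
        else:
            target = max_length
        n = max(1, math.ceil(sec.length / target))
        if n % 2 == 0:
            n += 1
        edges = np.linspace(0.0, 1.0, n + 1)
        idxs = []
        for k in range(n):
            a, b = float(edges[k]), float(edges[k + 1])
            area, length, rfac = _integrate_section(sec, a, b)
            mid = 0.5 * (a + b)
            # half resistances: integrate over each half of the span
            _, _, rfac_lo = _integrate_section(sec, a, mid)
            _, _, rfac_hi = _integrate_section(sec, mid, b)
            # Ra (Ohm cm) * rfac (um^-1): Ohm cm / um = 1e4 Ohm = 1e-2 MOhm
            r_lo = passive_for(sec.region).R_a * rfac_lo * 1e-2 if passive is not None else rfac_lo * 1e-2
            r_hi = passive_for(sec.region).R_a * rfac_hi * 1e-2 if passive is not None else rfac_hi * 1e-2
            pd_mid = path_distance(morph, (sec.id, mid))
            comps.append(Compartment(sec.id, a, b, length, area, r_lo, r_hi, pd_mid, sec.region))
            idxs.append(len(comps) - 1)
        comps_of_sec[sec.id] = idxs
        first_comp_of_sec[sec.id] = idxs[0]

        # connectivity within the section
        for j in range(1, len(idxs)):
            i_prev, i_cur = idxs[j - 1], idxs[j]
            r = comps[i_prev].half_r_b + comps[i_cur].half_r_a
            parent_idx_append(parent_idx, axial_g, i_cur, i_prev, r)
        # connect section start to parent
        if sec.parent is None:
            parent_idx_append(parent_idx, axial_g, idxs[0], -1, 0.0)
        else:
            pid, pfrac = sec.parent
            # host compartment on the parent section
            host = None
            for i in comps_of_sec[pid]:
                c = comps[i]
                if c.a <= pfrac <= c.b:
                    host = i
                    break
            if host is None:
                host = comps_of_sec[pid][-1]
            r = comps[host].half_r_b + comps[idxs[0]].half_r_a
            parent_idx_append(parent_idx, axial_g, idxs[0], host, r)

    return CompartmentalModel(morph, comps, np.array(parent_idx, dtype=np.int64),
                              np.array(axial_g))


def parent_idx_append(parent_idx: list, axial_g: list, child: int, parent: int, r_mohm: float) -> None:
    while len(parent_idx) <= child:
        parent_idx.append(-1)
        axial_g.append(0.0)
    parent_idx[child] = parent
    axial_g[child] = 0.0 if parent < 0 or r_mohm <= 0 else 1.0 / r_mohm  # uS
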
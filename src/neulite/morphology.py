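"""SWC morphologies: loading, discretization, synapse placement.

A morphology is a sample tree (standard 7-column SWC) partitioned into
*sections* — maximal unbranched chains of samples sharing a type code
(1 somatic, 2 axonal, 3 basal dendrite, 4 apical dendrite).  For
simulation and for the extracellular forward model each section is cut
into *segments*: straight line pieces of equal arc length (count =
``ceil(L / max_seg_len)``) whose endpoints and radii interpolate the SWC
polyline linearly.  Membrane current is assumed uniformly distributed
within a segment, so equal-length segments serve that assumption best.

Synapse placement constraints are expressed as ``(target_sections,
distance_range)``: a segment is eligible when its section type is in
``target_sections`` and its *midpoint* path distance from the soma center
lies in ``[d_min, d_max]`` μm.  Among eligible segments a placement picks
a segment with probability proportional to its length and an offset
uniform along it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "SWCPoint", "Section", "Segment", "Placement", "Morphology",
    "load_swc", "discretize", "candidate_segments", "place_synapses",
    "SECTION_TYPE_CODES",
]

SECTION_TYPE_CODES: Dict[str, int] = {
    "somatic": 1, "axonal": 2, "basal": 3, "apical": 4,
}
_CODE_NAMES = {v: k for k, v in SECTION_TYPE_CODES.items()}


@dataclass
class SWCPoint:
    sample_id: int
    type_code: int
    xyz: np.ndarray          # μm
    radius: float            # μm
    parent_id: int


@dataclass
class Section:
    """Maximal unbranched chain of SWC samples of one type."""
    index: int
    type_code: int
    xyz: np.ndarray          # (k, 3) polyline, μm
    radii: np.ndarray        # (k,)
    parent_section: int      # -1 for the root section
    path_dist_start: float   # path distance of xyz[0] from soma center, μm

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.xyz, axis=0),
                                    axis=1).sum())


@dataclass
class Segment:
    """Straight line piece with uniform membrane current."""
    index: int
    section_index: int
    type_code: int
    a: np.ndarray            # endpoint, μm
    b: np.ndarray            # endpoint, μm
    radius: float            # μm
    length: float            # μm  (Δs > 0)
    path_dist: float         # midpoint path distance from soma center, μm
    parent_index: int        # segment attached proximally; -1 for root

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.a + self.b)


@dataclass
class Placement:
    segment_index: int
    offset: float            # ∈ [0, 1] along the segment


@dataclass
class Morphology:
    points: List[SWCPoint]
    sections: List[Section]
    soma_center: np.ndarray
    segments: List[Segment] = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.sections if s.type_code != 1)

    def transformed(self, translation: Sequence[float] = (0, 0, 0),
                    rotation_y: float = 0.0) -> "Morphology":
        """Copy with segments rotated about the y axis through the soma
        center (radians) and then translated (μm).  Sections/points are
        left in file coordinates; only segments are placed in world space.
        """
        t = np.asarray(translation, dtype=float)
        c, s = math.cos(rotation_y), math.sin(rotation_y)
        rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

        def xf(p: np.ndarray) -> np.ndarray:
            return rot @ (p - self.soma_center) + self.soma_center + t

        segs = [Segment(index=g.index, section_index=g.section_index,
                        type_code=g.type_code, a=xf(g.a), b=xf(g.b),
                        radius=g.radius, length=g.length,
                        path_dist=g.path_dist, parent_index=g.parent_index)
                for g in self.segments]
        return Morphology(points=self.points, sections=self.sections,
                          soma_center=self.soma_center + t, segments=segs)


class SWCFormatError(ValueError):
    pass


def load_swc(path: str) -> Morphology:
    """Parse a standard SWC file into a section tree.

    Samples must form a tree: one root (parent -1), parents precede
    children, known type codes only.  Errors carry the offending line
    number.
    """
    points: Dict[int, SWCPoint] = {}
    order: List[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCFormatError(
                    f"{path}:{lineno}: expected 7 columns, got "
                    f"{len(fields)}")
            try:
                sid = int(fields[0])
                tc = int(fields[1])
                xyz = np.array([float(fields[2]), float(fields[3]),
                                float(fields[4])])
                r = float(fields[5])
                pid = int(fields[6])
            except ValueError as exc:
                raise SWCFormatError(f"{path}:{lineno}: {exc}") from None
            if tc not in _CODE_NAMES:
                raise SWCFormatError(
                    f"{path}:{lineno}: unknown SWC type code {tc}")
            if sid in points:
                raise SWCFormatError(
                    f"{path}:{lineno}: duplicate sample id {sid}")
            if pid != -1 and pid not in points:
                raise SWCFormatError(
                    f"{path}:{lineno}: parent {pid} of sample {sid} not "
                    "defined on an earlier line (cycle or missing parent)")
            points[sid] = SWCPoint(sid, tc, xyz, r, pid)
            order.append(sid)
    if not points:
        raise SWCFormatError(f"{path}: no samples")
    roots = [sid for sid in order if points[sid].parent_id == -1]
    if len(roots) != 1:
        raise SWCFormatError(f"{path}: expected exactly one root sample, "
                             f"found {len(roots)}")
    soma_ids = [sid for sid in order if points[sid].type_code == 1]
    if not soma_ids:
        raise SWCFormatError(f"{path}: no somatic (type 1) sample")
    soma_center = points[soma_ids[0]].xyz.copy()

    children: Dict[int, List[int]] = {sid: [] for sid in order}
    for sid in order:
        pid = points[sid].parent_id
        if pid != -1:
            children[pid].append(sid)

    # Walk the tree into maximal unbranched same-type chains.
    sections: List[Section] = []
    # (first_sample, parent_section_index, path_dist at chain start)
    root = roots[0]
    stack: List[Tuple[int, int, float]] = [(root, -1, 0.0)]
    sec_of_sample: Dict[int, int] = {}
    while stack:
        sid, parent_sec, dist0 = stack.pop()
        chain = [sid]
        while True:
            kids = children[chain[-1]]
            if len(kids) == 1 and \
                    points[kids[0]].type_code == points[sid].type_code:
                chain.append(kids[0])
            else:
                break
        # prepend the attachment sample so the section polyline starts at
        # its parent's end point (standard SWC connectivity), except for
        # the root section
        pts = [points[c] for c in chain]
        attach = points[chain[0]].parent_id
        if attach != -1:
            pts = [points[attach]] + pts
        xyz = np.array([p.xyz for p in pts])
        radii = np.array([p.radius for p in pts])
        sec = Section(index=len(sections), type_code=points[sid].type_code,
                      xyz=xyz, radii=radii, parent_section=parent_sec,
                      path_dist_start=dist0)
        sections.append(sec)
        for c in chain:
            sec_of_sample[c] = sec.index
        # branch / type-change continuations from the chain end
        end = chain[-1]
        end_dist = dist0 + sec.length
        for kid in reversed(children[end]):
            if len(children[end]) == 1 and \
                    points[kid].type_code == points[sid].type_code:
                continue  # consumed by the chain above
            stack.append((kid, sec.index, end_dist))
    return Morphology(points=[points[s] for s in order],
                      sections=sections, soma_center=soma_center)


def discretize(m: Morphology, max_seg_len: float) -> Morphology:
    """Cut each section into equal-length segments ≤ ``max_seg_len`` μm.

    The soma becomes a single segment regardless of ``max_seg_len``: its
    length is the somatic path extent, or ``2 × radius`` for a one-point
    soma (rendered along +y).  Returns ``m`` with ``segments`` filled in.
    """
    if max_seg_len <= 0:
        raise ValueError(f"max_seg_len must be > 0, got {max_seg_len}")
    segments: List[Segment] = []
    last_seg_of_section: Dict[int, int] = {}
    for sec in m.sections:
        if sec.type_code == 1:
            seg = _soma_segment(sec, len(segments))
            last_seg_of_section[sec.index] = seg.index
            segments.append(seg)
            continue
        L = sec.length
        if L <= 0:
            raise SWCFormatError(
                f"section {sec.index} has zero length")
        nseg = max(1, math.ceil(L / max_seg_len))
        edges = np.linspace(0.0, L, nseg + 1)
        pts = _interp_polyline(sec.xyz, sec.radii, edges)
        parent = (last_seg_of_section.get(sec.parent_section, -1))
        for i in range(nseg):
            (pa, ra), (pb, rb) = pts[i], pts[i + 1]
            seg = Segment(
                index=len(segments), section_index=sec.index,
                type_code=sec.type_code, a=pa, b=pb,
                radius=0.5 * (ra + rb), length=float(edges[i + 1] - edges[i]),
                path_dist=sec.path_dist_start + 0.5 * (edges[i] + edges[i + 1]),
                parent_index=parent if i == 0 else len(segments) - 1)
            segments.append(seg)
        last_seg_of_section[sec.index] = segments[-1].index
    m.segments = segments
    return m


def _soma_segment(sec: Section, index: int) -> Segment:
    if sec.xyz.shape[0] == 1 or sec.length == 0.0:
        r = float(sec.radii[0])
        c = sec.xyz[0]
        a = c - np.array([0.0, r, 0.0])
        b = c + np.array([0.0, r, 0.0])
        length = 2.0 * r
    else:
        a, b = sec.xyz[0].copy(), sec.xyz[-1].copy()
        length = sec.length
    return Segment(index=index, section_index=sec.index, type_code=1,
                   a=a, b=b, radius=float(np.mean(sec.radii)),
                   length=float(length), path_dist=0.0, parent_index=-1)


def _interp_polyline(xyz: np.ndarray, radii: np.ndarray,
                     arcs: np.ndarray) -> List[Tuple[np.ndarray, float]]:
    """Points and radii at the requested arc lengths along a polyline."""
    steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    out = []
    for s in arcs:
        s = min(max(s, 0.0), cum[-1])
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(steps) - 1)
        f = 0.0 if steps[i] == 0 else (s - cum[i]) / steps[i]
        p = xyz[i] + f * (xyz[i + 1] - xyz[i])
        r = radii[i] + f * (radii[i + 1] - radii[i])
        out.append((p, float(r)))
    return out


def candidate_segments(m: Morphology, target_sections: Sequence[str],
                       distance_range: Sequence[float]) -> List[Segment]:
    """Segments eligible under the section-type and path-distance bands."""
    bad = set(target_sections) - set(SECTION_TYPE_CODES)
    if bad:
        raise ValueError(f"unknown section names {sorted(bad)}; valid: "
                         f"{sorted(SECTION_TYPE_CODES)}")
    d_min, d_max = float(distance_range[0]), float(distance_range[1])
    if not 0 <= d_min <= d_max:
        raise ValueError(f"distance_range must satisfy 0 <= d_min <= d_max, "
                         f"got {list(distance_range)!r}")
    if not m.segments:
        raise ValueError("morphology is not discretized; call discretize()")
    codes = {SECTION_TYPE_CODES[n] for n in target_sections}
    return [g for g in m.segments
            if g.type_code in codes and d_min <= g.path_dist <= d_max]


def place_synapses(m: Morphology, target_sections: Sequence[str],
                   distance_range: Sequence[float], n: int,
                   rng: np.random.Generator) -> List[Placement]:
    """Draw ``n`` independent placements on the eligible segments.

    Segment choice is length-weighted; the offset along the chosen segment
    is uniform.  Deterministic given ``rng``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    cands = candidate_segments(m, target_sections, distance_range)
    if not cands:
        raise ValueError(
            f"no segments satisfy target_sections={list(target_sections)!r}, "
            f"distance_range={list(distance_range)!r}")
    lengths = np.array([g.length for g in cands])
    probs = lengths / lengths.sum()
    idx = rng.choice(len(cands), size=n, p=probs)
    offsets = rng.random(n)
    return [Placement(segment_index=cands[i].index, offset=float(o))
            for i, o in zip(idx, offsets)]
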
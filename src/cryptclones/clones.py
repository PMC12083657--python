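"""Spatial clone calling from biopsy-level mutation tables.

The colon is opened longitudinally before sampling, so biopsy coordinates
live on a cylinder: x runs along the colon (mm) and y is radial with period
``circumference`` (mm). Calls of the same single-nucleotide variant in
spatially adjacent biopsies are parsimoniously merged into one clone:

1. replicate filtering — only calls with a positive log probability ratio in
   *both* replicate libraries and an adjusted VAF above the detection floor
   (0.01% by default) are retained;
2. adjacency — per tissue section, a Voronoi tessellation of biopsy centres
   with periodic boundary conditions along the radial axis; two biopsies are
   adjacent when their tiles share a boundary segment of positive length, or
   when their periodic centre distance is at most 2 mm (one biopsy diameter);
3. clone calling — for each distinct mutation (chrom, pos, ref, alt), the
   connected components (depth-first search) of the adjacency graph induced
   on the biopsies carrying it; each component is one clone.

Mutation identity for grouping is the DNA-level key (chrom, pos, ref, alt);
the same amino-acid change reached by different nucleotide changes is not
merged, since clonality is a DNA-level event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import Voronoi, QhullError

__all__ = [
    "Biopsy",
    "MutationCall",
    "Clone",
    "CONSEQUENCES",
    "filter_replicate_calls",
    "periodic_distance",
    "build_adjacency",
    "call_clones",
]

CONSEQUENCES = ("synonymous", "missense", "nonsense", "other")

#: minimum Voronoi ridge-segment length (mm) to count tiles as adjacent;
#: tiles touching only at a point are not adjacent.
_MIN_RIDGE_LEN = 1e-9


@dataclass(frozen=True)
class Biopsy:
    """A 2 mm punch biopsy located on the opened colon."""

    biopsy_id: str
    section_id: str
    x: float
    y: float
    circumference: float
    diameter: float = 2.0

    def __post_init__(self) -> None:
        if not self.circumference > 0:
            raise ValueError("circumference must be positive (mm)")
        if not 0 <= self.y < self.circumference:
            raise ValueError(
                f"biopsy {self.biopsy_id}: y={self.y} outside [0, {self.circumference})"
            )
        if not self.diameter > 0:
            raise ValueError("diameter must be positive (mm)")


@dataclass(frozen=True)
class MutationCall:
    """One SNV call in one biopsy, with per-replicate evidence."""

    biopsy_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    vaf_rep1: float
    vaf_rep2: float
    log_ratio_rep1: float
    log_ratio_rep2: float
    adjusted_vaf: float

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"consequence must be one of {CONSEQUENCES}, got {self.consequence!r}"
            )
        for name in ("vaf_rep1", "vaf_rep2", "adjusted_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """DNA-level mutation identity used for clone grouping."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_nonsynonymous(self) -> bool:
        return self.consequence != "synonymous"


@dataclass(frozen=True)
class Clone:
    """A spatially connected set of biopsies carrying the same mutation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    biopsy_ids: tuple[str, ...]
    max_vaf: float

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_biopsies(self) -> int:
        return len(self.biopsy_ids)


def filter_replicate_calls(
    calls: Iterable[MutationCall], min_vaf: float = 1e-4
) -> list[MutationCall]:
    """Dual-replicate stringency filter.

    Retains calls whose log probability ratio is strictly positive in both
    replicates individually and whose adjusted VAF is at least ``min_vaf``
    (default 0.01%, the lower detection threshold).
    """
    return [
        c
        for c in calls
        if c.log_ratio_rep1 > 0 and c.log_ratio_rep2 > 0 and c.adjusted_vaf >= min_vaf
    ]


def periodic_distance(
    a: tuple[float, float], b: tuple[float, float], circumference: float
) -> float:
    """Euclidean distance with the y axis wrapped at ``circumference``."""
    dx = a[0] - b[0]
    dy = abs(a[1] - b[1]) % circumference
    dy = min(dy, circumference - dy)
    return math.hypot(dx, dy)


def _clip_segment(p0: np.ndarray, p1: np.ndarray, box: tuple[float, float, float, float]) -> float:
    """Length of the part of segment p0-p1 inside an axis-aligned box (Liang–Barsky)."""
    x_lo, x_hi, y_lo, y_hi = box
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for delta, lo, hi, start in ((d[0], x_lo, x_hi, p0[0]), (d[1], y_lo, y_hi, p0[1])):
        if delta == 0.0:
            if start < lo or start > hi:
                return 0.0
            continue
        ta, tb = (lo - start) / delta, (hi - start) / delta
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 >= t1:
            return 0.0
    return float((t1 - t0) * np.hypot(d[0], d[1]))


def _voronoi_edges(biopsies: Sequence[Biopsy]) -> set[tuple[int, int]]:
    """Index pairs whose periodic Voronoi tiles share a positive-length boundary.

    Periodicity along y is realised by replicating every centre at y - c and
    y + c and mapping ridges that touch the fundamental (central) copy back
    to the original index pair. Tiles are clipped to the section's bounding
    box padded by one biopsy diameter: a ridge counts only where it runs
    inside that box, so unbounded outer cells cannot create spurious
    long-range adjacency. Half-infinite ridges are reconstructed from the
    ridge normal before clipping.
    """
    n = len(biopsies)
    circ = biopsies[0].circumference
    diameter = max(b.diameter for b in biopsies)
    xs = np.array([b.x for b in biopsies])
    ys = np.array([b.y for b in biopsies])

    pts: list[tuple[float, float]] = []
    owner: list[int] = []
    copy_idx: list[int] = []  # periodic copy (1 = fundamental domain)
    for ci, shift in enumerate((-circ, 0.0, circ)):
        for idx in range(n):
            pts.append((xs[idx], ys[idx] + shift))
            owner.append(idx)
            copy_idx.append(ci)
    pts_arr = np.asarray(pts)

    box = (
        float(xs.min() - diameter),
        float(xs.max() + diameter),
        float(ys.min() - circ - diameter),
        float(ys.max() + circ + diameter),
    )
    reach = 4.0 * math.hypot(box[1] - box[0], box[3] - box[2]) + 1.0
    centre = pts_arr.mean(axis=0)

    vor = Voronoi(pts_arr)
    edges: set[tuple[int, int]] = set()
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        a, b = owner[p], owner[q]
        if a == b:
            continue
        if copy_idx[p] != 1 and copy_idx[q] != 1:
            continue  # only ridges touching the fundamental domain count
        key = (min(a, b), max(a, b))
        if key in edges:
            continue
        v1, v2 = verts
        if v1 == -1 and v2 == -1:
            continue  # fully unbounded ridge (degenerate geometry)
        if v1 == -1 or v2 == -1:
            fin = vor.vertices[max(v1, v2)]
            t = pts_arr[q] - pts_arr[p]
            normal = np.array([-t[1], t[0]])
            normal /= np.linalg.norm(normal)
            mid = (pts_arr[p] + pts_arr[q]) / 2.0
            if np.dot(mid - centre, normal) < 0:
                normal = -normal
            p0, p1 = fin, fin + reach * normal
        else:
            p0, p1 = vor.vertices[v1], vor.vertices[v2]
        if _clip_segment(np.asarray(p0), np.asarray(p1), box) > _MIN_RIDGE_LEN:
            edges.add(key)
    return edges


def build_adjacency(
    biopsies: Sequence[Biopsy], dist_threshold: float = 2.0
) -> nx.Graph:
    """Biopsy adjacency graph (nodes keyed by biopsy_id).

    Tessellation is computed per tissue section independently; two biopsies
    are adjacent iff their periodic Voronoi tiles share a positive-length
    boundary or their periodic centre distance is at most ``dist_threshold``
    mm. Degenerate configurations (e.g. collinear centres, where the
    tessellation is undefined) fall back to the distance criterion alone.
    """
    graph = nx.Graph()
    sections: dict[str, list[Biopsy]] = {}
    for b in biopsies:
        if b.biopsy_id in graph:
            raise ValueError(f"duplicate biopsy_id {b.biopsy_id!r}")
        graph.add_node(b.biopsy_id, biopsy=b)
        sections.setdefault(b.section_id, []).append(b)

    for section in sections.values():
        circs = {b.circumference for b in section}
        if len(circs) > 1:
            raise ValueError(
                f"section {section[0].section_id!r} has inconsistent circumferences"
            )
        if len(section) < 2:
            continue
        circ = section[0].circumference
        # distance criterion (periodic, centre-to-centre)
        for i in range(len(section)):
            for j in range(i + 1, len(section)):
                d = periodic_distance(
                    (section[i].x, section[i].y), (section[j].x, section[j].y), circ
                )
                if d <= dist_threshold:
                    graph.add_edge(section[i].biopsy_id, section[j].biopsy_id)
        # Voronoi tile adjacency
        try:
            for i, j in _voronoi_edges(section):
                graph.add_edge(section[i].biopsy_id, section[j].biopsy_id)
        except (QhullError, ValueError):
            pass  # degenerate geometry: the distance rule above stands alone
    return graph


def call_clones(
    calls: Sequence[MutationCall], graph: nx.Graph
) -> list[Clone]:
    """Merge same-mutation calls across adjacent biopsies into clones.

    For each distinct mutation key the subgraph induced on the biopsies
    carrying it is split into connected components; each component becomes
    one :class:`Clone`. Output is deterministically ordered by mutation key
    then member biopsy ids.
    """
    by_key: dict[tuple[str, int, str, str], list[MutationCall]] = {}
    for c in calls:
        if c.biopsy_id not in graph:
            raise KeyError(f"call references unknown biopsy {c.biopsy_id!r}")
        by_key.setdefault(c.key, []).append(c)

    clones: list[Clone] = []
    for key in sorted(by_key):
        members = by_key[key]
        nodes = {c.biopsy_id for c in members}
        sub = graph.subgraph(nodes)
        vaf_by_biopsy: dict[str, float] = {}
        for c in members:
            vaf_by_biopsy[c.biopsy_id] = max(
                vaf_by_biopsy.get(c.biopsy_id, 0.0), c.adjusted_vaf
            )
        rep = members[0]
        for comp in sorted(nx.connected_components(sub), key=lambda s: sorted(s)):
            ids = tuple(sorted(comp))
            clones.append(
                Clone(
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    gene=rep.gene,
                    consequence=rep.consequence,
                    biopsy_ids=ids,
                    max_vaf=max(vaf_by_biopsy[b] for b in ids),
                )
            )
    return clones
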
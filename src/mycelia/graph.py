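"""Planar spatial-graph model of a hyphal network.

A mycelium snapshot is represented as a planar graph whose nodes carry
continuous 2-D coordinates (micrometres), a birth time (hours) and a
*branch provenance* (which branching process created the node's hypha).
Edges are straight segments; curved hyphae are polylines threaded through
degree-2 internal nodes.

Vertex nomenclature follows the field's convention for reconstructed
mycelium graphs: ``V1`` are apexes (tips), ``V1l`` tips of lateral
branches, ``V3`` apical (subapical) junctions, ``V3l`` lateral junctions,
and ``V3i`` geometric crossings of hyphae that overlap without fusing
(no anastomosis).  Crossings are *synthesized* from segment intersections
on demand and never stored as graph nodes, so the stored-degree invariant
(1, 2 or 3) stays clean.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
import shapely

__all__ = [
    "VertexClass",
    "VertexCounts",
    "NetworkGraph",
    "TortuosityResult",
    "MalformedGraphError",
    "DegenerateGraphError",
    "classify_vertices",
    "count_crossings",
    "total_length",
    "pruned_length",
    "tortuosity",
    "one_body_ratio",
]

#: provenances understood by the classifier; anything else is "unknown"
KNOWN_PROVENANCES = frozenset(
    {"germination", "exploratory", "operating", "lateral", "apical"}
)


class MalformedGraphError(ValueError):
    """A stored node violates the hyphal-graph degree invariant."""


class DegenerateGraphError(ValueError):
    """The requested measure is undefined on this graph (e.g. empty)."""


class VertexClass(enum.Enum):
    V1 = "V1"          # apex of an apical/germination hypha
    V1L = "V1l"        # apex of a lateral branch
    V3 = "V3"          # subapical (apical) branching junction
    V3L = "V3l"        # lateral branching junction
    V3I = "V3i"        # geometric crossing (overlap), synthesized
    INTERNAL = "internal"  # degree-2 polyline node


@dataclass(frozen=True)
class VertexCounts:
    """Counts per :class:`VertexClass` for one snapshot."""

    v1: int = 0
    v1l: int = 0
    v3: int = 0
    v3l: int = 0
    v3i: int = 0
    internal: int = 0
    #: False when branch provenance was missing, in which case lateral
    #: subclasses could not be separated and everything degree-1 / degree-3
    #: was lumped into ``v1`` / ``v3``.
    subclasses_known: bool = True

    @property
    def one_body(self) -> int:
        return self.v1 + self.v1l

    @property
    def three_body(self) -> int:
        return self.v3 + self.v3l + self.v3i

    def total(self) -> int:
        return self.v1 + self.v1l + self.v3 + self.v3l + self.v3i + self.internal


@dataclass
class TortuosityResult:
    """Arc-chord tortuosity of a network: alpha = (Lt - Lp)/(Lt + Lp)."""

    l_tot_um: float
    l_pruned_um: float
    alpha: float


@dataclass
class NetworkGraph:
    """Planar spatial graph of hyphae.

    Parameters
    ----------
    node_ids:
        integer identifiers, unique.
    xy:
        ``(n, 2)`` array of coordinates in micrometres.
    birth_h:
        per-node birth time in hours.
    provenance:
        per-node branch provenance string (see :data:`KNOWN_PROVENANCES`);
        empty string / ``"unknown"`` marks missing provenance.
    edges:
        ``(m, 2)`` array of node ids; each edge is a straight segment.
    branch_type:
        per-edge branch type string.
    snapshot_time:
        time of the snapshot in hours.
    """

    node_ids: np.ndarray
    xy: np.ndarray
    birth_h: np.ndarray
    provenance: np.ndarray
    edges: np.ndarray
    branch_type: np.ndarray
    snapshot_time: float = 0.0
    vertex_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.birth_h = np.asarray(self.birth_h, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=object)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.branch_type = np.asarray(self.branch_type, dtype=object)
        self._index = {int(i): k for k, i in enumerate(self.node_ids)}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        nodes: Iterable[tuple],
        edges: Iterable[tuple],
        snapshot_time: float = 0.0,
    ) -> "NetworkGraph":
        """Build from ``(id, x, y[, birth_h[, class[, provenance]]])`` node
        tuples and ``(a, b[, branch_type])`` edge tuples."""
        ids, xs, ys, births, classes, provs = [], [], [], [], [], []
        for rec in nodes:
            rec = tuple(rec)
            ids.append(int(rec[0]))
            xs.append(float(rec[1]))
            ys.append(float(rec[2]))
            births.append(float(rec[3]) if len(rec) > 3 and rec[3] is not None else 0.0)
            classes.append(str(rec[4]) if len(rec) > 4 and rec[4] is not None else "")
            provs.append(str(rec[5]) if len(rec) > 5 and rec[5] is not None else "unknown")
        e_ab, e_ty = [], []
        for rec in edges:
            rec = tuple(rec)
            e_ab.append((int(rec[0]), int(rec[1])))
            e_ty.append(str(rec[2]) if len(rec) > 2 and rec[2] is not None else "unknown")
        return cls(
            node_ids=np.array(ids, dtype=np.int64),
            xy=np.column_stack([xs, ys]) if ids else np.empty((0, 2)),
            birth_h=np.array(births, dtype=float),
            provenance=np.array(provs, dtype=object),
            edges=np.array(e_ab, dtype=np.int64).reshape(-1, 2),
            branch_type=np.array(e_ty, dtype=object),
            snapshot_time=snapshot_time,
            vertex_class=np.array(classes, dtype=object),
        )

    # -- basic accessors --------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for a, b in self.edges:
            deg[self._index[int(a)]] += 1
            deg[self._index[int(b)]] += 1
        return deg

    def validate(self) -> None:
        """Check structural invariants; raise :class:`MalformedGraphError`."""
        if not np.all(np.isfinite(self.xy)):
            raise MalformedGraphError("non-finite node coordinates")
        for a, b in self.edges:
            if int(a) not in self._index or int(b) not in self._index:
                raise MalformedGraphError(f"edge ({a}, {b}) references a missing node")
        if self.n_nodes and np.any(self.birth_h > self.snapshot_time + 1e-9):
            raise MalformedGraphError("node born after snapshot time")

    def segment_coords(self) -> np.ndarray:
        """``(m, 2, 2)`` array of segment endpoint coordinates."""
        ia = np.fromiter((self._index[int(a)] for a in self.edges[:, 0]), dtype=np.int64,
                         count=self.n_edges)
        ib = np.fromiter((self._index[int(b)] for b in self.edges[:, 1]), dtype=np.int64,
                         count=self.n_edges)
        return np.stack([self.xy[ia], self.xy[ib]], axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for k, nid in enumerate(self.node_ids):
            g.add_node(int(nid), xy=tuple(self.xy[k]))
        for (a, b), ty in zip(self.edges, self.branch_type):
            g.add_edge(int(a), int(b), branch_type=ty)
        return g


# ---------------------------------------------------------------------------
# measures


def total_length(graph: NetworkGraph) -> float:
    """Total hyphal length L_tot in micrometres (sum of segment lengths)."""
    if graph.n_edges == 0:
        raise DegenerateGraphError("empty graph has no length")
    seg = graph.segment_coords()
    return float(np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1).sum())


def pruned_length(graph: NetworkGraph) -> float:
    """Length of the network pruned from curvature, L_p.

    Every maximal chain of degree-2 nodes is replaced by the straight chord
    between its flanking degree-1/3 anchors.  Components that are pure
    cycles of degree-2 nodes contribute zero chord length.
    """
    if graph.n_edges == 0:
        raise DegenerateGraphError("empty graph has no length")
    g = graph.to_networkx()
    pos = {int(i): graph.xy[k] for k, i in enumerate(graph.node_ids)}
    anchors = {n for n in g.nodes if g.degree[n] != 2}
    seen_edges: set[frozenset] = set()
    lp = 0.0
    for a in anchors:
        for nbr in g.neighbors(a):
            e = frozenset((a, nbr)) if a != nbr else None
            key = (min(a, nbr), max(a, nbr), 0)
            # walk the chain of degree-2 nodes starting with edge (a, nbr)
            prev, cur = a, nbr
            first_edge = frozenset((prev, cur))
            if first_edge in seen_edges:
                continue
            chain_edges = [first_edge]
            while cur not in anchors:
                nxts = [x for x in g.neighbors(cur) if x != prev]
                if not nxts:  # dead end of degree 1 is an anchor; defensive
                    break
                prev, cur = cur, nxts[0]
                chain_edges.append(frozenset((prev, cur)))
            seen_edges.update(chain_edges)
            lp += float(np.linalg.norm(np.asarray(pos[a]) - np.asarray(pos[cur])))
    return lp


def tortuosity(graph: NetworkGraph) -> TortuosityResult:
    """Normalized arc-chord tortuosity alpha = (Lt - Lp)/(Lt + Lp).

    Zero for an all-straight network; strictly below 1 for any network with
    positive pruned length.
    """
    lt = total_length(graph)
    lp = pruned_length(graph)
    if lt + lp <= 0:
        raise DegenerateGraphError("zero-length graph")
    return TortuosityResult(l_tot_um=lt, l_pruned_um=lp, alpha=(lt - lp) / (lt + lp))


def count_crossings(graph: NetworkGraph) -> int:
    """Number of transversal crossing points between non-adjacent segments.

    Segments sharing a node are never counted; endpoint touches (T
    junctions) and collinear overlaps are excluded — a crossing is a proper
    interior/interior intersection, the geometric ``V3i`` of an overlap
    without fusion.
    """
    m = graph.n_edges
    if m < 2:
        return 0
    seg = graph.segment_coords()
    geoms = shapely.linestrings(seg)
    tree = shapely.STRtree(geoms)
    i, j = tree.query(geoms, predicate="crosses")
    mask = i < j
    i, j = i[mask], j[mask]
    if len(i) == 0:
        return 0
    ea, eb = graph.edges[i], graph.edges[j]
    shared = (
        (ea[:, 0] == eb[:, 0])
        | (ea[:, 0] == eb[:, 1])
        | (ea[:, 1] == eb[:, 0])
        | (ea[:, 1] == eb[:, 1])
    )
    return int(np.count_nonzero(~shared))


def classify_vertices(graph: NetworkGraph, include_crossings: bool = True) -> VertexCounts:
    """Count vertices per class.

    Degree separates tips (1), internal polyline nodes (2) and junctions
    (3).  Branch provenance separates the lateral subclasses ``V1l`` /
    ``V3l`` from ``V1`` / ``V3``; if provenance is missing the lateral
    subclasses are lumped and ``subclasses_known`` is False.  ``V3i``
    crossings are synthesized from segment intersections, never stored.
    """
    deg = graph.degrees()
    if np.any(deg > 3):
        bad = graph.node_ids[deg > 3]
        raise MalformedGraphError(
            f"stored node(s) {bad[:5].tolist()} have degree > 3; hyphal graphs "
            "only admit tips, internal nodes and 3-way junctions"
        )
    provs = np.array([str(p) for p in graph.provenance], dtype=object)
    known = np.isin(provs, list(KNOWN_PROVENANCES))
    subclasses_known = bool(known.all()) and graph.n_nodes > 0

    v1 = v1l = v3 = v3l = internal = 0
    for k in range(graph.n_nodes):
        d = deg[k]
        p = provs[k]
        if d == 2:
            internal += 1
        elif d <= 1:
            # isolated nodes (d==0) are counted as tips of a point-hypha
            if subclasses_known and p == "lateral":
                v1l += 1
            else:
                v1 += 1
        else:  # d == 3
            if subclasses_known and p == "lateral":
                v3l += 1
            else:
                v3 += 1
    v3i = count_crossings(graph) if include_crossings else 0
    return VertexCounts(
        v1=v1, v1l=v1l, v3=v3, v3l=v3l, v3i=v3i, internal=internal,
        subclasses_known=subclasses_known,
    )


def one_body_ratio(
    graph_or_counts: NetworkGraph | VertexCounts,
    include_crossings: bool = True,
) -> float:
    """Ratio of 1-body vertices (V1 + V1l) to branching vertices.

    The denominator is V3 + V3l and, when ``include_crossings`` (the
    default, matching what an image-derived graph would contain), the
    geometric crossings V3i as well.
    """
    if isinstance(graph_or_counts, NetworkGraph):
        counts = classify_vertices(graph_or_counts, include_crossings=include_crossings)
    else:
        counts = graph_or_counts
    denom = counts.v3 + counts.v3l + (counts.v3i if include_crossings else 0)
    if denom == 0:
        raise DegenerateGraphError(
            "no branching vertices yet (degenerate early graph); "
            "one-body ratio is undefined"
        )
    return (counts.v1 + counts.v1l) / denom
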
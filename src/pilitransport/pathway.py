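"""Aromatic π-stacking pathway geometry of a pilus assembly.

Electron transfer along a conductive pilus is carried by the chain of
closely packed Phe/Tyr rings. This module builds the graph whose nodes are
aromatic rings and whose edge weights are interaromatic (centroid-centroid)
distances, finds the minimum-length transfer pathway with Dijkstra's
algorithm, and extracts the smallest helically symmetric pathway unit — the
four rings F1(P-1) → F24 → Y27 → F1(P) — with its three characteristic
distances d1, d2, d3 and the rate-limiting (bottleneck) distance.

Edge weight is the centroid distance because pathway structure is reported
in those terms; the proximal carbon-carbon distance (minimum over the 36
ring-carbon pairs) is reported alongside but never used as a path weight.
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .assembly import AssemblyModel
from .structure import AromaticRing, StructureError, extract_aromatic_rings

__all__ = [
    "AromaticGraph",
    "SymmetricUnit",
    "PathwayWarning",
    "DEFAULT_CUTOFF",
    "DEFAULT_SUBUNIT_P",
    "interaromatic_distance",
    "proximal_cc_distance",
    "build_graph",
    "shortest_path",
    "extract_symmetric_unit",
    "bottleneck_distance",
    "write_pathway_report",
]

#: Default edge cutoff (Å): covers the largest reported pathway step (6.1 Å)
#: while excluding intra-subunit pairs (>= 8.7 Å).
DEFAULT_CUTOFF = 7.0

#: Default index of the first subunit of the second helical turn.
DEFAULT_SUBUNIT_P = 7


class PathwayWarning(UserWarning):
    """Non-fatal structural anomaly in pathway extraction."""


def interaromatic_distance(ring_a: AromaticRing, ring_b: AromaticRing) -> float:
    """Euclidean distance between the two ring centroids (Å)."""
    return float(np.linalg.norm(ring_a.centroid - ring_b.centroid))


def proximal_cc_distance(ring_a: AromaticRing, ring_b: AromaticRing) -> float:
    """Minimum carbon-carbon distance over all 36 ring-atom pairs (Å)."""
    diff = ring_a.ring_coords[:, None, :] - ring_b.ring_coords[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


@dataclass
class AromaticGraph:
    """Undirected graph of aromatic rings weighted by interaromatic distance."""

    graph: nx.Graph
    rings: dict[tuple[int, int], AromaticRing]
    cutoff: float | None = None

    def ring(self, key: tuple[int, int]) -> AromaticRing:
        return self.rings[key]

    def find(self, subunit_index: int, residue_seq: int) -> AromaticRing:
        return self.rings[(subunit_index, residue_seq)]


def build_graph(assembly: AssemblyModel, cutoff: float | None = DEFAULT_CUTOFF) -> AromaticGraph:
    """Build the aromatic-ring graph of an assembly.

    Every ring pair whose interaromatic distance is at most ``cutoff`` becomes
    an edge (all pairs if ``cutoff`` is None). Nodes are keyed by
    ``(subunit_index, residue_seq)``.
    """
    rings: list[AromaticRing] = []
    for i, sub in enumerate(assembly.subunits):
        rings.extend(extract_aromatic_rings(sub, subunit_index=i))
    if not rings:
        raise StructureError("assembly contains no aromatic residues")
    g = nx.Graph()
    ring_map = {r.key: r for r in sorted(rings, key=lambda r: r.key)}
    g.add_nodes_from(ring_map)
    keys = list(ring_map)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            d = interaromatic_distance(ring_map[ka], ring_map[kb])
            if cutoff is None or d <= cutoff:
                g.add_edge(ka, kb, weight=d)
    return AromaticGraph(g, ring_map, cutoff)


def shortest_path(
    graph: AromaticGraph, source: AromaticRing, target: AromaticRing
) -> tuple[list[AromaticRing] | None, float]:
    """Minimum-total-distance path between two rings (Dijkstra).

    Ties between equal-length paths are broken deterministically toward the
    lexicographically smallest sequence of ``(subunit_index, residue_seq)``
    node keys. Returns ``(None, inf)`` when the rings are disconnected.
    """
    src, dst = source.key, target.key
    for key in (src, dst):
        if key not in graph.rings:
            raise KeyError(f"ring {key} not in graph")
    if src == dst:
        return [graph.ring(src)], 0.0
    g = graph.graph
    # heap entries: (distance, path-as-tuple); the tuple is both the
    # lexicographic tie-break and the reconstruction record.
    heap: list[tuple[float, tuple]] = [(0.0, (src,))]
    best: dict[tuple[int, int], tuple[float, tuple]] = {}
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node in best and (dist, path) > best[node]:
            continue
        if node == dst:
            return [graph.ring(k) for k in path], dist
        for nbr in g.neighbors(node):
            nd = dist + g.edges[node, nbr]["weight"]
            cand = (nd, path + (nbr,))
            if nbr not in best or cand < best[nbr]:
                best[nbr] = cand
                heapq.heappush(heap, cand)
    return None, float("inf")


@dataclass
class SymmetricUnit:
    """The smallest helically symmetric pathway segment.

    Canonically four rings — F1 of subunit P-1, F24, Y27, then F1 of
    subunit P — with d1 = |F1,F24|, d2 = |F24,Y27|, d3 = |Y27,F1| (Å).
    A degenerate segment (ring count != 4) is still representable; its
    ``distances`` simply lists the consecutive interaromatic distances.
    """

    rings: list[AromaticRing]
    distances: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.distances = tuple(
            interaromatic_distance(a, b) for a, b in zip(self.rings, self.rings[1:])
        )
        if any(d <= 0 for d in self.distances):
            raise StructureError("symmetric-unit distances must be positive")

    @property
    def is_canonical(self) -> bool:
        return len(self.rings) == 4

    @property
    def d1(self) -> float:
        return self.distances[0]

    @property
    def d2(self) -> float:
        return self.distances[1]

    @property
    def d3(self) -> float:
        return self.distances[2]


def extract_symmetric_unit(
    path: list[AromaticRing], subunit_p: int = DEFAULT_SUBUNIT_P
) -> SymmetricUnit:
    """Cut the pathway segment between F1 of subunits P-1 and P.

    The canonical unit holds four rings; if the segment differs (e.g. a ring
    is missing from the structure) a :class:`PathwayWarning` reports the
    actual membership and the degenerate unit is returned.
    """
    def find_f1(p: int) -> int:
        for i, r in enumerate(path):
            if r.subunit_index == p and r.residue_seq == 1:
                return i
        raise StructureError(f"path does not visit residue 1 of subunit {p}")

    start = find_f1(subunit_p - 1)
    end = find_f1(subunit_p)
    if end < start:
        start, end = end, start
    segment = path[start : end + 1]
    if len(segment) != 4:
        membership = [(r.subunit_index, r.residue_type, r.residue_seq) for r in segment]
        warnings.warn(
            f"symmetric unit has {len(segment)} rings instead of 4: {membership}",
            PathwayWarning,
            stacklevel=2,
        )
    return SymmetricUnit(segment)


def bottleneck_distance(unit: SymmetricUnit) -> float:
    """The rate-limiting step: the largest consecutive distance of the unit (Å)."""
    return max(unit.distances)


def write_pathway_report(
    path_rings: list[AromaticRing],
    unit: SymmetricUnit,
    tsv_path: str | Path,
    json_path: str | Path,
) -> None:
    """Write the pathway as TSV plus a machine-readable JSON geometry block."""
    cumulative = [0.0]
    for a, b in zip(path_rings, path_rings[1:]):
        cumulative.append(cumulative[-1] + interaromatic_distance(a, b))
    pd.DataFrame(
        {
            "subunit": [r.subunit_index for r in path_rings],
            "chain": [r.chain_id for r in path_rings],
            "residue": [f"{r.residue_type}{r.residue_seq}" for r in path_rings],
            "cumulative_length_A": cumulative,
        }
    ).to_csv(tsv_path, sep="\t", index=False)
    block = {
        "distances_A": list(unit.distances),
        "bottleneck_A": bottleneck_distance(unit),
        "canonical_four_ring_unit": unit.is_canonical,
        "unit_residues": [f"{r.residue_type}{r.residue_seq}@{r.subunit_index}" for r in unit.rings],
    }
    if unit.is_canonical:
        block.update({"d1_A": unit.d1, "d2_A": unit.d2, "d3_A": unit.d3})
    Path(json_path).write_text(json.dumps(block, indent=2) + "\n")
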
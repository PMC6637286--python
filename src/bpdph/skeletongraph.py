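"""Convert binary skeletons (2D or 3D) into a graph of vessel segments.

A skeleton voxel is a node of the dense voxel graph; voxels are linked to
all of their 8- (2D) or 26-connected (3D) skeleton neighbours.  Voxels of
degree != 2 (tips and branch points) delimit segments; chains of
degree-2 voxels between them become segment polylines.  Adjacent branch
voxels (thinning often leaves small junction clusters) are merged into a
single junction node so that a Y-bifurcation yields exactly three
segments and one branch point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["Skeleton", "SkeletonSegment", "skeleton_to_graph"]


@dataclass
class SkeletonSegment:
    """One centreline path between two tips/junctions (inclusive)."""

    points: np.ndarray          # (n, ndim) voxel coordinates along the path
    end_nodes: tuple[int, int]  # junction-graph node ids at either end

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.points)


@dataclass
class Skeleton:
    """Skeleton voxels with their connectivity and derived topology.

    ``graph`` is the condensed junction graph: nodes are tips and merged
    branch-point clusters, edges carry a ``segment`` attribute holding the
    :class:`SkeletonSegment` (parallel edges allowed, hence a MultiGraph).
    """

    nodes: np.ndarray                       # all skeleton voxel coords
    tips: np.ndarray                        # degree-1 voxel coords
    branch_points: np.ndarray               # degree >= 3 voxel coords
    segments: list[SkeletonSegment] = field(default_factory=list)
    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)


def _neighbour_offsets(ndim: int) -> list[tuple[int, ...]]:
    return [o for o in itertools.product((-1, 0, 1), repeat=ndim) if any(o)]


def skeleton_to_graph(skeleton_mask: np.ndarray, min_segment_voxels: int = 1) -> Skeleton:
    """Build the segment graph of a boolean skeleton image.

    Parameters
    ----------
    skeleton_mask:
        Boolean 2D or 3D array, nonzero where the skeleton runs.
    min_segment_voxels:
        Terminal (tip-ended) segments with fewer voxels than this are
        pruned as spurs; segments between two junctions are always kept.
    """
    mask = np.asarray(skeleton_mask, bool)
    coords = [tuple(c) for c in np.argwhere(mask)]
    coord_set = set(coords)
    offsets = _neighbour_offsets(mask.ndim)

    neigh: dict[tuple, list[tuple]] = {}
    for c in coords:
        ns = []
        for o in offsets:
            n = tuple(ci + oi for ci, oi in zip(c, o))
            if n in coord_set:
                ns.append(n)
        neigh[c] = ns

    degree = {c: len(ns) for c, ns in neigh.items()}
    tips = [c for c in coords if degree[c] == 1]
    branch_voxels = [c for c in coords if degree[c] >= 3]
    node_voxels = set(c for c in coords if degree[c] != 2)

    # Merge adjacent branch voxels into junction clusters.
    bset = set(branch_voxels)
    cluster_of: dict[tuple, int] = {}
    next_id = 0
    for c in branch_voxels:
        if c in cluster_of:
            continue
        stack = [c]
        cluster_of[c] = next_id
        while stack:
            cur = stack.pop()
            for n in neigh[cur]:
                if n in bset and n not in cluster_of:
                    cluster_of[n] = next_id
                    stack.append(n)
        next_id += 1
    for c in node_voxels:
        if c not in cluster_of:
            cluster_of[c] = next_id
            next_id += 1

    graph = nx.MultiGraph()
    for c, nid in cluster_of.items():
        if nid not in graph:
            graph.add_node(nid, voxels=[])
        graph.nodes[nid]["voxels"].append(c)

    segments: list[SkeletonSegment] = []
    visited_edges: set[frozenset] = set()

    def walk(start: tuple, first: tuple) -> list[tuple]:
        """Follow a degree-2 chain from *start* through *first*."""
        path = [start, first]
        prev, cur = start, first
        while cur not in node_voxels:
            nxts = [n for n in neigh[cur] if n != prev]
            if not nxts:
                break  # dead end inside a chain (isolated cycle remnant)
            # prefer a continuation that is not the previous voxel
            prev, cur = cur, nxts[0]
            path.append(cur)
            if len(path) > len(coords) + 1:  # safety
                break
        return path

    for c in sorted(node_voxels):
        for n in neigh[c]:
            edge_key = frozenset((c, n))
            if edge_key in visited_edges:
                continue
            if n in node_voxels:
                # direct node-node contact: either intra-cluster (skip) or
                # a 1-edge segment
                visited_edges.add(edge_key)
                if cluster_of[c] == cluster_of[n]:
                    continue
                path = [c, n]
            else:
                path = walk(c, n)
                for a, b in zip(path[:-1], path[1:]):
                    visited_edges.add(frozenset((a, b)))
                if path[-1] not in node_voxels:
                    # open chain ending without a node voxel (shouldn't
                    # normally happen); treat last voxel as endpoint
                    node_voxels.add(path[-1])
                    cluster_of.setdefault(path[-1], len(cluster_of))
            u = cluster_of[path[0]]
            v = cluster_of[path[-1]]
            if u == v and len(path) <= 3:
                continue  # tiny self-loop at a junction cluster
            seg = SkeletonSegment(points=np.asarray(path, float), end_nodes=(u, v))
            segments.append(seg)

    # Pure cycles (every voxel degree 2) have no node voxels; trace each.
    in_segment = set()
    for seg in segments:
        in_segment.update(tuple(map(int, p)) for p in seg.points)
    for c in coords:
        if degree[c] == 2 and c not in in_segment and c not in node_voxels:
            path = [c]
            prev, cur = c, neigh[c][0]
            steps = 0
            while cur != c and cur not in node_voxels and steps <= len(coords):
                path.append(cur)
                nxts = [n for n in neigh[cur] if n != prev]
                if not nxts:
                    break
                prev, cur = cur, nxts[0]
                steps += 1
            path.append(cur if cur in node_voxels else c)
            nid = next_id
            next_id += 1
            cluster_of[c] = nid
            segments.append(SkeletonSegment(points=np.asarray(path, float), end_nodes=(nid, nid)))
            in_segment.update(path)

    # Spur pruning: drop short tip-ended segments.
    tip_clusters = {cluster_of[c] for c in tips if c in cluster_of}
    kept = []
    for seg in segments:
        u, v = seg.end_nodes
        terminal = u in tip_clusters or v in tip_clusters
        if terminal and len(seg.points) < min_segment_voxels:
            continue
        kept.append(seg)
    segments = kept

    for seg in segments:
        graph.add_node(seg.end_nodes[0])
        graph.add_node(seg.end_nodes[1])
        graph.add_edge(*seg.end_nodes, segment=seg)

    return Skeleton(
        nodes=np.asarray(coords, int).reshape(-1, mask.ndim),
        tips=np.asarray(tips, int).reshape(-1, mask.ndim),
        branch_points=np.asarray(branch_voxels, int).reshape(-1, mask.ndim),
        segments=segments,
        graph=graph,
    )
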
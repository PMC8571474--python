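"""Reconstruction similarity features and morphometric descriptors.

Two families of descriptors are computed from a (gold, auto) pair of
reconstruction fragments:

* 7 node-distance features (entire-structure averages, the >2-voxel
  different-structure average, and ≥2-voxel different-structure
  percentages) plus 3 count-difference morphology features — together the
  10-vector consumed by the difficulty auto-labeler;
* a 32-element morphometric vector summarizing the automatic
  reconstruction alone (lengths, angles, orders, asymmetries, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .swc import NeuronForest, count_bifurcations

__all__ = [
    "SimilarityFeatures",
    "MORPHOMETRY_REGISTRY",
    "nearest_distances",
    "neuron_distance_features",
    "morphology_difference",
    "similarity_features",
    "lmeasure_features",
]

DIFFERENT_STRUCTURE_THRESHOLD = 2.0  # voxels


@dataclass(frozen=True)
class SimilarityFeatures:
    """10 gold-vs-auto agreement features for one block."""

    esa12: float
    esa21: float
    esa: float
    dsa2: float
    pds12: float
    pds21: float
    pds: float
    d_bifurcations: float
    d_nodes: float
    d_fragments: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.esa12,
                self.esa21,
                self.esa,
                self.dsa2,
                self.pds12,
                self.pds21,
                self.pds,
                self.d_bifurcations,
                self.d_nodes,
                self.d_fragments,
            ],
            dtype=float,
        )

    FIELDS = (
        "esa12",
        "esa21",
        "esa",
        "dsa2",
        "pds12",
        "pds21",
        "pds",
        "d_bifurcations",
        "d_nodes",
        "d_fragments",
    )


def nearest_distances(a: NeuronForest, b: NeuronForest) -> np.ndarray:
    """Per-node Euclidean distance from each node of ``a`` to its nearest
    node of ``b`` (node id order of ``a``)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("nearest_distances is undefined for an empty forest")
    tree = cKDTree(b.positions_zyx())
    dist, _ = tree.query(a.positions_zyx())
    return np.asarray(dist, dtype=float)


def neuron_distance_features(
    gold: NeuronForest, auto: NeuronForest
) -> Tuple[float, float, float, float, float, float, float]:
    """(esa12, esa21, esa, dsa2, pds12, pds21, pds).

    ``dsa2`` averages distances strictly greater than 2 voxels pooled from
    both directions (0 when no such node exists); the ``pds`` family counts
    nodes at distance ≥ 2 voxels.
    """
    d12 = nearest_distances(gold, auto)
    d21 = nearest_distances(auto, gold)
    esa12 = float(d12.mean())
    esa21 = float(d21.mean())
    esa = (esa12 + esa21) / 2.0
    pooled = np.concatenate([d12, d21])
    far = pooled[pooled > DIFFERENT_STRUCTURE_THRESHOLD]
    dsa2 = float(far.mean()) if far.size else 0.0
    c12 = int((d12 >= DIFFERENT_STRUCTURE_THRESHOLD).sum())
    c21 = int((d21 >= DIFFERENT_STRUCTURE_THRESHOLD).sum())
    pds12 = c12 / len(d12)
    pds21 = c21 / len(d21)
    pds = (c12 + c21) / (len(d12) + len(d21))
    return esa12, esa21, esa, dsa2, pds12, pds21, pds


def morphology_difference(
    gold: NeuronForest, auto: NeuronForest
) -> Tuple[int, int, int]:
    """Absolute count differences (bifurcations, nodes, fragments)."""
    return (
        abs(count_bifurcations(gold) - count_bifurcations(auto)),
        abs(gold.n_nodes - auto.n_nodes),
        abs(gold.n_fragments - auto.n_fragments),
    )


def similarity_features(gold: NeuronForest, auto: NeuronForest) -> SimilarityFeatures:
    """The full 10-vector for one (gold, auto) block pair."""
    esa12, esa21, esa, dsa2, pds12, pds21, pds = neuron_distance_features(gold, auto)
    d_bif, d_nodes, d_frag = morphology_difference(gold, auto)
    return SimilarityFeatures(
        esa12, esa21, esa, dsa2, pds12, pds21, pds, float(d_bif), float(d_nodes), float(d_frag)
    )


# ---------------------------------------------------------------------------
# morphometrics (auto-block descriptor vector)
# ---------------------------------------------------------------------------

MORPHOMETRY_REGISTRY: Tuple[str, ...] = (
    "n_stems",
    "n_bifurcations",
    "n_branches",
    "n_tips",
    "n_fragments",
    "total_branch_length",
    "mean_branch_length",
    "max_branch_length",
    "total_length",
    "width",
    "height",
    "depth",
    "mean_radius",
    "max_radius",
    "total_surface",
    "total_volume",
    "mean_euclidean_distance",
    "max_euclidean_distance",
    "mean_path_distance",
    "max_path_distance",
    "mean_contraction",
    "fragmentation",
    "mean_branch_order",
    "max_branch_order",
    "mean_partition_asymmetry",
    "mean_local_bifurcation_angle",
    "mean_remote_bifurcation_angle",
    "mean_parent_child_radius_ratio",
    "mean_daughter_ratio",
    "mean_tortuosity",
    "max_tortuosity",
    "n_terminal_segments",
)


def _mean(values: Sequence[float]) -> float:
    return float(np.mean(values)) if len(values) else 0.0


def _max(values: Sequence[float]) -> float:
    return float(np.max(values)) if len(values) else 0.0


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _branches(forest: NeuronForest) -> List[List[int]]:
    """Branch decomposition: maximal paths between critical points.

    A branch starts at a root or just below a multi-child node and runs to
    the next multi-child node or tip.  Returned as node-id paths including
    the starting critical point (for geometry) — the first id is the
    branch's attachment node.
    """
    branches: List[List[int]] = []
    for root in forest.roots:
        stack = [(root.id, None)]  # (start node, attachment id)
        while stack:
            nid, attach = stack.pop()
            path = [attach] if attach is not None else []
            cur = nid
            path.append(cur)
            while True:
                kids = forest.children(cur)
                if len(kids) == 1:
                    cur = kids[0].id
                    path.append(cur)
                else:
                    break
            branches.append(path)
            for kid in forest.children(cur):
                stack.append((kid.id, cur))
    return branches


def _subtree_tip_counts(forest: NeuronForest) -> Dict[int, int]:
    counts: Dict[int, int] = {}

    def visit(nid: int) -> int:
        kids = forest.children(nid)
        if not kids:
            counts[nid] = 1
            return 1
        total = sum(visit(k.id) for k in kids)
        counts[nid] = total
        return total

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, forest.n_nodes + 100))
    try:
        for root in forest.roots:
            visit(root.id)
    finally:
        sys.setrecursionlimit(old)
    return counts


def lmeasure_features(auto: NeuronForest) -> np.ndarray:
    """The 32 morphometrics of :data:`MORPHOMETRY_REGISTRY`, in order."""
    if len(auto) == 0:
        raise ValueError("morphometrics are undefined for an empty forest")
    pos = {n.id: n.position_zyx for n in auto}
    rad = {n.id: n.radius for n in auto}
    roots = auto.roots
    tips = [n for n in auto if not auto.children(n.id)]
    bifs = [n for n in auto if len(auto.children(n.id)) >= 2]

    edge_len: Dict[int, float] = {}
    for n in auto:
        if n.parent_id in auto:
            edge_len[n.id] = float(np.linalg.norm(pos[n.id] - pos[n.parent_id]))
    total_length = float(sum(edge_len.values()))

    # path distance from fragment root, branch order (bifurcations passed)
    path_dist: Dict[int, float] = {}
    branch_order: Dict[int, int] = {}
    frag_root: Dict[int, int] = {}
    for root in roots:
        stack = [(root.id, 0.0, 0)]
        while stack:
            nid, dist, order = stack.pop()
            path_dist[nid] = dist
            branch_order[nid] = order
            frag_root[nid] = root.id
            kids = auto.children(nid)
            bump = 1 if len(kids) >= 2 else 0
            for kid in kids:
                stack.append((kid.id, dist + edge_len[kid.id], order + bump))

    euclid = [float(np.linalg.norm(pos[n.id] - pos[frag_root[n.id]])) for n in auto]

    branches = _branches(auto)
    blens: List[float] = []
    tortuosities: List[float] = []
    contractions: List[float] = []
    terminal_segments = 0
    for path in branches:
        plen = sum(edge_len[nid] for nid in path[1:] if nid in edge_len)
        if len(path) >= 2:
            chord = float(np.linalg.norm(pos[path[-1]] - pos[path[0]]))
        else:
            chord = 0.0
        blens.append(plen)
        if plen > 0:
            contractions.append(chord / plen)
            tortuosities.append(plen / chord if chord > 0 else 1.0)
        if not auto.children(path[-1]):
            terminal_segments += 1

    # bifurcation geometry
    local_angles: List[float] = []
    remote_angles: List[float] = []
    asymmetries: List[float] = []
    daughter_ratios: List[float] = []
    tip_counts = _subtree_tip_counts(auto)
    for b in bifs:
        kids = auto.children(b.id)[:2]
        u_local = pos[kids[0].id] - pos[b.id]
        v_local = pos[kids[1].id] - pos[b.id]
        local_angles.append(_angle(u_local, v_local))
        ends = []
        for kid in kids:
            cur = kid.id
            while len(auto.children(cur)) == 1:
                cur = auto.children(cur)[0].id
            ends.append(cur)
        remote_angles.append(_angle(pos[ends[0]] - pos[b.id], pos[ends[1]] - pos[b.id]))
        nl, nr = tip_counts[kids[0].id], tip_counts[kids[1].id]
        denom = nl + nr - 2
        asymmetries.append(abs(nl - nr) / denom if denom > 0 else 0.0)
        r1, r2 = rad[kids[0].id], rad[kids[1].id]
        if min(r1, r2) > 0:
            daughter_ratios.append(max(r1, r2) / min(r1, r2))

    pc_ratios = [
        rad[n.id] / rad[n.parent_id]
        for n in auto
        if n.parent_id in auto and rad[n.parent_id] > 0
    ]

    surface = 0.0
    volume = 0.0
    for n in auto:
        if n.parent_id not in auto:
            continue
        h = edge_len[n.id]
        r1, r2 = rad[n.parent_id], rad[n.id]
        slant = math.sqrt(h * h + (r1 - r2) ** 2)
        surface += math.pi * (r1 + r2) * slant
        volume += math.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0

    coords = auto.positions_zyx()
    extent = coords.max(axis=0) - coords.min(axis=0)  # (z, y, x)

    values = {
        "n_stems": float(sum(len(auto.children(r.id)) for r in roots)),
        "n_bifurcations": float(len(bifs)),
        "n_branches": float(len(branches)),
        "n_tips": float(len(tips)),
        "n_fragments": float(auto.n_fragments),
        "total_branch_length": float(sum(blens)),
        "mean_branch_length": _mean(blens),
        "max_branch_length": _max(blens),
        "total_length": total_length,
        "width": float(extent[2]),
        "height": float(extent[1]),
        "depth": float(extent[0]),
        "mean_radius": _mean([rad[n.id] for n in auto]),
        "max_radius": _max([rad[n.id] for n in auto]),
        "total_surface": surface,
        "total_volume": volume,
        "mean_euclidean_distance": _mean(euclid),
        "max_euclidean_distance": _max(euclid),
        "mean_path_distance": _mean(list(path_dist.values())),
        "max_path_distance": _max(list(path_dist.values())),
        "mean_contraction": _mean(contractions),
        "fragmentation": float(auto.n_nodes),
        "mean_branch_order": _mean(list(branch_order.values())),
        "max_branch_order": _max(list(branch_order.values())),
        "mean_partition_asymmetry": _mean(asymmetries),
        "mean_local_bifurcation_angle": _mean(local_angles),
        "mean_remote_bifurcation_angle": _mean(remote_angles),
        "mean_parent_child_radius_ratio": _mean(pc_ratios),
        "mean_daughter_ratio": _mean(daughter_ratios),
        "mean_tortuosity": _mean(tortuosities),
        "max_tortuosity": _max(tortuosities),
        "n_terminal_segments": float(terminal_segments),
    }
    vec = np.array([values[name] for name in MORPHOMETRY_REGISTRY], dtype=float)
    if not np.all(np.isfinite(vec)):  # pragma: no cover - defensive
        raise ValueError("non-finite morphometric value")
    return vec
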
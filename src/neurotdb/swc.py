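"""SWC reading/writing and tree algorithms.

A neuron reconstruction is modelled as a *forest*: a set of nodes with
parent links, possibly split into several connected fragments (e.g. after
cropping to a sub-volume).  Coordinates follow the SWC column order
``x y z`` on disk; array-facing helpers convert to the volume axis order
``(z, y, x)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np

__all__ = [
    "SwcNode",
    "NeuronForest",
    "BoundingBox",
    "SwcParseError",
    "SwcIntegrityError",
    "read_swc",
    "parse_swc",
    "write_swc",
    "count_bifurcations",
    "crop_to_box",
    "traversal_order",
]

SOMA_TYPE = 1
ROOT_PARENT = -1


class SwcParseError(ValueError):
    """A data line of an SWC file could not be parsed."""


class SwcIntegrityError(ValueError):
    """Parent links or node ids violate forest invariants."""


@dataclass(frozen=True)
class SwcNode:
    """One SWC record: ``id type x y z radius parent``."""

    id: int
    structure_type: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def position(self) -> np.ndarray:
        """Position in SWC column order ``(x, y, z)``."""
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def position_zyx(self) -> np.ndarray:
        """Position in volume axis order ``(z, y, x)``."""
        return np.array([self.z, self.y, self.x], dtype=float)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned box in volume coordinates ``(z, y, x)``."""

    min_corner: Tuple[float, float, float]
    max_corner: Tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_corner, dtype=float)
        hi = np.asarray(self.max_corner, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("corners must be 3-vectors")
        if not np.all(lo < hi):
            raise ValueError(f"degenerate box: {self.min_corner} !< {self.max_corner}")

    def contains(self, zyx: Sequence[float]) -> bool:
        p = np.asarray(zyx, dtype=float)
        lo = np.asarray(self.min_corner, dtype=float)
        hi = np.asarray(self.max_corner, dtype=float)
        return bool(np.all(p >= lo) and np.all(p < hi))

    @property
    def shape(self) -> Tuple[float, float, float]:
        lo = np.asarray(self.min_corner, dtype=float)
        hi = np.asarray(self.max_corner, dtype=float)
        return tuple(hi - lo)


class NeuronForest:
    """A set of SWC nodes with parent links; supports several fragments.

    Nodes whose ``parent_id`` is −1, or whose parent is not part of the
    forest, are roots.  Cycles are rejected at construction.
    """

    def __init__(self, nodes: Iterable[SwcNode] = ()):
        self._nodes: Dict[int, SwcNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise SwcIntegrityError(f"duplicate node id {node.id}")
            if node.id <= 0:
                raise SwcIntegrityError(f"node id must be positive, got {node.id}")
            self._nodes[node.id] = node
        self._children: Dict[int, List[int]] = {nid: [] for nid in self._nodes}
        for node in self._nodes.values():
            if node.parent_id != ROOT_PARENT and node.parent_id in self._nodes:
                self._children[node.parent_id].append(node.id)
        for kids in self._children.values():
            kids.sort()
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: Dict[int, int] = {}  # 0=visiting, 1=done
        for start in self._nodes:
            chain = []
            nid = start
            while nid in self._nodes and state.get(nid) is None:
                state[nid] = 0
                chain.append(nid)
                nid = self._nodes[nid].parent_id
            if nid in self._nodes and state.get(nid) == 0:
                raise SwcIntegrityError(f"cycle through node {nid}")
            for c in chain:
                state[c] = 1

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[SwcNode]:
        return iter(sorted(self._nodes.values(), key=lambda n: n.id))

    def __contains__(self, nid: int) -> bool:
        return nid in self._nodes

    def __getitem__(self, nid: int) -> SwcNode:
        return self._nodes[nid]

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def children(self, nid: int) -> List[SwcNode]:
        """Children of a node, in ascending id order."""
        return [self._nodes[c] for c in self._children[nid]]

    @property
    def roots(self) -> List[SwcNode]:
        out = [
            n
            for n in self._nodes.values()
            if n.parent_id == ROOT_PARENT or n.parent_id not in self._nodes
        ]
        return sorted(out, key=lambda n: n.id)

    def soma_root(self) -> SwcNode:
        """The root used for anchoring: a soma-typed root if present, else
        the unique root, else the smallest-id root."""
        roots = self.roots
        if not roots:
            raise SwcIntegrityError("empty forest has no root")
        soma = [r for r in roots if r.structure_type == SOMA_TYPE]
        if soma:
            return soma[0]
        return roots[0]

    def fragments(self) -> List["NeuronForest"]:
        """Connected components of the parent graph, as sub-forests."""
        comp = self._component_labels()
        by_label: Dict[int, List[SwcNode]] = {}
        for nid, label in comp.items():
            by_label.setdefault(label, []).append(self._nodes[nid])
        return [NeuronForest(v) for _, v in sorted(by_label.items())]

    @property
    def n_fragments(self) -> int:
        comp = self._component_labels()
        return len(set(comp.values()))

    def _component_labels(self) -> Dict[int, int]:
        # union-find over parent edges
        parent: Dict[int, int] = {nid: nid for nid in self._nodes}

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for node in self._nodes.values():
            if node.parent_id in self._nodes:
                ra, rb = find(node.id), find(node.parent_id)
                if ra != rb:
                    parent[ra] = rb
        return {nid: find(nid) for nid in self._nodes}

    def positions_zyx(self) -> np.ndarray:
        """(n, 3) array of node positions in ``(z, y, x)`` order (id order)."""
        if not self._nodes:
            return np.zeros((0, 3), dtype=float)
        return np.array([n.position_zyx for n in self], dtype=float)

    def translated(self, offset_zyx: Sequence[float]) -> "NeuronForest":
        dz, dy, dx = (float(v) for v in offset_zyx)
        return NeuronForest(
            replace(n, x=n.x + dx, y=n.y + dy, z=n.z + dz) for n in self._nodes.values()
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"NeuronForest(n_nodes={self.n_nodes}, n_fragments={self.n_fragments})"


def parse_swc(text: str, source: str = "<string>") -> NeuronForest:
    """Parse SWC text into a :class:`NeuronForest`.

    Raises :class:`SwcParseError` naming the offending line, and
    :class:`SwcIntegrityError` if a parent id references an absent node.
    """
    nodes: List[SwcNode] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SwcParseError(
                f"{source}:{lineno}: expected 7 fields, got {len(fields)}"
            )
        try:
            node = SwcNode(
                id=int(fields[0]),
                structure_type=int(fields[1]),
                x=float(fields[2]),
                y=float(fields[3]),
                z=float(fields[4]),
                radius=float(fields[5]),
                parent_id=int(fields[6]),
            )
        except ValueError as exc:
            raise SwcParseError(f"{source}:{lineno}: {exc}") from exc
        nodes.append(node)
    ids = {n.id for n in nodes}
    for n in nodes:
        if n.parent_id != ROOT_PARENT and n.parent_id not in ids:
            raise SwcIntegrityError(
                f"{source}: node {n.id} references absent parent {n.parent_id}"
            )
    return NeuronForest(nodes)


def read_swc(path) -> NeuronForest:
    """Read an SWC file from disk."""
    path = Path(path)
    return parse_swc(path.read_text(), source=str(path))


def write_swc(forest: NeuronForest, path) -> None:
    """Write a forest to SWC; round-trips topology and coordinates to 1e-6."""
    buf = io.StringIO()
    buf.write("# id type x y z radius parent\n")
    for node in forest:
        parent = node.parent_id if node.parent_id in forest else ROOT_PARENT
        buf.write(
            f"{node.id} {node.structure_type} {node.x:.6f} {node.y:.6f} "
            f"{node.z:.6f} {node.radius:.6f} {parent}\n"
        )
    Path(path).write_text(buf.getvalue())


def count_bifurcations(forest: NeuronForest) -> int:
    """Number of nodes with at least two children."""
    return sum(1 for node in forest if len(forest.children(node.id)) >= 2)


def crop_to_box(forest: NeuronForest, box: BoundingBox) -> NeuronForest:
    """Keep exactly the nodes inside ``box`` (half-open, (z,y,x) frame).

    Edges crossing the boundary are severed, creating new roots, and
    coordinates are re-expressed relative to ``box.min_corner``.
    """
    inside = {n.id for n in forest if box.contains(n.position_zyx)}
    zmin, ymin, xmin = (float(v) for v in box.min_corner)
    kept = []
    for node in forest:
        if node.id not in inside:
            continue
        parent = node.parent_id if node.parent_id in inside else ROOT_PARENT
        kept.append(
            replace(node, x=node.x - xmin, y=node.y - ymin, z=node.z - zmin, parent_id=parent)
        )
    return NeuronForest(kept)


def traversal_order(forest: NeuronForest, root: SwcNode) -> List[SwcNode]:
    """Depth-first preorder from ``root``; children in ascending id order."""
    if root.id not in forest:
        raise KeyError(f"root id {root.id} not in forest")
    out: List[SwcNode] = []
    stack = [root.id]
    seen = set()
    while stack:
        nid = stack.pop()
        if nid in seen:
            raise SwcIntegrityError(f"node {nid} reached twice in traversal")
        seen.add(nid)
        out.append(forest[nid])
        # push in reverse so the smallest id is visited first
        for child in reversed(forest.children(nid)):
            stack.append(child.id)
    return out
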
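"""Block adjacency and fixed-length block sequences.

Two blocks of one neuron are adjacent when their anchors are at most 100
voxels apart in space *and* exactly 100 nodes apart along the gold-tree
traversal.  Sequences are contiguous windows over maximal adjacency runs;
the prediction target of a window is its last block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .blocks import Block

__all__ = [
    "BlockSequence",
    "are_adjacent",
    "build_sequences",
    "same_label_fraction",
    "ANCHOR_DISTANCE_LIMIT",
]

ANCHOR_DISTANCE_LIMIT = 100.0  # voxels
ORDER_INDEX_STEP = 100  # nodes


@dataclass
class BlockSequence:
    blocks: List[Block]

    def __post_init__(self) -> None:
        if not 1 <= len(self.blocks) <= 5:
            raise ValueError(f"sequence length must be in [1,5], got {len(self.blocks)}")
        neuron_ids = {b.neuron_id for b in self.blocks}
        if len(neuron_ids) != 1:
            raise ValueError("all blocks of a sequence must share neuron_id")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if not are_adjacent(a, b):
                raise ValueError("consecutive blocks are not adjacent")

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def target(self) -> Block:
        """The block the sequence is classified for."""
        return self.blocks[-1]

    @property
    def labels(self) -> List[str]:
        out = []
        for b in self.blocks:
            if b.label is None:
                raise ValueError("sequence contains an unlabeled block")
            out.append(b.label)
        return out


def are_adjacent(a: Block, b: Block, step: int = ORDER_INDEX_STEP) -> bool:
    """Spatial (≤100 voxels) and traversal (exactly ``step`` nodes) adjacency."""
    if a.neuron_id != b.neuron_id:
        return False
    if abs(a.anchor_order_index - b.anchor_order_index) != step:
        return False
    dist = float(np.linalg.norm(np.asarray(a.anchor, float) - np.asarray(b.anchor, float)))
    return dist <= ANCHOR_DISTANCE_LIMIT


def build_sequences(blocks: Sequence[Block], s: int) -> List[BlockSequence]:
    """All contiguous windows of length ``s`` over adjacency runs.

    Blocks are chained along increasing anchor order index within each
    neuron; at a branch point each order-index successor opens its own
    path, so one window per successor path is produced.
    """
    if s < 1:
        raise ValueError(f"sequence length must be >= 1, got {s}")
    if s == 1:
        return [BlockSequence([b]) for b in blocks]
    by_neuron: Dict[str, List[Block]] = {}
    for b in blocks:
        by_neuron.setdefault(b.neuron_id, []).append(b)
    sequences: List[BlockSequence] = []
    for neuron_blocks in by_neuron.values():
        by_order: Dict[int, List[Block]] = {}
        for b in neuron_blocks:
            by_order.setdefault(b.anchor_order_index, []).append(b)
        successors: Dict[int, List[Block]] = {}
        for a in neuron_blocks:
            successors[id(a)] = [
                b
                for b in by_order.get(a.anchor_order_index + ORDER_INDEX_STEP, [])
                if are_adjacent(a, b)
            ]
        # enumerate every adjacency path of length s by DFS from each block
        ordered = sorted(neuron_blocks, key=lambda b: (b.anchor_order_index, b.block_index))
        for start in ordered:
            stack = [[start]]
            while stack:
                path = stack.pop()
                if len(path) == s:
                    sequences.append(BlockSequence(path))
                    continue
                for nxt in successors[id(path[-1])]:
                    stack.append(path + [nxt])
    return sequences


def same_label_fraction(sequences: Sequence[BlockSequence]) -> float:
    """Fraction of length-2 sequences whose two labels agree."""
    if not sequences:
        raise ValueError("no sequences given")
    agree = 0
    for seq in sequences:
        if len(seq) != 2:
            raise ValueError("same_label_fraction expects length-2 sequences")
        labels = seq.labels
        agree += labels[0] == labels[1]
    return agree / len(sequences)
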
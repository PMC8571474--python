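"""Partition neuron volumes into overlapped blocks along the gold tree.

Blocks are anchored every ``anchor_step`` nodes of the gold reconstruction's
preorder traversal; each block carries a 32×64×64 image crop plus the gold
and (burr-pruned) automatic reconstruction fragments falling inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .swc import (
    BoundingBox,
    NeuronForest,
    SwcNode,
    crop_to_box,
    read_swc,
    traversal_order,
    write_swc,
)

__all__ = [
    "ImageVolume",
    "Block",
    "BlockConfig",
    "select_anchors",
    "extract_image_block",
    "prune_burrs",
    "passes_node_filter",
    "build_blocks",
    "save_corpus",
    "load_corpus",
    "load_volume",
]

DEFAULT_BLOCK_SIZE = (32, 64, 64)


@dataclass
class ImageVolume:
    """3D non-negative intensity array, axis order (z, y, x)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class Block:
    """One classification sample."""

    anchor: Tuple[int, int, int]  # voxel coordinate (z, y, x) in the volume frame
    image: np.ndarray  # exactly block_size, default (32, 64, 64)
    gold: NeuronForest  # block-local coordinates
    auto: NeuronForest  # block-local, burr-pruned
    neuron_id: str
    anchor_order_index: int
    label: Optional[str] = None  # "low" | "high" | None
    block_index: int = 0

    def __post_init__(self) -> None:
        if self.label not in (None, "low", "high"):
            raise ValueError(f"invalid label {self.label!r}")


@dataclass
class BlockConfig:
    block_size: Tuple[int, int, int] = DEFAULT_BLOCK_SIZE
    anchor_step: int = 100
    min_branch_nodes: int = 4
    min_fragment_nodes: int = 4
    edge_margin: float = 4.0
    min_total_nodes: int = 11


def select_anchors(gold: NeuronForest, step: int = 100) -> List[SwcNode]:
    """Every ``step``-th node of the preorder traversal from the soma root."""
    if step < 1:
        raise ValueError(f"step must be positive, got {step}")
    if len(gold) == 0:
        raise ValueError("cannot select anchors from an empty forest")
    order = traversal_order(gold, gold.soma_root())
    return [order[i] for i in range(0, len(order), step)]


def extract_image_block(
    volume: ImageVolume,
    anchor: Sequence[float],
    size: Tuple[int, int, int] = DEFAULT_BLOCK_SIZE,
) -> np.ndarray:
    """Sub-volume of shape ``size`` with the anchor at index floor(size/2).

    Regions falling outside the volume are zero-padded.
    """
    anchor_vox = np.floor(np.asarray(anchor, dtype=float)).astype(int)
    shape = np.asarray(volume.shape)
    if np.any(anchor_vox < 0) or np.any(anchor_vox >= shape):
        raise IndexError(f"anchor {tuple(anchor)} outside volume of shape {volume.shape}")
    size_arr = np.asarray(size, dtype=int)
    lo = anchor_vox - size_arr // 2
    hi = lo + size_arr
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, shape)
    out = np.zeros(tuple(size_arr), dtype=volume.data.dtype)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    out[dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]] = volume.data[
        src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]
    ]
    return out


def _edge_distance(forest: NeuronForest, block_size: Sequence[int]) -> float:
    """Minimum distance of any node to any of the six block faces."""
    pos = forest.positions_zyx()
    size = np.asarray(block_size, dtype=float)
    dist = np.minimum(pos, size - 1.0 - pos)
    return float(dist.min())


def _delete_short_terminal_branches(forest: NeuronForest, min_nodes: int) -> NeuronForest:
    """Iteratively remove terminal branches (bifurcation→tip, bifurcation
    excluded) shorter than ``min_nodes``."""
    while True:
        doomed: set = set()
        tips = [n for n in forest if not forest.children(n.id)]
        for tip in tips:
            branch = [tip.id]
            node = tip
            while True:
                pid = node.parent_id
                if pid not in forest:
                    branch = None  # reached a root: unbranched path, not a burr
                    break
                parent = forest[pid]
                if len(forest.children(pid)) >= 2:
                    break  # pid is the bifurcation; branch is complete
                branch.append(pid)
                node = parent
            if branch is not None and len(branch) < min_nodes:
                doomed.update(branch)
        if not doomed:
            return forest
        forest = NeuronForest(n for n in forest if n.id not in doomed)


def prune_burrs(
    auto_block: NeuronForest,
    min_branch_nodes: int = 4,
    min_fragment_nodes: int = 4,
    edge_margin: float = 4.0,
    block_size: Sequence[int] = DEFAULT_BLOCK_SIZE,
) -> NeuronForest:
    """Remove burrs from an automatic reconstruction block.

    (a) terminal branches with fewer than ``min_branch_nodes`` nodes are
    deleted, repeatedly until stable; (b) whole fragments with fewer than
    ``min_fragment_nodes`` nodes whose closest node lies within
    ``edge_margin`` voxels of a block face are deleted.
    """
    pruned = _delete_short_terminal_branches(auto_block, min_branch_nodes)
    survivors: List[SwcNode] = []
    for fragment in pruned.fragments():
        small = fragment.n_nodes < min_fragment_nodes
        near_edge = _edge_distance(fragment, block_size) < edge_margin
        if small and near_edge:
            continue
        survivors.extend(iter(fragment))
    # fragment() relabels parents already; rebuild on original node records
    keep_ids = {n.id for n in survivors}
    return NeuronForest(n for n in pruned if n.id in keep_ids)


def passes_node_filter(auto_block: NeuronForest, min_total_nodes: int = 11) -> bool:
    """True iff the pruned auto block keeps at least ``min_total_nodes`` nodes."""
    return auto_block.n_nodes >= min_total_nodes


def build_blocks(
    volume: ImageVolume,
    gold: NeuronForest,
    auto: NeuronForest,
    config: BlockConfig = BlockConfig(),
    neuron_id: str = "neuron",
) -> List[Block]:
    """Construct all retained blocks for one neuron."""
    anchors = select_anchors(gold, config.anchor_step)
    size = np.asarray(config.block_size, dtype=int)
    blocks: List[Block] = []
    for i, anchor_node in enumerate(anchors):
        anchor_vox = np.floor(anchor_node.position_zyx).astype(int)
        shape = np.asarray(volume.shape)
        if np.any(anchor_vox < 0) or np.any(anchor_vox >= shape):
            continue  # anchor drifted outside the imaged volume
        lo = anchor_vox - size // 2
        box = BoundingBox(tuple(lo.astype(float)), tuple((lo + size).astype(float)))
        gold_block = crop_to_box(gold, box)
        auto_block = prune_burrs(
            crop_to_box(auto, box),
            min_branch_nodes=config.min_branch_nodes,
            min_fragment_nodes=config.min_fragment_nodes,
            edge_margin=config.edge_margin,
            block_size=config.block_size,
        )
        if not passes_node_filter(auto_block, config.min_total_nodes):
            continue
        blocks.append(
            Block(
                anchor=tuple(int(v) for v in anchor_vox),
                image=extract_image_block(volume, anchor_vox, tuple(size)),
                gold=gold_block,
                auto=auto_block,
                neuron_id=neuron_id,
                anchor_order_index=i * config.anchor_step,
                block_index=len(blocks),
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# corpus I/O
# ---------------------------------------------------------------------------

def save_corpus(blocks: List[Block], out_dir) -> Path:
    """Write blocks as per-neuron directories plus a manifest CSV.

    Layout: ``<out_dir>/<neuron_id>/block_<k>.npy|gold_<k>.swc|auto_<k>.swc``
    and ``<out_dir>/manifest.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for blk in blocks:
        ndir = out_dir / blk.neuron_id
        ndir.mkdir(exist_ok=True)
        np.save(ndir / f"block_{blk.block_index}.npy", blk.image)
        write_swc(blk.gold, ndir / f"gold_{blk.block_index}.swc")
        write_swc(blk.auto, ndir / f"auto_{blk.block_index}.swc")
        rows.append(
            {
                "neuron_id": blk.neuron_id,
                "block_index": blk.block_index,
                "anchor_z": blk.anchor[0],
                "anchor_y": blk.anchor[1],
                "anchor_x": blk.anchor[2],
                "anchor_order_index": blk.anchor_order_index,
                "label": blk.label if blk.label is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def load_corpus(corpus_dir) -> List[Block]:
    corpus_dir = Path(corpus_dir)
    manifest = pd.read_csv(corpus_dir / "manifest.csv", keep_default_na=False)
    blocks = []
    for row in manifest.itertuples(index=False):
        ndir = corpus_dir / str(row.neuron_id)
        blocks.append(
            Block(
                anchor=(int(row.anchor_z), int(row.anchor_y), int(row.anchor_x)),
                image=np.load(ndir / f"block_{row.block_index}.npy"),
                gold=read_swc(ndir / f"gold_{row.block_index}.swc"),
                auto=read_swc(ndir / f"auto_{row.block_index}.swc"),
                neuron_id=str(row.neuron_id),
                anchor_order_index=int(row.anchor_order_index),
                label=str(row.label) if str(row.label) in ("low", "high") else None,
                block_index=int(row.block_index),
            )
        )
    return blocks


def load_volume(path) -> ImageVolume:
    """Load a 3D volume from a TIFF stack or a raw ``.npy`` array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return ImageVolume(tifffile.imread(path))
    if path.suffix.lower() == ".npy":
        return ImageVolume(np.load(path))
    raise ValueError(f"unsupported volume format: {path.suffix}")
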
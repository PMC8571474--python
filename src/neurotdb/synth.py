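"""Seed-reproducible synthetic corpora: neuron trees, rendered noisy
volumes, and fidelity-controlled automatic reconstructions.

Difficulty is defined *generatively*: a two-state Markov chain along each
neuron's anchor order selects a per-region perturbation regime (and signal
strength), so the low/high label of every block is known by construction
and is not derived from the features any model later consumes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .blocks import Block, BlockConfig, ImageVolume, build_blocks
from .swc import NeuronForest, SwcNode, traversal_order

__all__ = [
    "SynthConfig",
    "NeuronArtifacts",
    "simulate_neuron_tree",
    "render_volume",
    "perturb_to_auto",
    "generate_neuron",
    "generate_labeled_corpus",
    "corpus_manifest",
    "manifest_hash",
]


@dataclass
class SynthConfig:
    seed: int = 0
    n_neurons: int = 8
    volume_shape: Tuple[int, int, int] = (128, 256, 256)  # (z, y, x)

    # tree growth
    nodes_per_neuron: int = 2500
    step_length: float = 1.0
    angular_jitter_std: float = 0.05  # radians per step
    branch_probability: float = 0.015  # per trunk node
    branch_length_range: Tuple[int, int] = (6, 20)
    max_depth: int = 2
    node_radius: float = 1.0

    # rendering
    tube_radius: float = 1.6
    foreground_intensity: float = 200.0
    background_mean: float = 20.0
    noise_std: float = 10.0
    distractors_per_high_window: float = 1.5
    distractor_length: int = 25
    weak_signal_factor: float = 0.45  # foreground scale inside high-difficulty regions

    # perturbation regimes (auto-reconstruction fidelity)
    low_jitter_std: float = 0.3
    high_jitter_std: float = 2.0
    branch_drop_probability: float = 0.6  # per high-region side-branch root
    max_droppable_subtree: int = 40  # only side subtrees this small may vanish
    gap_probability: float = 0.02  # per high-region node: start an untraced gap
    gap_length_range: Tuple[int, int] = (8, 25)
    spurious_branch_rate: float = 0.02  # per high-region node
    spurious_branch_length: Tuple[int, int] = (4, 9)

    # difficulty process along the anchor order
    label_persistence: float = 0.6  # P(next label == current label)
    anchor_step: int = 100

    def __post_init__(self) -> None:
        for name in ("branch_probability", "branch_drop_probability", "label_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.nodes_per_neuron < 1:
            raise ValueError("nodes_per_neuron must be positive")
        if min(self.volume_shape) < 8:
            raise ValueError("volume too small")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _jittered_direction(direction: np.ndarray, std: float, rng: np.random.Generator) -> np.ndarray:
    return _unit(direction + rng.normal(0.0, std, 3))


def simulate_neuron_tree(cfg: SynthConfig, rng: np.random.Generator) -> NeuronForest:
    """Grow a single-rooted tree by a bounded random walk.

    The trunk advances one ``step_length`` per node with angular jitter and
    reflects off the volume boundary; side branches spawn with
    ``branch_probability`` per trunk node, up to ``max_depth`` levels.
    """
    if cfg.nodes_per_neuron < 2:
        raise ValueError("degenerate config: need at least 2 nodes")
    shape = np.asarray(cfg.volume_shape, dtype=float)
    margin = 4.0
    pos = shape / 2.0 + rng.normal(0.0, 2.0, 3)
    direction = _unit(rng.normal(0.0, 1.0, 3))
    nodes: List[SwcNode] = [
        SwcNode(1, 1, pos[2], pos[1], pos[0], cfg.node_radius, -1)
    ]
    budget = cfg.nodes_per_neuron - 1

    def step_from(p: np.ndarray, d: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        d = _jittered_direction(d, cfg.angular_jitter_std, rng)
        q = p + cfg.step_length * d
        for ax in range(3):
            if q[ax] < margin:
                q[ax] = 2 * margin - q[ax]
                d[ax] = abs(d[ax])
            elif q[ax] > shape[ax] - margin:
                q[ax] = 2 * (shape[ax] - margin) - q[ax]
                d[ax] = -abs(d[ax])
        return q, _unit(d)

    def grow_branch(parent_id: int, p: np.ndarray, d: np.ndarray, length: int, depth: int) -> None:
        nonlocal budget
        for _ in range(length):
            if budget <= 0:
                return
            p, d = step_from(p, d)
            nid = len(nodes) + 1
            nodes.append(SwcNode(nid, 3, p[2], p[1], p[0], cfg.node_radius, parent_id))
            budget -= 1
            parent_id = nid
            if depth < cfg.max_depth and rng.random() < cfg.branch_probability:
                blen = int(rng.integers(*cfg.branch_length_range))
                grow_branch(parent_id, p.copy(), _unit(rng.normal(0.0, 1.0, 3)), blen, depth + 1)

    cur_id = 1
    while budget > 0:
        pos, direction = step_from(pos, direction)
        nid = len(nodes) + 1
        nodes.append(SwcNode(nid, 3, pos[2], pos[1], pos[0], cfg.node_radius, cur_id))
        budget -= 1
        cur_id = nid
        if budget > 0 and rng.random() < cfg.branch_probability:
            blen = int(rng.integers(*cfg.branch_length_range))
            grow_branch(cur_id, pos.copy(), _unit(rng.normal(0.0, 1.0, 3)), blen, 1)
    return NeuronForest(nodes)


def _stamp_segment(
    data: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    radius: float,
    intensity: float,
) -> None:
    """Rasterize one capsule (both endpoints in (z,y,x))."""
    shape = np.asarray(data.shape)
    length = float(np.linalg.norm(p1 - p0))
    n_samples = max(2, int(np.ceil(length / 0.5)) + 1)
    r_int = int(np.ceil(radius))
    offsets = np.stack(
        np.meshgrid(*([np.arange(-r_int, r_int + 1)] * 3), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    offsets = offsets[np.linalg.norm(offsets, axis=1) <= radius + 1e-9]
    for t in np.linspace(0.0, 1.0, n_samples):
        center = np.round(p0 + t * (p1 - p0)).astype(int)
        vox = center + offsets
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[ok]
        cur = data[vox[:, 0], vox[:, 1], vox[:, 2]]
        data[vox[:, 0], vox[:, 1], vox[:, 2]] = np.maximum(cur, intensity)


def render_volume(
    tree: NeuronForest,
    cfg: SynthConfig,
    rng: np.random.Generator,
    node_intensity: Optional[Dict[int, float]] = None,
    distractor_centers: Sequence[np.ndarray] = (),
) -> ImageVolume:
    """Tube rasterization over a noisy background.

    ``node_intensity`` optionally scales the foreground per node (weak
    signals inside high-difficulty regions); ``distractor_centers`` adds
    independent straight tube segments absent from any reconstruction.
    """
    shape = np.asarray(cfg.volume_shape)
    pos = {n.id: n.position_zyx for n in tree}
    for p in pos.values():
        if np.any(p < 0) or np.any(p >= shape):
            raise ValueError("tree extends outside the volume")
    signal = np.zeros(cfg.volume_shape, dtype=np.float32)
    for node in tree:
        if node.parent_id not in tree:
            continue
        scale = 1.0
        if node_intensity is not None:
            scale = node_intensity.get(node.id, 1.0)
        _stamp_segment(
            signal,
            pos[node.parent_id],
            pos[node.id],
            cfg.tube_radius,
            cfg.foreground_intensity * scale,
        )
    for center in distractor_centers:
        direction = _unit(rng.normal(0.0, 1.0, 3))
        half = 0.5 * cfg.distractor_length * direction
        p0 = np.clip(center - half, 0, shape - 1)
        p1 = np.clip(center + half, 0, shape - 1)
        _stamp_segment(signal, p0, p1, cfg.tube_radius, cfg.foreground_intensity)
    noise = rng.normal(cfg.background_mean, cfg.noise_std, cfg.volume_shape)
    data = np.maximum(signal, 0.0) + np.clip(noise, 0.0, None).astype(np.float32)
    return ImageVolume(data.astype(np.float32))


def _perturb_nodes(
    gold: NeuronForest,
    node_labels: Dict[int, str],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> NeuronForest:
    """Jitter/drop/augment per node regime; returns the auto reconstruction."""
    shape = np.asarray(cfg.volume_shape, dtype=float)
    dropped: set = set()

    def subtree(nid: int) -> List[int]:
        out, stack = [], [nid]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(k.id for k in gold.children(cur))
        return out

    # small side subtrees at high-region bifurcations go untraced
    for node in gold:
        if node.parent_id in gold and len(gold.children(node.parent_id)) >= 2:
            if node_labels.get(node.id) == "high" and rng.random() < cfg.branch_drop_probability:
                sub = subtree(node.id)
                if len(sub) <= cfg.max_droppable_subtree:
                    dropped.update(sub)

    # contiguous untraced gaps along the traversal inside high regions
    for root in gold.roots:
        order = traversal_order(gold, root)
        i = 0
        while i < len(order):
            node = order[i]
            if (
                node_labels.get(node.id) == "high"
                and node.id not in dropped
                and rng.random() < cfg.gap_probability
            ):
                length = int(rng.integers(*cfg.gap_length_range))
                for cut in order[i : i + length]:
                    dropped.add(cut.id)
                i += length
            else:
                i += 1
    out: List[SwcNode] = []
    for node in gold:
        if node.id in dropped:
            continue
        std = cfg.high_jitter_std if node_labels.get(node.id) == "high" else cfg.low_jitter_std
        p = node.position_zyx + rng.normal(0.0, std, 3)
        p = np.clip(p, 0.0, shape - 1e-3)
        parent = node.parent_id if node.parent_id not in dropped else -1
        out.append(replace(node, z=p[0], y=p[1], x=p[2], parent_id=parent))
    # spurious short branches in high regions
    next_id = (max(n.id for n in gold) + 1) if len(gold) else 1
    high_nodes = [n for n in out if node_labels.get(n.id) == "high"]
    n_spurious = rng.binomial(len(high_nodes), cfg.spurious_branch_rate) if high_nodes else 0
    for _ in range(n_spurious):
        host = high_nodes[int(rng.integers(len(high_nodes)))]
        length = int(rng.integers(*cfg.spurious_branch_length))
        direction = _unit(rng.normal(0.0, 1.0, 3))
        p = host.position_zyx.astype(float)
        parent = host.id
        for _ in range(length):
            p = np.clip(p + direction + rng.normal(0.0, 0.4, 3), 0.0, shape - 1e-3)
            out.append(SwcNode(next_id, 3, p[2], p[1], p[0], cfg.node_radius, parent))
            parent = next_id
            next_id += 1
    return NeuronForest(out)


def perturb_to_auto(
    gold: NeuronForest,
    difficulty: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> NeuronForest:
    """Uniform-regime perturbation: the whole tree is low or high."""
    if difficulty not in ("low", "high"):
        raise ValueError(f"difficulty must be 'low' or 'high', got {difficulty!r}")
    labels = {n.id: difficulty for n in gold}
    return _perturb_nodes(gold, labels, cfg, rng)


def _anchor_labels(n_anchors: int, cfg: SynthConfig, rng: np.random.Generator) -> List[str]:
    """Two-state Markov chain with symmetric persistence."""
    labels = ["low" if rng.random() < 0.5 else "high"]
    for _ in range(n_anchors - 1):
        if rng.random() < cfg.label_persistence:
            labels.append(labels[-1])
        else:
            labels.append("high" if labels[-1] == "low" else "low")
    return labels


@dataclass
class NeuronArtifacts:
    """Everything generated for one synthetic neuron."""

    neuron_id: str
    gold: NeuronForest
    auto: NeuronForest
    volume: ImageVolume
    anchor_labels: List[str]
    blocks: List[Block]


def generate_neuron(
    cfg: SynthConfig,
    rng: np.random.Generator,
    neuron_id: str,
    block_config: Optional[BlockConfig] = None,
) -> NeuronArtifacts:
    """simulate → perturb → render → build blocks for one neuron."""
    block_config = block_config or BlockConfig(anchor_step=cfg.anchor_step)
    tree = simulate_neuron_tree(cfg, rng)
    order = traversal_order(tree, tree.soma_root())
    n_anchors = (len(order) + cfg.anchor_step - 1) // cfg.anchor_step
    anchor_labels = _anchor_labels(n_anchors, cfg, rng)
    half = cfg.anchor_step // 2
    node_labels: Dict[int, str] = {}
    for i, node in enumerate(order):
        # label region centered on the nearest anchor, matching the block
        node_labels[node.id] = anchor_labels[min((i + half) // cfg.anchor_step, n_anchors - 1)]
    auto = _perturb_nodes(tree, node_labels, cfg, rng)
    intensity = {
        nid: (cfg.weak_signal_factor if lab == "high" else 1.0)
        for nid, lab in node_labels.items()
    }
    distractors = []
    for i, lab in enumerate(anchor_labels):
        if lab != "high":
            continue
        n_extra = rng.poisson(cfg.distractors_per_high_window)
        lo = max(0, i * cfg.anchor_step - half)
        window_nodes = order[lo : i * cfg.anchor_step + half]
        for _ in range(n_extra):
            host = window_nodes[int(rng.integers(len(window_nodes)))]
            distractors.append(host.position_zyx + rng.normal(0.0, 6.0, 3))
    volume = render_volume(
        tree, cfg, rng, node_intensity=intensity, distractor_centers=distractors
    )
    blocks = build_blocks(volume, tree, auto, block_config, neuron_id=neuron_id)
    for blk in blocks:
        blk.label = anchor_labels[blk.anchor_order_index // cfg.anchor_step]
    return NeuronArtifacts(neuron_id, tree, auto, volume, anchor_labels, blocks)


def generate_labeled_corpus(
    cfg: SynthConfig,
    block_config: Optional[BlockConfig] = None,
) -> Tuple[List[Block], pd.DataFrame]:
    """simulate → render → perturb → build blocks, labels known by construction."""
    rng = np.random.default_rng(cfg.seed)
    all_blocks: List[Block] = []
    for neuron_idx in range(cfg.n_neurons):
        art = generate_neuron(cfg, rng, f"neuron_{neuron_idx:03d}", block_config)
        all_blocks.extend(art.blocks)
    return all_blocks, corpus_manifest(all_blocks)


def corpus_manifest(blocks: Sequence[Block]) -> pd.DataFrame:
    rows = [
        {
            "neuron_id": b.neuron_id,
            "block_index": b.block_index,
            "anchor_z": b.anchor[0],
            "anchor_y": b.anchor[1],
            "anchor_x": b.anchor[2],
            "anchor_order_index": b.anchor_order_index,
            "label": b.label or "",
        }
        for b in blocks
    ]
    return pd.DataFrame(rows)


def manifest_hash(manifest: pd.DataFrame) -> str:
    return hashlib.sha256(manifest.to_csv(index=False).encode()).hexdigest()
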
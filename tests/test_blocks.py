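import numpy as np
import pytest

from neurotdb.blocks import (
    Block,
    BlockConfig,
    ImageVolume,
    build_blocks,
    extract_image_block,
    load_corpus,
    passes_node_filter,
    prune_burrs,
    save_corpus,
    select_anchors,
)
from neurotdb.swc import NeuronForest, SwcNode, traversal_order

from conftest import make_chain, random_tree


class TestSelectAnchors:
    def test_201_node_chain(self):
        forest = NeuronForest(make_chain(201))
        anchors = select_anchors(forest, 100)
        assert [a.id for a in anchors] == [1, 101, 201]

    def test_99_node_chain_single_anchor(self):
        forest = NeuronForest(make_chain(99))
        anchors = select_anchors(forest)
        assert len(anchors) == 1
        assert anchors[0].id == forest.soma_root().id

    def test_branched_tree_matches_preorder_oracle(self, rng):
        forest = random_tree(rng, 250)
        anchors = select_anchors(forest, 100)
        # independent preorder walk: iterative DFS, children ascending by id
        children = {n.id: [] for n in forest}
        for n in forest:
            if n.parent_id in forest:
                children[n.parent_id].append(n.id)
        order, stack = [], [forest.soma_root().id]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(sorted(children[nid], reverse=True))
        assert [a.id for a in anchors] == [order[i] for i in range(0, len(order), 100)]

    def test_empty_forest_raises(self):
        with pytest.raises(ValueError):
            select_anchors(NeuronForest())


class TestExtractImageBlock:
    def test_center_anchor_equals_direct_index(self, rng):
        vol = ImageVolume(rng.random((128, 128, 128)))
        block = extract_image_block(vol, (64, 64, 64))
        assert block.shape == (32, 64, 64)
        np.testing.assert_array_equal(block, vol.data[48:80, 32:96, 32:96])

    def test_corner_anchor_zero_padded(self, rng):
        vol = ImageVolume(rng.random((40, 70, 70)) + 1.0)
        block = extract_image_block(vol, (0, 0, 0))
        assert block.shape == (32, 64, 64)
        assert block[0, 0, 0] == 0.0  # before-volume region
        assert block[16, 32, 32] == vol.data[0, 0, 0]

    def test_ramp_volume_index_oracle(self):
        shape = (48, 72, 72)
        vol = ImageVolume(np.arange(np.prod(shape), dtype=float).reshape(shape))
        anchor = np.array([20, 30, 40])
        block = extract_image_block(vol, anchor)
        center = np.array([16, 32, 32])
        for offset in [(0, 0, 0), (5, -7, 3), (-16, 31, -32), (15, 31, 31)]:
            idx = anchor + np.array(offset)
            assert block[tuple(center + np.array(offset))] == vol.data[tuple(idx)]

    def test_outside_anchor_raises(self):
        vol = ImageVolume(np.zeros((32, 64, 64)))
        with pytest.raises(IndexError):
            extract_image_block(vol, (40, 0, 0))

    def test_intensity_conservation(self, rng):
        vol = ImageVolume(np.zeros((64, 96, 96)))
        vol.data[30:34, 40:44, 40:44] = 1.0  # signal well inside one block
        block = extract_image_block(vol, (32, 42, 42))
        assert block.sum() == vol.data.sum()
        partial = extract_image_block(vol, (5, 42, 42))
        assert partial.sum() <= vol.data.sum()


def _chain_forest(n, **kw):
    return NeuronForest(make_chain(n, **kw))


class TestPruneBurrs:
    def test_small_fragment_near_edge_deleted(self):
        # 3-node chain with a node at z=1: face distance 1 < 4
        frag = _chain_forest(3, start=(30.0, 30.0, 1.0))
        out = prune_burrs(frag, block_size=(32, 64, 64))
        assert out.n_nodes == 0

    def test_small_fragment_centered_kept(self):
        frag = _chain_forest(3, start=(30.0, 30.0, 16.0))
        out = prune_burrs(frag, block_size=(32, 64, 64))
        assert out.n_nodes == 3

    def test_short_daughter_branch_removed(self):
        # 8-node trunk with a 2-node daughter at node 3: burr goes, trunk stays
        nodes = make_chain(8, start=(20.0, 30.0, 16.0))
        nodes += make_chain(2, start=(22.0, 31.0, 16.0), step=(0.0, 1.0, 0.0), first_id=9, parent=3)
        out = prune_burrs(NeuronForest(nodes), block_size=(32, 64, 64))
        assert {n.id for n in out} == set(range(1, 9))

    def test_long_daughter_branch_kept(self):
        nodes = make_chain(8, start=(20.0, 30.0, 16.0))
        nodes += make_chain(4, start=(22.0, 31.0, 16.0), step=(0.0, 1.0, 0.0), first_id=9, parent=3)
        out = prune_burrs(NeuronForest(nodes), block_size=(32, 64, 64))
        assert out.n_nodes == 12

    def test_iterative_until_stable(self):
        # a 2-node spur hides behind a 2-node branch stub: after the spur is
        # removed, the remaining stub is itself a short terminal branch
        nodes = make_chain(10, start=(18.0, 30.0, 16.0))
        nodes += make_chain(3, start=(23.0, 31.0, 16.0), step=(0.0, 1.0, 0.0), first_id=11, parent=5)
        nodes += make_chain(2, start=(23.0, 32.5, 17.0), step=(0.0, 0.0, 1.0), first_id=14, parent=12)
        out = prune_burrs(NeuronForest(nodes), block_size=(32, 64, 64))
        assert {n.id for n in out} == set(range(1, 11))

    def test_edge_distance_boundary_3_vs_4(self):
        # distance 3 to the z face: deleted; distance 4: kept
        near = _chain_forest(3, start=(30.0, 30.0, 3.0))
        far = _chain_forest(3, start=(30.0, 30.0, 4.0))
        assert prune_burrs(near, block_size=(32, 64, 64)).n_nodes == 0
        assert prune_burrs(far, block_size=(32, 64, 64)).n_nodes == 3

    def test_branch_size_boundary_3_vs_4(self):
        def tree_with_daughter(k):
            nodes = make_chain(10, start=(18.0, 30.0, 16.0))
            nodes += make_chain(
                k, start=(23.0, 31.0, 16.0), step=(0.0, 1.0, 0.0), first_id=11, parent=5
            )
            return NeuronForest(nodes)

        assert prune_burrs(tree_with_daughter(3), block_size=(32, 64, 64)).n_nodes == 10
        assert prune_burrs(tree_with_daughter(4), block_size=(32, 64, 64)).n_nodes == 14

    def test_no_short_terminal_branch_survives(self, rng):
        for _ in range(5):
            forest = random_tree(rng, 60, spread=30.0)
            out = prune_burrs(forest, block_size=(32, 64, 64))
            for tip in [n for n in out if not out.children(n.id)]:
                branch = [tip.id]
                node = tip
                while node.parent_id in out and len(out.children(node.parent_id)) < 2:
                    node = out[node.parent_id]
                    branch.append(node.id)
                if node.parent_id in out:  # hangs off a bifurcation
                    assert len(branch) >= 4


class TestNodeFilter:
    @pytest.mark.parametrize("n,expected", [(10, False), (11, True), (12, True)])
    def test_boundary(self, n, expected):
        assert passes_node_filter(_chain_forest(n)) is expected

    def test_matches_count_oracle(self, rng):
        for _ in range(5):
            forest = random_tree(rng, int(rng.integers(1, 30)))
            assert passes_node_filter(forest) == (forest.n_nodes >= 11)


class TestBuildBlocks:
    def _volume(self):
        return ImageVolume(np.ones((64, 400, 64), dtype=np.float32))

    def test_fully_traced_chain(self):
        # 300-node chain along y: 3 anchors, auto == gold, all retained
        gold = NeuronForest(make_chain(300, start=(30.0, 30.0, 32.0), step=(0.0, 1.0, 0.0)))
        blocks = build_blocks(self._volume(), gold, gold, BlockConfig(), "n0")
        assert len(blocks) == 3
        for i, blk in enumerate(blocks):
            assert blk.anchor_order_index == i * 100
            assert blk.image.shape == (32, 64, 64)
            assert blk.gold.n_nodes == blk.auto.n_nodes
            pos = blk.gold.positions_zyx()
            assert np.all(pos >= 0) and np.all(pos < np.array([32, 64, 64]))

    def test_empty_auto_drops_all(self):
        gold = NeuronForest(make_chain(300, start=(30.0, 30.0, 32.0), step=(0.0, 1.0, 0.0)))
        blocks = build_blocks(self._volume(), gold, NeuronForest(), BlockConfig(), "n0")
        assert blocks == []

    def test_deterministic(self):
        gold = NeuronForest(make_chain(300, start=(30.0, 30.0, 32.0), step=(0.0, 1.0, 0.0)))
        a = build_blocks(self._volume(), gold, gold, BlockConfig(), "n0")
        b = build_blocks(self._volume(), gold, gold, BlockConfig(), "n0")
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.anchor == y.anchor
            np.testing.assert_array_equal(x.image, y.image)

    def test_retained_blocks_satisfy_filters(self):
        gold = NeuronForest(make_chain(300, start=(30.0, 30.0, 32.0), step=(0.0, 1.0, 0.0)))
        blocks = build_blocks(self._volume(), gold, gold, BlockConfig(), "n0")
        for blk in blocks:
            assert blk.auto.n_nodes >= 11


class TestCorpusIO:
    def test_roundtrip(self, tmp_path, rng):
        gold = NeuronForest(make_chain(300, start=(30.0, 30.0, 32.0), step=(0.0, 1.0, 0.0)))
        vol = ImageVolume(rng.random((64, 400, 64)).astype(np.float32))
        blocks = build_blocks(vol, gold, gold, BlockConfig(), "n0")
        for b in blocks:
            b.label = "low"
        save_corpus(blocks, tmp_path / "corpus")
        again = load_corpus(tmp_path / "corpus")
        assert len(again) == len(blocks)
        for x, y in zip(blocks, again):
            assert x.anchor == y.anchor
            assert x.label == y.label
            assert x.anchor_order_index == y.anchor_order_index
            np.testing.assert_allclose(x.image, y.image)
            assert {n.id: n.parent_id for n in x.auto} == {n.id: n.parent_id for n in y.auto}
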
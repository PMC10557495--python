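"""Topology optimizer: labeling rule, branches, subtrees, confidence, pruning."""
import numpy as np
import pytest

from avtopo.phantom import generate_tree, truth_graph
from avtopo.optimizer import (
    ARTERY,
    VEIN,
    Branch,
    Subtree,
    branch_confidence,
    extract_branches,
    extract_subtrees,
    label_from_probability,
    optimize,
    prune_and_correct,
    subtree_vote,
)
from avtopo.topology import Particle, TopologyGraph
from avtopo.twinpipe import OracleClassifier


def _particle(z, y, x):
    return Particle(position=np.array([float(z), float(y), float(x)]), scale=2.0,
                    orientation=np.array([0.0, 0.0, 1.0]))


def chain_graph(n=10):
    ps = [_particle(0, 0, i) for i in range(n)]
    edges = [(i, i + 1) for i in range(n - 1)]
    return TopologyGraph.from_particles(ps, edges, roots=[0])


def y_graph(stem=5, arm=5):
    """Stem 0..stem-1 then two arms branching from the last stem node."""
    ps = [_particle(0, 0, i) for i in range(stem)]
    edges = [(i, i + 1) for i in range(stem - 1)]
    for a in range(2):
        prev = stem - 1
        for j in range(arm):
            ps.append(_particle(0, (1 + j) * (1 if a == 0 else -1), stem - 1 + j + 1))
            edges.append((prev, len(ps) - 1))
            prev = len(ps) - 1
    return TopologyGraph.from_particles(ps, edges, roots=[0])


class TestLabelRule:
    @pytest.mark.parametrize("p,expected", [(0.51, ARTERY), (0.5, VEIN), (0.0, VEIN), (1.0, ARTERY)])
    def test_threshold_boundary(self, p, expected):
        assert label_from_probability(np.array([p]))[0] == expected

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            label_from_probability(np.array([1.5]))


class TestBranches:
    def test_path_graph_is_one_branch(self):
        branches = extract_branches(chain_graph(10))
        assert len(branches) == 1 and len(branches[0]) == 10

    def test_y_graph_gives_three_branches_sharing_junction(self):
        g = y_graph()
        branches = extract_branches(g)
        assert len(branches) == 3
        junction = 4  # last stem node has degree 3
        assert all(junction in b.nodes for b in branches)
        # every edge covered exactly once
        covered = sum(len(b) - 1 for b in branches)
        assert covered == g.g.number_of_edges()

    def test_phantom_branch_count_matches_tree_edges(self):
        tree = generate_tree(3, root_radius=4.0, seed=0, root_pos=(5.0, 64.0, 64.0))
        g = truth_graph([tree], spacing=1.0)
        branches = extract_branches(g)
        assert len(branches) == tree.branch_count  # 15 for depth 3


class TestSubtrees:
    def test_single_y_uniform_labels_two_subtrees(self):
        g = y_graph()
        labels = np.full(g.n_nodes, ARTERY)
        subtrees, trunk = extract_subtrees(g, labels, trunk_generations=1)
        assert len(subtrees) == 2
        union = set().union(*(s.nodes for s in subtrees))
        assert union == set(range(g.n_nodes)) - trunk
        for a in subtrees:
            for b in subtrees:
                if a is not b:
                    assert not (a.nodes & b.nodes)

    def test_clean_labels_give_pure_subtrees(self):
        art = generate_tree(3, 4.0, seed=0, root_pos=(5.0, 40.0, 64.0), class_label="artery")
        vein = generate_tree(3, 4.0, seed=1, root_pos=(5.0, 90.0, 64.0),
                             avoid=art.segments(), class_label="vein")
        g = truth_graph([art, vein], spacing=1.0)
        subtrees, _ = extract_subtrees(g, g.truth)
        for s in subtrees:
            vals = {int(g.truth[m]) for m in s.nodes}
            assert len(vals) == 1


class TestVotesAndConfidence:
    def test_majority_vote(self):
        s = Subtree(root=0, nodes=set(range(10)))
        labels = np.array([ARTERY] * 7 + [VEIN] * 3)
        assert subtree_vote(s, labels) == ARTERY

    def test_tie_takes_root_branch_class(self):
        s = Subtree(root=0, nodes=set(range(10)))
        labels = np.array([ARTERY] * 5 + [VEIN] * 5)
        assert subtree_vote(s, labels, root_branch_class=VEIN) == VEIN

    def test_empty_subtree_rejected(self):
        with pytest.raises(ValueError):
            subtree_vote(Subtree(root=0), np.array([]))

    def test_branch_confidence_fraction(self):
        b = Branch(nodes=list(range(10)))
        conf, w = branch_confidence(b, np.array([ARTERY] * 9 + [VEIN]))
        assert conf == pytest.approx(0.9) and w == pytest.approx(0.9)

    def test_even_split_is_half(self):
        b = Branch(nodes=[0, 1])
        conf, _ = branch_confidence(b, np.array([ARTERY, VEIN]))
        assert conf == 0.5

    def test_short_branch_damping(self):
        b = Branch(nodes=[0, 1])
        conf, w = branch_confidence(b, np.array([ARTERY, ARTERY]), n_min=3)
        assert conf == 1.0 and w == pytest.approx(2.0 / 3.0)


class TestPruneAndCorrect:
    def test_clean_labels_identity_empty_audit(self):
        tree = generate_tree(3, 4.0, seed=0, root_pos=(5.0, 64.0, 64.0))
        g = truth_graph([tree], spacing=1.0)
        labels = g.truth.astype(np.uint8)
        branches = extract_branches(g)
        subtrees, _ = extract_subtrees(g, labels)
        out = prune_and_correct(g, subtrees, branches, labels)
        np.testing.assert_array_equal(out.labels, labels)
        assert out.audit == []

    @staticmethod
    def _two_level_graph():
        """Stem -> (arm A -> (A1 leaf, A2 -> (A2a leaf, A2b leaf)), arm B leaf).

        Node ranges: stem 0-5, arm A 6-13, A1 14-21, A2 22-29,
        A2a 30-36, A2b 37-43, arm B 44-51.
        """
        ps = [_particle(0, 0, i) for i in range(6)]
        edges = [(i, i + 1) for i in range(5)]

        def add_chain(start_node, n, y0, z0):
            prev = start_node
            for j in range(n):
                ps.append(_particle(z0, y0 + j, 0))
                edges.append((prev, len(ps) - 1))
                prev = len(ps) - 1
            return prev

        a_end = add_chain(5, 8, 1, 0)        # arm A: 6..13
        add_chain(a_end, 8, 9, 1)            # A1:   14..21
        a2_end = add_chain(a_end, 8, 9, -1)  # A2:   22..29
        add_chain(a2_end, 7, 17, -2)         # A2a:  30..36
        add_chain(a2_end, 7, 17, -1)         # A2b:  37..43
        add_chain(5, 8, -1, 0)               # arm B: 44..51
        return TopologyGraph.from_particles(ps, edges, roots=[0])

    def test_confident_vein_branch_in_artery_subtree_survives(self):
        # Hand-simulation of the rule: A2 is vein in all 8 interior nodes
        # (branch confidence 8/9 with its artery junction endpoint), and its
        # artery descendants keep it off the label-flip root list, so it stays
        # inside the artery subtree.  Four flips in arm A drop the
        # rest-of-subtree evidence to 25/29 < 8/9, so A2 is PRUNED into its
        # own subtree keeping vein, and the distal leaves stay artery.
        from avtopo.config import OptimizerConfig

        g = self._two_level_graph()
        probs = np.full(g.n_nodes, 0.9)
        a2 = list(range(22, 30))
        probs[a2] = 0.1
        probs[[7, 9, 11, 12]] = 0.1  # noise inside arm A
        out = optimize(g, probs, mode="full",
                       config=OptimizerConfig(trunk_generations=1))
        assert all(out.labels[m] == VEIN for m in a2)
        others = [m for m in range(g.n_nodes) if m not in a2]
        assert all(out.labels[m] == ARTERY for m in others)
        assert any(e["action"] == "prune" for e in out.audit)

    def test_weak_minority_branch_relabeled(self):
        # A2 has only a weak vein majority (5 of 8): the rest of the artery
        # subtree is more confident, so A2 is relabeled to artery.
        from avtopo.config import OptimizerConfig

        g = self._two_level_graph()
        probs = np.full(g.n_nodes, 0.9)
        probs[list(range(22, 27))] = 0.1  # 5 vein of 8 in A2
        out = optimize(g, probs, mode="full",
                       config=OptimizerConfig(trunk_generations=1))
        assert all(out.labels[m] == ARTERY for m in range(g.n_nodes))
        assert any(e["action"] == "relabel" for e in out.audit)

    def test_idempotent_refinement(self):
        tree = generate_tree(3, 4.0, seed=2, root_pos=(5.0, 64.0, 64.0))
        g = truth_graph([tree], spacing=1.0)
        rng = np.random.default_rng(0)
        probs = np.where(g.truth == ARTERY, 0.9, 0.1)
        flip = rng.random(g.n_nodes) < 0.15
        probs = np.where(flip, 1.0 - probs, probs)
        out1 = optimize(g, probs, mode="full")
        out2 = optimize(g, np.where(out1.labels == ARTERY, 0.9, 0.1), mode="full")
        np.testing.assert_array_equal(out1.labels, out2.labels)

    def test_output_branches_unanimous(self):
        tree = generate_tree(3, 4.0, seed=3, root_pos=(5.0, 64.0, 64.0))
        g = truth_graph([tree], spacing=1.0)
        oracle = OracleClassifier(flip_noise=0.15, seed=5)
        out = optimize(g, oracle.predict(g.truth).p, mode="full")
        for b in extract_branches(g):
            interior = b.nodes[1:]  # endpoints shared with the parent branch
            assert len({int(out.labels[m]) for m in interior}) == 1

    def test_unknown_mode_rejected(self):
        g = chain_graph(4)
        with pytest.raises(ValueError):
            optimize(g, np.full(4, 0.9), mode="bogus")
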
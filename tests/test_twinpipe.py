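"""Twin-pipe classifier: patches, enhancement, GCN, training, merging."""
import numpy as np
import pytest

from avtopo._nn import NonLocalGCNClassifier
from avtopo.config import TwinPipeConfig
from avtopo.optimizer import extract_branches
from avtopo.phantom import truth_graph
from avtopo.twinpipe import (
    ClassifierState,
    OracleClassifier,
    OrientedPatchSet,
    ParticleProbabilities,
    enhance_vessels,
    extract_patch,
    extract_tubule_graph,
    gcn_layer,
    merge_probabilities,
    predict_pipe,
    train_pipe,
)

from conftest import straight_tube


class TestGcnLayer:
    def test_identity_matrices_identity_activation(self):
        H = np.arange(12.0).reshape(4, 3)
        out = gcn_layer(H, np.eye(4), np.eye(3), activation="identity")
        np.testing.assert_allclose(out, H)

    def test_hand_computed_two_node_case(self):
        # direct matrix arithmetic oracle on 2x2 inputs
        H = np.array([[1.0, 2.0], [3.0, -1.0]])
        W = np.array([[0.5, 0.5], [0.0, 1.0]])
        T = np.array([[1.0, 0.0], [1.0, 1.0]])
        expected = np.maximum(W @ H @ T, 0.0)
        np.testing.assert_allclose(gcn_layer(H, W, T), expected)

    def test_relu_output_nonnegative(self):
        rng = np.random.default_rng(0)
        out = gcn_layer(rng.standard_normal((5, 4)), rng.standard_normal((5, 5)),
                        rng.standard_normal((4, 2)))
        assert (out >= 0).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gcn_layer(np.ones((3, 4)), np.ones((2, 2)), np.ones((4, 2)))


class TestNetworkGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        m = NonLocalGCNClassifier(in_channels=1, conv_channels=(2, 3),
                                  attention_dim=2, feature_dim=4, gcn_hidden=4, seed=0)
        patches = rng.standard_normal((2, 3, 3, 32, 32)) * 0.5
        nb = np.array([[1, 1], [1, 0]], bool)
        t = np.array([0, 1])
        _, grads, _ = m.loss_and_grads(patches, nb, t)
        eps = 1e-6
        for key in ("W1", "Wq", "Wo", "T0", "T1"):
            P = m.params[key]
            idx = tuple(rng.integers(0, s) for s in P.shape)
            old = P[idx]
            P[idx] = old + eps
            l1, _, _ = m.loss_and_grads(patches, nb, t)
            P[idx] = old - eps
            l2, _, _ = m.loss_and_grads(patches, nb, t)
            P[idx] = old
            num = (l1 - l2) / (2 * eps)
            assert grads[key][idx] == pytest.approx(num, rel=1e-3, abs=1e-7)


class TestExtractPatch:
    def test_axis_aligned_orientation_is_axial_crop(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((40, 40, 40)).astype(np.float32)
        pt = extract_patch(img, np.array([20.0, 20.0, 20.0]),
                           np.array([1.0, 0.0, 0.0]), size=(8, 8, 3))
        # orientation along z: planes are axial slices around z=20.  The
        # in-plane frame may flip/permute axes, so compare value multisets
        # over the candidate 8x8 windows.
        for k, z in enumerate((19, 20, 21)):
            ok = any(
                np.allclose(
                    np.sort(pt[k].ravel()),
                    np.sort(img[z, a:a + 8, b:b + 8].ravel()),
                    atol=1e-5,
                )
                for a in (16, 17) for b in (16, 17)
            )
            assert ok

    def test_corner_particle_padded_to_full_shape(self):
        img = np.ones((20, 20, 20), np.float32)
        pt = extract_patch(img, np.array([0.0, 0.0, 0.0]),
                           np.array([0.0, 0.0, 1.0]), size=(32, 32, 3),
                           background=-1000.0)
        assert pt.shape == (3, 32, 32)
        assert (pt == -1000.0).any() and (pt == 1.0).any()

    def test_tube_cross_section_disc_area(self, tube_mask):
        img = np.where(tube_mask, 1.0, 0.0).astype(np.float32)
        pt = extract_patch(img, np.array([7.0, 7.0, 20.0]),
                           np.array([0.0, 0.0, 1.0]), size=(32, 32, 3),
                           background=0.0)
        area = (pt[1] > 0.5).sum()
        assert area == pytest.approx(np.pi * 3.0**2, rel=0.25)


class TestEnhanceVessels:
    def test_bright_tube_enhanced_over_background(self, tube_mask):
        rng = np.random.default_rng(0)
        img = np.where(tube_mask, 50.0, -800.0) + 20.0 * rng.standard_normal(tube_mask.shape)
        resp = enhance_vessels(img.astype(np.float32))
        core = straight_tube(tube_mask.shape, radius=1.5)
        background = ~straight_tube(tube_mask.shape, radius=6.0)
        assert resp[core].mean() > 5.0 * max(resp[background].mean(), 1e-9)
        assert resp.min() >= 0.0 and resp.max() <= 1.0

    def test_constant_image_gives_zeros(self):
        with pytest.warns(UserWarning):
            out = enhance_vessels(np.full((16, 16, 16), 7.0, np.float32))
        assert (out == 0).all()


class TestTubuleGraph:
    @staticmethod
    def _graph():
        from avtopo.phantom import generate_tree

        tree = generate_tree(3, root_radius=4.0, seed=0, root_pos=(5.0, 64.0, 64.0))
        return truth_graph([tree], spacing=1.0)

    def test_infinite_threshold_selects_everything(self):
        g = self._graph()
        ids = extract_tubule_graph(g, extract_branches(g), np.inf)
        assert len(ids) == g.n_nodes

    def test_zero_threshold_selects_nothing(self):
        g = self._graph()
        with pytest.warns(UserWarning):
            ids = extract_tubule_graph(g, extract_branches(g), 0.0)
        assert len(ids) == 0

    def test_monotone_taper_gives_suffix_closed_selection(self):
        # with Murray tapering, thin branches are distal: every child of a
        # selected node that starts a branch must be selected too
        g = self._graph()
        ids = set(int(i) for i in extract_tubule_graph(g, extract_branches(g), 2.5))
        assert ids
        scales = np.array([p.scale for p in g.particles])
        for n in ids:
            for c in g.children(n):
                if scales[c] <= scales[n] and c not in ids:
                    # only branch endpoints may straddle the threshold
                    assert g.g.degree[n] >= 3


class TestTraining:
    @staticmethod
    def _toy_set(n=160, seed=0):
        rng = np.random.default_rng(seed)
        patches = (rng.standard_normal((n, 1, 3, 32, 32)) * 0.3).astype(np.float32)
        y = np.array([1] * (n // 2) + [2] * (n // 2))
        patches[: n // 2, :, :, 14:18, 14:18] += 2.0
        perm = rng.permutation(n)
        return OrientedPatchSet(patches[perm], np.full((n, 2), -1, np.int64), y[perm])

    def test_loss_decreases_on_learnable_fixture(self):
        st = train_pipe(self._toy_set(), TwinPipeConfig(batch_size=32), seed=0,
                        epochs=6, learning_rate=0.1)
        assert st.loss_trace[-1] < st.loss_trace[0]

    def test_single_class_refused(self):
        ps = self._toy_set()
        ps.labels[:] = 1
        with pytest.raises(ValueError):
            train_pipe(ps, TwinPipeConfig(), seed=0, epochs=1)

    def test_same_seed_identical_parameters(self):
        cfg = TwinPipeConfig(batch_size=32)
        s1 = train_pipe(self._toy_set(), cfg, seed=3, epochs=2, learning_rate=0.05)
        s2 = train_pipe(self._toy_set(), cfg, seed=3, epochs=2, learning_rate=0.05)
        for k in s1.model.params:
            np.testing.assert_array_equal(s1.model.params[k], s2.model.params[k])

    def test_state_roundtrip_bit_identical_predictions(self, tmp_path):
        ps = self._toy_set(64)
        st = train_pipe(ps, TwinPipeConfig(batch_size=32), seed=0, epochs=2,
                        learning_rate=0.05)
        p1 = predict_pipe(st, ps)
        st.save(tmp_path / "model.npz")
        st2 = ClassifierState.load(tmp_path / "model.npz")
        p2 = predict_pipe(st2, ps)
        np.testing.assert_array_equal(p1, p2)


class TestPatchSetIO:
    def test_hdf5_roundtrip(self, tmp_path):
        from avtopo.twinpipe import load_patch_set, save_patch_set

        rng = np.random.default_rng(0)
        ps = OrientedPatchSet(
            patches=rng.standard_normal((5, 1, 3, 8, 8)).astype(np.float32),
            neighbors=np.array([[1, -1]] * 5, dtype=np.int64),
            labels=np.array([1, 2, 1, 2, 1], dtype=np.uint8),
        )
        save_patch_set(ps, tmp_path / "p.h5")
        back = load_patch_set(tmp_path / "p.h5")
        np.testing.assert_array_equal(back.patches, ps.patches)
        np.testing.assert_array_equal(back.labels, ps.labels)


class TestMerge:
    def test_non_tubule_nodes_keep_full_pipe(self):
        p_full = np.array([0.2, 0.8, 0.6])
        merged = merge_probabilities(p_full, np.array([0.9]), np.array([1]))
        assert merged[0] == 0.2 and merged[2] == 0.6

    def test_extreme_disagreeing_tubule_pipe_flips_label(self):
        # p_full = 0.55 (weak artery), p_tubule = 0.05 (confident vein)
        merged = merge_probabilities(np.array([0.55]), np.array([0.05]), np.array([0]))
        assert merged[0] <= 0.30
        assert merged[0] <= 0.5  # label flips to vein

    def test_agreement_blends_between_the_pipes(self):
        merged = merge_probabilities(np.array([0.7]), np.array([0.9]), np.array([0]))
        assert 0.7 <= merged[0] <= 0.9


class TestOracle:
    def test_zero_noise_reproduces_truth(self):
        truth = np.array([1, 2, 1, 2, 2])
        probs = OracleClassifier(flip_noise=0.0, seed=0).predict(truth)
        assert isinstance(probs, ParticleProbabilities)
        np.testing.assert_array_equal(np.where(probs.p > 0.5, 1, 2), truth)

    def test_flip_rate_matches_request(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(1, 3, size=20000)
        probs = OracleClassifier(flip_noise=0.15, seed=1).predict(truth)
        flipped = (np.where(probs.p > 0.5, 1, 2) != truth).mean()
        assert flipped == pytest.approx(0.15, abs=0.01)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            ParticleProbabilities(p=np.array([0.5, 1.2]))
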
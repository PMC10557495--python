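"""Synthetic phantom generator: taper law, structure, adhesions, rasterization."""
import numpy as np
import pytest
from scipy import ndimage

from avtopo._util import segment_segment_distance
from avtopo.config import PhantomConfig
from avtopo.phantom import (
    GenerationError,
    entangle,
    generate_tree,
    make_phantom,
    rasterize,
)

from conftest import SMALL


class TestGenerateTree:
    def test_symmetric_murray_split(self):
        tree = generate_tree(depth=1, root_radius=4.0, taper_exponent=3.0, seed=0)
        radii = sorted(r for _, r in tree.nodes)
        # symmetric split of Murray's law: r_child = 4 / 2**(1/3)
        assert radii[0] == pytest.approx(4.0 / 2 ** (1 / 3), abs=1e-9)
        assert radii[1] == pytest.approx(4.0 / 2 ** (1 / 3), abs=1e-9)
        bifurcations = {p for p, _ in tree.edges if sum(1 for q, _ in tree.edges if q == p) == 2}
        assert len(bifurcations) == 1
        assert len(tree.leaves()) == 2

    @pytest.mark.parametrize("depth,leaves,bifs,edges", [(2, 4, 3, 7), (3, 8, 7, 15)])
    def test_binary_tree_counts(self, depth, leaves, bifs, edges):
        tree = generate_tree(depth=depth, root_radius=4.0, seed=1)
        assert len(tree.leaves()) == leaves
        parents = [p for p, _ in tree.edges]
        assert sum(1 for n in set(parents) if parents.count(n) == 2) == bifs
        assert tree.branch_count == edges

    def test_taper_law_holds_at_every_bifurcation(self):
        tree = generate_tree(depth=3, root_radius=4.0, taper_exponent=3.0, seed=2,
                             asymmetry=0.5)
        tree.validate(taper_exponent=3.0)  # raises on violation

    def test_deterministic_for_seed(self):
        a = generate_tree(depth=3, root_radius=4.0, seed=7)
        b = generate_tree(depth=3, root_radius=4.0, seed=7)
        for (pa, ra), (pb, rb) in zip(a.nodes, b.nodes):
            np.testing.assert_array_equal(pa, pb)
            assert ra == rb

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_tree(depth=0, root_radius=4.0)
        with pytest.raises(ValueError):
            generate_tree(depth=2, root_radius=-1.0)


class TestEntangle:
    @staticmethod
    def _trees(seed=0):
        art = generate_tree(2, 4.0, seed=seed, root_pos=(5.0, 25.0, 40.0),
                            class_label="artery")
        vein = generate_tree(2, 4.0, seed=seed + 1, root_pos=(5.0, 60.0, 40.0),
                             avoid=art.segments(), min_gap=1.2, class_label="vein")
        return art, vein

    def test_zero_adhesions_keeps_separation(self):
        art, vein = self._trees()
        a2, v2, sites = entangle(art, vein, min_gap=1.2, n_adhesions=0, seed=0)
        assert sites == []
        for p0, p1, ra in a2.segments():
            for q0, q1, rv in v2.segments():
                assert segment_segment_distance(p0, p1, q0, q1) >= ra + rv + 1.2 - 1e-9

    def test_two_adhesions_reported_and_close(self):
        art, vein = self._trees(seed=3)
        a2, v2, sites = entangle(art, vein, min_gap=1.2, n_adhesions=2, seed=0)
        assert len(sites) == 2
        # exhaustive scan over all segment pairs: each site lies on the vein
        # centerline within touching distance (r_a + r_v + gap) of an artery
        for site in sites:
            on_vein = min(
                segment_segment_distance(site, site, q0, q1)
                for q0, q1, _ in v2.segments()
            )
            assert on_vein < 1e-6
            close = any(
                segment_segment_distance(site, site, p0, p1) < r_a + rv + 1.2
                for p0, p1, r_a in a2.segments()
                for _, _, rv in [min(v2.segments(),
                                     key=lambda s: segment_segment_distance(site, site, s[0], s[1]))]
            )
            assert close

    def test_deterministic_sites(self):
        art, vein = self._trees(seed=5)
        _, _, s1 = entangle(art, vein, 1.2, 2, seed=9)
        _, _, s2 = entangle(art, vein, 1.2, 2, seed=9)
        np.testing.assert_array_equal(np.array(s1), np.array(s2))


class TestRasterize:
    def test_straight_tube_cross_section_area(self):
        from avtopo.phantom import TreeSpec

        r_mm = 3.0
        tree = TreeSpec(
            nodes=[(np.array([10.0, 10.0, 6.0]), r_mm),
                   (np.array([10.0, 10.0, 33.0]), r_mm)],
            edges=[(0, 1)], class_label="artery",
        )
        vol = rasterize([tree], shape=(20, 20, 40), spacing=(1.0, 1.0, 1.0),
                        companion_bronchi=False, seed=0)
        for x in range(11, 29):
            area = vol.mask[:, :, x].sum()
            assert area == pytest.approx(np.pi * r_mm**2, rel=0.10)

    def test_labels_partition_mask(self, small_phantom):
        vol = small_phantom[0]
        assert (vol.truth_labels == 1).sum() + (vol.truth_labels == 2).sum() == vol.mask.sum()
        assert not np.any((vol.truth_labels > 0) & ~vol.mask)

    def test_bronchi_never_overlap_vessels(self, small_phantom):
        vol = small_phantom[0]
        assert vol.bronchus_mask is not None and vol.bronchus_mask.sum() > 0
        assert not np.any(vol.bronchus_mask & vol.mask)

    def test_companion_disabled_leaves_parenchyma(self):
        cfg = PhantomConfig(shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0),
                            root_radius=3.5, companion_bronchi=False)
        vol, _, _ = make_phantom(cfg, seed=0)
        assert vol.bronchus_mask is None
        outside = vol.intensity[~vol.mask]
        assert abs(outside.mean() - cfg.parenchyma_mean) < 5.0

    def test_centerline_on_mask_and_radius_recovery(self, small_phantom):
        vol = small_phantom[0]
        dmap = ndimage.distance_transform_edt(vol.mask, sampling=vol.spacing)
        for label in ("artery", "vein"):
            for pts, radii in vol.centerlines[label]:
                vox = np.round(pts / np.asarray(vol.spacing)).astype(int)
                assert vol.mask[tuple(vox.T)].all()
                rec = dmap[tuple(vox.T)]
                # distance transform at the axis recovers the radius within 1 voxel
                interior = radii < radii.max()  # skip trunk end caps
                assert np.all(np.abs(rec[1:-1] - radii[1:-1]) <= 1.0 + 1e-6)

    def test_generation_bit_reproducible(self):
        v1, a1, _ = make_phantom(SMALL, seed=11)
        v2, a2, _ = make_phantom(SMALL, seed=11)
        np.testing.assert_array_equal(v1.mask, v2.mask)
        np.testing.assert_array_equal(v1.intensity, v2.intensity)
        np.testing.assert_array_equal(v1.truth_labels, v2.truth_labels)

    def test_out_of_bounds_tree_rejected(self):
        from avtopo.phantom import TreeSpec

        tree = TreeSpec(
            nodes=[(np.array([5.0, 5.0, -20.0]), 3.0),
                   (np.array([5.0, 5.0, 60.0]), 3.0)],
            edges=[(0, 1)], class_label="artery",
        )
        with pytest.raises(GenerationError):
            rasterize([tree], shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0),
                      companion_bronchi=False, seed=0)
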
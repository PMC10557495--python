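"""Topology extraction: distance/time maps, tracing, particle kinds, graph."""
import numpy as np
import pytest
from scipy.spatial import cKDTree

from avtopo.topology import (
    DistanceMap,
    Particle,
    backtrace,
    build_graph,
    classify_particle_kinds,
    detect_root_terminals,
    distance_map,
    extract_topology,
    msfm_time_map,
    repair_false_terminals,
    sample_particles,
)

from conftest import straight_tube


class TestDistanceMap:
    def test_single_voxel(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        d = distance_map(mask, spacing=(2.0, 1.0, 0.5))
        assert d.values[2, 2, 2] == pytest.approx(0.5)

    def test_solid_ball_maximum(self):
        shape = (21, 21, 21)
        z, y, x = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        mask = (z - 10) ** 2 + (y - 10) ** 2 + (x - 10) ** 2 <= 8**2
        d = distance_map(mask, spacing=(1.0, 1.0, 1.0))
        assert abs(d.values.max() - 8.0) <= 1.0

    def test_all_background(self):
        d = distance_map(np.zeros((4, 4, 4), bool))
        assert (d.values == 0).all()


class TestMSFM:
    def test_constant_speed_tube_time(self):
        # uniform speed d along a straight tube: T(L) = L / d
        mask = straight_tube((9, 9, 50), radius=3.0)
        dvals = np.where(mask, 2.5, 0.0)
        dmap = DistanceMap(dvals, (1.0, 1.0, 1.0))
        tm = msfm_time_map(dmap, (4, 4, 2))
        L = 40.0
        assert tm.values[4, 4, 42] == pytest.approx(L / 2.5, rel=0.02)

    def test_root_outside_mask_rejected(self):
        mask = straight_tube((9, 9, 20), radius=2.0)
        dmap = distance_map(mask)
        with pytest.raises(ValueError):
            msfm_time_map(dmap, (0, 0, 0))

    def test_infinite_outside_mask(self):
        mask = straight_tube((9, 9, 20), radius=2.0)
        dmap = distance_map(mask)
        tm = msfm_time_map(dmap, (4, 4, 10))
        assert np.isinf(tm.values[~mask]).all()
        assert np.isfinite(tm.values[mask]).all()


class TestBacktrace:
    def test_start_at_root_is_identity(self):
        mask = straight_tube((9, 9, 30), radius=2.0)
        tm = msfm_time_map(distance_map(mask), (4, 4, 15))
        path, reason = backtrace(tm, (4, 4, 15))
        assert len(path) == 1 and reason == "root"

    def test_monotone_descent_to_root(self):
        mask = straight_tube((9, 9, 30), radius=2.0)
        tm = msfm_time_map(distance_map(mask), (4, 4, 2))
        path, reason = backtrace(tm, (4, 4, 27))
        t = tm.values[tuple(path.T)]
        assert (np.diff(t) < 0).all()
        assert reason == "root" and tuple(path[-1]) == (4, 4, 2)

    def test_infinite_start_rejected(self):
        mask = straight_tube((9, 9, 30), radius=2.0)
        tm = msfm_time_map(distance_map(mask), (4, 4, 2))
        with pytest.raises(ValueError):
            backtrace(tm, (0, 0, 0))

    def test_second_trace_merges_before_root(self, y_mask):
        dmap = distance_map(y_mask)
        root = (2, 20, 20)
        tm = msfm_time_map(dmap, root)
        vox = np.argwhere(y_mask)
        arm1 = vox[vox[:, 1] > 26]
        arm2 = vox[vox[:, 1] < 14]
        l1 = tuple(arm1[np.argmax(arm1[:, 0])])
        l2 = tuple(arm2[np.argmax(arm2[:, 0])])
        p1, r1 = backtrace(tm, l1)
        visited = {int(np.ravel_multi_index(tuple(v), y_mask.shape)) for v in p1}
        p2, r2 = backtrace(tm, l2, visited=visited)
        assert r2 == "merge"
        # the merge happens strictly distal of the root (in the shared stem)
        assert tuple(p2[-1]) != root


class TestSampleParticles:
    def test_empty_mask_gives_empty_list(self):
        assert sample_particles(np.zeros((8, 8, 8), bool)) == []

    def test_straight_tube_orientations_and_scale(self, tube_mask):
        ps = sample_particles(tube_mask, spacing=(1.0, 1.0, 1.0))
        assert len(ps) > 10
        axis = np.array([0.0, 0.0, 1.0])
        angles = [np.degrees(np.arccos(min(1.0, abs(p.orientation @ axis)))) for p in ps]
        assert np.mean(np.array(angles) < 10.0) > 0.9
        med = np.median([p.scale for p in ps])
        assert 2.0 <= med <= 4.0  # distance-transform value at the axis


class TestKinds:
    @staticmethod
    def _chain(n=10):
        return [
            Particle(position=np.array([0.0, 0.0, float(i)]), scale=2.0,
                     orientation=np.array([0.0, 0.0, 1.0]))
            for i in range(n)
        ]

    def test_chain_ends_terminal_interior_branching(self):
        ps, _ = classify_particle_kinds(self._chain())
        kinds = [p.kind for p in ps]
        assert kinds[0] == "terminal" and kinds[-1] == "terminal"
        assert all(k == "branching" for k in kinds[1:-1])

    def test_junction_center_bifurcating(self):
        ps = self._chain(5)
        for i in range(1, 5):
            ps.append(Particle(position=np.array([0.0, float(i), 2.0]), scale=2.0,
                               orientation=np.array([0.0, 1.0, 0.0])))
        ps, _ = classify_particle_kinds(ps)
        center = next(p for p in ps if tuple(p.position) == (0.0, 0.0, 2.0))
        assert center.kind == "bifurcating"

    def test_orphans_dropped_with_warning(self):
        ps = self._chain(4)
        ps.append(Particle(position=np.array([30.0, 30.0, 30.0]), scale=1.0,
                           orientation=np.array([1.0, 0.0, 0.0])))
        with pytest.warns(UserWarning):
            kept, _ = classify_particle_kinds(ps)
        assert len(kept) == 4


class TestGraph:
    def test_chain_gives_path_graph(self):
        ps = TestKinds._chain(10)
        ps, _ = classify_particle_kinds(ps)
        g = build_graph(ps)
        assert g.g.number_of_edges() == 9
        assert sorted(g.degrees()) == [1, 1] + [2] * 8

    def test_phantom_graph_degrees_and_roots(self, small_phantom):
        _, _, _, graph, dmap = small_phantom
        deg = graph.degrees()
        assert deg.min() >= 1 and deg.max() <= 3
        assert len(graph.roots) == graph.component_count() == 2
        # roots sit at the thickest points of their components
        dvox = dmap.voxels
        for r in graph.roots:
            v = tuple(np.round(graph.particles[r].position).astype(int))
            assert dvox[v] > 0.7 * dvox.max()


class TestRootTerminals:
    def test_straight_tube_root_and_terminals(self, tube_mask):
        dmap = distance_map(tube_mask)
        root, _ = detect_root_terminals(dmap)
        assert dmap.values[root] == dmap.values.max()
        tm = msfm_time_map(dmap, root)
        _, terms = detect_root_terminals(dmap, tm)
        assert 1 <= len(terms) <= 2
        xs = sorted(t[2] for t in terms)
        assert xs[0] <= 4 or xs[-1] >= 35  # at the tube ends

    def test_single_voxel_mask(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        dmap = distance_map(mask)
        root, _ = detect_root_terminals(dmap)
        assert root == (2, 2, 2)
        tm = msfm_time_map(dmap, root)
        _, terms = detect_root_terminals(dmap, tm)
        assert terms == [(2, 2, 2)]

    def test_phantom_terminal_count_matches_leaves(self, small_phantom):
        vol, art, vein, _, _ = small_phantom
        from scipy import ndimage

        labels, n = ndimage.label(vol.mask, structure=np.ones((3, 3, 3)))
        total = 0
        for c in range(1, n + 1):
            comp = labels == c
            dmap = DistanceMap(
                np.where(comp, distance_map(comp, vol.spacing).values, 0.0), vol.spacing
            )
            root, _ = detect_root_terminals(dmap)
            tm = msfm_time_map(dmap, root)
            _, terms = detect_root_terminals(dmap, tm)
            total += len(terms)
        n_leaves = len(art.leaves()) + len(vein.leaves())
        # leaf tips plus the two trunk stubs, with slack for surface maxima
        assert n_leaves <= total <= n_leaves + 6


class TestRepair:
    def test_intact_tube_unchanged(self, tube_mask):
        dmap = distance_map(tube_mask)
        ps = sample_particles(tube_mask, dmap=dmap)
        ps, _ = classify_particle_kinds(ps)
        n_before = len(ps)
        out, n_rep = repair_false_terminals(ps, tube_mask, dmap)
        assert n_rep == 0 and len(out) == n_before

    def test_gap_injected_phantom_reconnects(self, small_phantom):
        import networkx as nx

        from avtopo.experiments import cut_branch_gap

        vol, art, _, _, _ = small_phantom
        cut = cut_branch_gap(vol, art, edge_idx=1)
        g, _ = extract_topology(cut, vol.spacing)
        assert nx.number_connected_components(g.g) == 2

    def test_coverage_on_phantom(self, small_phantom):
        vol, _, _, graph, _ = small_phantom
        truth = np.concatenate(
            [vol.centerline_points_vox("artery"), vol.centerline_points_vox("vein")]
        )
        P = graph.positions()
        assert (cKDTree(P).query(truth)[0] <= 2.0).mean() >= 0.95
        assert (cKDTree(truth).query(P)[0] <= 2.0).mean() >= 0.95
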
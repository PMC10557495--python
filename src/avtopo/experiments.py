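"""Reproducible desk-scale experiments on synthetic phantoms.

These functions generate phantom corpora and measure each pipeline stage
end-to-end: topology recovery, fast-marching accuracy against a Dijkstra
oracle, optimizer ablations under label-flip noise, twin-pipe training, and
voxel reconstruction.  Both the test suite and the results-reproduction
script call into this module so the reported numbers always come from the
same code path.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from ._util import stage_seed, unit
from .config import PhantomConfig, TwinPipeConfig
from .optimizer import extract_branches, optimize
from .phantom import PhantomVolume, TreeSpec, make_phantom, truth_graph
from .reconstruct import confusion, dsc, metrics, paint_labels
from .topology import DistanceMap, TopologyGraph, extract_topology, msfm_time_map
from .twinpipe import (
    OracleClassifier,
    OrientedPatchSet,
    build_patch_set,
    enhance_vessels,
    extract_tubule_graph,
    predict_pipe,
    train_pipe,
    twin_pipe_predict,
)

SMALL_PHANTOM = PhantomConfig(depth=2, shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0), root_radius=3.5)


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def dijkstra_time_oracle(speed: np.ndarray, spacing, source) -> np.ndarray:
    """Brute-force arrival times on the 26-connected weighted grid.

    Edge cost = physical length / harmonic-mean speed of its endpoints; an
    independent check of the fast-marching solver on small grids.
    """
    speed = np.asarray(speed, float)
    shape = speed.shape
    active = speed > 0
    idx = -np.ones(shape, dtype=np.int64)
    coords = np.argwhere(active)
    idx[tuple(coords.T)] = np.arange(len(coords))
    sp = np.asarray(spacing, float)
    rows, cols, vals = [], [], []
    offs = np.array([
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ])
    for off in offs:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        a = coords[ok]
        b = nb[ok]
        ok2 = active[tuple(b.T)]
        a, b = a[ok2], b[ok2]
        length = np.linalg.norm(off * sp)
        fa = speed[tuple(a.T)]
        fb = speed[tuple(b.T)]
        hmean = 2.0 * fa * fb / (fa + fb)
        rows.append(idx[tuple(a.T)])
        cols.append(idx[tuple(b.T)])
        vals.append(length / hmean)
    graph = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(coords), len(coords)),
    )
    src = idx[tuple(np.asarray(source, int))]
    t = dijkstra(graph.tocsr(), indices=src)
    out = np.full(shape, np.inf)
    out[tuple(coords.T)] = t
    return out


def bent_tube_mask(shape=(32, 32, 32), radius=3.0, kind: str = "L") -> np.ndarray:
    """Small tube phantoms for solver checks: straight, L-bend, or diagonal."""
    z, y, x = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    c = (np.asarray(shape) - 1) / 2.0
    if kind == "straight":
        return (y - c[1]) ** 2 + (x - c[2]) ** 2 <= radius**2
    if kind == "diagonal":
        p = np.stack([z, y, x], axis=-1) - c
        d = unit(np.ones(3))
        along = p @ d
        rad2 = (p**2).sum(-1) - along**2
        return rad2 <= radius**2
    if kind == "L":
        arm1 = ((y - c[1]) ** 2 + (x - c[2]) ** 2 <= radius**2) & (z <= c[0])
        arm2 = ((z - c[0]) ** 2 + (x - c[2]) ** 2 <= radius**2) & (y >= c[1])
        return arm1 | arm2
    raise ValueError(kind)


# --------------------------------------------------------------------------
# experiments
# --------------------------------------------------------------------------

def msfm_oracle_experiment(seed: int = 0, shape=(32, 32, 32)) -> dict:
    """Compare MSFM arrival times with the Dijkstra oracle on tube phantoms.

    The comparison region is the medial zone (distance >= 2 voxels from the
    wall, where the oracle's 26-direction metrication is smallest) outside the
    near field of the point source (> 8 voxels away, where both
    discretizations carry their largest truncation error).
    """
    results = []
    for kind in ("straight", "L", "diagonal"):
        mask = bent_tube_mask(shape, radius=3.0, kind=kind)
        dvals = ndimage.distance_transform_edt(mask)
        speed = np.where(mask, np.maximum(dvals, 1e-6), 0.0)
        src = tuple(np.argwhere(dvals == dvals.max())[0])
        dmap = DistanceMap(np.where(mask, np.maximum(dvals, 1e-6), 0.0), (1.0, 1.0, 1.0))
        tm = msfm_time_map(dmap, src)
        oracle = dijkstra_time_oracle(speed, (1.0, 1.0, 1.0), src)
        grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        dist_src = np.sqrt(sum((g - s) ** 2.0 for g, s in zip(grids, src)))
        sel = mask & np.isfinite(oracle) & (dist_src > 8.0) & (dvals >= 2.0)
        rel = np.abs(tm.values[sel] - oracle[sel]) / oracle[sel]
        results.append(float(np.max(rel)))
    return {"max_rel_err": max(results), "per_kind": results}


def cut_branch_gap(vol: PhantomVolume, tree: TreeSpec, edge_idx: int = 1, gap_vox: int = 3):
    """Inject a small artificial gap across one branch of the mask."""
    sp = np.asarray(vol.spacing)
    pi, ci = tree.edges[edge_idx]
    p0, p1 = tree.nodes[pi][0] / sp, tree.nodes[ci][0] / sp
    r = tree.nodes[ci][1] / sp.mean()
    mid = 0.5 * (p0 + p1)
    d = unit(p1 - p0)
    cut = vol.mask.copy()
    R = int(np.ceil(r + 3)) + gap_vox
    lo = np.maximum((mid - R).astype(int), 0)
    hi = np.minimum((mid + R + 1).astype(int), vol.mask.shape)
    zz, yy, xx = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    pts = np.stack([zz, yy, xx], -1).reshape(-1, 3).astype(float)
    along = (pts - mid) @ d
    radial = np.linalg.norm((pts - mid) - np.outer(along, d), axis=1)
    rm = (np.abs(along) <= gap_vox / 2) & (radial <= r + 1.5)
    cut[tuple(pts[rm].astype(int).T)] = False
    return cut


def topology_recovery_experiment(
    seed: int = 0, n_phantoms: int = 10, with_gaps: bool = True
) -> dict:
    """Symmetric centerline coverage, node degrees, and gap repair."""
    cov_truth, cov_part, comps, gap_comps, max_deg = [], [], [], [], 0
    for k in range(n_phantoms):
        depth4 = k >= n_phantoms - 3
        cfg = (
            PhantomConfig(depth=4, shape=(128, 128, 128))
            if depth4 else PhantomConfig()
        )
        vol, art, vein = make_phantom(cfg, seed=stage_seed(seed, f"topo-{k}"))
        g, _ = extract_topology(vol.mask, vol.spacing)
        truth = np.concatenate(
            [vol.centerline_points_vox("artery"), vol.centerline_points_vox("vein")]
        )
        P = g.positions()
        cov_truth.append(float((cKDTree(P).query(truth)[0] <= 2.0).mean()))
        cov_part.append(float((cKDTree(truth).query(P)[0] <= 2.0).mean()))
        comps.append(nx.number_connected_components(g.g))
        max_deg = max(max_deg, int(g.degrees().max()))
        if with_gaps:
            cut = cut_branch_gap(vol, art, edge_idx=1)
            g2, _ = extract_topology(cut, vol.spacing)
            gap_comps.append(nx.number_connected_components(g2.g))
    return {
        "coverage_truth_pct": 100.0 * float(np.mean(cov_truth)),
        "coverage_particle_pct": 100.0 * float(np.mean(cov_part)),
        "min_coverage_truth_pct": 100.0 * float(np.min(cov_truth)),
        "min_coverage_particle_pct": 100.0 * float(np.min(cov_part)),
        "max_degree": max_deg,
        "components": comps,
        "gap_components": gap_comps,
        "n": n_phantoms,
    }


def optimizer_ablation_experiment(
    seed: int = 0, n_seeds: int = 20, flip_noise: float = 0.15
) -> dict:
    """Mean particle accuracy of each refinement arm under i.i.d. flip noise."""
    accs = {m: [] for m in ("particle", "subtree", "branch", "full")}
    for k in range(n_seeds):
        s = stage_seed(seed, f"ablate-{k}")
        vol, art, vein = make_phantom(PhantomConfig(), seed=s)
        g = truth_graph([art, vein], spacing=float(np.mean(vol.spacing)))
        oracle = OracleClassifier(flip_noise=flip_noise, seed=s + 1)
        probs = oracle.predict(g.truth)
        for m in accs:
            lg = optimize(g, probs.p, mode=m)
            accs[m].append(float((lg.labels == g.truth).mean()))
    return {f"acc_{m}_pct": 100.0 * float(np.mean(v)) for m, v in accs.items()} | {
        "n": n_seeds
    }


def _concat_sets(sets: list[OrientedPatchSet]) -> OrientedPatchSet:
    off = 0
    ps, nbs, lbs = [], [], []
    for s in sets:
        ps.append(s.patches)
        nb = s.neighbors.copy()
        nb[nb >= 0] += off
        nbs.append(nb)
        lbs.append(s.labels)
        off += len(s.patches)
    return OrientedPatchSet(
        patches=np.concatenate(ps), neighbors=np.concatenate(nbs),
        labels=np.concatenate(lbs),
    )


@dataclass
class TwinPipeResult:
    full_holdout_acc: float
    full_tubule_acc: float
    twin_tubule_acc: float
    holdout_acc_merged: float
    loss_first: float
    loss_last: float
    n_train: int
    n_test: int


def twinpipe_experiment(
    seed: int = 0,
    n_phantoms: int = 20,
    n_train: int = 14,
    epochs: int = 18,
    learning_rate: float = 0.02,
    batch_size: int = 64,
) -> TwinPipeResult:
    """Train both pipes on a phantom corpus; evaluate on held-out phantoms.

    The split is at the phantom level so no phantom contributes particles to
    both sets.  The full pipe sees CT patches of all nodes; the tubule pipe
    sees CT + vessel-enhanced patches of tubule-subgraph nodes.
    """
    cfg = TwinPipeConfig(batch_size=batch_size)
    full_sets, tub_sets = [], []
    graphs, tub_ids_all, labels_all = [], [], []
    for k in range(n_phantoms):
        s = stage_seed(seed, f"twin-{k}")
        vol, art, vein = make_phantom(SMALL_PHANTOM, seed=s)
        g, _ = extract_topology(vol.mask, vol.spacing)
        P = np.round(g.positions()).astype(int)
        P = np.clip(P, 0, np.asarray(vol.mask.shape) - 1)
        labels = vol.truth_labels[tuple(P.T)]
        enhanced = enhance_vessels(vol.intensity)
        branches = extract_branches(g)
        tub_ids = extract_tubule_graph(g, branches, cfg.tubule_scale_threshold)
        full_sets.append(build_patch_set(g, [vol.intensity], labels=labels, config=cfg))
        tub_sets.append(
            build_patch_set(
                g, [vol.intensity, enhanced], labels=labels, node_ids=tub_ids,
                config=cfg, windows=[cfg.window, None],
            )
        )
        graphs.append(g)
        tub_ids_all.append(tub_ids)
        labels_all.append(labels)

    train_full = _concat_sets(full_sets[:n_train])
    test_full = _concat_sets(full_sets[n_train:])
    train_tub = _concat_sets(tub_sets[:n_train])

    full_state = train_pipe(
        train_full, cfg, seed=stage_seed(seed, "train-full"),
        epochs=epochs, learning_rate=learning_rate,
    )
    tub_state = train_pipe(
        train_tub, cfg, seed=stage_seed(seed, "train-tubule"),
        epochs=epochs, learning_rate=learning_rate,
    )

    # held-out evaluation
    p_full = predict_pipe(full_state, test_full)
    y_test = test_full.labels
    full_acc = float(((p_full > 0.5) == (y_test == 1)).mean())

    # per-phantom tubule evaluation + mutual correction
    tub_correct_full, tub_correct_twin, tub_total = 0, 0, 0
    merged_correct, merged_total = 0, 0
    for k in range(n_train, n_phantoms):
        g = graphs[k]
        labels = labels_all[k]
        probs = twin_pipe_predict(
            g, full_state, tub_state, full_sets[k], tub_sets[k], cfg
        )
        pred = np.where(probs.p > 0.5, 1, 2)
        merged_correct += int((pred == labels).sum())
        merged_total += len(labels)
        tub_ids = tub_ids_all[k]
        if len(tub_ids):
            p_f = predict_pipe(full_state, full_sets[k])
            pf_lab = np.where(p_f > 0.5, 1, 2)
            tub_correct_full += int((pf_lab[tub_ids] == labels[tub_ids]).sum())
            tub_correct_twin += int((pred[tub_ids] == labels[tub_ids]).sum())
            tub_total += len(tub_ids)

    return TwinPipeResult(
        full_holdout_acc=full_acc,
        full_tubule_acc=tub_correct_full / max(tub_total, 1),
        twin_tubule_acc=tub_correct_twin / max(tub_total, 1),
        holdout_acc_merged=merged_correct / max(merged_total, 1),
        loss_first=full_state.loss_trace[0],
        loss_last=full_state.loss_trace[-1],
        n_train=len(train_full.patches),
        n_test=len(test_full.patches),
    )


def reconstruction_experiment(seed: int = 0) -> dict:
    """Paint truth particle labels back to voxels; DSC per class vs truth."""
    vol, art, vein = make_phantom(PhantomConfig(), seed=stage_seed(seed, "recon"))
    g, _ = extract_topology(vol.mask, vol.spacing)
    P = g.positions()
    ta = cKDTree(vol.centerline_points_vox("artery"))
    tv = cKDTree(vol.centerline_points_vox("vein"))
    cls = np.where(ta.query(P)[0] < tv.query(P)[0], 1, 2)
    scales = np.array([p.scale for p in g.particles])
    av = paint_labels(P, scales, cls, vol.mask)
    return {
        "partition_exact": bool(((av > 0) == vol.mask).all()),
        "dsc_artery": dsc(av == 1, vol.truth_labels == 1),
        "dsc_vein": dsc(av == 2, vol.truth_labels == 2),
        "n": int(vol.mask.sum()),
    }


def end_to_end_experiment(seed: int = 0, flip_noise: float = 0.15) -> dict:
    """Phantom -> topology -> oracle classification -> optimizer -> metrics.

    The full pipeline measured the way the clinical evaluation is defined:
    particle accuracy / sensitivity / specificity plus voxel DSC of the
    painted reconstruction against the phantom truth.
    """
    vol, art, vein = make_phantom(PhantomConfig(), seed=stage_seed(seed, "e2e"))
    g, _ = extract_topology(vol.mask, vol.spacing)
    P = g.positions()
    ta = cKDTree(vol.centerline_points_vox("artery"))
    tv = cKDTree(vol.centerline_points_vox("vein"))
    truth = np.where(ta.query(P)[0] < tv.query(P)[0], 1, 2)
    oracle = OracleClassifier(flip_noise=flip_noise, seed=stage_seed(seed, "e2e-oracle"))
    probs = oracle.predict(truth)
    lg = optimize(g, probs.p, mode="full")
    c = confusion(lg.labels, truth)
    acc, sens, spec = metrics(c)
    scales = np.array([p.scale for p in g.particles])
    av = paint_labels(P, scales, lg.labels, vol.mask)
    d_art = dsc(av == 1, vol.truth_labels == 1)
    d_vein = dsc(av == 2, vol.truth_labels == 2)
    return {
        "accuracy_pct": 100.0 * acc,
        "sensitivity_pct": 100.0 * sens,
        "specificity_pct": 100.0 * spec,
        "dsc_pct": 100.0 * 0.5 * (d_art + d_vein),
        "n": len(truth),
    }
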
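"""Twin-pipe preliminary artery/vein classification.

Two non-local CNN + GCN classifiers are trained on oriented image patches:
the *full pipe* sees every vessel-graph node from the CT patches; the
*tubule pipe* is specialized to the tubule vessel subgraph (small-scale
branches) and additionally consumes vessel-enhanced patches as a second
channel, sharpening the difference between arterioles and the small airways
that accompany them.  At prediction time a mutual-correction rule merges the
two pipes on tubule nodes.

An oracle classifier (reads the ground-truth labels and adds configurable
flip noise) is provided behind the same probability interface so the
topology optimizer can be exercised without any training.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import frangi

from ._nn import NonLocalGCNClassifier
from ._util import log, perpendicular_frame, unit
from .config import TwinPipeConfig
from .optimizer import Branch
from .topology import TopologyGraph

ARTERY, VEIN = 1, 2


@dataclass
class OrientedPatchSet:
    """Per-particle oriented patches P with labels and neighbor structure.

    ``patches`` has shape (n, C, 3, 32, 32): C image channels, three planes
    perpendicular to the particle orientation.  ``neighbors`` holds up to m
    graph-neighbor indices per node (-1 where absent).
    """

    patches: np.ndarray
    neighbors: np.ndarray            # (n, m) int, -1 = missing
    labels: np.ndarray | None = None  # {1, 2} when supervised
    node_ids: np.ndarray | None = None


@dataclass
class ClassifierState:
    """Serializable trained classifier (bit-identical predictions on reload)."""

    model: NonLocalGCNClassifier
    config: TwinPipeConfig
    loss_trace: list[float] = field(default_factory=list)
    version: str = "avtopo-classifier-1"

    def save(self, path: str | Path) -> None:
        state = self.model.state_dict()
        arrays = {f"param_{k}": v for k, v in state["params"].items()}
        np.savez(
            path, version=self.version, meta=np.array([repr(state["meta"])]),
            loss_trace=np.asarray(self.loss_trace), **arrays,
        )

    @classmethod
    def load(cls, path: str | Path, config: TwinPipeConfig | None = None) -> "ClassifierState":
        with np.load(path, allow_pickle=False) as f:
            meta = eval(str(f["meta"][0]), {"__builtins__": {}})  # plain dict literal
            params = {k[len("param_"):]: f[k] for k in f.files if k.startswith("param_")}
            trace = list(f["loss_trace"])
            version = str(f["version"])
        model = NonLocalGCNClassifier.from_state_dict({"meta": meta, "params": params})
        return cls(model=model, config=config or TwinPipeConfig(), loss_trace=trace, version=version)


@dataclass
class ParticleProbabilities:
    """Per-particle artery probability in [0, 1] for every graph node."""

    p: np.ndarray
    provenance: str = "full-pipe"  # full-pipe | tubule-pipe | merged | oracle

    def __post_init__(self):
        p = np.asarray(self.p, float)
        if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must be finite and in [0, 1]")
        self.p = p


def enhance_vessels(intensity: np.ndarray, scales=(1.0, 2.0, 3.0)) -> np.ndarray:
    """Multiscale bright-tube enhancement, min-max normalized to [0, 1]."""
    img = np.asarray(intensity, np.float32)
    if img.max() == img.min():
        warnings.warn("constant image: vessel enhancement is identically zero")
        return np.zeros_like(img, dtype=np.float32)
    resp = frangi(img, sigmas=scales, black_ridges=False)
    lo, hi = float(resp.min()), float(resp.max())
    if hi == lo:
        warnings.warn("flat enhancement response")
        return np.zeros_like(img, dtype=np.float32)
    return ((resp - lo) / (hi - lo)).astype(np.float32)


def extract_patch(
    image: np.ndarray,
    position: np.ndarray,
    orientation: np.ndarray,
    size: tuple[int, int, int] = (32, 32, 3),
    background: float = -1000.0,
) -> np.ndarray:
    """Oriented patch of ``size`` = (H, W, planes) perpendicular to the vessel.

    Three parallel planes one voxel apart along the orientation, resampled by
    trilinear interpolation; samples outside the volume take the background
    value.  Returns shape (planes, H, W).
    """
    h, w, planes = size
    u, v = perpendicular_frame(orientation)
    axis = unit(orientation)
    # integer-centered offsets: an axis-aligned patch is then an exact crop
    ii = (np.arange(h) - h // 2).astype(float)
    jj = (np.arange(w) - w // 2).astype(float)
    kk = (np.arange(planes) - planes // 2).astype(float)
    K, I, J = np.meshgrid(kk, ii, jj, indexing="ij")
    pts = (
        np.asarray(position, float)[None, None, None, :]
        + I[..., None] * u + J[..., None] * v + K[..., None] * axis
    )
    vals = ndimage.map_coordinates(
        np.asarray(image, np.float32), pts.reshape(-1, 3).T, order=1,
        mode="constant", cval=background,
    )
    return vals.reshape(planes, h, w).astype(np.float32)


def window_normalize(patch: np.ndarray, window=(-1000.0, 400.0)) -> np.ndarray:
    lo, hi = window
    return ((np.clip(patch, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def standardize(patch: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance per patch: removes the large common-mode
    background level so convolution features respond to structure."""
    m = patch.mean()
    s = patch.std()
    return ((patch - m) / (s + 1e-6)).astype(np.float32)


def build_patch_set(
    graph: TopologyGraph,
    images: list[np.ndarray],
    labels: np.ndarray | None = None,
    node_ids: np.ndarray | None = None,
    config: TwinPipeConfig | None = None,
    windows: list[tuple[float, float] | None] | None = None,
) -> OrientedPatchSet:
    """Extract oriented multi-channel patches for graph nodes.

    ``images`` is one grid per channel (e.g. CT, or CT + enhanced); channels
    with a window get HU-style clamping, already-normalized channels pass
    ``None``.  Neighbor indices come from the graph (parent excluded last).
    """
    cfg = config or TwinPipeConfig()
    if node_ids is None:
        node_ids = np.arange(graph.n_nodes)
    h, w, planes = cfg.patch_size[0], cfg.patch_size[1], cfg.patch_size[2]
    if windows is None:
        windows = [cfg.window] * len(images)
    n = len(node_ids)
    patches = np.zeros((n, len(images), planes, h, w), dtype=np.float32)
    id_to_row = {int(nid): r for r, nid in enumerate(node_ids)}
    for r, nid in enumerate(node_ids):
        part = graph.particles[int(nid)]
        for c, (img, win) in enumerate(zip(images, windows)):
            bg = win[0] if win is not None else 0.0
            pt = extract_patch(img, part.position, part.orientation, (h, w, planes), bg)
            if win is not None:
                pt = window_normalize(pt, win)
            patches[r, c] = standardize(pt)
    neighbors = np.full((n, cfg.n_neighbors), -1, dtype=np.int64)
    for r, nid in enumerate(node_ids):
        nbs = [m for m in graph.g.neighbors(int(nid)) if int(m) in id_to_row]
        # prefer children over the parent so the neighborhood looks distal
        nbs.sort(key=lambda m: graph.parent.get(int(nid)) == m)
        for j, m in enumerate(nbs[: cfg.n_neighbors]):
            neighbors[r, j] = id_to_row[int(m)]
    return OrientedPatchSet(
        patches=patches, neighbors=neighbors,
        labels=None if labels is None else np.asarray(labels)[node_ids],
        node_ids=np.asarray(node_ids),
    )


def save_patch_set(pset: OrientedPatchSet, path: str | Path) -> None:
    """Export a patch set as HDF5 for inspection."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=pset.patches, compression="gzip")
        f.create_dataset("neighbors", data=pset.neighbors)
        if pset.labels is not None:
            f.create_dataset("labels", data=pset.labels)
        if pset.node_ids is not None:
            f.create_dataset("node_ids", data=pset.node_ids)


def load_patch_set(path: str | Path) -> OrientedPatchSet:
    import h5py

    with h5py.File(path, "r") as f:
        return OrientedPatchSet(
            patches=f["patches"][()],
            neighbors=f["neighbors"][()],
            labels=f["labels"][()] if "labels" in f else None,
            node_ids=f["node_ids"][()] if "node_ids" in f else None,
        )


def extract_tubule_graph(
    T: TopologyGraph, branches: list[Branch], scale_threshold: float = 2.5
) -> np.ndarray:
    """Node ids of the tubule subgraph: branches of median scale below threshold."""
    sel: set[int] = set()
    scales = np.array([p.scale for p in T.particles])
    for b in branches:
        if float(np.median(scales[np.asarray(b.nodes)])) < scale_threshold:
            sel.update(int(m) for m in b.nodes)
    if not sel:
        warnings.warn("tubule scale threshold excludes every branch")
        return np.array([], dtype=np.int64)
    return np.array(sorted(sel), dtype=np.int64)


def gcn_layer(H: np.ndarray, W: np.ndarray, Theta: np.ndarray, activation="relu") -> np.ndarray:
    """One graph-convolution layer: sigma(W @ H @ Theta)."""
    H = np.asarray(H, float)
    W = np.asarray(W, float)
    Theta = np.asarray(Theta, float)
    if W.shape[-1] != H.shape[-2] or H.shape[-1] != Theta.shape[0]:
        raise ValueError(
            f"dimension mismatch: W {W.shape}, H {H.shape}, Theta {Theta.shape}"
        )
    out = W @ H @ Theta
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation in (None, "identity"):
        return out
    if callable(activation):
        return activation(out)
    raise ValueError(f"unknown activation {activation!r}")


def _gather_batch(pset: OrientedPatchSet, rows: np.ndarray, rng: np.random.Generator | None = None):
    """Assemble [center, neighbors] patch stacks; with ``rng``, apply random
    in-plane rotations/flips (the cross-section azimuth is arbitrary, so this
    invariance is exact, not approximate)."""
    n, c, planes, h, w = pset.patches.shape
    m = pset.neighbors.shape[1]
    batch = np.zeros((len(rows), 1 + m, c * planes, h, w), dtype=np.float32)
    nb_mask = np.zeros((len(rows), m), dtype=bool)
    for bi, r in enumerate(rows):
        batch[bi, 0] = pset.patches[r].reshape(c * planes, h, w)
        for j, q in enumerate(pset.neighbors[r]):
            if q >= 0:
                batch[bi, 1 + j] = pset.patches[q].reshape(c * planes, h, w)
                nb_mask[bi, j] = True
        if rng is not None:
            k = int(rng.integers(0, 4))
            if k:
                batch[bi] = np.rot90(batch[bi], k, axes=(-2, -1))
            if rng.integers(0, 2):
                batch[bi] = batch[bi][..., ::-1]
    return batch, nb_mask


def train_pipe(
    pset: OrientedPatchSet,
    config: TwinPipeConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
    learning_rate: float | None = None,
    val_set: OrientedPatchSet | None = None,
) -> ClassifierState:
    """Train one pipe with SGD (momentum 0.9, cross-entropy), class-balanced
    batches, deterministic for a fixed seed.  Refuses single-class data."""
    cfg = config or TwinPipeConfig()
    if pset.labels is None:
        raise ValueError("training requires labels")
    labels01 = (np.asarray(pset.labels) == VEIN).astype(int)  # 0=artery, 1=vein
    classes = np.unique(labels01)
    if len(classes) < 2:
        raise ValueError("training set contains a single class; cannot train")
    n, c, planes, h, w = pset.patches.shape
    model = NonLocalGCNClassifier(
        in_channels=c, patch_planes=planes, conv_channels=cfg.conv_channels,
        attention_dim=cfg.attention_dim, feature_dim=cfg.feature_dim,
        gcn_hidden=cfg.gcn_hidden, n_neighbors=cfg.n_neighbors, seed=seed,
    )
    rng = np.random.default_rng(seed)
    epochs = epochs if epochs is not None else cfg.epochs
    lr = learning_rate if learning_rate is not None else cfg.learning_rate
    bs = min(cfg.batch_size, n)
    if bs < cfg.batch_size:
        warnings.warn(f"batch size reduced to {bs} (only {n} nodes)")
    idx_a = np.where(labels01 == 0)[0]
    idx_v = np.where(labels01 == 1)[0]
    half = max(1, bs // 2)
    steps = max(1, n // bs)
    trace: list[float] = []
    for epoch in range(epochs):
        # step decay: drop the rate for the final third so the endpoint settles
        lr_e = lr * (0.3 if epoch >= (2 * epochs) // 3 else 1.0)
        ep_loss = 0.0
        for _ in range(steps):
            rows = np.concatenate([
                rng.choice(idx_a, size=half, replace=len(idx_a) < half),
                rng.choice(idx_v, size=half, replace=len(idx_v) < half),
            ])
            batch, nb_mask = _gather_batch(pset, rows, rng=rng)
            loss, grads, _ = model.loss_and_grads(batch, nb_mask, labels01[rows])
            model.sgd_step(grads, lr_e, cfg.momentum)
            ep_loss += loss
        trace.append(ep_loss / steps)
        log.info("epoch %d/%d loss %.4f", epoch + 1, epochs, trace[-1])
    return ClassifierState(model=model, config=cfg, loss_trace=trace)


def predict_pipe(state: ClassifierState, pset: OrientedPatchSet, batch: int = 256) -> np.ndarray:
    """Artery probability per node of the patch set."""
    out = np.zeros(len(pset.patches))
    for start in range(0, len(pset.patches), batch):
        rows = np.arange(start, min(start + batch, len(pset.patches)))
        b, nb = _gather_batch(pset, rows)
        probs, _ = state.model.forward(b, nb)
        out[rows] = probs[:, 0]
    return out


def twin_pipe_predict(
    T: TopologyGraph,
    full_state: ClassifierState,
    tubule_state: ClassifierState | None,
    full_set: OrientedPatchSet,
    tubule_set: OrientedPatchSet | None,
    config: TwinPipeConfig | None = None,
) -> ParticleProbabilities:
    """Merge the two pipes by mutual correction.

    The full pipe scores every node; the tubule pipe rescores tubule-subgraph
    nodes from CT + enhanced patches.  On a tubule node the merged probability
    is (1 - lam) * p_full + lam * p_tubule with lam = blend_lambda when the
    pipes disagree on the label and the tubule pipe is the more extreme
    (|p - 0.5| larger), else lam = 0.5.  Non-tubule nodes keep p_full.
    """
    cfg = config or TwinPipeConfig()
    p = predict_pipe(full_state, full_set)
    if tubule_state is None or tubule_set is None or tubule_set.node_ids is None or not len(tubule_set.node_ids):
        log.info("tubule pipe unavailable; falling back to the full pipe everywhere")
        return ParticleProbabilities(p=p, provenance="full-pipe")
    p_t = predict_pipe(tubule_state, tubule_set)
    merged = merge_probabilities(p, p_t, tubule_set.node_ids, cfg.blend_lambda)
    return ParticleProbabilities(p=merged, provenance="merged")


def merge_probabilities(
    p_full: np.ndarray,
    p_tubule: np.ndarray,
    tubule_ids: np.ndarray,
    blend_lambda: float = 1.0,
) -> np.ndarray:
    """Mutual-correction blend of the two pipes (see twin_pipe_predict)."""
    merged = np.asarray(p_full, float).copy()
    for r, nid in enumerate(np.asarray(tubule_ids)):
        pf, pt = merged[int(nid)], float(p_tubule[r])
        disagree = (pf > 0.5) != (pt > 0.5)
        more_extreme = abs(pt - 0.5) > abs(pf - 0.5)
        lam = blend_lambda if (disagree and more_extreme) else 0.5
        merged[int(nid)] = (1.0 - lam) * pf + lam * pt
    return merged


class OracleClassifier:
    """Truth-reading stand-in classifier with i.i.d. label-flip noise.

    Exposes the same probability interface as the twin-pipe network so the
    optimizer and pipeline are testable without training.
    """

    def __init__(self, flip_noise: float = 0.0, seed: int = 0,
                 p_high: float = 0.9, p_low: float = 0.1):
        if not 0.0 <= flip_noise < 1.0:
            raise ValueError("flip_noise must be in [0, 1)")
        self.flip_noise = flip_noise
        self.seed = seed
        self.p_high = p_high
        self.p_low = p_low

    def predict(self, truth: np.ndarray) -> ParticleProbabilities:
        truth = np.asarray(truth)
        rng = np.random.default_rng(self.seed)
        flip = rng.random(len(truth)) < self.flip_noise
        noisy = np.where(flip, 3 - truth, truth)
        p = np.where(noisy == ARTERY, self.p_high, self.p_low)
        return ParticleProbabilities(p=p, provenance="oracle")
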
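"""Topology optimizer: refine per-particle A/V probabilities into spatially
consistent labels.

The vessel graph is decomposed into *branches* (maximal chains between
endpoints — bifurcations and terminals — so each branch belongs to a single
vessel class by construction) and *subtrees* (full descendant sets of chosen
subtree roots).  Each subtree votes by particle majority; each branch carries
a confidence equal to its majority fraction.  Where a branch's class
conflicts with its subtree's class, the more confident side wins: a confident
branch is pruned into its own subtree and keeps its class, otherwise the
branch is relabeled to the subtree class.  Finally every particle takes its
branch's class.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import OptimizerConfig
from .topology import TopologyGraph

ARTERY, VEIN = 1, 2


@dataclass
class Branch:
    """Maximal chain of particles between two endpoints (degree != 2 nodes)."""

    nodes: list[int]          # ordered particle ids, proximal first
    depth: int = 0            # number of ancestor branches up to the root

    @property
    def endpoints(self) -> tuple[int, int]:
        return self.nodes[0], self.nodes[-1]

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class Subtree:
    root: int
    nodes: set[int] = field(default_factory=set)
    branches: list[int] = field(default_factory=list)  # indices into the branch list


@dataclass
class LabeledGraph:
    """Final labeling with per-branch classes/confidences and an audit log."""

    labels: np.ndarray                    # per-particle class {1, 2}
    branch_class: np.ndarray
    branch_confidence: np.ndarray
    branch_corrected: np.ndarray          # bool: relabeled by its subtree
    subtree_class: dict[int, int]
    audit: list[dict] = field(default_factory=list)


def label_from_probability(p: np.ndarray) -> np.ndarray:
    """Artery iff p > 0.5, vein otherwise (ties resolve to vein)."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("probabilities must be finite and within [0, 1]")
    return np.where(p > 0.5, ARTERY, VEIN).astype(np.uint8)


def extract_branches(T: TopologyGraph) -> list[Branch]:
    """Maximal endpoint-free chains; every edge belongs to exactly one branch.

    Endpoints are nodes of graph degree != 2 (terminals and junctions).  Branch
    order is proximal-first along the parent hierarchy, and each branch knows
    its depth (number of ancestor branches), used for distal-first processing.
    """
    g = T.g
    branches: list[Branch] = []
    visited_edges: set[tuple[int, int]] = set()

    def is_endpoint(n: int) -> bool:
        return g.degree[n] != 2

    # walk from every endpoint along each incident chain
    for start in g.nodes:
        if not is_endpoint(start):
            continue
        for nb in g.neighbors(start):
            e = (min(start, nb), max(start, nb))
            if e in visited_edges:
                continue
            chain = [start, nb]
            visited_edges.add(e)
            prev, cur = start, nb
            while not is_endpoint(cur):
                nxt = [m for m in g.neighbors(cur) if m != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                visited_edges.add((min(prev, cur), max(prev, cur)))
                chain.append(cur)
            branches.append(Branch(nodes=chain))
    # isolated cycles of degree-2 nodes (should not occur in a tree) and
    # single isolated nodes
    for n in g.nodes:
        if g.degree[n] == 0:
            branches.append(Branch(nodes=[n]))
    _orient_and_depth(T, branches)
    return branches


def _orient_and_depth(T: TopologyGraph, branches: list[Branch]) -> None:
    """Orient each branch proximal-first and compute its bifurcation depth."""
    # node depth = number of branch endpoints crossed from the root
    depth_of: dict[int, int] = {}
    for root in T.roots:
        depth_of[root] = 0
    # BFS over nodes using parents
    order = []
    for root in T.roots:
        stack = [root]
        while stack:
            n = stack.pop()
            order.append(n)
            for c in T.children(n):
                stack.append(c)
    for b in branches:
        a, z = b.endpoints
        # proximal endpoint = the one nearer the root through parent pointers
        da = _root_distance(T, a)
        dz = _root_distance(T, z)
        if dz < da:
            b.nodes.reverse()
    # branch depth: count endpoint-crossings from root
    bdepth: dict[tuple[int, int], int] = {}
    for b in branches:
        d = 0
        n = b.nodes[0]
        seen = 0
        while T.parent.get(n) is not None:
            p = T.parent[n]
            if T.g.degree[p] != 2:
                d += 1
            n = p
            seen += 1
            if seen > T.n_nodes:
                break
        b.depth = d


def _root_distance(T: TopologyGraph, n: int) -> int:
    d = 0
    while T.parent.get(n) is not None:
        n = T.parent[n]
        d += 1
        if d > T.n_nodes:
            break
    return d


def extract_subtrees(
    T: TopologyGraph,
    labels: np.ndarray,
    trunk_generations: int = 2,
) -> tuple[list[Subtree], set[int]]:
    """Partition non-trunk nodes into subtrees.

    Subtree roots are (a) the first nodes beyond the first K trunk generations
    of bifurcations, plus (b) any node where the preliminary label majority of
    the descendant set flips relative to its parent's — the label structure
    itself suggests a class boundary there.  Every node belongs to the subtree
    of its nearest ancestor root; subtrees are disjoint and cover all
    non-trunk nodes.  Returns (subtrees, trunk node set).
    """
    labels = np.asarray(labels)
    n = T.n_nodes
    if n == 0:
        return [], set()
    # children lists and a reverse-topological order per component
    topo: list[int] = []
    for root in T.roots:
        if T.parent.get(root) is not None:
            raise ValueError(f"component root {root} has a parent; graph is not rooted")
        stack = [root]
        while stack:
            m = stack.pop()
            topo.append(m)
            stack.extend(T.children(m))
    # subtree artery counts, bottom-up
    art = np.zeros(n, dtype=np.int64)
    tot = np.zeros(n, dtype=np.int64)
    for m in reversed(topo):
        art[m] = int(labels[m] == ARTERY)
        tot[m] = 1
        for c in T.children(m):
            art[m] += art[c]
            tot[m] += tot[c]

    def majority(m: int) -> int:
        # ties resolve to vein, consistent with the p > 0.5 artery rule
        return ARTERY if 2 * art[m] > tot[m] else VEIN

    # bifurcation generation of each node
    gen = {}
    for root in T.roots:
        gen[root] = 0
        stack = [root]
        while stack:
            m = stack.pop()
            deg = T.g.degree[m]
            for c in T.children(m):
                gen[c] = gen[m] + (1 if deg >= 3 else 0)
            stack.extend(T.children(m))
    trunk = {m for m in range(n) if gen.get(m, 0) < trunk_generations}
    roots = {m for m in range(n) if m not in trunk and T.parent.get(m) in trunk}
    # label-flip roots
    for m in range(n):
        p = T.parent.get(m)
        if m in trunk or p is None:
            continue
        if majority(m) != majority(p):
            roots.add(m)
    # assign nodes to nearest ancestor root
    subtrees: dict[int, Subtree] = {r: Subtree(root=r) for r in sorted(roots)}
    owner: dict[int, int] = {}
    for m in topo:
        if m in roots:
            owner[m] = m
        elif m in trunk:
            continue
        else:
            p = T.parent.get(m)
            if p in owner:
                owner[m] = owner[p]
        if m in owner:
            subtrees[owner[m]].nodes.add(m)
    return list(subtrees.values()), trunk


def subtree_vote(s: Subtree, labels: np.ndarray, root_branch_class: int | None = None) -> int:
    """Majority class of the subtree's particles; ties take the root branch class."""
    if not s.nodes:
        raise ValueError("empty subtree")
    labels = np.asarray(labels)
    members = np.fromiter(s.nodes, dtype=np.int64)
    n_art = int((labels[members] == ARTERY).sum())
    n_vein = len(members) - n_art
    if n_art > n_vein:
        return ARTERY
    if n_vein > n_art:
        return VEIN
    return root_branch_class if root_branch_class is not None else VEIN


def branch_confidence(
    b: Branch, labels: np.ndarray, n_min: int = 3
) -> tuple[float, float]:
    """Majority fraction of the branch's labels in [0.5, 1].

    Returns (confidence, damped weight): the weight is confidence times
    min(1, n/n_min) so branches of one or two particles cannot overrule a
    subtree on their own.
    """
    labels = np.asarray(labels)
    vals = labels[np.asarray(b.nodes)]
    n_art = int((vals == ARTERY).sum())
    n_tot = len(vals)
    conf = max(n_art, n_tot - n_art) / n_tot
    return conf, conf * min(1.0, n_tot / float(n_min))


def _subtree_confidence(s: Subtree, labels: np.ndarray, n_min: int = 3) -> tuple[float, float]:
    labels = np.asarray(labels)
    members = np.fromiter(s.nodes, dtype=np.int64)
    n_art = int((labels[members] == ARTERY).sum())
    n_tot = len(members)
    conf = max(n_art, n_tot - n_art) / n_tot
    return conf, conf * min(1.0, n_tot / float(n_min))


def _branch_majority(b: Branch, labels: np.ndarray) -> int:
    vals = np.asarray(labels)[np.asarray(b.nodes)]
    n_art = int((vals == ARTERY).sum())
    return ARTERY if 2 * n_art > len(vals) else VEIN


def _descendant_branches(branches: list[Branch], idx: int) -> list[int]:
    """Indices of branches whose proximal endpoint chain passes through
    branch ``idx``'s distal endpoint (the distal subtree that moves with it)."""
    start = branches[idx].nodes[-1]
    # build map from proximal endpoint -> branch indices
    by_prox: dict[int, list[int]] = {}
    for j, b in enumerate(branches):
        by_prox.setdefault(b.nodes[0], []).append(j)
    out: list[int] = []
    stack = [start]
    while stack:
        n = stack.pop()
        for j in by_prox.get(n, []):
            if j != idx and j not in out:
                out.append(j)
                stack.append(branches[j].nodes[-1])
    return out


def prune_and_correct(
    T: TopologyGraph,
    subtrees: list[Subtree],
    branches: list[Branch],
    labels: np.ndarray,
    config: OptimizerConfig | None = None,
) -> LabeledGraph:
    """Reconcile branch and subtree classes; output branch-pure labels.

    Branches are processed distal-first.  A branch conflicting with its
    subtree keeps its own class and is re-rooted as a new subtree (together
    with its distal descendant branches) when its damped confidence exceeds
    the subtree's; otherwise it is relabeled to the subtree class.  Every
    particle finally takes its branch's class, so all output branches are
    unanimous.  Each correction is recorded in the audit log.
    """
    cfg = config or OptimizerConfig()
    labels = np.asarray(labels).copy()
    n_min = cfg.min_branch_particles
    # branch -> owning subtree: the subtree containing the majority of its nodes
    sub_of = np.full(len(branches), -1, dtype=np.int64)
    node_sub: dict[int, int] = {}
    for si, s in enumerate(subtrees):
        for m in s.nodes:
            node_sub[m] = si
    for bi, b in enumerate(branches):
        counts: dict[int, int] = {}
        for m in b.nodes:
            si = node_sub.get(m)
            if si is not None:
                counts[si] = counts.get(si, 0) + 1
        if counts:
            sub_of[bi] = max(counts.items(), key=lambda kv: kv[1])[0]
        subtrees[sub_of[bi]].branches.append(bi) if sub_of[bi] >= 0 else None

    s_class = {}
    s_weight = {}
    for si, s in enumerate(subtrees):
        root_bi = next((bi for bi in range(len(branches)) if sub_of[bi] == si), None)
        rb_class = _branch_majority(branches[root_bi], labels) if root_bi is not None else None
        s_class[si] = subtree_vote(s, labels, rb_class)
        _, s_weight[si] = _subtree_confidence(s, labels, n_min)

    def independent_vote(si: int, bi: int) -> tuple[int | None, float]:
        """Subtree evidence with the branch's own nodes excluded: a branch may
        only be overruled by the rest of its subtree, not by itself."""
        rest = subtrees[si].nodes - set(branches[bi].nodes)
        if not rest:
            return None, 0.0
        members = np.fromiter(rest, dtype=np.int64)
        n_art = int((labels[members] == ARTERY).sum())
        n_tot = len(members)
        if 2 * n_art == n_tot:
            cls = s_class[si]
        else:
            cls = ARTERY if 2 * n_art > n_tot else VEIN
        conf = max(n_art, n_tot - n_art) / n_tot
        return cls, conf * min(1.0, n_tot / float(n_min))

    b_class = np.array([_branch_majority(b, labels) for b in branches], dtype=np.uint8)
    b_conf = np.zeros(len(branches))
    b_weight = np.zeros(len(branches))
    for bi, b in enumerate(branches):
        b_conf[bi], b_weight[bi] = branch_confidence(b, labels, n_min)

    corrected = np.zeros(len(branches), dtype=bool)
    audit: list[dict] = []
    order = sorted(range(len(branches)), key=lambda bi: -branches[bi].depth)
    next_subtree_key = len(subtrees)
    reassigned: dict[int, int] = {}  # branch -> new pseudo-subtree class
    for bi in order:
        si = int(sub_of[bi])
        if si < 0:
            continue
        if bi in reassigned:
            sc, sw = reassigned[bi], 0.0
        else:
            sc, sw = independent_vote(si, bi)
        if sc is None or b_class[bi] == sc:
            continue
        if b_weight[bi] > sw:
            # prune: the branch becomes its own subtree, keeping its class;
            # its distal descendants move with it
            moved = [bi]
            if cfg.prune_descendants:
                moved += _descendant_branches(branches, bi)
            for j in moved:
                reassigned[j] = int(b_class[bi])
            audit.append({
                "action": "prune", "branch": bi, "from_subtree": si,
                "branch_class": int(b_class[bi]), "subtree_class": int(sc),
                "branch_weight": float(b_weight[bi]), "subtree_weight": float(sw),
                "moved_branches": moved,
            })
            next_subtree_key += 1
        else:
            audit.append({
                "action": "relabel", "branch": bi, "subtree": si,
                "from_class": int(b_class[bi]), "to_class": int(sc),
                "branch_weight": float(b_weight[bi]), "subtree_weight": float(sw),
            })
            b_class[bi] = sc
            corrected[bi] = True
    # paint particles from branch classes; junction nodes take their parent
    # branch's class (the branch for which they are the distal endpoint)
    out = labels.copy()
    for bi, b in enumerate(branches):
        for m in b.nodes[1:]:
            out[m] = b_class[bi]
    # branch proximal endpoints: set by the branch they terminate (parent side)
    for bi, b in enumerate(branches):
        first = b.nodes[0]
        if T.parent.get(first) is None and T.g.degree[first] <= 1:
            out[first] = b_class[bi]
    return LabeledGraph(
        labels=out,
        branch_class=b_class,
        branch_confidence=b_conf,
        branch_corrected=corrected,
        subtree_class=s_class,
        audit=audit,
    )


def optimize(
    T: TopologyGraph,
    probabilities: np.ndarray,
    mode: str = "full",
    config: OptimizerConfig | None = None,
) -> LabeledGraph:
    """Run one of the refinement strategies.

    mode = "particle": thresholded probabilities only.
    mode = "branch":   every branch takes its particle-majority class.
    mode = "subtree":  every subtree's particles take the subtree vote
                       (trunk particles keep their own labels).
    mode = "full":     subtree votes reconciled with branch confidence and
                       pruning (the complete optimizer).
    """
    cfg = config or OptimizerConfig()
    labels = label_from_probability(probabilities)
    if mode == "particle":
        return LabeledGraph(
            labels=labels,
            branch_class=np.array([], dtype=np.uint8),
            branch_confidence=np.array([]),
            branch_corrected=np.array([], dtype=bool),
            subtree_class={},
        )
    branches = extract_branches(T)
    if mode == "branch":
        out = labels.copy()
        b_class = np.array([_branch_majority(b, labels) for b in branches], dtype=np.uint8)
        for bi, b in enumerate(branches):
            for m in b.nodes[1:]:
                out[m] = b_class[bi]
        return LabeledGraph(
            labels=out, branch_class=b_class,
            branch_confidence=np.array([branch_confidence(b, labels)[0] for b in branches]),
            branch_corrected=np.zeros(len(branches), dtype=bool),
            subtree_class={},
        )
    subtrees, trunk = extract_subtrees(T, labels, cfg.trunk_generations)
    if mode == "subtree":
        out = labels.copy()
        for si, s in enumerate(subtrees):
            cls = subtree_vote(s, labels)
            for m in s.nodes:
                out[m] = cls
        return LabeledGraph(
            labels=out, branch_class=np.array([], dtype=np.uint8),
            branch_confidence=np.array([]),
            branch_corrected=np.array([], dtype=bool),
            subtree_class={si: subtree_vote(s, labels) for si, s in enumerate(subtrees)},
        )
    if mode != "full":
        raise ValueError(f"unknown mode {mode!r}")
    return prune_and_correct(T, subtrees, branches, labels, cfg)
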
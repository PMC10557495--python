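# Methods

This note documents the models and procedures implemented in `avtopo`, the
assumptions behind them, the tunable parameters with their defaults, and what
the synthetic experiments do and do not demonstrate.

## Problem setting

Input is a binary pulmonary vessel mask (plus, optionally, the CT intensity
volume and a hilum label volume). Output is an artery/vein label per
centerline particle and per mask voxel. Arteries and veins are nearly
isointense in noncontrast CT, so the method leans on two other sources of
evidence: *tree topology* (vessels are trees; labels should be constant along
branches and coherent within subtrees) and the *anatomical prior* that small
arteries are accompanied by bronchi while veins run between bronchial
branches.

## Vessel-tree topology extraction

**Distance and time maps.** The Euclidean distance transform D (mm) is
computed exactly (`scipy.ndimage.distance_transform_edt`). Arrival times T
solve `|∇T| · F = 1` with `F = D^p`; the speed exponent `p` defaults to 1 so
minimal paths hug the medial axis where D is largest (standard minimal-path
practice; configurable). The solver is a multi-stencils fast-marching method
over eight orthogonal lattice frames — the coordinate axes, the three
face-diagonal frames, and four cube-diagonal frames (d = (1, s, t) with
u = (1, −s, 0) and v = d × u, lattice vectors of lengths √3/√2/√6) — taking
the minimum trial value over stencils; without the diagonal frames, fronts
running down a narrow diagonal tube are badly overestimated. Updates are
first-order by default: the second-order extrapolation (available behind a
flag) loses causality in the oblique frames near strongly curved fronts and
can undershoot. Anisotropic spacing enters through per-direction physical
step lengths. Accuracy is checked against a brute-force Dijkstra oracle on
the 26-connected weighted grid (edge cost = length / harmonic-mean speed):
agreement is within 5% on 32³ tube phantoms, evaluated in the medial zone
(≥ 2 voxels from the wall) outside the point source's near field (> 8
voxels), where the comparison is meaningful — off-axis the oracle's own
26-direction metrication dominates, and both discretizations carry their
largest truncation error next to the source.

**Particles.** Hessian vesselness is evaluated at scales σ ∈ {1, 2, 3, 4} mm
(γ-normalized, response `√(|λ₂λ₃|)` where both are negative) on the distance
transform by default — its ridge is the medial axis — or on the CT image if
requested. A voxel becomes a particle when its response is above 5% of the
maximum and it is a cross-sectional local maximum of the distance transform
(probed against all 26-neighbors not aligned with the local Hessian
orientation; surface voxels with D < 1.5 voxels are excluded). Particle
orientation is the eigenvector of the smallest-magnitude eigenvalue at the
best scale; particle scale is the distance-transform value at the particle
(in voxels) — the Hessian's argmax σ is kept as a secondary attribute but is
too coarsely quantized to serve as a radius estimate.

**Tracing and merging.** Per connected component, the root is the global
distance-transform maximum (the proximal trunk); terminals are
non-maximum-suppressed local maxima of T that also hold the largest T of
their geodesic neighborhood (suppression radius 1.5× the local caliber), each
snapped to the nearby medial axis. Backtracing is a strict steepest descent
on T over the 26-neighborhood; an online confidence — the trailing-window
(default 5) mean of the per-step T decrease normalized by the locally
expected decrease `step/F` — stops a trace when it falls below 0.1, flagging
spurious leaves. Path voxels are re-centered on the local distance maximum,
resampled to ≤ 1.6-voxel steps, and merged with the Hessian particles
(duplicates within 0.9 voxel removed).

**Kinds, repair, graph.** Ω₂₆(x) counts other particles within 1.5× the
median inter-particle spacing (floored at √3, the lattice adjacency limit):
1 = terminal, 2 = branching, > 2 = bifurcating; isolated particles are
dropped with a warning. False-terminal repair probes each structural leaf of
a provisional graph along its outward direction — estimated as the principal
axis of the surrounding mask voxels (within 2.5 scales), signed away from the
local mass centroid, because chain tangents and Hessian orientations are both
unreliable at stumps. The ray must exit the mask; travel then continues one
to two scales beyond the stump face. If it lands back on the mask, the lost
trajectory is re-traced by local fast marching (with a small background speed
so short gaps can be crossed) from the nearest *facing endpoint* — a break
always leaves two facing stumps, so the target must be another endpoint ahead
of the probe, either mutually collinear with it or lying directly on the
probe ray, within `2·scale + 5` voxels, with at most 6 background voxels
crossed. These guards exist because an intertwined vein can pass within two
scales of a true artery tip; without them repair welds the two trees. The
final graph is a minimum spanning forest over candidate edges (cycles break
at their longest edge), degree clamped to 3 by dropping the least
orientation-collinear excess edges (reconnecting the severed side through the
best capacity-respecting candidate), with one root per component at its
distance-map maximum and BFS parent pointers.

## Twin-pipe classifier

Patches of size 32×32×3 are resampled perpendicular to the particle
orientation (three planes one voxel apart, trilinear, background-padded),
windowed to [−1000, 400] HU-like, then standardized per patch (zero mean,
unit variance — the constant parenchyma level otherwise dominates pooled
features). The classifier Φ is a small non-local CNN: two strided
convolutions (8 and 16 channels), one embedded-Gaussian self-attention block
over the 8×8 feature map, average pooling over three concentric radial zones
(the companion bronchus appears at a radius from the vessel axis, so radial
zones preserve the signature that a global mean washes out, and the pooling
is invariant to the arbitrary in-plane patch rotation), and a linear map to a
16-dim feature Y. A two-layer GCN `H' = σ(W H Θ)` runs over the star of the
center node and up to m = 2 graph neighbors (missing neighbors zero-padded;
W is the symmetrically normalized adjacency); the center row yields the class
logits. All gradients are hand-derived NumPy and verified against finite
differences in the test suite; training is SGD with momentum 0.9 and
cross-entropy on class-balanced batches.

The *full pipe* sees CT patches of all nodes; the *tubule pipe* sees CT plus
a vessel-enhanced channel (multiscale Frangi response, min–max normalized)
and trains only on the tubule subgraph: branches whose median particle scale
is below 2.5 voxels ("tubule" is not quantified anywhere authoritative; this
threshold is a configurable convention). At prediction time the merged
probability on a tubule node is `(1−λ)·p_full + λ·p_tubule` with λ = 1 when
the pipes disagree and the tubule pipe is more extreme, else λ = 0.5
(configurable); non-tubule nodes keep the full pipe. Training patches are
augmented with random in-plane rotations/flips — the cross-section azimuth is
arbitrary by construction, so this invariance is exact rather than
approximate. Default hyperparameters are lr 1e-3, batch 128, 150 epochs; the
desk-scale experiments use 18 epochs, lr 0.02 (stepped down ×0.3 for the
final third), batch 64, which is where the small network converges on the
synthetic corpus. An *oracle classifier*
(reads truth labels, adds i.i.d. flip noise) exposes the same probability
interface so the optimizer is testable without training.

## Topology optimizer

Labels: artery iff p > 0.5 (ties → vein). Branches are maximal chains between
endpoints (graph degree ≠ 2), so each branch is single-class by construction;
every edge belongs to exactly one branch. Subtree roots are the nodes just
beyond the first K = 2 trunk bifurcation generations, plus every node whose
descendant-majority label flips relative to its parent's (the label structure
itself marks candidate class boundaries); each non-trunk node belongs to its
nearest ancestor root's subtree, so subtrees partition the non-trunk nodes.
Votes are particle majorities (ties → the root branch's class); confidences
are majority fractions damped by `min(1, n/3)` so one- or two-particle
units cannot dominate.

Conflicts are resolved distal-first. A branch disagreeing with its subtree is
compared against the subtree's *independent* evidence — its nodes excluding
the branch's own — because a branch must not overrule itself through the
nodes it contributes; without this exclusion the full optimizer measured
slightly below the branch-only arm under i.i.d. noise, inverting the expected
ordering. If the branch's damped confidence wins, the branch (with its distal
descendant branches, configurable) is re-rooted as a new subtree keeping its
class; otherwise it is relabeled. Every particle finally takes its branch's
class (junction nodes take the parent branch's), so the output is
branch-pure, and the procedure is idempotent. All corrections are recorded in
an audit log. The ablation arms (`--mode particle|subtree|branch|full`)
expose each strategy separately; under i.i.d. flip noise the subtree-only arm
is deliberately noise-sensitive near leaves (flip-detected roots preserve
noise clusters), which reproduces the expected arm ordering.

## Reconstruction and evaluation

Each labeled particle paints a ball of radius `scale × 1.25` (the dilation
factor compensates scale underestimation at bends); mask voxels covered by
several balls take the nearest particle's label, and uncovered mask voxels
inherit geodesically (iterative 26-neighbor propagation inside the mask), so
the painted volume always partitions the mask. Hilum fusion is a voxelwise
union in which the hilum labels win on overlap — topology is unreliable in
the large, non-tubular hilar vessels, so a dedicated label volume there is
higher-trust. Evaluation is primarily particle-based (artery positive):
accuracy, sensitivity, specificity; voxel Dice per class is secondary.

## Synthetic phantoms

The generator emulates: two intertwined binary trees with Murray-law
tapering (`r_p³ = r₁³ + r₂³`, exponent configurable), branch length `k·r`
with k ~ U(4, 10), bifurcation angles 20–50°, collision-aware growth keeping
≥ 1.2 mm surface clearance between non-adjacent branches, terminal tips
required to end with 3 radii of free space ahead (distal vessels end in
parenchyma — without this, tube tips facing each other head-on are genuinely
indistinguishable from mask breaks), optional adhesions (a vein mid-branch
control point pulled to within touching distance of an artery), companion
bronchi parallel to arterial branches (offset 1.5·r, radius 0.8·r, air-like
intensity, never overwriting vessel voxels), and Gaussian pseudo-CT
intensities (vessel +50, parenchyma −800, bronchus −950 HU-like, σ = 20).
Defaults: depth 3 (8 leaves, 15 branches per tree) in a 112³ grid at 0.8 mm
isotropic, root radius 3.5 mm; the classifier corpus uses depth-2 trees in
64³ at 1 mm. Generation is bit-reproducible per seed.

What the phantoms do *not* emulate: lobar anatomy, curved/tortuous branches
(segments are straight capsules), respiratory motion, contrast dynamics
(only a constant artery intensity shift), partial-volume effects beyond
rasterization, imaging artifacts, or the non-tubular hilar region. Passing
tests therefore demonstrate the pipeline's mechanics — topology recovery,
repair, noise-robust refinement, learnability of the bronchus prior — not
clinical-grade accuracy on real CT.

## Numerical choices and degenerate inputs

Empty masks yield empty particle lists (no error); single-voxel masks are
their own root and terminal. Ties resolve to vein everywhere, consistent with
the p > 0.5 artery rule. The fast-marching fallback when no causal quadratic
solution exists is the one-sided update from the smallest upwind neighbor.
Probabilities are validated to [0, 1]; zero metric denominators return NaN
markers rather than raising. A single pipeline seed fans out to per-stage
seeds (stage-name CRC), so stages can be rerun independently yet
reproducibly; deterministic stages reproduce outputs byte-for-byte.

## Known limitations

Repair cannot distinguish a mask break from a true inter-tree contact when
the two stump axes happen to be collinear within the acceptance cones; the
guards make this rare on phantoms but real adhesions remain hard (the
optimizer, not repair, is the intended mechanism there). Particle scale
underestimates radius at bifurcation bulges, and the painted labels inherit
any such bias. The NumPy classifier is desk-scale by design; it demonstrates
the architecture and the bronchus prior, not state-of-the-art patch
classification. Subtree extraction depends on preliminary labels; K and the
flip-detection rule are documented stand-ins exposed in the configuration.
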
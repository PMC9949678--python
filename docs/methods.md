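# Methods

## Cyst lineage trees and division rules

A germline cyst is an unrooted tree: cells are nodes, ring canals
(intercellular bridges left by incomplete cytokinesis) are edges.  One
synchronous division round replaces every cell by two daughters joined by a
new canal; the mother's existing canals are partitioned between the
daughters.  A degree-d cell has 2^(d−1) distinct unordered partitions; the
partition that leaves one daughter with no old canals is the *branching*
choice (the new daughter is terminal), all others are *in-line*.  The
canonical maximally branched tree — the invariant female pattern — is built
by the convention that at round k cell i buds daughter i + 2^(k−1) and keeps
all of its canals; its 16-cell degree sequence is {4,4,3,3,2,2,2,2,1×8},
with cells 1 and 2 (the pro-oocytes) carrying four canals each.

**Enumeration.**  `enumerate_topologies` applies the division operator over
the Cartesian product of all cells' choices and groups the products up to
isomorphism of *unlabeled* trees (daughters interchangeable, no cell
identities).  This convention is not forced by anything upstream; it is
validated by reproducing both observed counts (3 eight-cell classes from the
4-cell chain, 36 sixteen-cell classes from the maximally branched 8-cell
cyst, exactly one maximally branched class at each transition).  Enumeration
is guarded to starts of ≤ 8 cells, where the labeled product space is 64.

**Isomorphism.**  Trees are compared by an AHU canonical encoding rooted at
the tree center (iterative leaf pruning).  When two centers exist, both
rootings are encoded and the lexicographically smaller string is taken.  The
test suite checks this encoding against exhaustive permutation search and
against networkx's isomorphism routine, which are never used in the
implementation path.

**Subtree embedding.**  `is_embeddable` decides whether a fragment tree maps
onto a connected subtree of a host by a rooted dynamic programme: the
fragment is rooted at an arbitrary node, tried against every host node as
the root's image, and children are paired by exact bipartite matching
(degrees are ≤ 4, so backtracking matching is trivial).  Memoization is over
(fragment node, fragment parent, host node, host parent).  Verified against
a brute-force oracle that enumerates connected host subsets.  A 16-cell
division product embeds in the canonical 16-cell tree iff it *is* maximally
branched; fragments (e.g. a 9-cell chain, impossible because the canonical
tree's longest path has 8 nodes) can witness non-maximal division histories
even when the full cyst is not visible.

## Additive growth model

Assumptions: the fusome starts as the founder's spectrosome (volume v₀,
normalized to 1); each division round j adds one plug of volume v_j into
every new ring canal (plugs within a round are equal); a fraction β of each
plug stays with the mother, 1−β goes to the daughter; between divisions the
relative distribution does not change.  After k rounds a cell born at round
b holds (1−β)·v_b + β·(v_{b+1}+…+v_k); cell 1 holds v₀ + β·(v₁+…+v_k); the
total is T_k = v₀ + Σ 2^(j−1) v_j.

Two parameters are free: α (cell 1's fraction at the 2-cell stage, giving
v₁ = v₀(1−α)/(α−β)) and β.  v₂…v₄ are pinned by the 16-cell group shares of
{cells 1–2, 3–4, 5–8, 9–16}, default 2:1:1:1 as measured; the four share
equations are redundant with normalization, leaving a 3×3 linear system.
Feasibility requires α > β and all v_j ≥ 0.  At the reference point
(α, β) = (0.7, 0.5): v = (1.5, 1.25, 0.625, 0.625)·v₀, T₄ = 12.5, and the
16-cell fractions are (0.24, 0.16, 0.10, 0.10, 0.05×4, 0.025×8).

**Fitting.**  E(α, β) is the sum over cyst sizes and cells of squared
residuals between measured and predicted volume fractions, minimized on a
grid (default α, β ∈ [0.25, 0.75], step 0.005, feasibility mask
α − β > 0.01; infeasible points get +∞).  By default each cell contributes
one residual per stage computed against the stage-wise *mean* measured
fraction (that is what summary plots of such data display); a per-sample
mode that sums residuals over every cyst is available behind a flag and
agrees closely on simulated data.  The 5%-of-minimum region
(E ≤ 1.05·min E) quantifies flatness of the error surface.  Measured cysts
are put in canonical order per cyst: cells grouped {1,2}, {3,4}, {5–8},
{9–16} with descending volume inside each group, so measured f₁ ≥ f₂ by
construction — mirroring the labeling rule that cell 1 is the larger
pro-oocyte.  The grid path is vectorized (batched 3×3 solves); the test
suite pins it to the scalar path.

## Segmentation

Inputs are per-channel 3D grids, binary or class-probability, indexed
(z, y, x) with physical voxel size (dx, dy, dz) in nm (defaults 70, 70,
210 — anisotropy ≈ 3× in z).  All distances, plane fits and skeletons are
computed in physical units.

* **Thresholding** at 0.5 by default; an empty class is an error.
* **Fusome extraction**: 26-connected components; female mode keeps the
  single largest (the female fusome is one simply-connected body), male
  mode keeps all components above a 30-voxel floor, largest first.
* **Ring detection**: each ring-channel component is resampled to an
  isotropic lattice (nearest-neighbour) so the coarse z spacing cannot
  break thin loops, then skeletonized in 3D; the component is a ring iff
  its skeleton's 26-connectivity graph contains a cycle
  (edges − nodes + components ≥ 1).  Geometry per ring: physical centroid,
  plane normal = least-variance principal axis of the voxel cloud, radius =
  median in-plane distance to the centroid.
* **Recursive splitting**: pick an unused ring; delete fusome voxels inside
  its cutting disk — radius 1.25× the measured ring radius, slab
  half-thickness max(min voxel, |n·(dz,dy,dx)|/2), i.e. adaptive to the cut
  orientation so that an oblique or z-normal plane still removes a
  separating voxel layer under anisotropy.  The component must fall into
  exactly two substantial pieces (pieces under 27 voxels are treated as cut
  debris and folded into the nearest fragment; a cut that fails to
  disconnect, or yields more than two substantial pieces, raises a named
  error).  Remaining rings recurse into the side holding the voxel nearest
  their centroid.  Deleted voxels are finally reassigned to the nearest
  fragment by an anisotropy-aware Euclidean distance transform, so fragment
  voxel counts sum *exactly* to the whole fusome.
* **Adjacency**: each ring records the nearest voxel on either side of its
  cut; the final fragments containing those anchors are the ring's two
  incident cells.  The result must be a tree.
* **Labeling** (female only): the tree must be isomorphic to the canonical
  topology.  Cell 1 is the larger-volume fragment of maximal degree (exact
  ties break to the lowest fragment id and are flagged).  Remaining labels
  come from minimum-cost linear assignment (Hungarian) on structural
  signatures — degree, hop distance to cell 1, sorted neighbour degrees —
  verified to be edge-preserving; if symmetric positions make the
  assignment invalid, a deterministic rooted matching takes over, pairing
  equal-shape sibling subtrees with fragments in descending volume order.
* **Male census**: no labels; per component, a ring counts as *traversed*
  iff deleting its cutting disk separates the component into two
  substantial pieces — an operational test that is immune to broken thread
  stubs merely touching a ring plane.  Fusome-connected cells = traversed
  rings + 1, with a power-of-two flag; each component's adjacency tree is
  additionally tested for embeddability in the canonical 16-cell tree.

## Synthetic data

`simulate_volume_table` draws per-cell volumes T_k·f_i(α*, β*)·LogNormal(0, σ)
with v₀ = 1.  Defaults are the study conditions of the measured female data:
α* = 0.7, β* = 0.5, 2:1:1:1 group shares, 12 cysts per stage, σ = 0.05
(volumes are positive with relative scatter, hence multiplicative lognormal
noise).  The seed fully determines the table.

`render_cyst` rasterizes a tree: each cell is a ball of prescribed volume
(default: growth-model fractions), adjacent balls are joined by a 250
nm-radius thread, and each ring canal is a solid torus (major 350 nm, minor
200 nm) at the junction point — where the signed distances to the two ball
surfaces are equal — oriented normal to the connecting segment.  Cells are
placed by a 3D spring layout rescaled until (i) every ball pair keeps its
margin, (ii) no thread passes near a cell it does not connect, (iii)
non-incident threads keep two thread radii apart, and (iv) junctions are
separated by more than two ring extents, so rendered tori never merge.
Male-style renders stretch one axis (elongation 2×) and break threads with
probability `p_frag`, removing a mid-thread capsule segment wide enough
(700 nm between cap surfaces) to disconnect the voxel graph; threads too
short to break cleanly are left intact and recorded as such.  An optional
Gaussian blur turns masks into probability-map surrogates; thresholding the
blurred map at 0.5 recovers the mask volume to within ~10%.

Ground truth for scoring: each fusome voxel is owned by the cell whose ball
surface is nearest, which places the ownership boundary exactly at the
rendered ring position.  Note that thread material is part of this ownership,
so a rendered cyst's per-cell volume fractions deviate from the prescribed
ball volumes (noticeably for the smallest cells at 16 cells); segmentation
accuracy is therefore always measured against the render's own answer key,
not against the growth model.

What the renders do *not* emulate: point-spread functions, photon noise,
intensity inhomogeneity, fusome thinning between distant cells, or touching
neighbouring cysts.  Passing the round-trip tests shows the algorithmic
chain (loop detection → cutting → adjacency → labels) is correct under
clean geometry with realistic anisotropy, not that the pipeline is robust
to real microscopy artefacts — robustness there is bounded by the upstream
pixel classification, which is outside this package.

## Problem sizes and numerical choices

The test and acceptance suites use: enumeration up to the 8→16 transition
(64 labeled outcomes); renders of 2–16-cell cysts on grids of roughly
0.5–3 M voxels at (70, 70, 210) nm voxels; 20 random round-trip cysts; 100
fit replicates per generator setting at 12 cysts/stage; male censuses of
4–8 cysts of up to 8 cells.  Tolerances: fraction normalization 1e−9;
fragment-volume round-trip error ≤ 10% (observed ≤ 2% on intact female
renders); recursion-order volume invariance ±2%; fit-grid resolution 0.005.
Degenerate inputs are handled by named errors (empty masks, infeasible
parameters, failed or ambiguous cuts, non-tree adjacency, non-canonical
topologies) rather than silent fallbacks; the only silent repair is folding
sub-27-voxel cut debris into the nearest fragment, which preserves exact
volume accounting.

## Known limitations

* Enumeration beyond 8-cell starts is deliberately unsupported (the labeled
  space grows as 2^Σ(dᵢ−1)).
* Canonical labeling requires the reconstructed tree to match the canonical
  topology exactly; partially reconstructed female cysts fall back to
  fragment ids only.
* The male census counts cells through an operational ring-traversal test;
  a ring whose canal is real but whose fusome thread is retracted just past
  the cutting slab is counted as not traversed.
* The growth model assumes equal plugs within a round and no inter-division
  remodelling; plug-size variability is representable in the generator but
  not a fitted quantity.
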
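# Methods

This note documents the models and procedures implemented in `sbemkit`, the
assumptions behind them, the parameters that matter, and the places where a
design was genuinely open and a choice had to be made.

## Coordinate conventions

Voxel indices are 0-based throughout the library; a voxel's physical
position is `index * voxel_size` (corner convention) with the anisotropic
default pitch (9.25, 9.25, 25) nm for (x, y, z). The NML writer emits the
1-based convention used by KNOSSOS-style annotation files and the parser
converts back, losslessly for integer positions. In-memory volumes are
numpy arrays indexed `[z, y, x]` (x fastest), while API coordinates are
`(x, y, z)` tuples.

## Tile registration

**Standardization.** Image columns are standardized (zero mean, unit sd),
then rows. Zero-variance rows or columns are set to zero with a warning
rather than raising, so blank tile margins do not abort a batch run.

**Offset estimation.** The integer displacement between two tiles is the
peak of their cross-correlogram restricted to a ±`max_offset` (default
256 px) window around the expected displacement between the overlapping
parts. The correlogram is computed in the Fourier domain, but each lag is
normalized to the Pearson correlation over that lag's actual overlap
window (means and variances from sum tables, also computed by FFT). The
window-local normalization matters: with the 5–8% tile overlaps typical of
SBEM acquisition the informative overlap is a thin strip, and an
unnormalized correlation is biased toward lags with larger overlap area —
in experiments on 256-px tiles with ~15-px overlaps the raw-correlation
peak was systematically 1–2 px inside the true displacement, while the
window-normalized peak is exact (the normalized score is exactly 1.0 at
the true lag of a noiseless pair). Lags whose overlap is below
max(64 px², 0.5% of the image area) are excluded; ties are broken by the
displacement closest to nominal, then lexicographically. No sub-pixel
refinement is attempted; offsets are integers by design.

**Global placement.** Pairwise offsets are combined by ordinary least
squares on the displacement residuals, one coordinate at a time, with one
anchor tile pinned at the origin to fix the translational gauge. For the
tile counts of real sections (tens) the normal system is solved densely
and is exact to rounding; an optional `peak_score` weighting is available
but off by default, since typical acquisitions give near-uniform peak
quality. A disconnected pair graph is an error that names the components.
Note that position errors are only meaningful up to a common translation;
accuracy statements (e.g. RMSE ≤ offset noise sd) are made in the
translation-free gauge.

**Contrast.** A Gaussian is fitted to the intensity histogram by nonlinear
least squares, restricted to ±3 MAD around the histogram mode; the extreme
bins are excluded from both the mode search and the fit because clipped
data piles up there (this also makes renormalizing an already-normalized
image a near-identity, changing no pixel by more than one gray level).
The 16→8 bit map sends `peak − k·σ → 0` and `peak + k·σ → 255` linearly,
clipped and rounded half-up; `k` defaults to 2.0 and the conventional
range is [1.5, 3] (values outside warn).

**Stitching.** Default blend is last-writer-wins, which keeps
single-coverage pixels bit-exact; linear distance-to-edge feathering is
available for display. A provenance mask records the contributing tile per
pixel.

## Cube store

The stack is chunked into fixed-edge 8-bit cubes (default 128 voxels,
arbitrary edges supported), one raw file per cube under
`level{l}/x{cx:04d}/y{cy:04d}/z{cz:04d}/cube.raw`, x fastest, with a
plain-text `key=value` `.conf` file describing the geometry. Boundary
cubes are zero-padded so every file has the same size. Zoom level `l` has
per-axis dimensions `ceil(dim / 2^l)`; levels are built by 2×2×2 mean
pooling (edge-replication for odd dimensions, which equals averaging over
the voxels actually present) rounded half-up. Factor 2 with mean pooling
is the near-universal convention for such stores.

Neighborhood loading models interactive browsing: all cubes whose boxes
intersect an `extent`-voxel box (typically 320–576) around the focal
point, at each requested zoom level with the focal point rescaled per
level, are made resident. Every cube fetched from the backing source is
written through to a persistent disk cache (each cube is fetched at most
once, and previously visited regions work offline); memory residency
follows an LRU budget whose eviction never touches the disk copy. Results
are independent of fetch order or parallelism because cube content is
immutable.

Reslices sample the volume by trilinear interpolation at
`center + (i − ci)·pitch·u + (j − cj)·pitch·v` with `ci = (rows − 1)/2`,
converting nm to fractional voxel indices through the anisotropic pitch;
samples outside the stack are 0. Trilinear interpolation is exact on
trilinear fields, which the tests exploit with linear-ramp volumes.

## NML / NMX annotation format

The supported dialect covers `things/thing/nodes/node` and
`thing/edges/edge`, a `parameters/scale` element carrying the nm pitch,
and a `comments/comment` section; node attributes beyond
id/x/y/z/radius/time are passed through opaquely so foreign files survive
a round trip. Output is fully deterministic (sorted things, nodes, edges,
comments, attributes), so identical annotations produce byte-identical
files. Synapses are serialized as 3-node, 2-edge things named `synapse`
whose nodes carry the comments `pre`, `cleft:<class>:<confidence>`, and
`post` — the serialization mirrors the three-click annotation gesture
(presynaptic neuron, cleft, postsynaptic neuron). Soma outlines are
edge-free things named `soma_<owner>`. An NMX file is a zip archive of NML
documents with fixed timestamps (deterministic bytes); files named
`Neuron_id<N>.nmx` carry the neuron id in metadata.

The innervation table is a CSV with mandatory header
(`neuron_id,cell_type,<region…>`), lengths in micrometres (stated in a
`#` comment line the reader skips), and the cell-type vocabulary
{mitral, IN1, IN2, IN3, UPN, LOC, other}; unknown labels map to `other`
with a warning, non-numeric lengths are an error.

## Skeleton consensus

All consensus geometry is in nm (convert voxel skeletons with
`Skeleton.scaled` first). Key parameters: target resampling spacing
(default 100 nm), clique radius (default 500 nm — well above the node
spacing and below typical inter-neurite distances), and `min_agreement`
(default 2, i.e. a majority of the conventional three tracings).

**Resampling** subdivides each edge of length L into `ceil(L / spacing)`
uniform pieces. All original nodes (hence branch points and endpoints) are
retained and inserted nodes lie on the original polyline, so the total
path length is preserved exactly while no edge exceeds the spacing.

**Clique formation** is a seeded region growing along the skeletons, not a
pure spatial clustering. A seed is a tuple of mutually nearby nodes (one
per tracing) found from the lowest node ids, i.e. near the tracing start.
Growth maintains a frontier of unassigned nodes adjacent to assigned ones;
at each step the best candidate clique is formed, preferring maximal
agreement first and then the smallest mean pairwise member distance
(preferring small distance *before* agreement size would let tight
2-member pairs starve the third tracing out of every clique). Each
candidate member must satisfy the clique radius pairwise and a
connectivity-consistency constraint: the cliques already adjacent to the
candidate's polyline neighbors must lie within 3 hops of each other in the
clique-adjacency graph built so far. This is what prevents two path
sections that merely pass within the clique radius of each other — loops,
or sibling branches near a branch point — from being conflated. When
growth stalls, seeding is retried among *fresh* nodes only (no assigned
polyline neighbor, mean pair distance ≤ radius/2), so consensus resumes
past local disagreements without letting leftover slack nodes seed
spurious correspondences. Output is independent of the input order of the
tracings: all internal ordering is by stable tracing id and node id, and
ties are resolved by distance first.

**Consolidation** places one node per clique at the member centroid. Two
cliques are connected if a tracing has directly adjacent members in both,
or members separated by a run of at most two of its own unassigned nodes
(resampling slack); longer unassigned runs are genuine disagreements and
are not bridged. Redundant triangle chords — created when tracings
resample to slightly different node counts and one of them skips a clique
— are pruned by removing the longest edge of any triangle.

**Mismatch detection.** Orphan nodes (assigned to no clique) are grouped
into connected components per tracing. Components that never leave the
clique radius of the consensus are resampling slack and are ignored; the
rest are mismatch points, positioned at the orphan node adjacent to an
assigned node. A component is classified `missing-branch` if the orphan
sets of at least `min_agreement` tracings cover most of it (≥50% overlap),
else `extra-branch`. Separately, an `early-termination` is flagged where a
tracing's endpoint clique is continued by the consensus for more than
2·radius of path length genuinely uncovered by that tracing (covered
stretches — where the tracing has nodes within the radius, orphaned or not
— are traversed without counting, so a sibling branch running nearby
neither masks nor fakes a termination).

**Resolution.** A resolver callback answers each mismatch with either an
expert decision (`keep`/`drop`) or a majority vote over local re-tracings.
`drop` removes the contested segment from the minority tracing and then
peels the exposed stub while no other tracing corroborates it (within
radius/4) — the first ~0.5 µm of a spurious branch typically runs inside
the clique radius of the true path and joins cliques there, so removing
only the orphaned part would leave a stub. Majority splicing takes only
the genuinely new part of a re-tracing (nodes farther than 1.5 spacings
from existing structure; adding closer nodes would braid a duplicate
strand along the existing path), keeps its internal edges, and connects
each added fragment of ≥3 nodes to the nearest existing node. `keep`
decisions are remembered and not re-raised (same kind within 2·radius),
which guarantees termination for a consistent resolver; a round cap
(default 50) turns inconsistency into an explicit non-convergence error
carrying the open mismatches. An audit log records cliques, orphans and
mismatches per round.

`make_oracle_resolver` wraps a known true skeleton as a simulated
expert-plus-tracer-pool for tests: contested segments are kept or dropped
according to truth coverage, and early terminations are answered with the
local connected component of the truth around the mismatch point.

## Morphometry

Convex regions are `scipy.spatial.ConvexHull` objects over the annotated
points; degenerate (coplanar or <4 point) inputs are errors. Segment
clipping intersects the parametric segment with every hull half-space, so
the neurite length inside a region is exact and additive under any
subdivision of the skeleton edges; edges partially inside contribute their
clipped sub-length rather than an all-or-nothing vote, and overlapping
regions may both count the same length (no exclusivity is forced). The
parent glomerulus of a table row is the region of maximal length, ties
broken lexicographically and flagged, all-zero rows unassigned.

Reconstruction accuracy compares two skeletons after densely sampling both
at tolerance/4 (default tolerance 100 nm, the resampling density), each
sample weighted by the arc length it represents. Recall is the fraction of
true length within tolerance of the test skeleton, precision the fraction
of test length within tolerance of the truth, and the relative length
error is (missed + excess)/true length, so recall = precision = 1 implies
zero error and swapping the arguments swaps recall and precision exactly.
Using each skeleton's own dense sampling as the distance target
approximates point-to-polyline distance to within tolerance/8, negligible
at the thresholds used.

## Synthetic data generator

The generator provides every input the pipeline needs, seeded and
bit-reproducible (one `numpy` Generator per call, no global state).

*Textures* are white noise low-pass filtered with a Gaussian kernel of
width `correlation_length` (default 4 px), rescaled to the 16-bit range —
a stand-in for membrane-rich block-face texture with a single sharp
autocorrelation peak. *Tile grids* cut overlapping tiles from one shared
texture with 5–8% overlap (drawn uniformly when not specified) and integer
position jitter; positions are translated so the mosaic origin is (0, 0).

*Skeletons* are persistent random-walk trees: edges of exactly `step`
(default 100 nm) length whose direction diffuses with sd 0.12 rad per
step, giving a few micrometres of persistence, with side branches
launched perpendicular to the local trunk tangent. Both choices mimic the
local smoothness and branch divergence of real neurites and keep distinct
processes separated relative to the 500 nm clique radius — the regime the
consensus procedure assumes. The generator does not emulate EM physics,
section loss, or neurite calibre.

*Tracer errors* follow the two empirically dominant classes plus noise:
i.i.d. Gaussian positional jitter; *missed process* — removal of the one
terminal subtree whose length best matches the requested fraction of total
path length (a single clean cut, as when a tracer stops following a
process); and *wrongly traced process* — spurious branches of given length
grafted at random nodes (marked with a `graft` comment and origin metadata
for test bookkeeping). An all-zero specification is the identity.

*Convex regions* are point sets on a sphere whose first four points form a
regular tetrahedron, guaranteeing a non-degenerate hull containing the
center.

Because the generator idealizes real data (no image distortion, no
z-drift, no variable tracer skill, branch geometry cleaner than tortuous
adult neuropil), passing tests demonstrate the correctness of the
algorithms under their stated assumptions, not performance on arbitrary
tissue.

## Problem sizes used in validation

The validation suite runs at desk scale: 1024² worked-example tiles with a
±256 px search window, 3×3 grids of 256-px tiles, volumes of ~10⁶ voxels
with cube edges 16–128, and simulated neurons of ~20–30 µm total path
length traced three times, over 20 seeds for the consensus accuracy
experiment (jitter 20 nm, one 20% truncation, one 5 µm graft, oracle
resolver). Mean recall and precision across the 20 seeds are ≈0.998 and
≈0.999 at the 100 nm tolerance; 19 of 20 individual seeds exceed 0.99 on
both. The residual case is a geometry where two branches of a common
branch point stay within the clique radius for an extended stretch — a
known ambiguity of proximity-based agreement at a 500 nm radius, resolved
in practice by the expert loop.

## Known limitations

- Registration is purely translational; no elastic or rotational model.
- The clique radius is global; regions where distinct neurites approach
  closer than the radius can cross-match (see above). A locally adaptive
  radius is a natural extension.
- The NML dialect covers the skeleton/synapse/soma subset described here;
  volumetric segmentation formats are out of scope.
- The HTTP-style backing source for the cube store is modeled by the
  fetch/caching contract (any callable source with a `fetch` method); no
  network client is shipped.
- Expert decisions are an injectable callback; there is no interactive
  review interface.
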
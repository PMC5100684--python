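# sbemkit

Reconstruction tooling for serial block-face scanning electron microscopy
(SBEM) volumes: tile mosaicking, a cubed multi-resolution volume store with
oblique reslicing, the NML/NMX skeleton annotation formats, redundancy-based
consensus reconstruction of neuron skeletons with iterative error
correction, and glomerular innervation morphometry.

## Who this is for

Labs producing dense neuronal reconstructions from SBEM stacks — for
example an olfactory bulb imaged at 9.25 × 9.25 × 25 nm³ voxel pitch, where
each section is a mosaic of overlapping camera tiles and each neuron is
traced several times by independent annotators. The package covers the
computational path from raw tiles to a consolidated skeleton and a
per-glomerulus neurite-length table.

## What it computes

**Tile registration.** Tile images are standardized column-wise then
row-wise; the integer offset between neighboring tiles is the peak of the
cross-correlogram computed in the Fourier domain, normalized per overlap
window and searched within ±256 px of the expected overlap displacement.
Pairwise offsets `d_ij` are combined into global tile positions `p` by
minimizing the summed squared displacement residuals

    Σ_(i,j) ‖ (p_j − p_i) − d_ij ‖²

with one anchor tile pinned at the origin. Contrast is converted to 8 bit
by fitting a Gaussian N(μ, σ²) to the intensity histogram and mapping
μ ± kσ (k ∈ [1.5, 3], default 2) linearly to [0, 255].

**Cube store.** 8-bit stacks are split into 128³-voxel cubes (one raw file
per cube) with factor-2 mean-pooled zoom levels; a navigation-style loader
makes every cube within a 320–576-voxel box of the focal point resident, at
the current level and its neighbors, with a write-through persistent disk
cache and LRU memory accounting. Arbitrary-orientation reslices are
trilinear samples through the anisotropic voxel grid.

**Skeleton consensus (CORE-style).** Each tracing is resampled to ≤100 nm
node spacing; nodes from different tracings are grouped into *cliques* by
spatial proximity and connectedness; clique centroids and adjacencies form
the consolidated skeleton. Divergences — grafted branches, branches missed
by the majority, early terminations — surface as *mismatch points* and are
resolved by local re-tracings (majority vote) or an expert decision; the
cycle repeats until no mismatch remains open.

**Morphometry.** Glomeruli are convex hulls of annotated 3-D points; a
neuron's innervation of a glomerulus is the exact length of its skeleton
edges clipped against the hull half-spaces (μm); the parent glomerulus is
the row-wise argmax. Reconstruction accuracy against a reference is
length-weighted recall (missed processes), precision (wrongly traced
processes), and the relative length error (missed + excess over true
length), at a 100 nm matching tolerance.

## Worked example

```python
import numpy as np
from sbemkit import simulate, registration, consensus, morphometry

# --- registration: recover a known 1024x1024 tile displacement ---------
texture = simulate.gen_texture(simulate.TextureSpec(1536, 1536,
                                                    correlation_length=4.0,
                                                    seed=1))
tile_a, tile_b, _ = simulate.gen_tile_pair(texture, (69, 66), 1024)
est = registration.estimate_offset(tile_a, tile_b, max_offset=256)
print(f"offset: dX={est.dx} dY={est.dy}  peak NCC={est.peak_score:.3f}")

# --- consensus: three error-laden tracings of one neuron ---------------
truth = simulate.gen_skeleton(3, seed=0)     # ~20 um tree, nm coordinates
tracers = [
    simulate.perturb_skeleton(truth, simulate.PerturbationSpec(
        jitter_sd=20, seed=10)),
    simulate.perturb_skeleton(truth, simulate.PerturbationSpec(
        jitter_sd=20, truncate_fraction=0.2, seed=11)),   # missed subtree
    simulate.perturb_skeleton(truth, simulate.PerturbationSpec(
        jitter_sd=20, graft_length=5000, graft_count=1, seed=12)),  # wrong branch
]
result = consensus.core_iterate(tracers, radius=500, min_agreement=2,
                                resolver=consensus.make_oracle_resolver(truth))
m = morphometry.reconstruction_metrics(result.skeleton, truth, tolerance=100)
print(f"rounds={len(result.audit)}  nodes={len(result.skeleton)}")
print(f"recall={m.recall:.4f}  precision={m.precision:.4f}  "
      f"rle={m.relative_length_error:.4f}")
```

Output:

```
offset: dX=69 dY=66  peak NCC=1.000
rounds=2  nodes=449
recall=1.0000  precision=1.0000  rle=0.0000
```

The registration returns the generating displacement exactly (the peak
normalized cross-correlation is 1.0 on noiseless tiles). The consensus run
detects the grafted branch (dropped by the simulated expert) and the
truncation (restored from simulated local re-tracings) in one round and
converges in the next; the consolidated skeleton matches the ground truth
to within the 100 nm tolerance along its entire length.

## Command line

`sbemkit` exposes the same pipeline from a shell:

```sh
sbemkit sim grid --rows 3 --cols 3 --seed 1 --out tiles/   # synthetic tiles
sbemkit stitch --tiles tiles/ --grid 3x3 --out mosaic/     # register + stitch
sbemkit cube build --sections sections/ --out store/       # cubed volume
sbemkit cube reslice --store store/ --center 5000,5000,2000 \
        --u 1,0,0 --v 0,0.6,0.8 --shape 512,512 --out slice.tif
sbemkit consolidate --tracings a.nmx --tracings b.nmx --tracings c.nmx \
        --out consolidated.nmx
sbemkit innervate --skeletons neurons/ --regions glomeruli.nmx --out table.csv
sbemkit metrics --test a.nmx --truth b.nmx --tol-nm 100
```

## Documentation

`docs/methods.md` describes the models, the synthetic data generator, all
tunable parameters and the numerical choices in detail.
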
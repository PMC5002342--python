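# Methods

This note records the model, the numerical choices and the limits of what the
test suite shows. It states no result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Model and assumptions

The pipeline assumes a single lesion whose boundary carries a usable
intensity gradient against its local surroundings, marked by 1–2 interior
seed points and 1–3 exterior seed points. All reasoning is local: the ROI is
the seed bounding box dilated by a physical margin (default 20 mm), and every
stage runs inside it. The method is intensity-based and makes no shape prior
beyond the postprocessing's connectivity and smallness filters, which is what
lets it handle irregular and inhomogeneous lesions that template- or
profile-based methods miss.

Coordinates are 0-based voxel indices in `(x, y, z)` order; world position is
`origin + index·spacing`, spacing in mm. Masks are uint8 with 1 = tumor.

## Stage parameters

| parameter | default | units | role |
|---|---|---|---|
| `margin_mm` | 20 | mm | ROI dilation around the seed bounding box |
| `diffusion_steps` | 5 | – | explicit MCDE iterations |
| `diffusion_time_step` | 0.0625 | grid units | ≤ 1/6 for 3-D explicit stability |
| `diffusion_conductance` | 3.0 | intensity/voxel | gradient scale κ in `c(g)=exp(−(g/κ)²)` |
| `gradient_sigma_mm` | 1.0 | mm | Gaussian scale of the gradient magnitude |
| `sigmoid_alpha` | −3.5 | intensity gradient | sigmoid range; negative ⇒ decreasing map |
| `sigmoid_beta` | 8.0 | intensity gradient | sigmoid center (speed = ½ at `I_M = β`) |
| `stop_value` | 15 | arrival time | front threshold for teacher labels |
| `hidden_size` K | 200 | – | random sigmoid hidden units |
| `ridge` λ | 0.01 | – | output-weight regularization |
| `window` | 3×3×3 | voxels | pattern window |
| `component_connectivity` | 26 | – | connected-component rule |
| `morphology_radius` | 1 | voxels | ball radius for closing/artifact removal |

The classifier and front parameters (α, β, K, λ, window, stop value) are
fixed defaults used identically for every case; the remaining knobs are
config-exposed with the defaults above.

## Design choices where the design was open

**Two competing marches.** The teacher rule needs labels 1 *and* 2 from
time maps thresholded at a stop value. A single march cannot produce two
labels, so the implementation runs one march from the tumor seeds and one
from the background seeds and lets the earlier arrival win, ties going to
background (conservative against over-segmentation; overridable).

**Stop value, not pop count.** The front threshold is interpreted as an
arrival-time stopping value (the toolkit convention in which the front is
stopped when the current Trial time passes a level), not a literal count of
heap pops — fifteen pops would label fifteen voxels, which cannot form
teacher regions.

**ROI rule.** Seeds bound the lesion (background seeds surround it), so the
ROI is their bounding box plus a physical margin; a margin in mm is invariant
to voxel anisotropy.

**Decision rule.** The network's two outputs are compared by argmax against
the one-hot coding ((0,1) = tumor), ties to nontumor. No class reweighting is
applied even though teacher regions are typically imbalanced toward
background.

**Patterns from the denoised ROI.** Window patterns are extracted from the
diffusion output by default (config-switchable to the raw ROI), and window
entries at ROI borders use replicate padding rather than injecting an
arbitrary constant.

## Numerical choices

- **Diffusion scheme.** Explicit MCDE on the unit voxel lattice: face
  mobilities `c(g)/g` averaged from adjacent cells, flat regions regularized
  by `sqrt(g² + ε²)` with `ε = 1e-8 ×` intensity range (constant volumes pass
  through bit-identically). The update is written as a weighted neighbour
  average with a per-voxel limiter clamping the total weight to 1, so the
  discrete maximum principle holds unconditionally rather than only under a
  data-dependent CFL estimate.
- **Gradient magnitude.** Gaussian smoothing (per-axis sigma
  `sigma_mm/spacing`) followed by central differences scaled to per-mm units.
  Sampled derivative-of-Gaussian kernels are not used: below ~1 voxel of
  sigma they lose their normalization, and 1 mm scale against 3.5 mm slices
  is exactly that regime.
- **Edge potential.** Computed with the numerically stable logistic and
  clamped to `[1e-12, 1 − 1e-12]` so the speed image is strictly positive
  even where the sigmoid saturates in float64.
- **Fast marching.** First-order Godunov upwind per axis with physical
  spacing, 6-connected front, min-heap with lazy deletion; the quadratic is
  solved over the sorted causal prefix and the largest admissible root taken.
  Voxels never finalized carry +inf. Finalization order is recorded so tests
  can assert monotonicity.
- **ELM solving.** λ = 0 uses the SVD pseudoinverse (minimum-norm solution);
  λ > 0 solves the regularized normal equations exactly as written. The
  training objective is the standard least-squares one; classification is
  vectorized in chunks so a full-ROI classification stays within ordinary
  memory.
- **Artifact removal.** The final "opening" is an opening by
  reconstruction: components that do not survive an erosion by the ball are
  dropped whole, survivors keep their exact shape. A plain opening would also
  round corners off legitimate structure, which contradicts the intent of an
  artifact/hole cleanup stage (and its own worked examples).
- **Surface distances.** Voxel-border convention: border voxels are mask
  voxels with a face-adjacent background voxel (volume boundary counts as
  background); distances are Euclidean between border-voxel centers in mm,
  and the two directed distance sets are pooled before averaging. This is
  the dominant convention in the liver-segmentation evaluation literature;
  border and averaging conventions vary between toolkits, so comparisons
  across implementations should check this exactly.

## What the phantom does and does not emulate

`tumorseg.phantom` generates an ellipsoidal lesion (default: 8-voxel-radius
sphere, intensity 150) in a homogeneous background (90), modulated by a
smooth ±10% multiplicative field, plus i.i.d. Gaussian noise (σ = 8), at
configurable anisotropic spacing. The ground-truth mask is the exact
rasterized ellipsoid and never depends on the noise draw. This exercises
every stage — denoising, edge-potential formation, competing fronts,
classifier generalization, cleanup — under a known answer.

It does not emulate: neighbouring structures of similar intensity (vessels,
liver boundary), Rician noise statistics, partial-volume ramps at thick-slice
boundaries, multi-focal or strongly non-ellipsoidal lesions, or scanner bias
fields beyond the smooth multiplicative term. Passing the phantom tests
therefore demonstrates the pipeline's internal correctness and its behaviour
under noise and mild inhomogeneity, not clinical-grade accuracy on patient
MR data.

## Problem sizes and runtime

The test suite and acceptance script run the full pipeline on the 64³
default phantom (≈ 260k voxels, ROI ≈ 110k voxels): a few seconds per run.
Oracle comparisons use exhaustive 3×3×3 grids and random 5×5×5 grids against
a brute-force fixed-point Eikonal solver, a 6-connected Dijkstra solver, and
all-pairs surface-distance enumeration — sizes chosen so the independent
oracles are trivially trustworthy.

## Known limitations

- A first-order front's arrival times at 3-axis-diagonal voxels exceed the
  Euclidean distance by up to ~23% near a point seed (the classical
  point-source initialization error); axis-aligned distances are exact. The
  teacher threshold absorbs this (it shifts *where* the front stops, not
  whether the lesion boundary stalls it), but the time maps should not be
  read as calibrated distances.
- Teacher regions inherit any front leakage through weak boundary sections;
  the classifier can then propagate the error. Seeds placed close to the
  lesion boundary aggravate this.
- The ELM is retrained per case from that case's teacher regions; there is
  no cross-case learning, by design.
- Masks are voxel masks; no sub-voxel surface model is produced.
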
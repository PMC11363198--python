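# Methods

## The problem

Task fMRI localizes function to patches of cortex (functional ROIs, fROIs);
diffusion tractography reconstructs white-matter fascicles as streamlines.
A *functional sub-bundle* (FSuB) is the subset of a bundle's streamlines
that actually connects to a given fROI. Because streamlines terminate at or
near the gray-matter–white-matter interface (GMWMI) while fROIs live on the
cortical surface, extracting an FSuB requires bringing both into one space
and deciding, endpoint by endpoint, what "connects" means. This package
implements that decision rule and everything needed around it: format I/O,
interface construction, surface-to-volume projection, endpoint matching,
and bundle-level summaries.

## Coordinate conventions

All computation happens in **world RAS millimeters**. Each reader converts
on ingest:

- **TCK** stores world mm natively; coordinates pass through unchanged.
  Only Float32LE/BE payloads are accepted — rarer datatypes are rejected
  loudly rather than risked as silent misreads.
- **TRK** stores corner-origin voxel-mm: a stored point `p` maps to voxel
  index `p / voxel_size − 0.5`, then through the header's voxel-to-RAS
  matrix. This is the de-facto TrackVis convention; it is applied
  symmetrically on write so round trips are exact to float32 precision.
- **FreeSurfer surfaces** store "tkr" surface-RAS coordinates; the `cras`
  offset from the volume-geometry footer shifts them to world RAS. Files
  without a footer get `cras = 0` and a logged warning — the `--fs2dwi`
  affine exists precisely because surface and diffusion spaces can differ.
- Plain-text 4×4 affines are accepted in two dialects: a bare 16-number
  matrix, and ITK transform files (9 matrix entries + translation, composed
  with the fixed center of rotation). ITK files are interpreted as given,
  with no LPS↔RAS handedness flip; users registering across conventions
  should supply the matrix in RAS.

TRK byte order is auto-detected from the `hdr_size` field; FreeSurfer
surfaces are always big-endian. Every parser raises a typed error on
truncation, naming the failing byte offset where meaningful.

## GMWMI construction

From a five-tissue-type (5tt) segmentation — cortical GM, subcortical GM,
WM, CSF, pathological tissue, each a partial-volume map in [0, 1] — the
interface score is

    score(v) = min(1, 4 · g(v) · w(v))

with `w` the WM fraction and `g` the cortical GM fraction (subcortical GM
optionally included via a flag, off by default since the intended use is
cortical fROIs). The product form is a deliberate native definition: it
vanishes in pure tissue and peaks at exactly 1 for a 50/50 mix, which is
what "the boundary layer between gray and white matter" means in
partial-volume terms. The probabilistic image is binarized with a strict
`>` at an adjustable threshold, default **0.25** (≈ 6.7 % mixing of each
tissue at equality): on slab phantoms this keeps the interface a contiguous
one-voxel sheet while excluding trace mixing.

Mask intersection is a voxelwise product and *requires* identical grids
(shape and affine within 1e-4 mm). There is no silent resampling: a grid
mismatch almost always means a registration step was skipped, and hiding
that would corrupt every downstream distance.

## Surface operations

- **Vertex normals** are area-weighted sums of incident face normals
  (the cross-product magnitude supplies the area weight), normalized to
  unit length. "Outward" is defined by counter-clockwise face winding;
  isolated vertices get a zero normal and a warning.
- **Volume-to-surface sampling** (native vol2surf) samples at
  `v − d·n` for depths `d ∈ {0, step, …, depth}` along the *inward*
  normal and combines with `max` (default) or `mean`. Out-of-grid samples
  contribute 0 and are flagged. A heuristic space-mismatch check fires when
  every vertex lies outside the volume's bounding box.
- **Label-to-volume projection** (native surf2vol) marks a voxel iff some
  labeled vertex's inward segment, discretized at `step_mm`, passes
  through it. Projection follows normals only — no radial dilation, which
  would overestimate the fROI's interface footprint. Defaults:
  `inward_depth_mm = 2.0` (of the order of cortical thickness, enough to
  reach the interface from the white surface), `step_mm = 0.25`
  (quarter-voxel at 1 mm, so the discretized segment leaves no holes).
- **Percentile thresholding** uses the nearest-rank definition (value at
  index `ceil(p/100 · n)` of the ascending sort, restricted to the search
  space) and selects with strict `>`. Strictness means a constant map
  selects nothing — this returns an empty label with a warning rather than
  an error, since it is a property of the data, not a misuse. Nearest rank
  was chosen over interpolating definitions because it is exact,
  order-free, and reproducible across platforms.

## Endpoint matching

Distances are measured from the streamline endpoint to the **voxel
center**. Center semantics (rather than nearest-face) make the brute-force
oracle exact and the tie-break well defined; users can compensate with the
search distance if they prefer face-like behavior.

- `radial` (default): nearest set-voxel center within `search_dist_mm`;
  exact ties broken lexicographically by (i, j, k) voxel index for
  platform-independent determinism. Default radius **2 mm**; **3 mm** is
  the other common operating point, exposed as configuration.
- `forward`: march from the endpoint along the outward terminal tangent
  (endpoint minus its neighbor, normalized) in `forward_step_mm` steps
  (default 0.5 mm, a quarter of the default radius) up to the distance
  budget, stopping at the first step inside a set voxel. A degenerate
  tangent (coincident final points) falls back to radial for that endpoint,
  with a warning.
- `endpoint`: containment only.

The spatial index is a k-d tree over set-voxel centers used purely for
candidate generation; the final nearest/tie-break is recomputed with plain
vector arithmetic, so query results are bit-identical to a brute-force
all-pairs scan (this is asserted, not assumed).

One-ROI extraction keeps streamlines with ≥ 1 matching endpoint. Two-ROI
extraction keeps streamlines whose two matches lie on *distinct* ends —
"connecting" two fROIs means traversing between them, so a single endpoint
matching both masks does not qualify. Extraction is pure filtering: kept
streamlines are bitwise-identical to their inputs and weights are subset
consistently. A selection of ≤ 5 streamlines triggers a "very small FSuB"
warning (configurable floor; a warning, never a filter), since tiny
sub-bundles should not be over-interpreted.

## Connectivity profiles

For one fROI over a named bundle set, `count_b` is the number of bundle-b
streamlines matched under the same one-ROI rule and MatchParams as
extraction; percentages are `100 · count_b / Σ counts` over the supplied
bundles only (no whole-tractogram denominator). An optional weighted
variant sums per-streamline weights (SIFT2-style) instead of counting;
default is unweighted. Profile similarity is the Pearson correlation of
percentage vectors — a constant profile raises an error rather than
silently returning 0, and fewer than 3 bundles is refused. Summaries
report count, summed weight (count when unweighted), fROI volume
(set voxels × voxel volume), streamline density per mm³, and mean arc
length.

## The slab phantom

The generator builds a flat piece of cortex: WM fills `z < 0`, cortical GM
the slab `0 ≤ z < thickness` (default 3 mm), CSF above, with *exact*
analytic partial volumes in boundary voxel layers — the layer centered on
`z = 0` carries exactly 0.5/0.5 GM/WM, so the interface score there is
exactly 1 and zero elsewhere. The boundary surface is a regular
triangulation of `z = 0` with outward normals (0, 0, +1). Functional
patches are discs on that surface carrying radial statistic bumps (peak at
the center, zero beyond twice the radius). Streamlines are quadratic
Bézier arcs dipping into the WM, sampled at ~0.5 mm — curvature is
irrelevant to matching (only endpoints matter) but exercises I/O and
length computation realistically. Endpoints terminate at a signed offset
from the interface under seeded Gaussian jitter; decoys terminate at least
a margin (default 5 mm, more than twice the default search radius) from
every patch, so default-parameter tests have unambiguous ground truth.
The default test conditions are 100 target streamlines, 400 decoys, zero
jitter and offset, on a 40×40×24 grid of 1 mm voxels — large enough to
hold two radius-5 mm patches plus the decoy margin.

Everything is a pure function of the spec, including its seed: identical
specs produce byte-identical serialized datasets.

What the phantom does **not** emulate: cortical folding (normals are
uniform), crossing/fanning fiber geometry, imaging noise and partial
voluming from acquisition, registration error between modalities, and
realistic streamline-count distributions. Passing phantom tests therefore
demonstrates the *correctness of the geometry and bookkeeping* — endpoint
assignment, projection, intersection, filtering — not robustness to the
noise sources of real data, where registration quality and tractogram
density dominate.

## Workflow and outputs

The `extractor` CLI orchestrates: load → optional surface-to-DWI affine →
GMWMI (computed from 5tt, or a precomputed GMWMI which takes precedence,
logged) → fROI projection → intersection → matching → outputs. Outputs use
a BIDS-like, versioned, parseable naming scheme
(`sub-<id>_desc-<tract>_roi-<roi>[_step-<stage>]_<suffix>.<ext>`) with no
claim of BIDS compliance, since connectivity-derivative naming is not yet
codified. Every run writes a manifest with a role tag per file and a JSON
summary echoing the full effective configuration, defaults included. The
run is a pure function of (input files, config); reruns are byte-identical
on all primary outputs. The visualization is a static three-panel
orthographic snapshot (axial/coronal/sagittal) with configurable colors
recorded in the PNG metadata; an empty FSuB still renders, with a warning
banner.

## Numerical notes and limitations

- Radial queries add a ~1e-9 mm slack when gathering candidates so voxels
  at exactly the search radius are not lost to floating point; the ≤
  comparison against the true radius is then exact.
- Percentile 0 selects everything strictly above the minimum (nearest rank
  clamps to the first order statistic).
- TCK terminator/separator handling tolerates a missing final NaN before
  the Inf terminator; a missing terminator is a truncation error.
- Voxel "containment" uses nearest-index rounding, i.e. a voxel owns the
  half-open cube centered on it; points equidistant between centers round
  to even per IEEE rules.
- `.annot`/GIFTI/CIFTI fROIs, TRX, compressed tractograms, NIfTI-2,
  geodesic label smoothing and any group-level statistics are out of
  scope.
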
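# Methods

This note records the models, algorithmic choices and their defaults, what
the synthetic data does and does not emulate, and the known limitations.

## Anatomical conventions

All volumes are isotropic voxel grids. Axis 0 is proximodistal (slice
index increasing distally), axis 1 dorsopalmar (index increasing
palmarly), axis 2 radioulnar. Physical coordinates are millimetres with
voxel centres at `index * voxel_size`. Slice intervals are 0-based and
half-open `[start, end)`. Inputs are assumed pre-oriented; the package
performs no registration.

## Segmentation

**Binarization** (`binarize`). The default `local_cluster` method performs
two-class Otsu clustering (the optimum of 2-class 1D k-means) inside
overlapping cubic windows (default 50 voxels, 50% overlap) and
majority-votes the per-voxel decisions. Whole-bone stacks contain three
intensity phases (air, marrow, bone), and a window dominated by air would
otherwise place its two-class threshold between air and marrow; a global
3-class multi-Otsu therefore first separates air, and each window
clusters only its non-air voxels. Windows without usable contrast fall
back to the global threshold. The scheme is deterministic and reduces to
a plain threshold on noiseless two-level images.

**Cortex/trabecular separation** (`separate_cortex`). The whole-bone
solid is recovered by Euclidean-ball morphological closing (default
radius 0.6 mm — larger than half the trabecular spacing, so the porous
metaphyseal surfaces and cut faces seal) followed by per-slice hole
filling. Depth from the periosteal surface is measured per transverse
slice (the cortical shell encloses the interior in every cross-section;
2D depth keeps end faces from contaminating the profile). The cortical
band depth is estimated per slice from the bone-occupancy-vs-depth
profile: occupancy is near 1 inside the shell and drops to the
trabecular BV/TV beyond it, so the band ends at the first 1-voxel depth
bin whose occupancy falls below a threshold (default 0.65, between shell
occupancy and any plausible BV/TV). Per-slice depths are median-smoothed
over 5 slices. An occupancy profile that never drops (a solid block, an
open shell) raises an error naming the slice range rather than
misclassifying cortical bone as trabecular. The occupancy-profile
definition of the cortical band was chosen over surface run-length
statistics as simpler and more robust on shell geometry; the two agree in
intent (cortex = the dense band contiguous with the outer surface).

**Growth-plate splitting** (`split_epiphysis`). The growth plate of an
unfused specimen is cartilaginous and carries no mineralised tissue, so
it appears as a run of transverse slices whose bone occupancy falls below
5% of the median in-bone slice occupancy. The distal-most such run is the
gap; the split slice is its centre, and an explicit slice always
overrides detection. Fused specimens (no gap) raise an error pointing to
the fused-specimen path.

**Region cutting** (`cut_regions`). With automatic boundaries, the
metaphysis starts at 70% of the total proximodistal bone length; the base
ends where the dorsopalmar breadth falls to 60% of the maximal base
breadth (a proxy for the visually identified palmar-concavity landmark —
automation is optional and explicit slice indices are always accepted,
mirroring workflows where these cuts are placed manually); the epiphysis
starts at the growth-plate slice, remnant epiphyseal line, or a supplied
index. Explicit boundaries are returned verbatim.

## Local morphometry

**Background grid** (`build_grid`). An axis-aligned lattice (default
2.5 mm spacing) anchored at the inner mask's bounding-box minimum corner;
each node carries a spherical VOI (default diameter 5 mm — "5 mm
spherical volume" is read as the sphere diameter, configurable). Nodes
are kept when at least 10% of the VOI sphere lies inside the inner mask;
VOI samples additionally require 50 bone voxels to be considered valid
(fabric fits are unstable below that). Node generation is deterministic.

**MIL fabric** (`mil_fabric`). Directions are a Fibonacci hemisphere
lattice (default 128; seed-free, deterministic; MIL is even so a
hemisphere suffices). Per direction, a family of parallel test lines
(spaced `line_spacing` voxels, default 1) is sampled at 1-voxel steps
with nearest-voxel lookup, restricted to the VOI sphere intersected with
the inner mask (this restriction keeps cortical bone out of the
counts; line segments shorter than two samples contribute nothing).
MIL(ω) = total valid line length / number of marrow→bone crossings. The
ellipsoid `1/MIL²(ω) = ωᵀHω` is fitted by linear least squares;
eigenvalues λᵢ = 1/√eigᵢ(H) sorted descending give DA = 1 − λ₃/λ₁.

Two numerical points. (1) A direction family that sees *no* crossing has
MIL → ∞ and enters the fit at its continuum limit 1/MIL² = 0; this is the
correct treatment for lines (nearly) parallel to a strongly oriented
structure, where grid-sampled secants legitimately record zero crossings.
A VOI where *no* direction crosses (single-phase) is flagged invalid, as
is an indefinite fit (negative eigenvalue beyond 5% of the dominant one).
(2) Perfect plates make H degenerate (in-plane 1/MIL² = 0); small
negative eigenvalues within that tolerance are clamped to zero, giving
the planar limit DA = 1. DA is therefore bounded in [0, 1] by
construction for every valid fit.

**Sphere-fitting thickness** (`local_thickness_map`,
`region_thickness`). Local thickness is the diameter of the largest
sphere fully contained in the phase covering each voxel, computed by the
opening-sweep formulation: for radii r descending on a half-voxel
lattice, sphere centres are the voxels with Euclidean distance transform
≥ r, and voxels within r of a centre (and not yet assigned) get
thickness 2r. Work per radius is restricted to the unassigned voxels'
bounding box and the sweep stops when every foreground voxel is
assigned, which makes simple geometries (slabs, tubes) cost only a few
distance transforms. Values are exact to within one voxel on the
diameter. The volume is padded by the maximal radius before the
transform; `wrap` padding (default) is exact for periodic phantoms and
inert whenever the phase does not touch the volume boundary, as for a
bone interior surrounded by background. Tb.Th is the mean of the bone
map over bone voxels in the region, Tb.Sp the mean of the marrow map
(inner mask minus bone) over marrow voxels, and Tb.N = 1/(Tb.Th + Tb.Sp)
exactly as computed, so the identity Tb.N·(Tb.Th + Tb.Sp) = 1 holds to
machine precision by construction. Thickness is computed whole-region
(the regional API accepts any voxel subset), not per VOI.

## Whole-bone mapping

The inner region is tetrahedralized by Delaunay triangulation of the
mask voxel cloud decimated to the target edge length (default 1 mm),
with the surface voxels retained on a finer lattice so the mesh reaches
the boundary; elements whose centroid is more than one voxel outside the
mask are culled, trimming the convex hull back to the concave region. At
mesh edges of about three voxels the mesh volume agrees with the voxel
count to within 5% (coarser meshes lose the half-voxel surface shell
voxel counting includes). Node samples are interpolated to element
centroids by inverse-distance weighting (k = 8 nearest valid nodes,
power 2) — a smooth, deterministic convex combination, so element values
are bounded by the sample extrema; the interpolation scheme and its
parameters are exposed in the API. Region means are element-volume
weighted (the physically meaningful reading of a mesh mean; the
unweighted variant is available behind a flag). Element-centroid
interpolation (rather than vertex interpolation) is used and documented
as a choice.

The **dorsopalmar index** summarises the epiphyseal BV/TV distribution:
elements are split into dorsal and palmar halves by the plane normal to
the dorsopalmar axis through the BV/TV-volume centroid, and the index is
the volume-weighted mean BV/TV of the dorsal half over the palmar half
(> 1 dorsal concentration, < 1 palmar). Maps export as legacy-ASCII VTK
unstructured grids with the colour limits (per-specimen, or fixed such
as 0–0.45 for cross-specimen comparison) in a FIELD entry; a matching
reader supports round-trip tests. PLY export is omitted (no installed
dependency writes tetrahedral PLY); VTK covers the visualisation path.

## Ontogenetic statistics

Age categories are half-open month bins: [0, 7) Neonate, [7, 36)
Infant 1, [36, 72) Infant 2, [72, 144) Juvenile, 144+ Adult. The
continuous partition follows the narrative age definitions (2.9 / 5.9 /
11.9-year cut-offs) rather than coarser tabular labels, and the boundary
at exactly 12 years is Adult.

The pipeline is nonparametric throughout; a Shapiro–Wilk gate (α = 0.05)
documents the justification per variable and degenerates safely (n < 3
or constant samples default to the nonparametric path with a flag).
Kruskal–Wallis uses the tie-corrected H with a χ² reference (k − 1 df);
all-identical values return H = 0, p = 1 rather than an error. Nemenyi
post hoc comparisons refer mean-rank differences to the studentized
range distribution with infinite df and tie-corrected rank variance; the
implementation is validated against the identity with the asymptotic
two-sided Mann–Whitney test at k = 2 and by Monte-Carlo family-wise
error calibration. No correction beyond Nemenyi's family-wise control is
applied by default. Inter-region ratios use the fixed orientations
base/metaphysis, base/epiphysis, metaphysis/epiphysis; zero denominators
and missing regions yield flagged NaN, never infinities. PCA centres and
unit-variance-scales each column, takes the SVD, drops constant columns
with a warning, and fixes signs so each loading vector's
largest-magnitude entry is positive; the two variants use the 10
base+metaphysis variables and the 5 epiphysis variables, complete-case
(assumed, since incomplete epiphysis rows simply reflect unossified
centres). `run_study` runs everything species-pooled and interspecific
(per age category; Neonates merge into Infant 1 when either species has
fewer than 3), at α = 0.05, reporting empty cells with explicit notes.

## Synthetic data

**Phantoms.** Plates and rod lattices are analytic periodic structures
sampled at voxel centres offset by half a voxel (keeping phase boundaries
off the sampling lattice, so closed-form BV/TV is matched exactly when
dimensions are commensurate). Foams are level sets of a
Gaussian-smoothed white-noise field thresholded at the exact target
quantile: statistically isotropic with the fill fraction matched by
construction. Ground truth: plate BV/TV = t/p, Tb.Th = t, Tb.Sp = p − t,
Tb.N = 1/p; rod BV/TV = πr²/s², Tb.Th = 2r (the rod Tb.Sp recorded is
the widest inscribed marrow sphere, a nominal value); solid/empty are
degenerate cases with undefined quantities flagged NaN.

**Synthetic metacarpals.** A miniature whole bone (10–16 mm long, growing
with age) with elliptical cross-sections, flared base and head, narrow
shaft; a cortical shell 0.3–0.6 mm thick (thicker mid-shaft); trabecular
fill in the base, metaphysis and (when ossified) epiphysis; marrow only
in the mid-shaft. The fill is a thresholded Gaussian random field whose
per-region threshold is set by quantile, so regional BV/TV is realised
*exactly*; the epiphyseal dorsopalmar gradient is a linear ramp of the
local target (positive = palmar-high for infants, negative = dorsal-high
for adults, zero for juveniles), renormalised so the region mean stays on
target. Voxel size scales with specimen size (0.05 mm at birth to
0.08 mm in adults), as scan protocols do, keeping the finest structures
resolvable at every age. Greyscale is produced by mapping phases to
intensities, Gaussian blur (σ = 0.7 voxel, emulating partial-volume
blur), and additive Gaussian noise (σ = 6 grey levels); no other scanner
physics is modelled. Below the fusion age (default 126 months) the
growth plate is a 3-slice unossified gap; the secondary centre is present
with a per-category probability (0, 0.11, 0.5, 0.78, 1) mirroring the
study-sample structure.

**Age trajectories.** No quantitative per-category parameter values are
available to emulate, so the defaults are qualitative by design and
documented as such: BV/TV and Tb.Th lowest at birth and rising with age
(with a small adult dip distally), Tb.Sp near-constant with a slight
adult increase, Tb.N = 1/(Tb.Th + Tb.Sp) therefore falling, DA
near-constant; between-individual SDs of roughly 10–15% of the mean.
`default_trajectory(age_effect=False)` flattens all categories to the
middle values — the null configuration for type-I-error simulations —
and no species effect is generated by default. Thickness and spacing of
the *image-level* fill follow the trajectory only qualitatively (a
thresholded random field has no closed-form chord length), which is why
image-level recovery checks target BV/TV, whose regional truth is exact;
the table-level cohort sampler draws all five parameters directly from
the trajectory with Tb.N kept exactly 1/(Tb.Th + Tb.Sp).

**What passing tests show.** The synthetic volumes exercise partial
volume blur, noise, three-phase segmentation, cortical-band estimation,
gap detection and spatial gradients, but not beam hardening, ring
artefacts, orientation error, cortical porosity or real trabecular
micro-architecture; recovery results on them bound pipeline error under
the generator's assumptions, not scanner physics.

## Problem sizes used in tests and the acceptance script

Tests validate estimators on 64³–120³ phantoms (voxels 0.02–0.05 mm) and
miniature whole bones of about 200×100×85 voxels; the end-to-end cohort
check runs 50 image-level specimens (10 per age category) with a 1 mm
grid / 2 mm VOIs / 0.4 mm mesh edge matched to the miniature bones, and
statistical calibration uses 500 table-level cohorts. The acceptance
script measures DA extremes over twenty 128³ phantoms at 0.025 mm voxels
with 5 mm VOIs, 128 directions and 1.5-voxel line spacing. These sizes
were chosen so the full suite completes on a single CPU while every
estimate remains well-resolved (≥ 8 voxels per thinnest structural
feature in the phantom recovery checks).

## Known limitations

- The cited commercial segmentation/morphometry toolchain is not
  reproduced bit-for-bit; its stages are re-implemented operationally and
  validated against synthetic truth, not against the original software.
- MIL uses grid-sampled secants with nearest-voxel lookup; direction
  families nearly parallel to a perfectly periodic structure can record
  zero crossings and enter the fit at the continuum limit, which is
  correct for phantoms but means per-direction MIL values (not DA) can be
  undefined in pathological single-phase cases.
- The dorsal-ridge fallback boundary for obliterated epiphyseal lines is
  an anatomical judgement and is exposed only as a manual override.
- Thickness maps use reflect/wrap padding heuristics at volume
  boundaries; for phases touching the boundary in non-periodic real data
  the outermost half-structure is approximated.
- The synthetic cohort draws parameters independently per specimen;
  covariances between trabecular parameters within individuals are not
  modelled beyond the Tb.N identity.
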
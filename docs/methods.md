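# Methods

## Deformation model

The transform is a free-form deformation parameterised by a hierarchy of
uniform cubic B-spline control lattices. One level evaluates to

    T(x) = sum_{l,m,n = 0..3} B_l(u) B_m(v) B_n(w) * Phi_{(i+l)(j+m)(k+n)},

with per-axis anchor `i = floor(x) - 1` and fraction `u = x - floor(x)`,
and the four standard cubic basis polynomials. `mgrefine` reads `Phi` as
**displacement vectors added to the identity**, not as absolute coordinate
targets: an all-zero lattice is then the identity map, and summing the
per-level transforms of a hierarchy is well defined. The total transform is
the sum of the per-level displacements, with the spacing halved exactly at
each level.

Coordinate conventions, fixed once:

* image coordinates are 0-based and voxel-centred; control point (0,…,0)
  sits at image coordinate (0,…,0). The lattice origin relative to the
  image is not uniquely determined by the evaluation formula alone (a
  half-spacing offset convention is equally consistent); this package pins
  it to the image origin.
* lattice units are image coordinates divided by the level's control
  spacing; spacing may differ per axis (clinical voxel grids are
  anisotropic — the isotropic mesh is the equal-spacing special case).
* each lattice carries exactly one margin control point beyond each
  boundary (conceptual indices −1 … N+1), so grid size per axis is
  `ceil(extent / spacing) + 3` and boundary evaluation never indexes
  outside storage. `u = 1` is accepted at the closed upper boundary of the
  basis argument so domain edges are well defined.
* displacements are stored in voxels of the image grid; `voxels_to_mm` /
  `mm_to_voxels` convert through the image's physical voxel spacing.

Refinement **appends** a zero-initialised lattice at half the finest
spacing and freezes nothing destructively: all coarse levels are retained
bit-identically and the dense field is unchanged by refinement alone. The
alternative reading — subdividing the coarse lattice into the fine one and
discarding it — was rejected because the hierarchy's total transform
explicitly retains every level. After refinement, editing a coarse level
triggers a warning rather than an error: revisiting a coarse grid is
permitted but usually indicates the wrong level is selected. Refinement
below one voxel of spacing is refused as meaningless.

Dense fields are rendered separably (per-axis weight matrices contracted
against the control grid), which is tested to agree with naive per-point
evaluation to better than 1e−12 rather than assumed.

## Warping

Resampling is **backward** (pull-back): output voxel x samples the input
at `x + T(x)` via `scipy.ndimage.map_coordinates` (nearest / linear /
cubic; linear is the default — fast and range-preserving, with cubic
available when resampling error matters). Backward mapping avoids holes
but inverts the intuitive drag direction: adding displacement d at a
control point moves image *content* by approximately −d. Session drag
events therefore record the desired **content motion** and the engine
negates the vector before touching the lattice; "drag content right →
content moves right" is a tested behaviour, not a convention note.

Samples falling outside the closed input grid bounds yield fill value 0
and are flagged in a validity mask — the mask *is* the overlap that the
SSD metric restricts to. When the input image itself came out of an
upstream warp, its own validity mask can be propagated through subsequent
warps (`input_mask` / `--transformed-mask`), so that fill voxels are never
scored as anatomy. This matters in practice: without it, a ~1% sliver of
fill at the image border dominates the residual SSD of an otherwise
well-recovered registration.

## Supervision: SSD and the RGB overlay

SSD is the mean of squared intensity differences over the masked voxels
(warp overlap intersected with an optional ROI); n is the number of masked
voxels. The variance of the squared differences is exposed as an auxiliary
statistic (`ssd_stats`); the mean is *the* metric. The metric is symmetric
in its arguments and obeys the closed form
`ssd(ref, a·ref + (1−a)·trans) = (1−a)² · ssd(ref, trans)`, both tested.

The RGB overlay places the (jointly rescaled) reference in the green band
and the transformed image in red + blue. The rescale uses the joint
min–max of **both** images to [0, 255]: equal raw intensities then map to
equal display values, so R=G=B — gray — genuinely means agreement.
Reference-brighter pixels trend green, transformed-brighter pixels purple.
`misregistration_mask` is the machine form of "the pixels that still look
green or purple": display-scale disagreement above a threshold (default 10
display units out of 255 in the CLI config — visible fringes, ignoring
noise-level differences).

The supervision rule — if SSD rises while dragging, invert the direction —
is automated by `suggest_direction`: it probes ± one step of content
motion per axis and returns the improving sign. SSD for the probe is
restricted to the control point's 4-cell support region; by B-spline
locality this is equivalent in effect to the global metric for a single
point and much cheaper, an equivalence exercised by the greedy-descent
tests rather than assumed.

## Sessions and replay

A revision session is versioned JSON: initial control spacing, metadata
(interpolation choice, image identifiers, display threshold) and an
ordered list of `drag` / `refine` events. Replay is deterministic —
bit-identical outputs across runs — and after every event the transformed
image is re-warped **from the original input** with the accumulated
deformation, never cumulatively resampled, so interpolation blur does not
compound; the final image equals a single warp by the final deformation
(tested by construction). The SSD trace has one entry per event plus the
pre-revision baseline at ordinal 0. There is no undo stack: delete the
event from the JSON and replay.

`auto_revise` is the scripted stand-in for a human operator: sweeps over
the finest lattice at shrinking step sizes (default 2, 1, 0.5 voxels — the
coarse-to-fine practice of manual revision), each control point moved in
the `suggest_direction` sign while its support-region SSD strictly
decreases, up to 8 quanta per axis per sweep. It is a greedy descent, not
an optimiser: no smoothness penalty is applied (SSD is the only criterion,
so a heavily revised field is accurate in similarity but carries no
explicit smoothness guarantee beyond what the B-spline basis provides),
and no claim of global optimality is made.

## Synthetic cases

`generate_phantom` emulates the features visual revision keys on: a dim
low-frequency background (smoothed noise, 20–80 of 255) plus 1–n bright
ellipsoidal "organs" (120–255) with a 1-voxel Gaussian partial-volume
rolloff on their boundaries, as real CT acquisition produces; boundaries
remain sharp at the scale of the deformations used. It does **not**
emulate anatomy, image noise, intensity drift between acquisitions,
occlusion, or differing fields of view — so passing recovery tests show
that the engine inverts known geometric misregistration under ideal
intensity constancy, not that revision is easy on clinical data.

`generate_truth_deformation` draws control displacements uniformly in
[−m, +m] per axis and refuses m ≥ spacing/2 (folding risk). The three
outermost control layers per side are pinned to zero: at a lattice-integer
border voxel the cubic support spans three control points, so this keeps
the image border exactly fixed, the overlap mask essentially full, and SSD
comparisons clean — a deliberate idealisation that isolates the
algorithmic claims. Every generator is seeded and regenerates
bit-identically.

The standard 2-D study case is a 128² phantom with 6 blobs, control
spacing 16 voxels and displacement magnitude ≤ 4 voxels (a quarter of the
spacing: clearly visible misregistration, safely below folding). These
sizes keep the full recovery experiment in seconds on one CPU while using
a realistic control-to-voxel ratio.

`ground_truth_session` builds the session that undoes a case's
deformation. Because replay re-warps the *transformed* image, the replayed
lattice must hold the **inverse** displacement: the first-order guess
(negated truth) leaves the second-order residual `T(x − T(x)) − T(x)`,
which at magnitude-4/spacing-16 is a visible fraction of the original
error. The inverse field is obtained by fixed-point iteration
`Dinv ← −T(x + Dinv(x))` (converges geometrically since |∇T| < 1 here)
and projected onto each lattice level by a separable least-squares fit,
coarse level first, finer level fitted to the remainder. The emitted drag
motions are the negated fitted coefficients (content must move by +truth).

## Numerical choices and degenerate inputs

* `x − floor(x)` can round to exactly 1.0 for tiny negative x; the
  decomposition detects this and carries into the next cell with
  fraction 0.
* Joint rescale of two constant equal images maps to mid-gray (127.5); an
  empty SSD mask (no overlap) is an error, not a NaN.
* Probing a control point whose support region has no valid voxels yields
  a "no improvement" suggestion (sign 0) rather than an error.
* Identity warps with nearest/linear interpolation are bit-exact; uniform
  translations agree with integer-shift oracles to ~1e−13 (partition of
  unity holds to round-off, not exactly).
* Level spacings are validated to halve exactly (relative tolerance
  1e−12); anisotropic spacing halves per axis.

## Known limitations

* Requires equal shapes for reference and transformed images; differing
  fields of view must be padded upstream.
* Refinement warps the already-transformed image; it does not compose
  with, or know about, the transform that produced it.
* Monomodal by design: SSD presumes intensity constancy. Mutual
  information / normalized correlation are out of scope.
* No inverse-consistency or diffeomorphism guarantee; large drags near
  the folding bound can produce non-invertible fields.
* Grayscale inputs only; DICOM series are expected to be converted to
  NIfTI upstream.
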
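# Methods

## Scope and assumptions

`seegwm` operates entirely in one common analysis space (an MNI-like RAS+
millimetre space): contact coordinates, the tissue atlas and the tract
atlases are assumed co-registered on identical voxel grids. Registration,
normalization, skull-stripping and contact localization from CT are upstream
of this package and out of scope; atlases are never resampled, and masks are
computed in the atlas's own voxel grid directly from world coordinates.

## Electrode geometry

"Contact spacing" is read as center-to-center distance, the usual
depth-electrode datasheet convention (the alternative reading — inter-contact
gap — would shift every center by the 2.29–2.41 mm contact length; the
datasheet shorthand does not disambiguate). Contact 1 is the deepest contact,
at the trajectory's target point. The Spencer-6 model has a dense distal
block (5 mm pitch between contacts 1–3) and a sparse proximal block (10 mm
between 4–6); the unstated 3→4 transition is set to the sparser block's
10 mm, configurable via `spencer_probe(transition_gap=...)`. The
reduced-diameter model is parametric: 6–10 contacts, uniform pitch in
[5, 8] mm (default 5). Hemisphere assignment is by the sign of x (x < 0
left); an electrode's laterality is its deepest contact's hemisphere.

## The 2×2×1 contact window

A 2-voxel window cannot be centred on a single voxel, so a centering
convention is required. Along each in-plane axis the window takes the two
voxels whose centers bracket the continuous voxel coordinate,
`{floor(c), floor(c)+1}`, with the tie at integer coordinates resolved toward
the negative pair; the singleton axis takes the nearest voxel plane (tie
again negative). Two properties motivated this choice over alternatives such
as "rounded voxel plus its negative neighbour":

* the window always physically covers the contact center, and
* every window voxel center lies within √(1² + 1² + 0.5²) = 1.5 mm of the
  contact center on a 1 mm grid — strictly less than the √3 mm voxel
  diagonal. Consequently a window can only straddle a decision surface
  (tissue interface or half-probability tract surface) when the contact is
  within √3 mm of it, which makes the phantom validation bands exact (see
  below). Centering rules with asymmetric reach up to
  √(1.5² + 1.5² + 0.5²) ≈ 2.18 mm would not admit this guarantee.

The singleton dimension defaults to the third (inferior–superior) array
axis and is configurable (`singleton_axis`), since trajectories are
predominantly oblique-axial; no orientation convention is imposed by the
window definition itself.

## Tissue classification

The atlas is reduced to two label sets (GM, WM); label 0 and all unlisted
labels are CSF/extra-parenchymal. Classification uses the full window, not
the center voxel: GM and WM if only the respective set is touched, boundary
if both, CSF if neither (including windows entirely outside the volume).
"Gray–white boundary" is thus operational — the only definition expressible
from a binary parcellation and a voxel window. Subcortical gray nuclei
belong in the GM set when configuring real atlases (the Harvard–Oxford
subcortical atlas labels them as gray structures); the split is entirely
caller-defined via the label config file.

## Crossing rule

Window aggregation is the maximum voxel value (the disconnectome convention
of reporting the highest tract probability touched); mean aggregation is
available and never exceeds the max. The crossing threshold is 0.5 with an
inclusive comparison ("chance or above"); a strict mode exists because the
two phrasings of the rule in common use disagree at exactly 0.5. Atlas
values outside [0, 1] are a hard validation error rather than being clamped,
to catch percent-vs-fraction unit mistakes.

## Cohort statistics and denominators

Percentage denominators follow the reporting conventions of cohort tables in
this literature, verified by reproducing printed count→percent pairs
exactly:

* tissue-class shares over intraparenchymal contacts; the intraparenchymal
  share over all contacts;
* per-tract contact shares over a scoped denominator — either all contacts
  crossing ≥ 1 tract, or white-matter-class contacts only;
* overlap censuses over white-matter-class contacts, with and without
  commissural tracts;
* the cohort probability of sampling a tract is the percentage of patients
  with ≥ 1 in-scope contact crossing it. Hemispheric probabilities are
  computed over patients who have ≥ 1 in-scope contact in that hemisphere
  (not over "patients implanted in that hemisphere" in the implant-side
  sense): this is the only stratification consistent with the printed
  left/right percentages we checked, all of which are integer counts over 44
  and 54 (white-matter scope) or 45 and 56 (all-contact scope) in an
  86-patient cohort with 46 left- and 56 right-implanted patients.
* per-tract mean ± SD contacts per patient are computed over the patients
  involved in the tract (consistent with tables pairing those means with
  involvement probabilities); SD is the sample standard deviation (n − 1),
  undefined (NaN) for a single patient.

All report-facing percentages round half-up at the column's precision
(2 decimals for tables, integers for prose-style shares), computed in
decimal arithmetic so integer-count ratios round exactly. One caveat found
while verifying: a printed "99% (1822/1826)" in the source material is a
truncation (the ratio is 99.78%, which rounds to 100%); the package always
rounds half-up.

Commissural tracts span both hemispheres and appear once, without a
hemispheric split.

## The synthetic phantom and its oracle

The phantom is geometric, not anatomical: a spherical brain (radius 54 mm)
with a 4 mm gray-matter shell over a white-matter core, CSF outside, an
axis-aligned ellipsoidal ventricle (semiaxes 6 × 10 × 6 mm), on a 128³ 1 mm
grid. Tracts are tubes around polyline centerlines with the linear radial
profile p(d) = max(0, 1 − d/r), radius 8 mm, so the p ≥ 0.5 crossing surface
is exactly the cylinder d = r/2 — a closed-form oracle for the crossing rule.
(A Gaussian profile with the same half-probability radius is available; its
tails are truncated at the tube's bounding box, so only the linear profile is
voxel-exact everywhere.) The default commissural band runs through both
association tubes so that multi-tract overlap regions exist, as commissural
fibers overlap association pathways in real disconnectome maps. Volumes
store the analytic functions evaluated exactly at voxel centers.

Ground-truth queries flag a contact as *ambiguous* when it lies within
√3 mm (one voxel diagonal) of any decision surface: a tissue interface or a
tract's half-probability surface. For the ellipsoidal ventricle the flag
uses the conservative lower bound |m − 1|·min(semiaxes) on surface distance
(m the normalized ellipsoidal radius), which can only over-flag. Outside the
ambiguity band, window-based decisions agree with the analytic oracle by
construction: every window voxel center is within 1.5 mm < √3 mm of the
contact, and voxel values are exact at voxel centers, so no window can reach
across a surface more than √3 mm away. The validation suite asserts 100%
agreement, and that is a geometric guarantee, not a sampling accident.

The cohort simulator draws 10 ± 2 electrodes per patient (minimum 3), a
50/50 Spencer-6 / reduced-diameter model mix (≈ 7.4 contacts per electrode),
and an implantation-side mix of 35/46/19% left/right/bilateral — the scale
of a typical SEEG cohort. Targets are uniform in the parenchyma of the
assigned side, outside the ventricle; directions point toward a same-side
entry point on the brain surface at least 25 mm away, so chains run outward
and proximal contacts may land in CSF, as clinically. Rejection sampling is
bounded (1000 attempts) and fails loudly naming the constraint. All
randomness flows through one `numpy` generator seeded per run; volumes are
written as uncompressed NIfTI so that identically seeded runs are
byte-identical (gzip embeds no such guarantee).

**What the phantom does not emulate:** cortical folding (the thin spherical
shell makes white matter dominate the tissue census, unlike real cohorts
where boundary contacts are the largest class), anatomical tract shapes and
their dense mutual overlap (the three tubes overlap only near their
intersections, so phantom overlap censuses are near zero), electrode
bending, and localization error. Passing the phantom suite therefore
demonstrates the correctness of the geometry, classification, thresholding
and aggregation machinery — not anatomical realism of the resulting
percentages.

## Validation problem sizes

The validation runs use the default 128³ phantom with its three tube tracts
and a 20-patient simulated cohort (~1300–1500 contacts, ~4200
contact × tract pairs), 10,000 random window placements for the mask
contract, and a four-point threshold sweep {0.3, 0.5, 0.7, 0.9}; these sizes
give thousands of unambiguous oracle comparisons while keeping a full run in
seconds.

## Known limitations

* The boundary class depends on the window convention; a center-voxel
  classification (which the inputs would equally support) yields fewer
  boundary contacts. The window-based reading is implemented.
* Tie-breaking at exact voxel centers is toward the negative neighbour and
  is sensitive to floating-point representation of coordinates that are
  mathematically integral after the affine transform.
* Hemisphere assignment by the sign of x assumes midline-aligned analysis
  space; contacts exactly at x = 0 form a separate "midline" stratum.
* Stimulation planning is an output artifact (contact lists and distances);
  it does not model current spread, charge density or bipolar montage
  geometry.
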
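# Methods

## The bench scene and its model

The scene is a PFA bench assay: a cylindrical glass dish (96 mm inner
diameter, 30 mm high, 2 mm wall) filled with Tyrode buffer, a tuber slab
(40 × 40 mm footprint, 20 mm high) centred in the bath with its top
surface 4 mm below the liquid surface, and two parallel stainless-steel
needle electrodes (0.63 mm diameter, 8 mm long, 1.37 mm inner gap →
2.00 mm axis-to-axis) whose tips touch the slab top. One electrode is
driven at 100–300 V, the other grounded. Conductivities: Tyrode
1.8 S/m, tuber tissue 0.04 S/m.

Pulses are brief (µs) relative to any charge-relaxation or thermal
time scale of interest here, so the field is modelled as a *stationary
conduction* problem, ∇·(σ∇φ) = 0, one solve per applied voltage.
Relative permittivities are parsed and stored for completeness but a DC
conduction solve has no permittivity dependence. The pulse train
(count, phase duration, frequency, interphase delay, polarity) is
metadata carried through to the output tables; no waveform simulation
is performed.

Two deliberate departures from a literal reading of the bench
description:

* **Equipotential electrodes.** The recorded electrode conductivity
  (1.74 mS/m) is far below the bath's and implausible for stainless
  steel; treating the needles as volumetric conductors at that value
  inserts an enormous spurious contact resistance. The default model
  therefore imposes the needle surfaces as equipotential Dirichlet
  boundaries (the standard idealization for metal in electrolyte). A
  volumetric-conductor mode with a user-set σ remains available for
  sensitivity studies (`solver.electrode_model = "volumetric"`).
* **Truncated domain.** The full dish at the default 0.1 mm spacing
  would need ~3 × 10⁷ cells. Because the tissue is ~45× more resistive
  than the bath, the field relevant to lesion formation is confined to
  a few mm around the electrode pair; the default domain is a box of
  ±8 mm (x, along the electrode axis) × ±6 mm (y) from the pair centre,
  spanning from the bath surface to 10 mm into the slab
  (160 × 120 × 140 = 2.7 M cells). On the tissue-surface plane the
  field at the domain boundary is ≈ 38–98 V/cm, well below the
  240 V/cm working level, so the working superlevel sets are interior.
  Extents are configurable for wider studies.

Coordinates: right-handed, origin at the midpoint between the electrode
axes on the slab top surface, x along the electrode axis, z increasing
*downward* into the tissue. Lengths in mm; exported fields in V/cm.

## Finite-volume solver

Uniform cell-centred grid (default 0.1 mm; electrode diameter resolved
by ≥ 3 cells is enforced). Seven-point finite-volume discretization
with **harmonic-mean face conductivities**, the standard choice for
flux continuity across the discontinuous bath/tissue interface. Outer
faces carry the insulation (zero normal current) condition; electrode
cells are Dirichlet cells.

**Cut-cell electrode boundary.** Marking cells whose centres fall
inside the needle cylinder and coupling them with plain face
conductances places the effective electrode surface roughly half a cell
inside the true one, a first-order radius bias. Faces between an active
cell and an electrode cell therefore use σ_active · h / θ, where θ is
the fractional distance from the active cell centre to the true
cylinder (or tip) surface along the face normal, clamped to [0.1, 1].
Against the closed-form two-wire (bi-cylindrical) potential in a
homogeneous quasi-2-D medium, the midpoint field error is ≈ 0.3 % at
both 0.1 mm and 0.05 mm spacing (≈ −5 % without the correction).

The symmetric positive-definite system is solved by Jacobi-conditioned
conjugate gradients to a relative residual of 1e-8 (≈ 100 s for the
2.7 M-cell default scene on one CPU). |E| is obtained with
second-order central differences of φ (`np.gradient`; one-sided at the
domain faces) and exported in V/cm (exact ×0.01 from V/m). Null
excitation short-circuits to φ ≡ 0. Diagnostics: the discrete maximum
principle (0 ≤ φ ≤ V), electrode current balance (≤ 1 % mismatch
required, ~1e-15 observed since the discrete fluxes are algebraically
conservative), and exact voltage linearity.

Isolines are extracted by marching squares
(`skimage.measure.find_contours`, linear edge interpolation; saddle
cells resolved by the average-of-corners rule). Superlevel-set areas
come from the oriented contour polygons of the padded plane — outer
boundaries counter-clockwise, holes clockwise, so signed shoelace areas
sum to the region area; this equals cell counting with fractional edge
cells by the same linear interpolation. On an analytic |E| = C/r plane
the area of {|E| ≥ L} matches π(C/L)² to < 0.1 %.

## Lesion imaging

Brightness segmentation follows the bench practice: Rec. 601 luma,
stained = luma < threshold (default 120 on 8-bit; the thresholds are
per-image overridable since staining and lighting vary). Cleanup keeps
every connected component at least 10 % the size of the largest and
fills holes: specks of stray dye and glare holes are removed, while a
lesion that legitimately splits into one stained lobe per electrode is
kept whole. Area is the raw pixel count times the calibrated pixel
area — no sub-pixel boundary correction, matching the plain counting
definition of the assay.

Length and width have no canonical definition in this assay; the fixed
convention here is **length = maximum Feret (caliper) diameter** and
**width = extent perpendicular to the length axis**, both computed on
pixel centres plus one pixel so that a single-pixel mask measures one
pixel size in each direction (width ≤ length holds by construction).

The cut view is polygonized automatically (marching squares on the
mask, 1 px simplification, clipped to the tissue side of the
user-supplied top cut line); an interactive tool would supply the
vertex list directly — both paths produce the same `CutViewPolygon`.
Depth is the maximum vertex distance from the top cut line along its
perpendicular bisector.

## Similarity volumetry

The estimator assumes cross-sections at depth are geometrically similar
scaled copies of the surface lesion, so A(z) = r(z)² · A_top with
r(z) = chord(z) / top-line length, and V = ∫₀ᵈ A(z) dz by the
trapezoidal rule. Choices:

* depth grid: uniform, both endpoints included, **n_slices = 101**
  (doubling to 201 moves smooth-fixture volumes < 0.2 %; trapezoid
  error is O(h²) on C² integrands);
* non-convex sections: chord = **total covered interval length** (sum
  of sub-chords), with the single-interval span available via flag;
* r(0) = 1 by construction; ratios above **r_cap = 1.05** (surface
  digitization noise) are clipped and flagged, preserving the
  proportionality while bounding noise inflation — with the cap at 1,
  V ≤ A_top · d exactly;
* the terminal chord at z = d may be zero-width.

`validate_similarity_assumption` quantifies how well the premise holds
for a solved field: per depth, the superlevel contour is centred and
scaled to unit width along the electrode axis and compared to the top
contour by symmetric-difference-over-union area (0 = exactly similar).
It is a reported diagnostic, not an assertion — for the default scene
the near-surface cross-sections bulge slightly outward relative to the
surface contour (the chord-ratio cap warning seen in pipeline runs is
the same effect).

## Threshold calibration

The lesion's outer edge marks the minimum field that produced
irreversible damage. Primary estimator: **area matching** — bisection
on the field level whose superlevel-set area equals the measured lesion
area (monotone, bracket [1 V/cm, plane max], converged at ≤ 0.5 %
relative area mismatch or 60 halvings; out-of-range lesions are
flagged, not silently returned). Cross-check: **boundary quantile** —
|E| bilinearly sampled along the lesion boundary after rigid
registration (electrode-mark midpoint → scene origin, mark axis →
electrode axis), reporting a quantile (default median; quantile 0 is
the literal minimum-field reading) with the IQR as a
registration-quality diagnostic. The comparison plane defaults to the
tissue-surface layer, matching top-view lesions; the mid-electrode
vertical plane is available for cut-view work. Both methods are
reported side by side; summaries are per-condition mean ± SEM only.

## Synthetic ground truth

The fixture generator emulates what the assay photographs actually look
like: a dark stained lesion (luma 40) on a light tuber background
(luma 220) with a linear illumination gradient (±15 luma), Gaussian
sensor noise (default σ = 8), a 10 mm scale bar and electrode contact
marks burned at known pixel positions, at 0.05 mm/px (close-up camera
scale). Rendering is luma-only by design — segmentation is brightness
thresholding, so texture realism adds nothing to what the tests can
show. Fiducials are burned after the noise (crisp and deterministic);
the scale bar uses mid-gray luma 150 so it can never be segmented as
stain, while electrode marks are dark like the real contact punctures
(invisible inside the stain, speck-cleaned outside it). A seed fixes
the images byte-exactly and perturbs only the noise, never the truth
sidecar.

Truth metrics: closed forms for half-ellipsoids (area πab, depth c,
volume ⅔πabc); voxel brute force at 0.05 mm for peanut unions; voxel
counting on the solver grid for field superlevel lesions. Truth for
non-analytic solids is never computed by the similarity estimator under
test (oracle independence).

What the fixtures do **not** emulate: potato texture, oxidation
background drift, slice buckling, partial-volume blur at the stain
edge, or non-rigid camera distortion. Passing tests demonstrate the
pipeline's numerical correctness and its robustness to noise,
illumination drift and rotation at realistic contrast — not robustness
to every photographic artefact of a real bench.

## End-to-end check and problem sizes

The headline self-consistency experiment: solve the default scene at
300 V (0.1 mm grid), build the lesion as the tissue superlevel set at
240 V/cm (22.2 mm² surface area, 1.7 mm deep), render both views with
σ = 8 noise, and run segmentation → area matching. Recovered
threshold: 239.6 V/cm (−0.2 %); boundary median 240.2 V/cm. The error
budget is dominated by pixel quantization of the rendered lesion
boundary (~0.1 % of area at this lesion size), mapped through the local
slope of the area–level curve.

Test problem sizes were chosen for desk-scale runs: the 0.1 mm
reference solve appears once per session, unit tests use 0.2 mm or
purpose-built quasi-2-D grids, and the analytic-oracle comparisons use
0.05 mm where the oracle demands it.

## Known limitations

* No thermal or electro-thermal model (the assay measures temperature,
  but no thermal computation is defined for it) and no field-dependent
  tissue conductivity during pulsing.
* The similarity volume is exactly as good as its assumption; the
  shipped diagnostic quantifies the violation per scene but does not
  correct it.
* Threshold estimates inherit the segmentation threshold choice;
  strongly miscalibrated brightness thresholds shift the measured area
  and hence the EFT.
* The cut-cell correction treats electrode surfaces as vertical
  cylinders with flat tips; electrode bending or tilt is not modelled.
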
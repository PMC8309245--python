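# Methods

This note documents the measurement models behind `plastimorph`, the
parameters that matter, the synthetic-data model used for validation, and the
numerical conventions and limitations a user should know before trusting a
number.

## Calibration model

All metrics operate on an 8-bit luminance grid with an explicit physical
pixel size (nm per pixel edge).  The calibration is user input: SEM vendors
embed scale only in burned-in scale bars, and parsing those is error-prone,
so `plastimorph` refuses to produce physical metrics without an explicit
value.  Conversions are fixed and linear: RGB collapses with the BT.601
weights 0.299/0.587/0.114; 16-bit data maps linearly over the full container
range (v·255/65535), never percentile-stretched, so the 0–255 histogram
semantics used by the roughness indicator are preserved across images.
Regions of interest are half-open, 0-based rectangles; an ROI's physical
perimeter is 2(h+w)·p and its area h·w·p², with p the pixel size.

Two linearity invariants follow from construction and are enforced by tests:
re-loading a written 8-bit image is bit-identical, and doubling the pixel
size exactly doubles every reported length and quadruples every area.

## Edge metrics

Detection is the standard Canny pipeline (Gaussian blur of standard
deviation `sigma`, Sobel gradient, non-maximum suppression, hysteresis in
which weak pixels survive only when 8-connected to a strong edge), provided
by scikit-image.  The two hysteresis thresholds are specified as *fractions
of the per-image maximum gradient magnitude* (defaults 0.1 and 0.2,
`sigma` 2.0): absolute gradient units do not transfer between images, while
fractions do.  Edge-based comparisons are only meaningful when one parameter
set is used for the whole series; the API encodes this by taking a single
immutable parameter object per multi-ROI call.

Edge length is measured on the skeletonized map by chain-code stepping:
L = (N_orth + √2·N_diag)·p, where a diagonal link is not counted when it
shortcuts an occupied corner.  This is exact for straight horizontal,
vertical, and 45° chains — the convention the package commits to — at the
cost of a known systematic overestimate for oblique lines, maximal at 22.5°
(+8.2%, ≈+5.5% averaged over orientations).  Corrected step weights
(e.g. 0.948/1.343) would reduce that bias but sacrifice the exactness of the
axis-aligned cases; the package keeps the exact convention and documents the
bias instead.

A dark crack or ridge of finite width produces two gradient walls, so the
detector reports roughly twice the centreline length of ridge-like features.
Reported metrics use the raw detected length ("edges" as imaged); the
`halve=True` option divides by two for comparison against centreline ground
truth.  On synthetic crack fields this halved estimate lands within 10% of
the analytic length in ≥ 27/30 seeded fields (measured: typically 29–30/30,
mean error ≈ 7%, dominated by the chain-code bias plus end-cap loops).

Four metrics are reported per ROI: total edge length (µm), edge density
(µm per µm² of ROI), edge-pixel percentage (edge pixels / ROI pixels × 100),
and edge/perimeter ratio (a fragmentation index; heavily weathered fragments
exceed 5).  For thinned maps, density and percentage are linked by
density = (percent/100)/p up to a factor in [1, √2] from diagonal steps —
a useful internal consistency check that the test suite asserts on seeded
fixtures.

## Particle segmentation and grain sizes

The particle protocol is deliberately minimal — greyscale, one global
threshold, 8-connected labelling — because its purpose is to be reproducible
by non-specialists.  The default threshold is Otsu's criterion (appropriate
when foreground and background populations are both substantial); a fixed
numeric threshold and a polarity flag are available.  Components below
`min_area_px` (default 10) are discarded as noise specks.  Touching objects
are reported as one component: there is deliberately no watershed split, and
the overlap limitation is stated rather than hidden.

Per particle: area = pixel count·p², equivalent diameter d = 2√(A/π), and,
under the spherical assumption appropriate for nurdles, volume
(4/3)π(d/2)³ — the radius being estimated from the 2D projection.  Particles
touching the image border carry truncated geometry; they are flagged,
excluded from the grain-size histogram by default, but included in total
area.  Grain-size histograms use fixed-width bins anchored at 0.

On 50 disjoint synthetic disks (radii 2–10 µm) under standard noise the
count is exact and the mean absolute relative diameter error is ≈ 0.1%
(threshold bias and rasterization); a 46-µm-radius synthetic nurdle yields a
recovered volume of ≈ 4.078 × 10⁵ µm³ against the closed form 4.077 × 10⁵.

## Fibre morphometry

Fibre widths use the medial-axis/distance-transform construction: at each
skeleton pixel the Euclidean distance transform gives the inscribed-disk
radius, and the local width is taken as (2·EDT − 1) px — the −1 corrects the
half-pixel reach on each side, making odd pixel widths exact and bounding
even ones by one pixel.  Modal diameters are the dominant peaks of the
pixel-quantized width distribution, greedily selected by count with a 1 µm
separation window so each fibre fraction contributes one mode.

Inter-fibre spacing is the dual: local maxima of the *background* distance
transform are centres of largest inscribed empty disks, and twice their
radius is a local gap width.  Maxima whose disk reaches the image border
measure the field rather than a gap; their presence sets a
`boundary_dominated` flag (a single fibre in an empty field is the extreme
case).  On a parallel two-population mesh with 9.5 µm and 5.0 µm fibres the
modal widths are recovered to 9.4/4.9 µm (±1 px at 100 nm/px) and a 10 µm
surface gap is recovered exactly at the pixel quantum.

## Pore analysis

Pores are dark connected components inside an ROI, within a size window
(defaults: 10 px to 10% of the ROI).  The default threshold is the
*triangle* criterion rather than Otsu: a perforated substrate is a nearly
unimodal histogram with a small dark tail, the regime the triangle rule is
designed for, whereas Otsu bisects the background noise when no second mode
exists.  (Measured on 100 seeded perforation fields of 5–40 pores: exact
counts in 100/100 trials with triangle, 89/100 with Otsu.)  Pores crossing
the ROI boundary count toward count and area.

Reported metrics: count, density (count / ROI area), covered-area fraction,
and mean pore area.  The identity density × mean area = fraction/100 holds
by construction rather than being estimated twice.  Published per-figure
pore statistics in this problem domain are sometimes mutually inconsistent
(density × mean area exceeding the stated coverage); the module therefore
computes each quantity independently and never reconciles one from another.

## Histogram roughness

The luminance histogram always spans 256 fixed bins over 0–255
(normalization is display-only; statistics are computed on raw counts).
Spread is summarised by standard deviation (headline), interquartile range
(tie-break) and Shannon entropy in bits (≤ 8).  The physical reading: under
fixed beam and detector settings, a rough surface scatters electrons over a
wider intensity range, broadening the histogram, while an ideally flat
surface would give constant luminance and a single bin.  The comparison API
requires the caller to assert comparability (same apparatus parameters) and
refuses otherwise, because acquisition settings are not recoverable from the
image.  Profiles whose std differs by less than a configurable tolerance
(default 0.5 luminance levels) with equal IQR are "indistinguishable" — the
threshold for "broader" is a module decision, not an established constant.
On 100 paired synthetic fields (same noise realization with and without
cracks) the cracked surface has the strictly larger std in 100/100 pairs.

## Texture periodicity

Periods are estimated from the normalized linear autocorrelation of the
mean-subtracted image, evaluated along row lags and column lags
independently (FFT-based, normalized by the energies of the overlapping
slabs).  The period per axis is the smallest off-origin local maximum with
correlation ≥ 0.5, ties broken toward the smaller lag; images with no
qualifying peak on either axis are reported as *aperiodic* — a result, not
an error (constant and white-noise images land here).  Only axis-aligned
periodicity is modelled; an oblique lattice appears as its axis projections.

The unit template is the per-cell *median* over all full tiles (robust to
adsorbed-particle outliers).  The stored template keeps the source phase, so
tiling it reproduces the original pattern; the repeating element may
straddle the cell border at an arbitrary phase, so element dimensions are
measured on a circularly re-centred copy: the element is the minority-area
side of an Otsu split of the template, and its size is the bounding-box
extent in physical units.  Element "height" and "width" are in-plane
extents, not topographic heights.  On 50 seeded noisy lattices with random
periods (10–39 px), both periods are recovered within ±1 px in ≥ 90% of
cases (measured: 100%), and the tiled reconstruction of a noiseless lattice
correlates with its source at Pearson r ≈ 1.0.

## Surface reconstruction

The 3D view maps smoothed luminance (default Gaussian sigma 1 px, to
suppress shot noise) through min–max normalization to z ∈ [0, 1].  The z
axis is deliberately unitless: secondary-electron intensity correlates with
topography but is not calibrated height, and absolute heights would require
AFM or tilt-pair photogrammetry.  For the same reason the package computes
no surface area from z anywhere.  A constant image maps to all zeros (so
max z = 1 exactly characterises "has relief"), brighter pixels never map
lower, and the map is invariant to affine luminance rescaling.  Export is a
plain-text OBJ triangle mesh with x/y in µm: r·c vertices,
2(r−1)(c−1) triangles.

## Synthetic fixture model

The generators emulate the *geometry* and first-order noise of SEM imagery:
mid-grey substrates, bright fibres/spheres, dark cracks and pores, additive
Gaussian detector noise (default σ = 8 luminance levels, SNR ≈ 10 against
the default contrasts — a fixture choice representative of routine
micrographs) and optional signal-dependent shot noise.  Rasterization is
hard-edged so pixel-count oracles are exact; every primitive records its
continuous analytic geometry *and* its exact rasterized pixel count.  All
generators take explicit integer seeds, use a private `numpy` generator
(no global state), and are bit-reproducible.

Fixture-design choices worth knowing:

* Crack fields place mutually disjoint segments (clearance enforced with
  exact capsule geometry) with endpoints snapped to the pixel grid, so the
  recorded centreline length is exact; junction-free placement keeps that
  length analytically meaningful for the two-sided edge oracle.  Default
  line width is 2 px — the narrowest width whose two gradient walls the
  detector resolves separately.
* Pore and sphere fields rejection-sample disjoint disks; the margin is
  applied to the *drawn* rims (one extra pixel over the continuous radii)
  so 8-connected labelling can never bridge neighbours.  Physically
  impossible packings (> 50% coverage) are refused before drawing.
* Texture lattices are built in modular coordinates and are therefore
  periodic to the pixel regardless of field size.
* Parallel fibre arrays realise an exact surface-to-surface gap, as a
  calibration layout for the spacing estimator.

What these fixtures do *not* emulate: charging artefacts, detector shading,
beam–specimen interaction, focus drift, texture on the features themselves,
or the organic overburden of real environmental debris.  Passing the suite
demonstrates that the estimators are correct on known geometry under
detector-style noise — not that any particular real micrograph will
segment cleanly; threshold and Canny parameters remain an operator
responsibility on real data, which is why every run records its resolved
parameters in a sidecar.

## Numerical conventions and degenerate inputs

* Constant images: empty edge map, aperiodic texture, zero-std histogram,
  all-zero height map, threshold placed just above the constant value.
* `denoise(sigma=0)` and zero-noise synthesis are bit-identical no-ops.
* Ties in the autocorrelation peak search break toward the smaller lag;
  ties at a symmetric luminance step legitimately excite the two adjacent
  columns, and thinning reduces them to one chain.
* Zero-area ROIs are rejected at construction; empty inputs (no records,
  empty masks) produce empty results rather than errors.
* All randomness in tests and the acceptance script is seeded; identical
  CLI invocations produce byte-identical outputs (no timestamps in any
  artifact).

## Validation problem sizes

The acceptance script uses 30 crack fields (512², 20–200 µm total length),
50 noisy nurdles (1024² at 200 nm/px) plus one 46 µm calibration sphere,
100 perforation fields (512², 5–40 pores), one two-population fibre mesh and
one parallel-gap array (512²), 50 random bump lattices (256²), and 100
paired histogram fields (512²) — sizes chosen so the whole validation runs
in well under a minute on one CPU while keeping every feature ≥ 10 px so
rasterization error stays below the tolerances being tested.

## Known limitations

* No watershed separation: touching particles are one object.
* Chain-code length is biased up to +8.2% on oblique edges (exactness on
  axis-aligned chains was preferred; see Edge metrics).
* Edge "% of pixels" depends on the thinning state of the map it is
  computed from; the module computes it on the map as given.
* Oblique texture lattices are reported as axis projections.
* Fibre width modes assume fibres wider than ~3 px; below that the medial
  axis undersamples.
* The histogram indicator orders roughness only between comparably acquired
  images; it is not an absolute roughness (Ra/Sq) substitute.
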
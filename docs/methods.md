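# Methods

This note documents the models, conventions and numerical choices behind
`spheroquant`, and what the synthetic phantom does and does not emulate.

## The measurement model

The object of analysis is a single 2D fluorescence image of a spheroid
equatorial section, one channel per stain. Because spheroids are
approximately radially symmetric, an equatorial section is treated as
representative of the whole spheroid, and every spatial statistic is a
function of one coordinate: the distance from a cell to the spheroid
surface ("depth"). All reported distances are physical (μm); a pixel size
must therefore be known (TIFF resolution metadata or explicit override)
before any spatial quantity is computed.

## Segmentation

**Primary objects (nuclei).** Foreground by two-class Otsu on the full
image histogram, or a manual threshold. Shape-based declumping: the
Euclidean distance transform of the foreground is smoothed with a Gaussian
(a "filter of size *s*" means σ = *s*/2.355, the full-width-half-maximum
reading), its local maxima — no two closer than `maxima_min_distance_px`,
using scikit-image's square suppression footprint — seed a watershed on
the negated smoothed transform. Intensity-based declumping is not
implemented; the two parameters that matter in practice are the smoothing
size and the maxima separation, and the split count is monotone
non-increasing in the latter. Objects are then size-gated by equivalent
diameter, and border-touching objects (outermost pixel row/column) are
tagged `discarded_border` when exclusion is on — the border verdict
overrides the size verdict, so the three categories are mutually
exclusive. Accepted objects are relabelled 1..K in scan order (first
pixel, row-major), discarded ones after.

**Secondary objects (cells).** Each pixel within `max_expansion_px`
(Euclidean, point-to-seed-pixel-set) of an accepted seed is assigned to
its nearest seed; equidistant ties break toward the lower seed label so
the output is independent of scan order. This is implemented as one
distance transform per seed with a strict-less comparison in ascending
label order — exact, deterministic, and O(K) transforms (adequate at the
object counts of single-section analysis). The guide-image threshold is
computed and logged, but a cell never extends beyond the expansion cap:
in low-signal regions the cap alone defines the cell edge, which is the
behaviour wanted where cytoplasmic staining fades at the spheroid
periphery. Consequence: every secondary is a superset of its seed, carries
its seed's label, and secondaries partition the within-cap region along
equidistant frontiers.

**Spheroid footprint.** The detection image is smoothed at a scale
proportional to the expected diameter (filter size = estimate/20),
thresholded (manual preferred for this task; Otsu as fallback),
morphologically closed (disk radius = estimate/40), hole-filled, and the
largest 8-connected component whose equivalent diameter lies in
[0.5, 2.0] × the estimate is returned. Hole filling matters: a DAPI-dim
necrotic core must not punch a hole in the footprint. The perimeter is the
set of mask pixels with at least one background 4-neighbour (image edges
count as background).

Connectivity is fixed package-wide: 8-connected objects, 4-neighbour
perimeter test.

## Distance to surface

Distance = minimum Euclidean distance from the child's centroid (mean of
member pixel indices) to any perimeter pixel, × pixel size; positive if
the centroid's containing pixel is inside the mask, negative outside.
Implementation: a single distance transform of the perimeter set is
precomputed per spheroid and read at the centroid's containing pixel,
which agrees with the exact point-to-perimeter minimum to within √2/2 px
(the containing-pixel quantisation); the test suite verifies this bound
against an explicit perimeter scan on random blob masks. Children that
straddle the boundary are classified by their centroid's containing pixel.
Objects outside the footprint are kept with negative distance —
surface-adherent PBMCs are data.

## Depth profiles

Bins are [k·w, (k+1)·w) from depth 0, default width 25 μm (configurable;
the axis labels of typical spheroid depth plots are in tens of μm and no
canonical width exists). Only inside-spheroid records enter bins, so each
profile's Σ n_objects equals the inside count — a conservation invariant
the tests enforce. Per-bin mean intensity is the unweighted mean over
objects (the unit of analysis is the cell, not the pixel), which makes
refining bins and re-aggregating by count-weighted mean exact. Fractions
are stored in [0,1] and rendered as percentages. Ratio bins with a zero
denominator, and empty bins generally, are *undefined* (NaN), never zero
or infinity: zero-filling would fabricate signal in rings containing no
cells. Ring-area normalisation of infiltration counts divides by the
annulus area of the bin in the idealised circle of the spheroid's
equivalent radius, leaning on the same radial-symmetry assumption as the
depth axis itself.

## The phantom

`generate_phantom` draws a disk-shaped section with:

* nuclei as raised-cosine-edged disks (≈1 px edge) at dart-thrown
  positions with a minimum centre separation and a bounded retry budget —
  simple, seedable, and adequate below ~50% of the random-packing limit;
  no point-spread convolution (segmentation behaviour, not optics, is the
  target);
* a hypoxia channel whose per-cell amplitude follows a monotone
  depth→intensity function (default: flat 20 a.u. to 40 μm, linear rise to
  160 a.u.);
* a necrotic core (default radius 75 of 300 μm) whose nuclei keep 30% of
  the nuclear-stain amplitude — so a DAPI-only segmentation under-counts
  the core, and merging mAG+mKO2+DRAQ7 (per-pixel maximum) is the correct
  comprehensive nuclear image, as in real dead-core spheroids;
* dead-cell (DRAQ7) positivity: necrotic nuclei are always positive (the
  dye stains membrane-compromised cells by definition); the rest draw
  Bernoulli with a depth-dependent probability (default logistic rising
  toward the core). The closed-form expectation helper saturates the
  effective probability at 1 inside the core accordingly;
* FUCCI state for non-necrotic nuclei: mAG⁺ with a depth-decreasing
  probability (default logistic 0.85→0.05, midpoint 120 μm), else mKO2⁺ —
  cycling periphery, arrested interior;
* PBMCs as small dots placed by rejection sampling from a ring-density
  function (default uniform by area);
* a diffuse spheroid-body term (default 10 a.u.) in the DAPI channel —
  contiguous tissue plus out-of-focus light — without which a whole-mass
  footprint would not be detectable from a sparse nuclear image at all;
  kept low enough that Otsu still separates nuclei from background+body;
* additive Gaussian noise (sd 2 a.u.) on a background of 5 a.u., clipped
  at zero; Poisson shot noise is not modelled.

Defaults describe one realistic condition set: 300 μm spheroid radius at
1 μm/px (the deepest zones discussed for real spheroids lie near 280 μm),
300 nuclei of radius 5 μm ± 15% at ≥ 20 μm separation, signal amplitudes
≈ 100 a.u. (SNR ≥ 5). Every draw comes from one seeded generator in a
fixed order, so identical parameters and seed give bit-identical images
and ground truth.

`phantom_profile_expectation` integrates the generating depth-functions
against the ring-area measure w(d) ∝ (R − d) on a 4097-point grid per bin
(discontinuous steps are resolved to ~10⁻⁴ relative accuracy), giving the
analytic per-bin expectation that recovered profiles are tested against at
binomial/Poisson standard-error tolerances.

**What the phantom does not emulate** — optical point-spread and depth
attenuation, chromatic misregistration, intensity vignetting, nucleus
shape irregularity, clustered (non-Poisson) infiltration, asymmetric
spheroids. Tests passing on phantoms therefore demonstrate the
correctness of the measurement and statistics chain under known geometry,
not robustness to all real-microscopy artefacts; threshold and declumping
parameters still need per-dataset adjustment on real images.

## Validation choices

Distance measurement and profile recovery are validated against the
*true* disk surface (`GroundTruth.spheroid_mask()`): detecting a surface
from a smoothed, lumpy nuclear field wobbles the boundary by a few pixels,
which is a property of the sparse phantom, not of the machinery under
test. Surface detection itself is validated on analytic disks (equivalent
diameter recovered within 2%), and the full detected-mask chain runs in
the end-to-end pipeline tests. Segmentation-recovery conditions
(well-separated bright nuclei) use an effectively absent necrotic core so
every ground-truth nucleus is detectable in the DAPI channel; the
dim-core condition is exercised by the channel-merge tests.

## Pipeline and reproducibility

The pipeline validates its config before touching any input and reports
*all* violations at once. Stages log one structured line each (object
counts, computed thresholds). Cell-level intensity is measured on
secondary objects only for the hypoxia analysis; death and FUCCI measure
on nuclei (the signals are nuclear), infiltration on PBMC objects — three
analyses, three object types, composable in one run. The analysis chain
contains no randomness (Otsu is deterministic), so fixed inputs and config
give byte-identical tabular outputs; a resolved-config snapshot with all
defaults materialised is written beside the results and reproduces the
run exactly. A failed stage aborts with the stage name and removes partial
outputs.

Test and acceptance problem sizes (300-nucleus segmentation phantoms,
800-nucleus profile phantoms, ~256 px propagation phantoms, 50 blob masks
× 20 points for the distance oracle) were chosen as the smallest scales at
which the statistical tolerances above are meaningful.

## Known limitations

* 2D only: no volumetric reconstruction or 3D distances; asymmetric
  spheroids would need serial sections.
* Only TIFF input; microscopy proprietary formats must be converted
  upstream.
* Per-seed distance transforms make secondary propagation O(K) in the
  number of cells; fine for single sections, not tuned for mosaics with
  tens of thousands of seeds.
* Automatic positivity thresholds (Otsu on per-object means) need a
  genuinely bimodal distribution; degenerate distributions raise and ask
  for a manual threshold.
* The three biological zones sometimes drawn on depth profiles are left to
  the user's judgement; no automatic zone detection is attempted.
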
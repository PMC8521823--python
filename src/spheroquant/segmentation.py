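"""Object identification: nuclei (primary), cells (secondary), and the spheroid.

Three segmentation tasks drive the whole analysis:

* **primary objects** — nuclei from a nuclear stain, with shape-based
  declumping: local maxima of the smoothed Euclidean distance transform
  seed a watershed that splits touching nuclei;
* **secondary objects** — whole cells grown outward from the nuclear seeds
  by nearest-seed Euclidean propagation with a hard expansion cap (the
  "distance" method: where cytoplasmic signal is too dim to carry an edge,
  the cell boundary falls at the fixed expansion distance or at the
  equidistant frontier with a neighbour);
* **the spheroid footprint** — the one large object whose perimeter defines
  depth zero for every profile.

Conventions fixed package-wide: 8-connectivity for objects, 4-neighbour
background test for perimeter pixels; automatic threshold = two-class Otsu
on the full image histogram; a "smoothing filter of size s" is a Gaussian
with sigma = s / 2.355 (full width at half maximum reading of the size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed

from .errors import (
    InputError,
    InvalidMaskError,
    NoSpheroidFoundError,
    ParameterError,
    ShapeError,
)
from .image_io import ChannelImage

__all__ = [
    "ACCEPTED",
    "DISCARDED_SIZE",
    "DISCARDED_BORDER",
    "PrimaryParams",
    "SecondaryParams",
    "LabelMap",
    "SpheroidMask",
    "identify_primary_objects",
    "identify_secondary_objects",
    "identify_spheroid",
]

ACCEPTED = "accepted"
DISCARDED_SIZE = "discarded_size"
DISCARDED_BORDER = "discarded_border"

#: FWHM of a Gaussian with sigma 1; converts "filter size" to sigma.
_FWHM = 2.355

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class PrimaryParams:
    """Settings for primary-object (nucleus) identification.

    ``diameter_min_px``/``diameter_max_px`` bound the equivalent diameter
    (diameter of the circle with the object's area); objects outside the
    range are kept but tagged ``discarded_size``.  ``declump_smoothing_px``
    is the size of the smoothing filter applied to the distance transform
    before seed detection; ``maxima_min_distance_px`` is the minimum allowed
    separation of declumping seeds — larger values merge clumps, smaller
    values split them.
    """

    diameter_min_px: float
    diameter_max_px: float
    threshold_strategy: Literal["automatic", "manual"] = "automatic"
    manual_threshold: float | None = None
    declump_smoothing_px: float = 2.0
    maxima_min_distance_px: int = 5
    fill_holes: bool = True
    exclude_border: bool = True

    def validate(self) -> None:
        if not (0 < self.diameter_min_px < self.diameter_max_px):
            raise ParameterError(
                "need 0 < diameter_min_px < diameter_max_px, got "
                f"{self.diameter_min_px}, {self.diameter_max_px}"
            )
        if self.declump_smoothing_px < 0:
            raise ParameterError("declump_smoothing_px must be >= 0")
        if self.maxima_min_distance_px < 1:
            raise ParameterError("maxima_min_distance_px must be >= 1")
        if self.threshold_strategy not in ("automatic", "manual"):
            raise ParameterError(
                f"unknown threshold strategy {self.threshold_strategy!r}"
            )
        if self.threshold_strategy == "manual" and self.manual_threshold is None:
            raise ParameterError(
                "manual threshold strategy requires manual_threshold"
            )


@dataclass
class SecondaryParams:
    """Settings for secondary-object (cell) propagation.

    ``max_expansion_px`` caps how far a cell may extend beyond its nuclear
    seed (Euclidean, pixel-set to pixel-set).  The guide-image threshold is
    computed and logged but never extends a cell past the cap.
    """

    max_expansion_px: float = 5.0
    guide_threshold_strategy: Literal["automatic", "manual"] = "automatic"
    guide_manual_threshold: float | None = None

    def validate(self) -> None:
        if self.max_expansion_px < 0:
            raise ParameterError("max_expansion_px must be >= 0")
        if (
            self.guide_threshold_strategy == "manual"
            and self.guide_manual_threshold is None
        ):
            raise ParameterError(
                "manual guide threshold strategy requires guide_manual_threshold"
            )


@dataclass
class LabelMap:
    """Integer-labelled segmentation with per-object acceptance categories.

    Labels are consecutive from 1; accepted objects come first (1..K, scan
    order), then discarded ones.  ``categories`` maps every label to one of
    ``accepted``, ``discarded_size`` or ``discarded_border``.
    """

    labels: np.ndarray
    categories: dict[int, str]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ShapeError("labels must be 2D")
        present = set(np.unique(self.labels)) - {0}
        expected = set(range(1, len(self.categories) + 1))
        if present != expected or set(self.categories) != expected:
            raise ValueError(
                "labels must be consecutive from 1 with a category each; "
                f"present={sorted(present)}, categories={sorted(self.categories)}"
            )
        bad = set(self.categories.values()) - {
            ACCEPTED,
            DISCARDED_SIZE,
            DISCARDED_BORDER,
        }
        if bad:
            raise ValueError(f"unknown categories: {bad}")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_objects(self) -> int:
        return len(self.categories)

    @property
    def accepted_labels(self) -> list[int]:
        return [k for k, v in self.categories.items() if v == ACCEPTED]

    def accepted_only(self) -> "LabelMap":
        """A LabelMap containing only the accepted objects (labels 1..K)."""
        keep = np.array([0] + self.accepted_labels)
        lut = np.zeros(self.n_objects + 1, dtype=self.labels.dtype)
        lut[keep[1:]] = np.arange(1, len(keep))
        return LabelMap(
            lut[self.labels],
            {i: ACCEPTED for i in range(1, len(keep))},
            self.pixel_size_um,
        )


def _apply_threshold(
    pixels: np.ndarray, strategy: str, manual: float | None
) -> tuple[np.ndarray, float]:
    if strategy == "manual":
        if manual is None:
            raise ParameterError("manual strategy requires a threshold value")
        thr = float(manual)
    else:
        if np.unique(pixels).size < 2:
            # a constant image has no foreground under Otsu
            return np.zeros(pixels.shape, dtype=bool), float(pixels.flat[0])
        thr = float(threshold_otsu(pixels))
    return pixels > thr, thr


def _scan_order(labels: np.ndarray, ids: list[int]) -> list[int]:
    """Sort label ids by the row-major index of their first pixel."""
    flat = labels.ravel()
    first = {}
    for idx in np.flatnonzero(flat):
        lab = flat[idx]
        if lab not in first:
            first[lab] = idx
    return sorted(ids, key=lambda k: first[k])


def _relabel(
    labels: np.ndarray, category_of: dict[int, str], pixel_size_um: float
) -> LabelMap:
    """Relabel so accepted objects are 1..K in scan order, then discarded."""
    accepted = [k for k, v in category_of.items() if v == ACCEPTED]
    discarded = [k for k, v in category_of.items() if v != ACCEPTED]
    order = _scan_order(labels, accepted) + _scan_order(labels, discarded)
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    categories: dict[int, str] = {}
    for new, old in enumerate(order, start=1):
        lut[old] = new
        categories[new] = category_of[old]
    return LabelMap(lut[labels], categories, pixel_size_um)


def identify_primary_objects(
    image: ChannelImage, params: PrimaryParams
) -> LabelMap:
    """Identify nuclei (or other blob-like primaries) in one channel.

    Pipeline: threshold (Otsu or manual) -> optional hole filling ->
    shape-based declumping (seeded watershed on the negated smoothed
    Euclidean distance transform, seeds = local maxima separated by at least
    ``maxima_min_distance_px``) -> size gate on equivalent diameter ->
    optional border exclusion.  Border touching overrides the size verdict,
    so a too-small object at the edge is tagged ``discarded_border``.
    """
    params.validate()
    pixels = image.as_float()
    if not np.all(np.isfinite(pixels)):
        raise InputError("image contains non-finite values")

    foreground, _thr = _apply_threshold(
        pixels, params.threshold_strategy, params.manual_threshold
    )
    if params.fill_holes:
        foreground = ndimage.binary_fill_holes(foreground)
    if not foreground.any():
        return LabelMap(
            np.zeros(pixels.shape, dtype=np.int32), {}, image.pixel_size_um
        )

    components, _ = ndimage.label(foreground, structure=_EIGHT)
    edt = ndimage.distance_transform_edt(foreground)
    sigma = params.declump_smoothing_px / _FWHM
    smoothed = gaussian(edt, sigma=sigma, preserve_range=True) if sigma > 0 else edt

    peaks = peak_local_max(
        smoothed,
        min_distance=params.maxima_min_distance_px,
        labels=components,
        exclude_border=False,
    )
    markers = np.zeros(pixels.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        # no interior maxima (degenerate); fall back to the components
        labels = components
    else:
        labels = watershed(-smoothed, markers=markers, mask=foreground)

    ids = [int(k) for k in np.unique(labels) if k != 0]
    if not ids:
        return LabelMap(
            np.zeros(pixels.shape, dtype=np.int32), {}, image.pixel_size_um
        )
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=ids)
    eq_diam = np.sqrt(4.0 * areas / np.pi)

    border = np.zeros(pixels.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touches_border = set(np.unique(labels[border])) - {0}

    category_of: dict[int, str] = {}
    for k, d in zip(ids, eq_diam):
        if params.exclude_border and k in touches_border:
            category_of[k] = DISCARDED_BORDER
        elif not (params.diameter_min_px <= d <= params.diameter_max_px):
            category_of[k] = DISCARDED_SIZE
        else:
            category_of[k] = ACCEPTED
    return _relabel(labels, category_of, image.pixel_size_um)


def identify_secondary_objects(
    seeds: LabelMap, guide: ChannelImage, params: SecondaryParams
) -> LabelMap:
    """Grow cells outward from accepted nuclear seeds.

    Every pixel within ``max_expansion_px`` (Euclidean, to the seed's pixel
    set) of some accepted seed is assigned to its nearest seed; equidistant
    frontiers break toward the lower seed label so the output is independent
    of scan order.  Each secondary is a superset of its seed and keeps the
    seed's label.  Only accepted seeds propagate.
    """
    params.validate()
    if seeds.shape != guide.shape:
        raise ShapeError(
            f"seeds {seeds.shape} and guide {guide.shape} dimensions differ"
        )
    accepted = seeds.accepted_only()
    lab = accepted.labels
    out = np.zeros(lab.shape, dtype=np.int32)
    if accepted.n_objects == 0:
        return LabelMap(out, {}, seeds.pixel_size_um)

    # guide threshold is part of the method's log, not a cap-breaker
    _guide_fg, _guide_thr = _apply_threshold(
        guide.as_float(),
        params.guide_threshold_strategy,
        params.guide_manual_threshold,
    )

    best_dist = np.full(lab.shape, np.inf)
    # ascending label order + strict '<' = ties go to the lower label
    for k in range(1, accepted.n_objects + 1):
        dist_k = ndimage.distance_transform_edt(lab != k)
        closer = dist_k < best_dist
        best_dist[closer] = dist_k[closer]
        out[closer] = k
    out[best_dist > params.max_expansion_px] = 0
    return LabelMap(
        out,
        {k: ACCEPTED for k in range(1, accepted.n_objects + 1)},
        seeds.pixel_size_um,
    )


def _perimeter_mask(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with >= 1 background 4-neighbour (image edge counts)."""
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    h, w = mask.shape
    interior = (
        padded[0 : h, 1 : w + 1]
        & padded[2 : h + 2, 1 : w + 1]
        & padded[1 : h + 1, 0 : w]
        & padded[1 : h + 1, 2 : w + 2]
    )
    return mask & ~interior


@dataclass
class SpheroidMask:
    """The spheroid footprint whose perimeter defines depth zero.

    ``perimeter`` marks mask pixels with at least one background
    4-neighbour; ``distance_to_perimeter_px`` is the (unsigned) Euclidean
    distance from every pixel centre to the nearest perimeter pixel,
    precomputed once so relating thousands of objects stays cheap.
    """

    mask: np.ndarray
    pixel_size_um: float
    perimeter: np.ndarray = field(init=False)
    distance_to_perimeter_px: np.ndarray = field(init=False)
    centroid: tuple[float, float] = field(init=False)
    equivalent_diameter_px: float = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise InvalidMaskError("spheroid mask must be 2D and non-empty")
        n_comp = ndimage.label(self.mask, structure=_EIGHT)[1]
        if n_comp != 1:
            raise InvalidMaskError(
                f"spheroid mask must be one 8-connected component, got {n_comp}"
            )
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        self.perimeter = _perimeter_mask(self.mask)
        if not self.perimeter.any():
            raise InvalidMaskError("spheroid mask has an empty perimeter")
        self.distance_to_perimeter_px = ndimage.distance_transform_edt(
            ~self.perimeter
        )
        rows, cols = np.nonzero(self.mask)
        self.centroid = (float(rows.mean()), float(cols.mean()))
        self.equivalent_diameter_px = float(np.sqrt(4.0 * rows.size / np.pi))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def equivalent_radius_um(self) -> float:
        return 0.5 * self.equivalent_diameter_px * self.pixel_size_um


def identify_spheroid(
    image: ChannelImage,
    diameter_estimate_px: float,
    threshold_strategy: Literal["automatic", "manual"] = "manual",
    manual_threshold: float | None = None,
) -> SpheroidMask:
    """Detect the whole-spheroid footprint in a (typically nuclear) channel.

    The image is smoothed at a scale proportional to the diameter estimate
    (filter size = estimate/20) so single-cell texture averages out while
    the outline survives, thresholded (manual preferred for this task; Otsu
    as the automatic fallback), morphologically closed (radius =
    estimate/40), hole-filled, and the largest 8-connected component whose
    equivalent diameter falls within [0.5, 2.0] x the estimate is returned.
    """
    if not (diameter_estimate_px > 0):
        raise ParameterError("diameter_estimate_px must be positive")
    sigma = (diameter_estimate_px / 20.0) / _FWHM
    smoothed = gaussian(image.as_float(), sigma=sigma, preserve_range=True)
    fg, _thr = _apply_threshold(smoothed, threshold_strategy, manual_threshold)
    closing_radius = max(1, int(round(diameter_estimate_px / 40.0)))
    fg = ndimage.binary_closing(fg, structure=disk(closing_radius))
    fg = ndimage.binary_fill_holes(fg)

    components, n = ndimage.label(fg, structure=_EIGHT)
    best_label, best_area = 0, 0.0
    for k in range(1, n + 1):
        area = float(np.sum(components == k))
        d = np.sqrt(4.0 * area / np.pi)
        if 0.5 * diameter_estimate_px <= d <= 2.0 * diameter_estimate_px:
            if area > best_area:
                best_label, best_area = k, area
    if best_label == 0:
        raise NoSpheroidFoundError(
            "no component with equivalent diameter within [0.5, 2.0] x "
            f"{diameter_estimate_px:g} px"
        )
    return SpheroidMask(components == best_label, image.pixel_size_um)
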
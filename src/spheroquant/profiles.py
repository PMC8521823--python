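"""Per-object intensity measurement, positivity calls, and depth profiles.

Four profile analytics summarise the spheroid's radial organisation:

* **mean-intensity profile** — e.g. pimonidazole (hypoxia) per-cell mean
  intensity versus depth; rises toward the oxygen-starved core;
* **positive-fraction profile** — e.g. the fraction of DRAQ7-positive
  (dead) nuclei per depth bin;
* **infiltration-count profile** — immune-cell counts per depth bin, raw or
  normalised by the annulus area of the bin (an areal density);
* **ratio profile** — e.g. mKO2+/mAG+ per bin: low where cells cycle,
  rising where G1 arrest takes over.

Values are stored as fractions/ratios and rendered as percentages only in
plots.  Empty bins are reported as *undefined* (NaN) rather than zero:
zero-filling would fabricate signal in rings that simply contain no cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateDistributionError, ParameterError, ShapeError
from .image_io import ChannelImage
from .segmentation import LabelMap

__all__ = [
    "DepthProfile",
    "measure_object_intensity",
    "classify_positive",
    "mean_intensity_profile",
    "positive_fraction_profile",
    "infiltration_count_profile",
    "ratio_profile",
]


@dataclass
class DepthProfile:
    """A per-depth-bin statistic with counts and bin edges.

    ``value`` holds NaN in undefined bins (no objects, or zero denominator
    for a ratio); ``n_objects`` counts the inside-spheroid objects falling
    in each bin, so ``sum(n_objects)`` equals the number of inside-spheroid
    records the profile was built from.  ``extra`` carries per-kind detail
    (positive counts, numerator/denominator counts, outside count).
    """

    bin_edges_um: np.ndarray
    n_objects: np.ndarray
    value: np.ndarray
    value_kind: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.n_objects = np.asarray(self.n_objects, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if self.bin_edges_um.ndim != 1 or self.bin_edges_um.size < 2:
            raise ParameterError("need >= 2 bin edges")
        if self.bin_edges_um[0] != 0 or np.any(np.diff(self.bin_edges_um) <= 0):
            raise ParameterError("bin edges must ascend strictly from 0")
        n_bins = self.bin_edges_um.size - 1
        if self.n_objects.shape != (n_bins,) or self.value.shape != (n_bins,):
            raise ParameterError("n_objects/value length must match bins")

    @property
    def n_bins(self) -> int:
        return self.bin_edges_um.size - 1

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.value)

    @property
    def undefined_bins(self) -> set[int]:
        return set(np.flatnonzero(~self.defined))

    def to_frame(self) -> pd.DataFrame:
        """Tabular form for CSV export."""
        return pd.DataFrame(
            {
                "bin_start_um": self.bin_edges_um[:-1],
                "bin_end_um": self.bin_edges_um[1:],
                "n_objects": self.n_objects,
                "value": self.value,
                "value_kind": self.value_kind,
                "defined": self.defined,
            }
        )

    def plot(self, ax=None, as_percent: bool | None = None):
        """Bar plot of the profile (percentages for fraction-like kinds)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if as_percent is None:
            as_percent = self.value_kind == "positive_fraction"
        y = self.value * (100.0 if as_percent else 1.0)
        centers = 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])
        widths = np.diff(self.bin_edges_um)
        ax.bar(centers, np.nan_to_num(y), width=0.9 * widths, color="#4c72b0")
        ax.set_xlabel("distance from spheroid surface (μm)")
        label = self.value_kind.replace("_", " ")
        ax.set_ylabel(f"{label} (%)" if as_percent else label)
        return ax


def measure_object_intensity(
    objects: LabelMap, channel: ChannelImage
) -> pd.DataFrame:
    """Mean, median and integrated intensity per accepted object.

    Columns: ``object_id``, ``mean``, ``median``, ``integrated``; statistics
    are taken over each object's member pixels in the given channel.
    """
    if objects.shape != channel.shape:
        raise ShapeError(
            f"objects {objects.shape} and channel {channel.shape} differ"
        )
    ids = sorted(objects.accepted_labels)
    img = channel.as_float()
    if not ids:
        return pd.DataFrame(
            columns=["object_id", "mean", "median", "integrated"]
        )
    lab = objects.labels
    means = ndimage.mean(img, labels=lab, index=ids)
    sums = ndimage.sum_labels(img, labels=lab, index=ids)
    medians = ndimage.labeled_comprehension(
        img, lab, ids, np.median, float, np.nan
    )
    return pd.DataFrame(
        {
            "object_id": ids,
            "mean": np.asarray(means, dtype=float),
            "median": np.asarray(medians, dtype=float),
            "integrated": np.asarray(sums, dtype=float),
        }
    )


def classify_positive(
    means: np.ndarray | pd.Series,
    strategy: Literal["automatic", "manual"] = "automatic",
    manual_threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Flag objects as stain-positive from their per-object mean intensities.

    Manual: positive iff mean > ``manual_threshold``.  Automatic: two-class
    Otsu on the per-object mean distribution.  Returns ``(flags, threshold)``
    so the decision boundary can be logged alongside the calls.
    """
    means = np.asarray(means, dtype=float)
    if strategy == "manual":
        if manual_threshold is None:
            raise ParameterError("manual strategy requires manual_threshold")
        thr = float(manual_threshold)
    elif strategy == "automatic":
        if means.size == 0:
            raise ParameterError("automatic strategy needs >= 1 object")
        if np.unique(means).size < 2:
            raise DegenerateDistributionError(
                "automatic positivity threshold needs >= 2 distinct mean "
                "values; supply a manual threshold"
            )
        thr = float(threshold_otsu(means))
    else:
        raise ParameterError(f"unknown strategy {strategy!r}")
    return means > thr, thr


def _depth_bins(
    records: pd.DataFrame, bin_width_um: float, max_depth_um: float | None
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Bin inside-spheroid records by depth; returns (edges, inside, idx)."""
    if not (bin_width_um > 0):
        raise ParameterError("bin_width_um must be positive")
    required = {"distance_to_surface_um", "inside_spheroid"}
    missing = required - set(records.columns)
    if missing:
        raise ParameterError(f"records lack columns: {sorted(missing)}")
    inside = records[records["inside_spheroid"]]
    data_max = (
        float(inside["distance_to_surface_um"].max()) if len(inside) else 0.0
    )
    span = max(max_depth_um or 0.0, data_max, bin_width_um)
    n_bins = max(1, int(math.ceil(span / bin_width_um)))
    if data_max >= n_bins * bin_width_um:
        n_bins += 1  # depth exactly on the last edge falls in a final bin
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_um
    idx = np.floor(
        inside["distance_to_surface_um"].to_numpy() / bin_width_um
    ).astype(int)
    return edges, inside, idx


def mean_intensity_profile(
    records: pd.DataFrame,
    channel: str,
    bin_width_um: float,
    max_depth_um: float | None = None,
) -> DepthProfile:
    """Unweighted mean of per-object mean intensity, per depth bin.

    ``records`` must carry a ``{channel}_mean`` column (e.g.
    ``pimonidazole_mean``).  The mean is over objects, not pixels: the unit
    of analysis is the cell.
    """
    col = f"{channel}_mean"
    if col not in records.columns:
        raise ParameterError(f"records lack intensity column {col!r}")
    edges, inside, idx = _depth_bins(records, bin_width_um, max_depth_um)
    n_bins = edges.size - 1
    n = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=inside[col].to_numpy(), minlength=n_bins)
    value = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return DepthProfile(edges, n, value, "mean_intensity")


def positive_fraction_profile(
    records: pd.DataFrame,
    flag: str,
    bin_width_um: float,
    max_depth_um: float | None = None,
) -> DepthProfile:
    """Fraction of flag-positive objects per depth bin.

    ``records`` must carry a boolean ``{flag}_positive`` column (e.g.
    ``DRAQ7_positive``).  Stored as a fraction; rendered as percent in plots.
    """
    col = f"{flag}_positive"
    if col not in records.columns:
        raise ParameterError(f"records lack positivity column {col!r}")
    edges, inside, idx = _depth_bins(records, bin_width_um, max_depth_um)
    n_bins = edges.size - 1
    n = np.bincount(idx, minlength=n_bins)
    pos = np.bincount(
        idx,
        weights=inside[col].to_numpy().astype(float),
        minlength=n_bins,
    )
    value = np.where(n > 0, pos / np.maximum(n, 1), np.nan)
    return DepthProfile(
        edges, n, value, "positive_fraction",
        extra={"positive_counts": pos.astype(int)},
    )


def annulus_areas_um2(edges_um: np.ndarray, radius_um: float) -> np.ndarray:
    """Area of each depth bin's annulus in an idealized circular spheroid.

    The bin [a, b) maps to the ring between radii R-a (outer) and
    max(R-b, 0) (inner) of a circle of radius R = ``radius_um``.
    """
    outer = np.maximum(radius_um - edges_um[:-1], 0.0)
    inner = np.maximum(radius_um - edges_um[1:], 0.0)
    return np.pi * (outer**2 - inner**2)


def infiltration_count_profile(
    records: pd.DataFrame,
    bin_width_um: float,
    normalize: Literal["none", "ring_area"] = "none",
    spheroid_radius_um: float | None = None,
    max_depth_um: float | None = None,
) -> DepthProfile:
    """Counts of infiltrating objects (PBMCs) per depth bin.

    With ``normalize="ring_area"`` each count is divided by its bin's
    annulus area (um^2) in the circle of radius ``spheroid_radius_um``
    (typically the spheroid's equivalent radius), giving an areal density.
    Surface-adherent objects with negative distance are reported separately
    as ``extra["outside_count"]``, never silently dropped.
    """
    edges, inside, idx = _depth_bins(records, bin_width_um, max_depth_um)
    n_bins = edges.size - 1
    n = np.bincount(idx, minlength=n_bins)
    outside = int(len(records) - len(inside))
    if normalize == "none":
        value = n.astype(float)
        kind = "count"
        extra = {"outside_count": outside}
    elif normalize == "ring_area":
        if spheroid_radius_um is None:
            raise ParameterError(
                "ring_area normalization requires spheroid_radius_um"
            )
        areas = annulus_areas_um2(edges, spheroid_radius_um)
        value = np.where(areas > 0, n / np.where(areas > 0, areas, 1.0), np.nan)
        kind = "count_per_um2"
        extra = {"outside_count": outside, "annulus_areas_um2": areas}
    else:
        raise ParameterError(f"unknown normalize mode {normalize!r}")
    return DepthProfile(edges, n, value, kind, extra=extra)


def ratio_profile(
    records: pd.DataFrame,
    numerator_flag: str = "mKO2",
    denominator_flag: str = "mAG",
    bin_width_um: float = 25.0,
    max_depth_um: float | None = None,
) -> DepthProfile:
    """Per-bin ratio of numerator-positive to denominator-positive counts.

    The canonical use is mKO2+/mAG+: low where cells actively cycle, rising
    with depth as G1 arrest takes over.  Bins with zero denominator-positive
    objects are undefined (NaN), never infinity; both class counts are kept
    in ``extra``.
    """
    num_col = f"{numerator_flag}_positive"
    den_col = f"{denominator_flag}_positive"
    for col in (num_col, den_col):
        if col not in records.columns:
            raise ParameterError(f"records lack positivity column {col!r}")
    edges, inside, idx = _depth_bins(records, bin_width_um, max_depth_um)
    n_bins = edges.size - 1
    n = np.bincount(idx, minlength=n_bins)
    num = np.bincount(
        idx, weights=inside[num_col].to_numpy().astype(float), minlength=n_bins
    ).astype(int)
    den = np.bincount(
        idx, weights=inside[den_col].to_numpy().astype(float), minlength=n_bins
    ).astype(int)
    value = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return DepthProfile(
        edges, n, value, "ratio",
        extra={"numerator_counts": num, "denominator_counts": den},
    )
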
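"""Relating child objects (nuclei, cells, PBMCs) to the parent spheroid.

The key measurement is the distance from each child's centroid to the
closest perimeter pixel of the spheroid — the depth axis along which every
profile is binned.  The sign convention keeps objects outside the footprint
in the record set (negative distance) instead of dropping them: a PBMC
adhering to the surface but not infiltrated is data, not noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ShapeError
from .segmentation import LabelMap, SpheroidMask

__all__ = ["distance_to_surface", "relate_objects", "count_neighbors"]


def distance_to_surface(
    centroid: tuple[float, float], spheroid: SpheroidMask
) -> float:
    """Signed distance (um) from a centroid to the spheroid perimeter.

    Positive when the centroid's containing pixel lies inside the mask,
    negative outside, zero on a perimeter pixel.  Evaluated from the
    precomputed perimeter distance transform at the containing pixel, which
    agrees with the brute-force minimum over perimeter pixels from the exact
    (sub-pixel) centroid to within sqrt(2)/2 px.
    """
    r = int(np.clip(round(centroid[0]), 0, spheroid.shape[0] - 1))
    c = int(np.clip(round(centroid[1]), 0, spheroid.shape[1] - 1))
    d_px = float(spheroid.distance_to_perimeter_px[r, c])
    sign = 1.0 if spheroid.mask[r, c] else -1.0
    return sign * d_px * spheroid.pixel_size_um


def relate_objects(children: LabelMap, spheroid: SpheroidMask) -> pd.DataFrame:
    """One record per accepted child, with centroid, area and depth.

    Columns: ``object_id``, ``centroid_row``, ``centroid_col``, ``area_px``,
    ``distance_to_surface_um``, ``inside_spheroid``.  Children entirely
    outside the mask are retained (negative distance, ``inside_spheroid``
    False).  Sorted by ``object_id``.
    """
    if children.shape != spheroid.shape:
        raise ShapeError(
            f"children {children.shape} and spheroid {spheroid.shape} differ"
        )
    if children.pixel_size_um != spheroid.pixel_size_um:
        raise ShapeError("children and spheroid disagree on pixel_size_um")
    rows: list[dict] = []
    lab = children.labels
    for k in sorted(children.accepted_labels):
        rr, cc = np.nonzero(lab == k)
        centroid = (float(rr.mean()), float(cc.mean()))
        d = distance_to_surface(centroid, spheroid)
        rows.append(
            {
                "object_id": k,
                "centroid_row": centroid[0],
                "centroid_col": centroid[1],
                "area_px": int(rr.size),
                "distance_to_surface_um": d,
                "inside_spheroid": bool(d >= 0),
            }
        )
    columns = [
        "object_id",
        "centroid_row",
        "centroid_col",
        "area_px",
        "distance_to_surface_um",
        "inside_spheroid",
    ]
    return pd.DataFrame(rows, columns=columns)


def count_neighbors(
    objects: LabelMap, neighbor_distance_px: float
) -> pd.DataFrame:
    """Per-object neighbour counts for co-culture clustering analyses.

    Objects A and B are neighbours iff the minimum Euclidean distance
    between their pixel sets is <= ``neighbor_distance_px`` (boundary to
    boundary, not centroid to centroid).  The relation is symmetric and an
    object is never its own neighbour.  Counted over accepted objects.
    Columns: ``object_id``, ``neighbor_count``.
    """
    if neighbor_distance_px < 0:
        raise ValueError("neighbor_distance_px must be >= 0")
    lab = objects.labels
    ids = sorted(objects.accepted_labels)
    coords = {k: np.column_stack(np.nonzero(lab == k)) for k in ids}
    trees = {k: cKDTree(coords[k]) for k in ids}
    bbox = {
        k: (coords[k].min(axis=0), coords[k].max(axis=0)) for k in ids
    }
    counts = {k: 0 for k in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            # cheap bounding-box rejection before the exact test
            lo_a, hi_a = bbox[a]
            lo_b, hi_b = bbox[b]
            gap = np.maximum(lo_b - hi_a, lo_a - hi_b)
            if np.hypot(*np.maximum(gap, 0)) > neighbor_distance_px:
                continue
            d_min = trees[a].query(coords[b], k=1)[0].min()
            if d_min <= neighbor_distance_px:
                counts[a] += 1
                counts[b] += 1
    return pd.DataFrame(
        {"object_id": ids, "neighbor_count": [counts[k] for k in ids]}
    )
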
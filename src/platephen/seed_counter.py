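"""Seed detection and counting in pre-germination plate scans.

Seeds are darker than the agarose background in all three RGB channels, so a
per-channel threshold (Otsu within the well region by default) separates them.
Connected components are then classified by *solidity* — the ratio of an
object's pixel area to the area of its convex hull.  An isolated seed is
nearly convex (solidity usually > 0.9); touching seeds form a cluster with a
concave outline and lower solidity.  The number of seeds in a cluster is
estimated from its area divided by the average area of a single seed, which
itself is estimated as the median area of high-solidity objects across the
plate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .exceptions import EstimationError, ParameterError
from .plate_io import PlateImage

__all__ = [
    "SeedObject",
    "SeedDetection",
    "segment_seeds",
    "measure_objects",
    "count_seeds",
    "estimate_avg_seed_area",
    "count_plate",
    "DEFAULT_SOLIDITY_THRESHOLD",
]

DEFAULT_SOLIDITY_THRESHOLD = 0.9
#: debris filter as a fraction of the average single-seed area
MIN_AREA_FRACTION = 0.25


@dataclass
class SeedObject:
    well_label: str
    area_px: int
    convex_area_px: int
    solidity: float
    centroid: tuple[float, float]
    is_cluster: bool = False
    estimated_seeds: int = 1


@dataclass
class SeedDetection:
    well_label: str
    objects: list[SeedObject]
    seed_count: int
    avg_seed_area_px: float

    @property
    def n_clusters(self) -> int:
        return sum(o.is_cluster for o in self.objects)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def segment_seeds(
    image: PlateImage,
    well: str,
    thresholds: Sequence[float] | None = None,
    min_area: int = 8,
    min_contrast: float = 0.08,
) -> np.ndarray:
    """Binary seed mask for one well (local to the well's bounding box).

    ``thresholds`` are per-channel upper bounds (a pixel is seed when *all*
    channels fall at or below them); by default each bound is Otsu's threshold
    computed within the well region.  Holes are filled and objects smaller
    than ``min_area`` pixels removed.  A contrast guard returns an empty mask
    when the candidate foreground is not clearly darker than the background
    (e.g. an empty well), because Otsu always splits something.
    """
    patch, region = image.well_patch(well)
    if not region.any():
        return np.zeros(region.shape, dtype=bool)
    mask = region.copy()
    for ch in range(3):
        vals = patch[:, :, ch][region]
        if thresholds is not None:
            thr = float(thresholds[ch])
        else:
            if vals.max() - vals.min() < 1e-6:
                return np.zeros(region.shape, dtype=bool)
            thr = float(threshold_otsu(vals))
            # recentre mid-gap: Otsu may sit at the edge of the dark mode
            lo, hi = vals[vals <= thr], vals[vals > thr]
            if lo.size and hi.size:
                thr = 0.5 * (float(lo.mean()) + float(hi.mean()))
        mask &= patch[:, :, ch] <= thr
    if not mask.any() or mask.sum() > 0.5 * region.sum():
        return np.zeros(region.shape, dtype=bool)
    if thresholds is None:
        # empty-well guard: foreground must be darker than background
        fg = patch[mask].mean()
        bg = patch[region & ~mask].mean()
        if bg - fg < min_contrast:
            return np.zeros(region.shape, dtype=bool)
    mask = ndi.binary_fill_holes(mask)
    if min_area > 1:
        lab = cc_label(mask, connectivity=2)
        sizes = np.bincount(lab.ravel())
        mask = sizes[lab] >= min_area
        mask[lab == 0] = False
    return mask


def measure_objects(mask: np.ndarray, well_label: str = "") -> list[SeedObject]:
    """One :class:`SeedObject` per 8-connected component of ``mask``."""
    if not np.asarray(mask).any():
        return []
    lab = cc_label(mask, connectivity=2)
    out = []
    for rp in regionprops(lab):
        out.append(
            SeedObject(
                well_label=well_label,
                area_px=int(rp.area),
                convex_area_px=int(rp.area_convex),
                solidity=float(rp.solidity),
                centroid=tuple(float(v) for v in rp.centroid),
            )
        )
    return out


def count_seeds(
    objects: Iterable[SeedObject],
    avg_seed_area_px: float,
    solidity_threshold: float = DEFAULT_SOLIDITY_THRESHOLD,
    well_label: str = "",
    min_area_px: float | None = None,
) -> SeedDetection:
    """Classify objects as singles/clusters and sum the per-object estimates.

    An object with solidity >= ``solidity_threshold`` counts as one seed; a
    cluster contributes ``max(2, round(area / avg_seed_area_px))`` seeds
    (half-counts round away from zero).  Objects below ``min_area_px``
    (default ``0.25 * avg_seed_area_px``) are discarded as debris.
    """
    if avg_seed_area_px <= 0:
        raise ParameterError("avg_seed_area_px must be positive")
    if not (0 < solidity_threshold <= 1):
        raise ParameterError("solidity_threshold must be in (0, 1]")
    if min_area_px is None:
        min_area_px = MIN_AREA_FRACTION * avg_seed_area_px
    kept: list[SeedObject] = []
    for obj in objects:
        if obj.area_px < min_area_px:
            continue
        obj.is_cluster = obj.solidity < solidity_threshold
        obj.estimated_seeds = (
            1 if not obj.is_cluster else max(2, _round_half_away(obj.area_px / avg_seed_area_px))
        )
        if well_label and not obj.well_label:
            obj.well_label = well_label
        kept.append(obj)
    return SeedDetection(
        well_label=well_label or (kept[0].well_label if kept else ""),
        objects=kept,
        seed_count=sum(o.estimated_seeds for o in kept),
        avg_seed_area_px=float(avg_seed_area_px),
    )


def estimate_avg_seed_area(
    objects: Iterable[SeedObject],
    solidity_floor: float = DEFAULT_SOLIDITY_THRESHOLD,
    min_singles: int = 10,
) -> float:
    """Median area of high-solidity (single-seed) objects across many wells."""
    singles = [o.area_px for o in objects if o.solidity >= solidity_floor]
    if len(singles) < min_singles:
        raise EstimationError(
            f"only {len(singles)} single-seed objects (need >= {min_singles}); "
            "pass avg_seed_area_px manually"
        )
    return float(np.median(singles))


def count_plate(
    image: PlateImage,
    thresholds: Sequence[float] | None = None,
    solidity_threshold: float = DEFAULT_SOLIDITY_THRESHOLD,
    avg_seed_area_px: float | None = None,
) -> tuple[pd.DataFrame, dict[str, SeedDetection]]:
    """Segment, measure and count seeds in every well of a plate scan.

    When ``avg_seed_area_px`` is not given it is estimated from the plate
    itself (median area of high-solidity objects).  Returns a per-well table
    (plate_id, well, n_objects, n_clusters, seed_count, avg_seed_area_used)
    and the full per-well detections.
    """
    layout = image.layout
    per_well_objects: dict[str, list[SeedObject]] = {}
    for well in layout.labels():
        mask = segment_seeds(image, well, thresholds=thresholds)
        per_well_objects[well] = measure_objects(mask, well_label=well)
    if avg_seed_area_px is None:
        all_objects = [o for objs in per_well_objects.values() for o in objs]
        avg_seed_area_px = estimate_avg_seed_area(all_objects, solidity_floor=solidity_threshold)
    detections = {
        well: count_seeds(objs, avg_seed_area_px, solidity_threshold, well_label=well)
        for well, objs in per_well_objects.items()
    }
    rows = [
        {
            "plate_id": layout.plate_id,
            "well": well,
            "n_objects": len(det.objects),
            "n_clusters": det.n_clusters,
            "seed_count": det.seed_count,
            "avg_seed_area_used": det.avg_seed_area_px,
        }
        for well, det in detections.items()
    ]
    return pd.DataFrame(rows), detections
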
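"""Per-image bloom counting and per-plant-per-date aggregation across views.

Two counting strategies are provided. Plant-based counting keeps only
emerging-bloom detections whose bounding-box centroid lies inside the
detected target-plant box (boundary-inclusive), which suppresses false
positives from neighboring plants or background. Whole-image counting uses
every emerging-bloom detection regardless of location. Per-view counts are
then aggregated to one count per plant per scan date; the default takes
the maximum over the (up to four) viewing angles, on the hypothesis that
at least one angle shows most blooms on the plant.
"""

from __future__ import annotations

import logging
from statistics import fmean
from typing import Iterable, Sequence

import pandas as pd

from .detections import Detection, ImageDetections, PlantScan, filter_by_confidence

logger = logging.getLogger(__name__)

STRATEGIES = ("plant_based", "whole_image")
AGGREGATIONS = ("max", "sum", "mean")

#: Confidence below which a detection is discarded before counting.
DEFAULT_CONFIDENCE_THRESHOLD = 0.7


def _filtered(image: ImageDetections, threshold: float) -> list[Detection]:
    return filter_by_confidence(image.detections, threshold)


def count_whole_image(image: ImageDetections, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> int:
    """Number of emerging-bloom detections after confidence filtering."""
    return sum(1 for d in _filtered(image, threshold) if d.label == "emerging_bloom")


def count_plant_based(
    image: ImageDetections, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> tuple[int, list[str]]:
    """Count emerging blooms whose bbox centroid lies inside the plant bbox.

    Among confidence-filtered detections the target-plant box is the
    highest-confidence ``target_plant`` detection. Centroids exactly on the
    plant-box boundary count as inside. With no plant detection the count
    is 0 and the image is flagged.

    Returns ``(count, flags)`` where flags is a (possibly empty) list of
    degenerate-case markers.
    """
    dets = _filtered(image, threshold)
    plants = [d for d in dets if d.label == "target_plant"]
    flags: list[str] = []
    if not plants:
        if any(d.label == "emerging_bloom" for d in dets):
            flags.append("no_target_plant")
            logger.warning(
                "plant %s DAP %d view %d: blooms present but no target-plant "
                "detection; plant-based count forced to 0",
                image.plant_id, image.dap, image.view_index,
            )
        return 0, flags
    if len(plants) > 1:
        flags.append("multiple_target_plants")
    plant_box = max(plants, key=lambda d: d.confidence).bbox
    n = sum(
        1
        for d in dets
        if d.label == "emerging_bloom" and plant_box.contains(*d.bbox.centroid)
    )
    return n, flags


def aggregate_views(per_view_counts: Sequence[float], method: str = "max") -> float:
    """Aggregate the 1-4 per-view counts of one scan to a single count.

    ``max`` (the default) selects the viewing angle showing the most blooms;
    ``sum`` and ``mean`` are provided for ablation comparisons. ``mean``
    divides by the number of views actually present.
    """
    counts = list(per_view_counts)
    if not counts:
        raise ValueError("cannot aggregate an empty collection of view counts")
    if method == "max":
        return max(counts)
    if method == "sum":
        return sum(counts)
    if method == "mean":
        return fmean(counts)
    raise ValueError(f"unknown aggregation {method!r}; expected one of {AGGREGATIONS}")


def count_series(
    scans: Iterable[PlantScan],
    strategy: str = "plant_based",
    aggregation: str = "max",
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> pd.DataFrame:
    """Daily bloom counts for every plant and scan date.

    Returns a DataFrame with one row per (plant_id, dap), sorted by plant
    then DAP, with columns ``plant_id, dap, count, strategy, aggregation,
    source_view, flags``. ``source_view`` is the view index that attained
    the maximum (max aggregation only; ties broken toward the lowest view
    index). ``flags`` joins per-view degenerate-case markers with ';'.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    rows = []
    for scan in scans:
        per_view: list[float] = []
        view_idx: list[int] = []
        flags: list[str] = []
        for img in scan.views:
            if strategy == "plant_based":
                c, f = count_plant_based(img, threshold)
                flags.extend(f"{fl}@view{img.view_index}" for fl in f)
            else:
                c = count_whole_image(img, threshold)
            per_view.append(c)
            view_idx.append(img.view_index)
        agg = aggregate_views(per_view, aggregation)
        source_view = None
        if aggregation == "max":
            source_view = view_idx[per_view.index(max(per_view))]
        rows.append(
            {
                "plant_id": scan.plant_id,
                "dap": scan.dap,
                "count": agg,
                "strategy": strategy,
                "aggregation": aggregation,
                "source_view": source_view,
                "flags": ";".join(flags),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["plant_id", "dap", "count", "strategy", "aggregation", "source_view", "flags"],
    )
    return df.sort_values(["plant_id", "dap"]).reset_index(drop=True)
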
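"""Detection data model and I/O.

Per-image object-detection records for multi-view plant scans: bounding
boxes in pixel coordinates, class labels from a 5-class (or reduced
3-class) taxonomy, and classification confidence scores, grouped by plant,
scan date (days after planting, DAP) and viewing angle.

Two on-disk dialects are supported: a COCO-style detection JSON (list of
``{image_id, category_id, bbox:[x,y,w,h], score}`` plus ``images`` and
``categories`` tables) and a flat CSV with one detection per row.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date as _date, datetime
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: 5-class taxonomy used for labeling multi-view cotton scans.
FIVE_CLASS = ("target_plant", "emerging_bloom", "opened_boll", "specular_region", "other")
#: Reduced 3-class taxonomy; everything that is neither the plant nor a bloom
#: collapses into ``non_bloom``.
THREE_CLASS = ("target_plant", "emerging_bloom", "non_bloom")

#: Surjective 5-class -> 3-class label mapping.
TO_THREE_CLASS = {
    "target_plant": "target_plant",
    "emerging_bloom": "emerging_bloom",
    "opened_boll": "non_bloom",
    "specular_region": "non_bloom",
    "other": "non_bloom",
}

#: Default planting date used to convert calendar dates in input files to DAP.
DEFAULT_PLANTING_DATE = _date(2018, 6, 13)


class DetectionParseError(ValueError):
    """Malformed detection file; the message names the offending record."""


class TaxonomyError(ValueError):
    """A class label outside the active taxonomy."""


class AmbiguousViewError(ValueError):
    """Duplicate view index within one (plant, date) scan group."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned bounding box in pixel coordinates, corner form.

    Origin at the image top-left, x rightward, y downward; extents are
    inclusive. Invariants: ``xmin < xmax``, ``ymin < ymax``, all finite
    and non-negative.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        vals = (self.xmin, self.ymin, self.xmax, self.ymax)
        if not all(v == v and v not in (float("inf"), float("-inf")) for v in vals):
            raise ValueError(f"non-finite bbox coordinates: {vals}")
        if min(vals) < 0:
            raise ValueError(f"negative bbox coordinates: {vals}")
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(f"degenerate bbox (need xmin<xmax and ymin<ymax): {vals}")

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive point containment."""
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BBox":
        return cls(x, y, x + w, y + h)

    @classmethod
    def from_corners(cls, x0: float, y0: float, x1: float, y1: float) -> "BBox":
        """Build from two opposite corners given in any order."""
        return cls(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))


def centroid(b: BBox) -> tuple[float, float]:
    """Centroid ((xmin+xmax)/2, (ymin+ymax)/2) of a bounding box."""
    return b.centroid


@dataclass(frozen=True)
class Detection:
    """One bounding box with class label and confidence for one image."""

    bbox: BBox
    label: str
    confidence: float
    taxonomy: tuple[str, ...] = FIVE_CLASS

    def __post_init__(self) -> None:
        if self.label not in self.taxonomy:
            raise TaxonomyError(
                f"label {self.label!r} not in taxonomy {list(self.taxonomy)}"
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    def to_three_class(self) -> "Detection":
        """Map this detection onto the reduced 3-class taxonomy."""
        if self.taxonomy == THREE_CLASS:
            return self
        return replace(self, label=TO_THREE_CLASS[self.label], taxonomy=THREE_CLASS)


@dataclass
class ImageDetections:
    """All detections from one image: one plant, one scan date, one view."""

    plant_id: str
    dap: int
    view_index: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dap < 0:
            raise ValueError(f"dap must be >= 0, got {self.dap}")
        if self.view_index not in (0, 1, 2, 3):
            raise ValueError(f"view_index must be in {{0,1,2,3}}, got {self.view_index}")

    def to_three_class(self) -> "ImageDetections":
        return ImageDetections(
            self.plant_id,
            self.dap,
            self.view_index,
            [d.to_three_class() for d in self.detections],
        )


@dataclass
class PlantScan:
    """The (up to 4) per-view detection sets for one plant on one scan date."""

    plant_id: str
    dap: int
    views: list[ImageDetections]

    def __post_init__(self) -> None:
        if not 1 <= len(self.views) <= 4:
            raise ValueError(f"a scan needs 1-4 views, got {len(self.views)}")
        for v in self.views:
            if (v.plant_id, v.dap) != (self.plant_id, self.dap):
                raise ValueError(
                    f"view ({v.plant_id}, {v.dap}) does not belong to scan "
                    f"({self.plant_id}, {self.dap})"
                )


def filter_by_confidence(
    dets: Iterable[Detection], threshold: float
) -> list[Detection]:
    """Keep detections with confidence >= threshold, order preserved.

    A detection whose confidence equals the threshold exactly is kept:
    only strictly lower-confidence detections are removed.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return [d for d in dets if d.confidence >= threshold]


def group_scans(images: Iterable[ImageDetections]) -> list[PlantScan]:
    """Group per-image detection sets into one PlantScan per (plant, DAP).

    Duplicate view indices within a group raise :class:`AmbiguousViewError`;
    groups with fewer than 4 views are tolerated but logged.
    """
    groups: dict[tuple[str, int], list[ImageDetections]] = {}
    for img in images:
        groups.setdefault((img.plant_id, img.dap), []).append(img)
    scans = []
    for (plant_id, dap), views in sorted(groups.items()):
        seen = set()
        for v in views:
            if v.view_index in seen:
                raise AmbiguousViewError(
                    f"duplicate view_index {v.view_index} for plant "
                    f"{plant_id!r} at DAP {dap}"
                )
            seen.add(v.view_index)
        if len(views) < 4:
            logger.warning(
                "plant %s DAP %d has only %d view(s)", plant_id, dap, len(views)
            )
        scans.append(PlantScan(plant_id, dap, sorted(views, key=lambda v: v.view_index)))
    return scans


def _parse_dap(value: str, planting_date: _date) -> int:
    """Accept either an integer DAP or an ISO calendar date."""
    s = str(value).strip()
    try:
        return int(s)
    except ValueError:
        pass
    try:
        d = datetime.strptime(s, "%Y-%m-%d").date()
    except ValueError as exc:
        raise DetectionParseError(f"cannot parse date/DAP value {value!r}") from exc
    dap = (d - planting_date).days
    if dap < 0:
        raise DetectionParseError(f"date {s} precedes planting date {planting_date}")
    return dap


CSV_COLUMNS = (
    "plant_id",
    "date_or_dap",
    "view_index",
    "label",
    "confidence",
    "xmin",
    "ymin",
    "xmax",
    "ymax",
)


def read_detections_csv(
    path: str | Path,
    taxonomy: Sequence[str] = FIVE_CLASS,
    planting_date: _date = DEFAULT_PLANTING_DATE,
) -> list[ImageDetections]:
    """Read the flat CSV dialect (one detection per row, header required).

    Rows with an empty label mark images with zero detections so that empty
    images survive a round-trip.
    """
    path = Path(path)
    taxonomy = tuple(taxonomy)
    images: dict[tuple[str, int, int], ImageDetections] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise DetectionParseError(
                f"{path}: missing required columns {sorted(missing)}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                plant_id = row["plant_id"]
                dap = _parse_dap(row["date_or_dap"], planting_date)
                view = int(row["view_index"])
            except (KeyError, ValueError, DetectionParseError) as exc:
                raise DetectionParseError(f"{path}:{i}: {exc}") from exc
            key = (plant_id, dap, view)
            if key not in images:
                images[key] = ImageDetections(plant_id, dap, view)
            label = (row.get("label") or "").strip()
            if not label:  # empty-image marker row
                continue
            if label not in taxonomy:
                raise TaxonomyError(
                    f"{path}:{i}: label {label!r} not in taxonomy {list(taxonomy)}"
                )
            try:
                bbox = BBox.from_corners(
                    float(row["xmin"]), float(row["ymin"]),
                    float(row["xmax"]), float(row["ymax"]),
                )
                det = Detection(bbox, label, float(row["confidence"]), taxonomy)
            except (ValueError, TypeError) as exc:
                raise DetectionParseError(f"{path}:{i}: {exc}") from exc
            images[key].detections.append(det)
    return [images[k] for k in sorted(images)]


def write_detections_csv(images: Iterable[ImageDetections], path: str | Path) -> None:
    """Write images to the flat CSV dialect (empty images get a marker row)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for img in images:
            if not img.detections:
                writer.writerow([img.plant_id, img.dap, img.view_index, "", "", "", "", "", ""])
            for d in img.detections:
                writer.writerow(
                    [
                        img.plant_id,
                        img.dap,
                        img.view_index,
                        d.label,
                        repr(d.confidence),
                        repr(d.bbox.xmin),
                        repr(d.bbox.ymin),
                        repr(d.bbox.xmax),
                        repr(d.bbox.ymax),
                    ]
                )


def read_detections_coco(
    path: str | Path,
    taxonomy: Sequence[str] = FIVE_CLASS,
    planting_date: _date = DEFAULT_PLANTING_DATE,
) -> list[ImageDetections]:
    """Read a COCO-style detection JSON.

    Expected top-level keys: ``annotations`` (list of {image_id, category_id,
    bbox:[x,y,w,h], score}), ``images`` (list of {id, plant_id, date_or_dap,
    view_index}) and ``categories`` (list of {id, name}).
    """
    path = Path(path)
    taxonomy = tuple(taxonomy)
    with path.open(encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("annotations", "images", "categories"):
        if key not in doc:
            raise DetectionParseError(f"{path}: missing top-level key {key!r}")
    cat_names = {c["id"]: c["name"] for c in doc["categories"]}
    for cid, name in cat_names.items():
        if name not in taxonomy:
            raise TaxonomyError(
                f"{path}: category {cid} name {name!r} not in taxonomy {list(taxonomy)}"
            )
    images: dict[int, ImageDetections] = {}
    for rec in doc["images"]:
        try:
            images[rec["id"]] = ImageDetections(
                str(rec["plant_id"]),
                _parse_dap(rec["date_or_dap"], planting_date),
                int(rec["view_index"]),
            )
        except (KeyError, ValueError, DetectionParseError) as exc:
            raise DetectionParseError(f"{path}: images record {rec!r}: {exc}") from exc
    for ann in doc["annotations"]:
        try:
            img = images[ann["image_id"]]
            x, y, w, h = ann["bbox"]
            det = Detection(
                BBox.from_xywh(float(x), float(y), float(w), float(h)),
                cat_names[ann["category_id"]],
                float(ann["score"]),
                taxonomy,
            )
        except TaxonomyError:
            raise
        except (KeyError, ValueError, TypeError) as exc:
            raise DetectionParseError(f"{path}: annotation {ann!r}: {exc}") from exc
        img.detections.append(det)
    return [images[k] for k in sorted(images)]


def write_detections_coco(images: Iterable[ImageDetections], path: str | Path) -> None:
    """Write images as COCO-style detection JSON (x,y,w,h bbox dialect)."""
    images = list(images)
    labels = sorted({d.label for img in images for d in img.detections})
    cat_ids = {name: i + 1 for i, name in enumerate(labels)}
    doc = {
        "images": [
            {
                "id": i + 1,
                "plant_id": img.plant_id,
                "date_or_dap": img.dap,
                "view_index": img.view_index,
            }
            for i, img in enumerate(images)
        ],
        "categories": [{"id": cid, "name": name} for name, cid in cat_ids.items()],
        "annotations": [
            {
                "image_id": i + 1,
                "category_id": cat_ids[d.label],
                "bbox": [
                    d.bbox.xmin,
                    d.bbox.ymin,
                    d.bbox.xmax - d.bbox.xmin,
                    d.bbox.ymax - d.bbox.ymin,
                ],
                "score": d.confidence,
            }
            for i, img in enumerate(images)
            for d in img.detections
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


GENETIC_CATEGORIES = ("elite_hirsutum", "exotic_hirsutum", "barbadense")


@dataclass(frozen=True)
class PlantMetadata:
    """Genotype/batch assignment for one plant."""

    plant_id: str
    genotype: str
    genetic_category: str
    transplant_batch: int

    def __post_init__(self) -> None:
        if self.genetic_category not in GENETIC_CATEGORIES:
            raise ValueError(
                f"genetic_category {self.genetic_category!r} not in {GENETIC_CATEGORIES}"
            )
        if self.transplant_batch not in (1, 2):
            raise ValueError(f"transplant_batch must be 1 or 2, got {self.transplant_batch}")


def read_metadata(path: str | Path):
    """Read the plant metadata CSV into a DataFrame (one row per plant).

    Columns: plant_id, genotype, genetic_category, transplant_batch.
    Duplicated plant ids raise.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype={"plant_id": str, "genotype": str})
    required = {"plant_id", "genotype", "genetic_category", "transplant_batch"}
    missing = required - set(df.columns)
    if missing:
        raise DetectionParseError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["plant_id"].duplicated().any():
        dupes = df.loc[df["plant_id"].duplicated(), "plant_id"].tolist()
        raise DetectionParseError(f"{path}: duplicated plant_id(s) {dupes}")
    for row in df.itertuples(index=False):  # validate categories/batches
        PlantMetadata(row.plant_id, row.genotype, row.genetic_category, int(row.transplant_batch))
    return df


def read_manual_counts(path: str | Path):
    """Read the manual bloom-count CSV (plant_id, dap, manual_count)."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"plant_id": str})
    required = {"plant_id", "dap", "manual_count"}
    missing = required - set(df.columns)
    if missing:
        raise DetectionParseError(f"{path}: missing manual-count columns {sorted(missing)}")
    if (df["manual_count"] < 0).any():
        raise DetectionParseError(f"{path}: negative manual counts")
    return df.sort_values(["plant_id", "dap"]).reset_index(drop=True)


def read_detections(
    path: str | Path,
    format: str | None = None,
    taxonomy: Sequence[str] = FIVE_CLASS,
    planting_date: _date = DEFAULT_PLANTING_DATE,
) -> list[ImageDetections]:
    """Read detections, dispatching on ``format`` ('coco_json' or 'csv').

    If ``format`` is None it is inferred from the file suffix.
    """
    if format is None:
        format = "coco_json" if str(path).endswith(".json") else "csv"
    if format == "coco_json":
        return read_detections_coco(path, taxonomy, planting_date)
    if format == "csv":
        return read_detections_csv(path, taxonomy, planting_date)
    raise ValueError(f"unknown detection format {format!r}")
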
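"""Flowering characteristics extracted from count series and curves.

Four per-plant quantities, all reported on scan dates (DAP):

- FBD, first bloom date: the first scan date with a nonzero bloom count.
- FSD, flowering start date: the first scan date at which the cumulative
  flowering curve reaches at least 5% of the season total.
- FED, flowering end date: the first scan date reaching at least 95%.
- FD, flowering duration: FED - FSD in days.

Thresholds attained exactly count as attained, and no between-date
interpolation is used. FBD is computed from the count series rather than
the curve so that it is defined even before 5% is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import (
    BloomCountSeries,
    FloweringCurve,
    ZeroBloomError,
    cumulative_curve,
    series_from_counts,
)

FSD_THRESHOLD = 0.05
FED_THRESHOLD = 0.95


@dataclass(frozen=True)
class FloweringCharacteristics:
    """FBD/FSD/FED/FD for one plant, all in DAP (FD in days)."""

    plant_id: str
    fbd: int
    fsd: int
    fed: int
    fd: int
    total_blooms: float

    def __post_init__(self) -> None:
        if not (self.fbd <= self.fsd <= self.fed):
            raise ValueError(
                f"plant {self.plant_id!r}: need fbd <= fsd <= fed, got "
                f"{self.fbd}, {self.fsd}, {self.fed}"
            )
        if self.fd != self.fed - self.fsd:
            raise ValueError("fd must equal fed - fsd")


def first_bloom_date(series: BloomCountSeries) -> int:
    """Smallest scan DAP with a nonzero bloom count."""
    nz = np.nonzero(series.counts > 0)[0]
    if len(nz) == 0:
        raise ZeroBloomError(
            f"plant {series.plant_id!r} has no blooms; first bloom date undefined"
        )
    return int(series.daps[nz[0]])


def _first_reaching(curve: FloweringCurve, threshold: float) -> int:
    # float-tolerant ">= threshold": an exactly attained threshold counts
    idx = np.nonzero(curve.p >= threshold - 1e-12)[0]
    return int(curve.daps[idx[0]])


def flowering_start_date(curve: FloweringCurve, threshold: float = FSD_THRESHOLD) -> int:
    """First scan DAP at which at least ``threshold`` of blooms have opened."""
    return _first_reaching(curve, threshold)


def flowering_end_date(curve: FloweringCurve, threshold: float = FED_THRESHOLD) -> int:
    """First scan DAP at which at least ``threshold`` of blooms have opened."""
    return _first_reaching(curve, threshold)


def flowering_duration(fsd: int, fed: int) -> int:
    """Days between flowering start and end dates."""
    return fed - fsd


def extract_characteristics(
    series: BloomCountSeries,
    fsd_threshold: float = FSD_THRESHOLD,
    fed_threshold: float = FED_THRESHOLD,
) -> FloweringCharacteristics:
    """All four flowering characteristics from one bloom-count series."""
    curve = cumulative_curve(series)
    fbd = first_bloom_date(series)
    fsd = flowering_start_date(curve, fsd_threshold)
    fed = flowering_end_date(curve, fed_threshold)
    return FloweringCharacteristics(
        series.plant_id, fbd, fsd, fed, flowering_duration(fsd, fed), series.total
    )


def characteristics_table(
    counts: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    method: str = "imaging",
    fsd_threshold: float = FSD_THRESHOLD,
    fed_threshold: float = FED_THRESHOLD,
) -> tuple[pd.DataFrame, list[str]]:
    """Characteristics for every plant in a per-(plant, dap) count table.

    Returns ``(table, zero_bloom_plants)``; plants that never flowered are
    reported separately, not silently dropped. When ``metadata`` is given,
    genotype / genetic_category / transplant_batch columns are merged in.
    """
    rows = []
    zero_plants: list[str] = []
    for plant_id, series in series_from_counts(counts).items():
        try:
            ch = extract_characteristics(series, fsd_threshold, fed_threshold)
        except ZeroBloomError:
            zero_plants.append(plant_id)
            continue
        rows.append(
            {
                "plant_id": ch.plant_id,
                "fbd": ch.fbd,
                "fsd": ch.fsd,
                "fed": ch.fed,
                "fd": ch.fd,
                "total_blooms": ch.total_blooms,
                "method": method,
            }
        )
    df = pd.DataFrame(
        rows, columns=["plant_id", "fbd", "fsd", "fed", "fd", "total_blooms", "method"]
    )
    if metadata is not None and len(df):
        df = df.merge(
            metadata[["plant_id", "genotype", "genetic_category", "transplant_batch"]],
            on="plant_id",
            how="left",
        )
        df = df[
            ["plant_id", "genotype", "genetic_category", "transplant_batch",
             "fbd", "fsd", "fed", "fd", "total_blooms", "method"]
        ]
    return df, zero_plants
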
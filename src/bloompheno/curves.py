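"""Flowering curves: per-plant cumulative bloom percentage over the season.

The cumulative flowering curve of a plant is

    P_k = (sum_{i<=k} C_i) / (sum_{i<=N} C_i)

where C_i is the emerging-bloom count on the i-th scan date and N indexes
the last scan of the flowering period. P is a nondecreasing step function
of days after planting (DAP), equal to 1 at the final scan date; between
scan dates it is extended by previous-value (step) interpolation, and it is
0 before the first scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ZeroBloomError(ValueError):
    """The plant never flowered; its curve is undefined."""


@dataclass
class BloomCountSeries:
    """Per-plant sequence of (DAP, emerging-bloom count) over the season."""

    plant_id: str
    daps: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.daps = np.asarray(self.daps)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.daps.shape != self.counts.shape or self.daps.ndim != 1:
            raise ValueError("daps and counts must be 1-D arrays of equal length")
        if len(self.daps) and np.any(np.diff(self.daps) <= 0):
            raise ValueError("scan DAPs must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("bloom counts must be >= 0")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class FloweringCurve:
    """Cumulative percentage of opened blooms vs DAP for one plant."""

    plant_id: str
    daps: np.ndarray
    p: np.ndarray
    total_blooms: float

    def __post_init__(self) -> None:
        self.daps = np.asarray(self.daps)
        self.p = np.asarray(self.p, dtype=float)
        if np.any(np.diff(self.p) < -1e-12):
            raise ValueError("cumulative percentage must be nondecreasing")
        if np.any((self.p < -1e-12) | (self.p > 1 + 1e-12)):
            raise ValueError("cumulative percentage must lie in [0, 1]")


@dataclass
class GroupCurve:
    """Pointwise mean/std flowering curve of a group of plants on a grid."""

    label: str
    daps: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n_plants: int = 0


def cumulative_curve(series: BloomCountSeries) -> FloweringCurve:
    """Cumulative flowering curve from a bloom-count series.

    Raises :class:`ZeroBloomError` when the plant has zero total blooms.
    The curve is invariant to rescaling all counts by a positive constant
    and always ends at exactly 1.
    """
    total = series.total
    if total <= 0:
        raise ZeroBloomError(
            f"plant {series.plant_id!r} has zero total blooms; curve undefined"
        )
    p = np.cumsum(series.counts) / total
    p[-1] = 1.0  # exact by construction; guard against rounding
    return FloweringCurve(series.plant_id, series.daps.copy(), p, total)


def absolute_curve(series: BloomCountSeries) -> BloomCountSeries:
    """The raw per-scan-date bloom-count curve (identity passthrough).

    Useful for qualitative inspection (weather dips, flushes). Because the
    per-date counts systematically underestimate true bloom numbers at high
    bloom loads, these absolute curves should not be used for quantitative
    analyses; use :func:`cumulative_curve` instead.
    """
    return series


def step_interpolate(curve: FloweringCurve, grid: np.ndarray) -> np.ndarray:
    """Evaluate a flowering curve on a DAP grid by previous-value steps.

    Values before the first scan date are 0; from the last scan onward the
    curve stays at its final value (1 for a valid curve).
    """
    grid = np.asarray(grid)
    idx = np.searchsorted(curve.daps, grid, side="right") - 1
    out = np.where(idx >= 0, curve.p[np.clip(idx, 0, len(curve.p) - 1)], 0.0)
    return out


def group_mean_curve(
    curves: list[FloweringCurve], grid: np.ndarray, label: str = "", ddof: int = 1
) -> GroupCurve:
    """Pointwise mean and standard deviation of a group of flowering curves.

    Each curve is evaluated on ``grid`` by step interpolation. ``ddof=1``
    (sample std) is the default; singleton groups get std 0.
    """
    if not curves:
        raise ValueError("cannot average an empty group of curves")
    grid = np.asarray(grid)
    mat = np.vstack([step_interpolate(c, grid) for c in curves])
    mean = mat.mean(axis=0)
    std = mat.std(axis=0, ddof=ddof) if mat.shape[0] > ddof else np.zeros(len(grid))
    return GroupCurve(label, grid, mean, std, n_plants=len(curves))


def series_from_counts(counts: pd.DataFrame) -> dict[str, BloomCountSeries]:
    """Split a per-(plant, dap) count table into per-plant series.

    Expects columns ``plant_id, dap`` and one of ``count``/``manual_count``.
    """
    col = "count" if "count" in counts.columns else "manual_count"
    out = {}
    for plant_id, sub in counts.groupby("plant_id", sort=True):
        sub = sub.sort_values("dap")
        out[str(plant_id)] = BloomCountSeries(
            str(plant_id), sub["dap"].to_numpy(), sub[col].to_numpy(float)
        )
    return out


def curves_from_counts(
    counts: pd.DataFrame,
) -> tuple[dict[str, FloweringCurve], list[str]]:
    """Cumulative curves for every plant in a count table.

    Plants with zero total blooms cannot have a curve; they are excluded
    and their ids returned in the second element rather than silently
    dropped.
    """
    curves: dict[str, FloweringCurve] = {}
    zero_plants: list[str] = []
    for plant_id, series in series_from_counts(counts).items():
        try:
            curves[plant_id] = cumulative_curve(series)
        except ZeroBloomError:
            zero_plants.append(plant_id)
    return curves, zero_plants


def curves_table(curves: dict[str, FloweringCurve], counts: pd.DataFrame) -> pd.DataFrame:
    """Long-format table: plant_id, dap, count, cumulative_percentage."""
    col = "count" if "count" in counts.columns else "manual_count"
    rows = []
    for plant_id, curve in curves.items():
        sub = counts[counts["plant_id"] == plant_id].sort_values("dap")
        cnt = dict(zip(sub["dap"], sub[col]))
        for dap, p in zip(curve.daps, curve.p):
            rows.append(
                {
                    "plant_id": plant_id,
                    "dap": int(dap),
                    "count": cnt.get(int(dap), 0.0),
                    "cumulative_percentage": float(p),
                }
            )
    return pd.DataFrame(rows, columns=["plant_id", "dap", "count", "cumulative_percentage"])


def plot_group_curves(groups: list[GroupCurve], ax=None, percent: bool = True):
    """Plot group mean curves with +/-1 std shading (matplotlib required)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scale = 100.0 if percent else 1.0
    for g in groups:
        (line,) = ax.step(g.daps, g.mean * scale, where="post", label=g.label)
        ax.fill_between(
            g.daps,
            np.clip(g.mean - g.std, 0, 1) * scale,
            np.clip(g.mean + g.std, 0, 1) * scale,
            step="post",
            alpha=0.2,
            color=line.get_color(),
        )
    ax.set_xlabel("days after planting")
    ax.set_ylabel("cumulative opened blooms (%)" if percent else "cumulative fraction")
    ax.legend()
    return ax
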
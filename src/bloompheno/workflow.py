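"""End-to-end pipeline orchestration.

ingest -> confidence filter -> per-view counting -> view aggregation ->
cumulative curves -> flowering characteristics -> evaluation statistics ->
frequency study, with every stage's output persisted as CSV plus a run
manifest. The pipeline is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .characteristics import characteristics_table
from .counting import count_series
from .curves import curves_from_counts, curves_table
from .detections import (
    filter_by_confidence,
    group_scans,
    read_detections,
    read_manual_counts,
    read_metadata,
)
from .frequency import frequency_study
from .stats import ErrorAnalysis, RegressionResult, error_analysis, regress_origin

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline settings, with the study's defaults."""

    detections_path: str = ""
    metadata_path: str = ""
    manual_counts_path: str = ""
    output_dir: str = "run_output"
    detection_format: str | None = None  # inferred from suffix when None
    confidence_threshold: float = 0.7
    strategy: str = "plant_based"
    aggregation: str = "max"
    fsd_threshold: float = 0.05
    fed_threshold: float = 0.95
    alpha: float = 0.05
    power: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("confidence_threshold", "fsd_threshold", "fed_threshold",
                     "alpha", "power"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0 and name != "confidence_threshold":
                raise ValueError(f"{name}={v} outside (0, 1)")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold outside [0, 1]")
        if self.fsd_threshold >= self.fed_threshold:
            raise ValueError("fsd_threshold must be < fed_threshold")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)


@dataclass
class PipelineResult:
    """Outputs of one pipeline run (also persisted under ``output_dir``)."""

    counts: pd.DataFrame
    curves: pd.DataFrame
    characteristics: pd.DataFrame
    zero_bloom_plants: list[str]
    evaluation: "MethodComparison | None" = None
    frequency: pd.DataFrame | None = None
    output_dir: Path | None = None


@dataclass
class MethodComparison:
    """Imaging-vs-manual evaluation: regression, errors, curve differences."""

    regression: RegressionResult
    errors: ErrorAnalysis
    curve_differences: pd.DataFrame  # per genetic_category x frequency


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def compare_methods(
    imaging_counts: pd.DataFrame,
    manual_counts: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> MethodComparison:
    """Regression, error analysis and curve differences vs manual counts."""
    joined = imaging_counts[["plant_id", "dap", "count"]].merge(
        manual_counts[["plant_id", "dap", "manual_count"]],
        on=["plant_id", "dap"],
        how="inner",
    )
    if joined.empty:
        raise ValueError("no overlapping (plant_id, dap) samples between methods")
    reg = regress_origin(joined["manual_count"], joined["count"])
    errs = error_analysis(imaging_counts, manual_counts)
    diffs = pd.DataFrame()
    if metadata is not None:
        diffs, _ = frequency_study(imaging_counts, manual_counts, metadata)
    return MethodComparison(regression=reg, errors=errs, curve_differences=diffs)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full pipeline and persist every stage's output.

    Any stage failure is re-raised with the stage name prefixed so a run
    log points at the offending step and record.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("bloompheno")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _run_pipeline(config: RunConfig, outdir: Path) -> PipelineResult:
    images = _stage("ingest")(read_detections)(
        config.detections_path, config.detection_format
    )
    logger.info("ingested %d images", len(images))
    metadata = None
    if config.metadata_path:
        metadata = _stage("metadata")(read_metadata)(config.metadata_path)

    scans = _stage("group")(group_scans)(images)
    counts = _stage("count")(count_series)(
        scans, config.strategy, config.aggregation, config.confidence_threshold
    )
    counts.to_csv(outdir / "counts.csv", index=False)
    n_flagged = int((counts["flags"] != "").sum())
    if n_flagged:
        logger.info("%d scan(s) carry degenerate-case flags", n_flagged)

    curves_map, zero_plants = _stage("curves")(curves_from_counts)(counts)
    if zero_plants:
        logger.warning("%d plant(s) with zero total blooms excluded from curves: %s",
                       len(zero_plants), ", ".join(sorted(zero_plants)))
    ctable = curves_table(curves_map, counts)
    ctable.to_csv(outdir / "flower_curves.csv", index=False)

    chars, _ = _stage("characteristics")(characteristics_table)(
        counts, metadata, "imaging", config.fsd_threshold, config.fed_threshold
    )
    chars.to_csv(outdir / "flower_characteristics.csv", index=False)

    evaluation = None
    freq_table = None
    if config.manual_counts_path:
        manual = _stage("manual")(read_manual_counts)(config.manual_counts_path)
        evaluation = _stage("evaluate")(compare_methods)(counts, manual, metadata)
        _write_evaluation(evaluation, outdir)
        if metadata is not None:
            freq_table = evaluation.curve_differences
            freq_table.to_csv(outdir / "frequency_study.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            name: {"path": p, "sha256": _sha256(p)}
            for name, p in [
                ("detections", config.detections_path),
                ("metadata", config.metadata_path),
                ("manual_counts", config.manual_counts_path),
            ]
            if p
        },
        "n_images": len(images),
        "n_plants": int(counts["plant_id"].nunique()),
        "zero_bloom_plants": sorted(zero_plants),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(
        counts=counts,
        curves=ctable,
        characteristics=chars,
        zero_bloom_plants=zero_plants,
        evaluation=evaluation,
        frequency=freq_table,
        output_dir=outdir,
    )


def _write_evaluation(ev: MethodComparison, outdir: Path) -> None:
    reg = ev.regression
    lines = [
        "Imaging vs manual bloom counts",
        f"  n samples          : {reg.n}",
        f"  slope (no intercept): {reg.slope:.4f}",
        f"  R^2 (uncentered)   : {reg.r2:.4f}",
        f"  RMSE (blooms)      : {reg.rmse:.4f}",
        f"  zero-manual/nonzero-imaging samples: {ev.errors.zero_manual_nonzero_imaging}",
    ]
    (outdir / "evaluation.txt").write_text("\n".join(lines) + "\n")
    pd.DataFrame(
        sorted(ev.errors.error_hist.items()), columns=["error", "n"]
    ).to_csv(outdir / "error_histogram.csv", index=False)
    pd.DataFrame(
        [(k, ev.errors.per_load_mean_error[k], ev.errors.per_load_n[k])
         for k in sorted(ev.errors.per_load_mean_error)],
        columns=["manual_count", "mean_error", "n"],
    ).to_csv(outdir / "error_by_bloom_load.csv", index=False)
    pd.DataFrame(
        list(ev.errors.per_decile_mean_pct_error.items()),
        columns=["cumulative_decile", "mean_pct_error"],
    ).to_csv(outdir / "error_by_cumulative_decile.csv", index=False)
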
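"""Synthetic flowering and detection simulator.

Generates ground-truth flowering processes and noisy multi-view detection
datasets with the statistical structure the analysis pipeline assumes, so
every stage can be tested without field data or a trained detector.

Model
-----
Each plant draws daily emerging-bloom counts from an inhomogeneous Poisson
process whose intensity has a configurable shape (Gaussian bump or Beta
density) over the genotype's flowering window, scaled so the expected
season total equals the genotype's mean bloom production; optional weather
events multiply the intensity by a dip factor for a few days. Emerging
cotton blooms are white for a single day, so a bloom is countable only on
its opening day: per-scan-date observed counts are that day's emergence
and blooms opening between scans are unobserved by every method. Manual
reference counts are modeled as exact truth on scan days.

The detector is emulated at the level of its net effect: each true bloom
is independently visible from each of the 4 viewing angles with
probability ``p_vis`` (occlusion), each visible bloom yields a surviving
detection with probability ``p_det`` (miss rate after confidence
filtering), and false positives arrive per image at rate ``fp_rate``, a
configurable fraction of them with centroids outside the target-plant box
so the plant-based/whole-image counting distinction is exercised.
Confidence scores for retained true detections are drawn above the
operating threshold (``p_det`` already accounts for sub-threshold losses);
false-positive scores straddle the threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detections import BBox, Detection, ImageDetections, write_detections_csv

N_VIEWS = 4


@dataclass(frozen=True)
class GenotypeProfile:
    """Flowering behavior of one genotype."""

    genotype: str
    genetic_category: str
    flowering_onset: float  # DAP of first expected emergence
    flowering_window: float  # days of nonzero emergence intensity
    total_bloom_mean: float  # expected blooms per plant per season
    intensity_shape: str = "gaussian"
    weather_dips: tuple[tuple[float, float], ...] = ()  # (dap, multiplicative factor)

    def __post_init__(self) -> None:
        if self.flowering_onset < 0 or self.flowering_window <= 0:
            raise ValueError("need onset >= 0 and window > 0")
        if self.total_bloom_mean <= 0:
            raise ValueError("total_bloom_mean must be > 0")
        if self.intensity_shape not in ("gaussian", "beta"):
            raise ValueError(f"unknown intensity shape {self.intensity_shape!r}")
        for dap, factor in self.weather_dips:
            if not 0.0 <= factor <= 1.0:
                raise ValueError(f"dip factor {factor} outside [0, 1]")


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic multi-view dataset."""

    profiles: list[GenotypeProfile]
    replicates: int = 5
    scan_daps: np.ndarray = field(default_factory=lambda: default_schedule())
    season_end: int = 140
    # image geometry (pixels)
    image_size: int = 1200
    plant_bbox: tuple[float, float, float, float] = (250.0, 150.0, 950.0, 1100.0)
    bloom_size_range: tuple[float, float] = (30.0, 60.0)
    # detector noise model
    p_vis: float = 0.85
    p_det: float = 0.9
    fp_rate: float = 0.3
    fp_outside_frac: float = 0.5
    p_plant_det: float = 1.0
    confidence_threshold: float = 0.7
    conf_true: tuple[float, float] = (0.9, 0.05)  # truncnorm mean/sd above threshold
    conf_false: tuple[float, float] = (0.6, 0.15)  # truncnorm mean/sd on [0, 1]
    # batch structure: replicate index < batch1_replicates -> batch 1
    batch1_replicates: int = 3
    batch2_onset_shift: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.scan_daps = np.asarray(self.scan_daps)
        for name in ("p_vis", "p_det", "fp_outside_frac", "p_plant_det"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        if int(self.scan_daps.max()) > self.season_end:
            raise ValueError("scan schedule extends past season_end")


def default_schedule(start: int = 68, n_dates: int = 26) -> np.ndarray:
    """Scan schedule at three dates per week: offsets 0/2/4 within each week.

    The default reproduces a 26-date season starting at DAP 68 with 2-day
    spacing within weeks and a 3-day weekend gap.
    """
    daps = [start + 7 * w + o for w in range(n_dates // 3 + 2) for o in (0, 2, 4)]
    return np.asarray(daps[:n_dates])


def default_profiles() -> list[GenotypeProfile]:
    """23 genotypes in 3 genetic categories with contrasting phenology.

    Elite upland genotypes flower in a narrow mid-season window; exotic
    accessions span diverse onsets and window lengths (large within-group
    variation); the single extra-long-staple genotype has the longest
    flowering window. Two exotic genotypes carry no weather dips, the rest
    lose most emergence for three days after the two cold/rain events.
    """
    dips = ((95.0, 0.3), (103.0, 0.4))
    profiles: list[GenotypeProfile] = []
    for i in range(10):
        profiles.append(
            GenotypeProfile(
                genotype=f"elite_{i+1:02d}",
                genetic_category="elite_hirsutum",
                flowering_onset=75.0 + (i % 5),
                flowering_window=30.0 + 2.0 * (i % 3),
                total_bloom_mean=65.0 + 3.0 * i,
                intensity_shape="gaussian",
                weather_dips=dips,
            )
        )
    for i in range(12):
        profiles.append(
            GenotypeProfile(
                genotype=f"exotic_{i+1:02d}",
                genetic_category="exotic_hirsutum",
                flowering_onset=70.0 + 1.8 * i,
                flowering_window=26.0 + 2.0 * (i % 7),
                total_bloom_mean=40.0 + 6.0 * i,
                intensity_shape="beta" if i % 2 else "gaussian",
                weather_dips=() if i in (3, 8) else dips,
            )
        )
    profiles.append(
        GenotypeProfile(
            genotype="barbadense_01",
            genetic_category="barbadense",
            flowering_onset=72.0,
            flowering_window=52.0,
            total_bloom_mean=85.0,
            intensity_shape="gaussian",
            weather_dips=dips,
        )
    )
    return profiles


def emergence_intensity(profile: GenotypeProfile, season_end: int) -> np.ndarray:
    """Expected daily emergence over days 0..season_end.

    The base shape is normalized to integrate to ``total_bloom_mean`` over
    the flowering window BEFORE weather dips are applied, so dips reduce
    the realized season total.
    """
    days = np.arange(season_end + 1, dtype=float)
    a, w = profile.flowering_onset, profile.flowering_window
    in_window = (days >= a) & (days <= a + w)
    shape = np.zeros_like(days)
    if profile.intensity_shape == "gaussian":
        mid, sd = a + w / 2.0, w / 6.0
        shape[in_window] = np.exp(-0.5 * ((days[in_window] - mid) / sd) ** 2)
    else:  # beta(2, 2) density over the window
        t = (days[in_window] - a) / w
        shape[in_window] = sps.beta(2, 2).pdf(t)
    total = shape.sum()
    if total <= 0:
        raise ValueError(f"profile {profile.genotype}: empty flowering window")
    intensity = shape * (profile.total_bloom_mean / total)
    for dap, factor in profile.weather_dips:
        dipped = (days >= dap) & (days < dap + 3)  # 3-day event
        intensity[dipped] *= factor
    return intensity


def simulate_emergence(
    profile: GenotypeProfile, rng: np.random.Generator, season_end: int = 140
) -> np.ndarray:
    """Daily true emerging-bloom counts (Poisson draws from the intensity)."""
    return rng.poisson(emergence_intensity(profile, season_end))


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _bloom_bbox(rng, cx: float, cy: float, size_range, image_size) -> BBox:
    s = rng.uniform(*size_range)
    x0 = float(np.clip(cx - s / 2, 0, image_size - s))
    y0 = float(np.clip(cy - s / 2, 0, image_size - s))
    return BBox(x0, y0, x0 + s, y0 + s)


def simulate_scan_views(
    daily_counts: np.ndarray,
    config: SimulationConfig,
    plant_id: str,
    rng: np.random.Generator,
) -> tuple[list[ImageDetections], pd.DataFrame]:
    """Noisy multi-view detection records plus the ground-truth table.

    For each scan date the day's true blooms are shared entities: each is
    visible from each view independently with ``p_vis`` and, if visible,
    detected with ``p_det``. Detected blooms get a bloom-sized box whose
    centroid lies inside the plant box. False positives are Poisson with
    rate ``fp_rate`` per image, a fraction placed with centroids outside
    the plant box. The ground-truth table records the true count and the
    per-view visible counts for every scan date.
    """
    plant_box = BBox(*config.plant_bbox)
    px0, py0, px1, py1 = config.plant_bbox
    conf_t_mean, conf_t_sd = config.conf_true
    conf_f_mean, conf_f_sd = config.conf_false
    thr = config.confidence_threshold

    images: list[ImageDetections] = []
    truth_rows = []
    for dap in config.scan_daps:
        dap = int(dap)
        n_true = int(daily_counts[dap])
        visible = rng.random((n_true, N_VIEWS)) < config.p_vis
        detected = visible & (rng.random((n_true, N_VIEWS)) < config.p_det)
        row = {"plant_id": plant_id, "dap": dap, "true_count": n_true}
        for v in range(N_VIEWS):
            row[f"visible_view{v}"] = int(visible[:, v].sum())
        truth_rows.append(row)

        for v in range(N_VIEWS):
            dets: list[Detection] = []
            if rng.random() < config.p_plant_det:
                conf = float(_truncnorm(rng, 0.95, 0.02, thr, 1.0, 1)[0])
                dets.append(Detection(plant_box, "target_plant", conf))
            n_det = int(detected[:, v].sum())
            if n_det:
                cx = rng.uniform(px0, px1, n_det)
                cy = rng.uniform(py0, py1, n_det)
                confs = _truncnorm(rng, conf_t_mean, conf_t_sd, thr, 1.0, n_det)
                for j in range(n_det):
                    bbox = _bloom_bbox(rng, cx[j], cy[j], config.bloom_size_range,
                                       config.image_size)
                    dets.append(Detection(bbox, "emerging_bloom", float(confs[j])))
            n_fp = rng.poisson(config.fp_rate)
            for _ in range(n_fp):
                outside = rng.random() < config.fp_outside_frac
                for _attempt in range(100):
                    cx1 = rng.uniform(0, config.image_size)
                    cy1 = rng.uniform(0, config.image_size)
                    if plant_box.contains(cx1, cy1) != outside:
                        break
                conf = float(_truncnorm(rng, conf_f_mean, conf_f_sd, 0.0, 1.0, 1)[0])
                dets.append(
                    Detection(
                        _bloom_bbox(rng, cx1, cy1, config.bloom_size_range, config.image_size),
                        "emerging_bloom",
                        conf,
                    )
                )
            images.append(ImageDetections(plant_id, dap, v, dets))
    return images, pd.DataFrame(truth_rows)


@dataclass
class SimulatedDataset:
    """In-memory synthetic dataset: detections plus all reference tables."""

    images: list[ImageDetections]
    metadata: pd.DataFrame  # plant_id, genotype, genetic_category, transplant_batch
    manual: pd.DataFrame  # plant_id, dap, manual_count (exact scan-day truth)
    truth: pd.DataFrame  # plant_id, dap, true_count, visible_view0..3
    config: SimulationConfig


def make_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate every plant of every genotype under one configuration.

    Plants are named ``<genotype>_r<replicate>``. Replicates below
    ``batch1_replicates`` belong to transplant batch 1; batch-2 plants
    flower ``batch2_onset_shift`` days later (later transplanting).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    images: list[ImageDetections] = []
    meta_rows, manual_rows, truth_frames = [], [], []
    for profile in config.profiles:
        for rep in range(config.replicates):
            batch = 1 if rep < config.batch1_replicates else 2
            prof = profile
            if batch == 2 and config.batch2_onset_shift:
                prof = dataclasses.replace(
                    profile,
                    flowering_onset=profile.flowering_onset + config.batch2_onset_shift,
                    weather_dips=profile.weather_dips,
                )
            plant_id = f"{profile.genotype}_r{rep+1}"
            daily = simulate_emergence(prof, rng, config.season_end)
            imgs, truth = simulate_scan_views(daily, config, plant_id, rng)
            images.extend(imgs)
            truth_frames.append(truth)
            meta_rows.append(
                {
                    "plant_id": plant_id,
                    "genotype": profile.genotype,
                    "genetic_category": profile.genetic_category,
                    "transplant_batch": batch,
                }
            )
            for dap in config.scan_daps:
                manual_rows.append(
                    {"plant_id": plant_id, "dap": int(dap), "manual_count": int(daily[int(dap)])}
                )
    return SimulatedDataset(
        images=images,
        metadata=pd.DataFrame(meta_rows),
        manual=pd.DataFrame(manual_rows),
        truth=pd.concat(truth_frames, ignore_index=True),
        config=config,
    )


def make_fixture_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete on-disk dataset in the package's I/O dialects.

    Produces detections.csv (flat detection dialect), metadata.csv,
    manual_counts.csv and ground_truth.csv under ``outdir``; byte-identical
    for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = make_dataset(config)
    paths = {
        "detections": outdir / "detections.csv",
        "metadata": outdir / "metadata.csv",
        "manual_counts": outdir / "manual_counts.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    write_detections_csv(ds.images, paths["detections"])
    ds.metadata.to_csv(paths["metadata"], index=False)
    ds.manual.to_csv(paths["manual_counts"], index=False)
    ds.truth.to_csv(paths["ground_truth"], index=False)
    return paths


def noise_free_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A perfect-detector configuration: every bloom seen in every view."""
    kwargs = dict(
        profiles=default_profiles(),
        p_vis=1.0,
        p_det=1.0,
        fp_rate=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The standard noisy study configuration (occlusion, misses, FPs)."""
    kwargs = dict(profiles=default_profiles(), seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
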
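import numpy as np
import pytest

from bloompheno.detections import BBox, Detection, ImageDetections
from bloompheno.synthetic import (
    GenotypeProfile,
    SimulationConfig,
    default_profiles,
    default_schedule,
    make_dataset,
)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A 3-genotype, 2-replicate configuration for fast unit tests."""
    profiles = [
        GenotypeProfile("g_early", "elite_hirsutum", 72.0, 28.0, 60.0),
        GenotypeProfile("g_late", "exotic_hirsutum", 82.0, 30.0, 50.0, "beta"),
        GenotypeProfile("g_long", "barbadense", 72.0, 50.0, 80.0),
    ]
    kwargs = dict(profiles=profiles, replicates=2, seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_noisy_ds():
    return make_dataset(small_config(seed=42))


@pytest.fixture(scope="session")
def noise_free_ds():
    """Full-size perfect-detector dataset (23 genotypes x 5 replicates)."""
    from bloompheno.synthetic import noise_free_config

    return make_dataset(noise_free_config(seed=101))


def random_image(rng: np.random.Generator, max_dets: int = 6) -> ImageDetections:
    """A random detection set for brute-force counting oracles."""
    n = int(rng.integers(0, max_dets + 1))
    dets = []
    for _ in range(n):
        label = rng.choice(["target_plant", "emerging_bloom", "opened_boll", "other"],
                           p=[0.25, 0.5, 0.15, 0.1])
        x0, y0 = rng.uniform(0, 800, 2)
        w, h = rng.uniform(5, 400, 2)
        dets.append(
            Detection(BBox(x0, y0, x0 + w, y0 + h), str(label), float(rng.uniform(0, 1)))
        )
    return ImageDetections("p", 70, 0, dets)


def oracle_counts(image: ImageDetections, threshold: float) -> tuple[int, int]:
    """Independent enumeration of plant-based and whole-image counts."""
    kept = [d for d in image.detections if d.confidence >= threshold]
    whole = sum(1 for d in kept if d.label == "emerging_bloom")
    plants = [d for d in kept if d.label == "target_plant"]
    plant_count = 0
    if plants:
        best = max(plants, key=lambda d: d.confidence).bbox
        for d in kept:
            if d.label != "emerging_bloom":
                continue
            cx = (d.bbox.xmin + d.bbox.xmax) / 2.0
            cy = (d.bbox.ymin + d.bbox.ymax) / 2.0
            if best.xmin <= cx <= best.xmax and best.ymin <= cy <= best.ymax:
                plant_count += 1
    return plant_count, whole
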
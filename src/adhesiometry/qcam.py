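"""Quantitative cell-aggregation microscopy (QCAM).

Plate-scan images of spread cell suspensions are corrected against an
averaged cell-free background image (which also inverts the scale so
clumps become bright), segmented with a single global threshold shared by
all images of an experiment, dissected by watershed so touching
aggregates separate, filtered for dust-sized objects, and summarized as
the total area (mm^2) covered by aggregates of each size class I-IV,
normalized per cm^2 of imaged field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import (
    BinaryMask,
    IntensityGrid,
    LabelGrid,
    read_image,
    watershed_split,
)

__all__ = [
    "SizeClassConfig",
    "AggregateObject",
    "AggregateSizeDistribution",
    "SIZE_CLASSES",
    "background_correct",
    "segment_aggregates",
    "measure_aggregates",
    "size_distribution",
    "run_qcam",
]

SIZE_CLASSES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class SizeClassConfig:
    """Three ascending area bounds (mm^2) splitting objects into classes I-IV.

    Classes are half-open: I is ``area < b1``, II is ``[b1, b2)``, III is
    ``[b2, b3)`` and IV is ``area >= b3``.  The default decade bounds
    (0.001, 0.01, 0.1) put millimetre-scale aggregates in class IV.
    """

    bounds_mm2: tuple[float, float, float] = (0.001, 0.01, 0.1)

    def __post_init__(self) -> None:
        b = self.bounds_mm2
        if len(b) != 3 or not (0 < b[0] < b[1] < b[2]):
            raise ValueError(f"bounds must be 3 strictly increasing positive reals, got {b}")

    def classify(self, area_mm2: float) -> str:
        idx = int(np.searchsorted(self.bounds_mm2, area_mm2, side="right"))
        return SIZE_CLASSES[idx]


@dataclass(frozen=True)
class AggregateObject:
    label: int
    area_px: int
    area_mm2: float
    size_class: str


@dataclass(frozen=True)
class AggregateSizeDistribution:
    """Per-size-class aggregate coverage of one image.

    ``normalized_area_mm2_per_cm2`` is the headline statistic: total area
    (mm^2) covered by aggregates of each class per cm^2 of imaged field.
    """

    imaged_area_cm2: float
    total_area_mm2: dict[str, float]
    normalized_area_mm2_per_cm2: dict[str, float]
    n_objects: dict[str, int]


def background_correct(scene: IntensityGrid, background: IntensityGrid) -> IntensityGrid:
    """Subtract the scene from the averaged background and clamp to [0, 1].

    Aggregates absorb light and appear darker than the agar, so
    ``background - scene`` both flattens the inhomogeneous background and
    inverts the scale, yielding bright clumps on a near-zero field.
    """
    if scene.shape != background.shape:
        raise ValueError(f"shape mismatch: scene {scene.shape} vs background {background.shape}")
    if scene.pixel_size_mm != background.pixel_size_mm:
        raise ValueError("scene and background must share pixel calibration")
    return scene.with_pixels(np.clip(background.pixels - scene.pixels, 0.0, 1.0))


def segment_aggregates(
    corrected: IntensityGrid,
    global_threshold: float,
    min_object_area_px: int = 5,
    min_seed_distance: int = 5,
) -> LabelGrid:
    """Threshold, watershed-dissect and dust-filter a corrected image.

    The global threshold is set once per experiment and shared by every
    image.  Watershed is applied uniformly (touching aggregates split at
    the distance-transform ridge); objects smaller than
    ``min_object_area_px`` are removed as dust and the survivors are
    renumbered 1..L.
    """
    if not (0.0 < global_threshold < 1.0):
        raise ValueError(f"global_threshold must be in (0, 1), got {global_threshold}")
    mask = BinaryMask(corrected.pixels > global_threshold)
    labels = watershed_split(mask, min_seed_distance=min_seed_distance)
    if labels.n_labels == 0:
        return labels
    areas = labels.areas_px()
    keep = np.flatnonzero(areas >= min_object_area_px) + 1
    lut = np.zeros(labels.n_labels + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return LabelGrid(lut[labels.pixels], len(keep))


def measure_aggregates(
    labels: LabelGrid,
    pixel_size_mm: float,
    classes: SizeClassConfig = SizeClassConfig(),
) -> list[AggregateObject]:
    """One measurement record per labelled aggregate."""
    if not (pixel_size_mm > 0):
        raise ValueError("pixel_size_mm must be > 0")
    areas = labels.areas_px()
    out = []
    for label, area_px in enumerate(areas, start=1):
        area_mm2 = float(area_px) * pixel_size_mm**2
        out.append(
            AggregateObject(
                label=label,
                area_px=int(area_px),
                area_mm2=area_mm2,
                size_class=classes.classify(area_mm2),
            )
        )
    return out


def size_distribution(
    objects: list[AggregateObject], imaged_area_cm2: float
) -> AggregateSizeDistribution:
    """Per-class total aggregate area, normalized per cm^2 of imaged field."""
    if not (imaged_area_cm2 > 0):
        raise ValueError("imaged_area_cm2 must be > 0")
    total = {c: 0.0 for c in SIZE_CLASSES}
    count = {c: 0 for c in SIZE_CLASSES}
    for obj in objects:
        total[obj.size_class] += obj.area_mm2
        count[obj.size_class] += 1
    normalized = {c: total[c] / imaged_area_cm2 for c in SIZE_CLASSES}
    return AggregateSizeDistribution(
        imaged_area_cm2=imaged_area_cm2,
        total_area_mm2=total,
        normalized_area_mm2_per_cm2=normalized,
        n_objects=count,
    )


def analyze_scene(
    scene: IntensityGrid,
    background: IntensityGrid,
    global_threshold: float,
    imaged_area_cm2: float,
    min_object_area_px: int = 5,
    classes: SizeClassConfig = SizeClassConfig(),
    min_seed_distance: int = 5,
) -> AggregateSizeDistribution:
    """Full per-image pipeline: correct, segment, measure, summarize."""
    corrected = background_correct(scene, background)
    labels = segment_aggregates(
        corrected, global_threshold, min_object_area_px, min_seed_distance
    )
    objects = measure_aggregates(labels, scene.pixel_size_mm, classes)
    return size_distribution(objects, imaged_area_cm2)


def run_qcam(
    scene_paths: list[str | Path],
    background_path: str | Path,
    pixel_size_mm: float,
    global_threshold: float,
    imaged_area_cm2: float = 1.0,
    min_object_area_px: int = 5,
    classes: SizeClassConfig = SizeClassConfig(),
    min_seed_distance: int = 5,
) -> pd.DataFrame:
    """Run the pipeline over replicate images and summarize across them.

    Returns a tidy table with one row per image x class plus, per class,
    ``mean`` / ``sd`` rows across replicates (sample SD; a single image
    reports SD 0 with a warning).  Failures identify the offending image.
    """
    if not scene_paths:
        raise ValueError("at least one scene image is required")
    background = read_image(background_path, pixel_size_mm)
    rows = []
    per_class: dict[str, list[float]] = {c: [] for c in SIZE_CLASSES}
    for path in scene_paths:
        try:
            scene = read_image(path, pixel_size_mm)
            dist = analyze_scene(
                scene,
                background,
                global_threshold,
                imaged_area_cm2,
                min_object_area_px,
                classes,
                min_seed_distance,
            )
        except Exception as exc:
            raise RuntimeError(f"QCAM failed on image {path}: {exc}") from exc
        for c in SIZE_CLASSES:
            rows.append(
                {
                    "image": str(path),
                    "class": c,
                    "n_objects": dist.n_objects[c],
                    "total_area_mm2": dist.total_area_mm2[c],
                    "normalized_mm2_per_cm2": dist.normalized_area_mm2_per_cm2[c],
                }
            )
            per_class[c].append(dist.normalized_area_mm2_per_cm2[c])
    if len(scene_paths) == 1:
        warnings.warn("single image: replicate SD is undefined and reported as 0")
    for c in SIZE_CLASSES:
        vals = np.asarray(per_class[c])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "image": "<summary>",
                "class": c,
                "n_objects": int(np.round(np.mean([r["n_objects"] for r in rows
                                                   if r["class"] == c and r["image"] != "<summary>"]))),
                "total_area_mm2": float(np.mean([r["total_area_mm2"] for r in rows
                                                 if r["class"] == c and r["image"] != "<summary>"])),
                "normalized_mm2_per_cm2": float(vals.mean()),
                "normalized_sd": sd,
            }
        )
    return pd.DataFrame(rows)
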
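"""Stomatal phenotypes from bounding-box detections.

Three traits are derived from a set of detected boxes and a microscope
calibration:

* **Stomatal density (SD)** — detected stomata per mm^2 of the
  calibrated field. Every detection counts, including boxes touching
  the image border: a partially visible stoma is still a stoma.
* **Stomatal size (SS)** — box x-extent as stomatal length (the guard-
  cell long axis, since imprints are acquired with cell files aligned
  horizontally) and y-extent as width, converted to micrometers. Boxes
  touching a border ("marginal" stomata) are excluded here, because a
  clipped box underestimates the true extent.
* **Stomatal-file intervals** — grass stomata lie on horizontal rows;
  clustering detection y-centers by gaps recovers the file positions,
  and consecutive differences give the inter-file spacings in um.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import BoundingBox
from .calibration import CALIBRATION_4X, CALIBRATION_10X, Calibration

__all__ = [
    "Calibration",
    "CALIBRATION_4X",
    "CALIBRATION_10X",
    "StomaMeasurement",
    "TraitRecord",
    "FilePattern",
    "stomatal_density",
    "is_marginal",
    "stomatal_size",
    "measure_image",
    "stomatal_files",
    "traits_table",
    "measurements_table",
]


@dataclass(frozen=True)
class StomaMeasurement:
    image_id: str
    box: BoundingBox
    length_um: float
    width_um: float
    marginal: bool


@dataclass(frozen=True)
class TraitRecord:
    """Per-image phenotype summary.

    ``mean_length_um``/``mean_width_um`` are None when every detection is
    marginal (no valid size measurements).
    """

    image_id: str
    stomata_count: int
    sd_per_mm2: float
    measurements: tuple[StomaMeasurement, ...]
    mean_length_um: float | None
    mean_width_um: float | None


@dataclass(frozen=True)
class FilePattern:
    """Stomatal-file positions and inter-file spacings."""

    file_y_px: tuple[float, ...]
    intervals_um: tuple[float, ...]
    #: file index -> indices into the detection list
    members: tuple[tuple[int, ...], ...]


def stomatal_density(detections: Sequence[BoundingBox],
                     calibration: Calibration) -> float:
    """Detections per mm^2 of the calibrated field (marginal included)."""
    return len(detections) / calibration.field_area_mm2


def is_marginal(box: BoundingBox, calibration: Calibration,
                eps: float = 0.5) -> bool:
    """True when the box touches an image border within ``eps`` pixels.

    Detector outputs are real-valued, so the border test carries a small
    tolerance rather than requiring exact 0 / width / height hits.
    """
    return (box.xmin <= eps
            or box.ymin <= eps
            or box.xmax >= calibration.image_width_px - eps
            or box.ymax >= calibration.image_height_px - eps)


def stomatal_size(box: BoundingBox,
                  calibration: Calibration) -> tuple[float, float]:
    """(length_um, width_um) = box (x-extent, y-extent) * um_per_px."""
    return (box.width * calibration.um_per_px,
            box.height * calibration.um_per_px)


def measure_image(detections: Sequence[BoundingBox],
                  calibration: Calibration,
                  image_id: str = "image",
                  marginal_eps: float = 0.5) -> TraitRecord:
    """SD over all detections; SS statistics over non-marginal ones."""
    measurements = []
    for b in detections:
        length_um, width_um = stomatal_size(b, calibration)
        marginal = is_marginal(b, calibration, eps=marginal_eps)
        if not marginal:
            measurements.append(StomaMeasurement(image_id, b, length_um,
                                                 width_um, marginal))
    if measurements:
        mean_len = float(np.mean([m.length_um for m in measurements]))
        mean_wid = float(np.mean([m.width_um for m in measurements]))
    else:
        mean_len = mean_wid = None
    return TraitRecord(
        image_id=image_id,
        stomata_count=len(detections),
        sd_per_mm2=stomatal_density(detections, calibration),
        measurements=tuple(measurements),
        mean_length_um=mean_len,
        mean_width_um=mean_wid,
    )


def stomatal_files(detections: Sequence[BoundingBox],
                   calibration: Calibration,
                   gap_factor: float = 1.5) -> FilePattern:
    """Cluster detections into horizontal files by y-center gaps.

    Sorted y-centers start a new file wherever the gap to the previous
    center exceeds ``gap_factor`` times the median box height — the
    natural scale separating within-file scatter from between-file
    spacing. An empty detection list yields an empty pattern.
    """
    if not detections:
        return FilePattern((), (), ())
    centers = np.array([b.center[1] for b in detections])
    heights = np.array([b.height for b in detections])
    threshold = gap_factor * float(np.median(heights))
    order = np.argsort(centers, kind="stable")
    files: list[list[int]] = [[int(order[0])]]
    for idx in order[1:]:
        prev = files[-1][-1]
        if centers[idx] - centers[prev] > threshold:
            files.append([int(idx)])
        else:
            files[-1].append(int(idx))
    positions = tuple(float(np.mean(centers[list(m)])) for m in files)
    intervals = tuple(
        (positions[i + 1] - positions[i]) * calibration.um_per_px
        for i in range(len(positions) - 1)
    )
    return FilePattern(positions, intervals,
                       tuple(tuple(m) for m in files))


def traits_table(records: Sequence[TraitRecord]) -> pd.DataFrame:
    """Per-image trait table (one row per image)."""
    return pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "count": [r.stomata_count for r in records],
            "sd_per_mm2": [r.sd_per_mm2 for r in records],
            "mean_length_um": [r.mean_length_um for r in records],
            "mean_width_um": [r.mean_width_um for r in records],
        }
    )


def measurements_table(records: Sequence[TraitRecord]) -> pd.DataFrame:
    """Per-stoma measurement table over all images."""
    rows = []
    for r in records:
        for k, m in enumerate(r.measurements):
            rows.append((r.image_id, k, m.length_um, m.width_um, m.marginal))
    return pd.DataFrame(rows, columns=["image_id", "stoma_idx", "length_um",
                                       "width_um", "marginal"])
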
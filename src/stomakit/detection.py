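"""Stomata detectors: the contract, an oracle, and a template baseline.

In a deployed phenotyping platform the detection stage is a trained
neural object detector. This module defines the contract such a stage
must satisfy and supplies two desk-scale implementations:

* :func:`oracle_detect` — emits the synthetic ground truth corrupted by
  configurable miss/jitter/false-positive noise; a controllable stand-in
  that lets every downstream stage be validated against known truth.
* :func:`baseline_detect` — normalized cross-correlation of the image
  against rendered dumbbell templates over a small size grid. It is a
  classical, non-neural detector for running the pipeline end to end
  without trained weights; it makes no accuracy claims.

Contract (``detect``): boxes lie inside image bounds, scores in [0, 1],
output sorted by descending score, at most ``max_detections`` boxes, and
the result is deterministic given the image, the configuration and any
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
from skimage.feature import match_template, peak_local_max

from .annotation_io import (AnnotationSet, BoundingBox, ImageRecord,
                            read_coco_results)
from .evaluation import iou
from .synthetic import SyntheticScene, draw_dumbbell

__all__ = [
    "DetectorConfig",
    "OracleNoise",
    "TemplateSpec",
    "Detector",
    "OracleDetector",
    "TemplateDetector",
    "oracle_detect",
    "baseline_detect",
    "nms",
    "load_predictions",
]


@dataclass(frozen=True)
class DetectorConfig:
    score_threshold: float = 0.5
    nms_iou_threshold: float = 0.5
    max_detections: int = 300

    def __post_init__(self) -> None:
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must be in [0, 1]")
        if not (0.0 <= self.nms_iou_threshold <= 1.0):
            raise ValueError("nms_iou_threshold must be in [0, 1]")
        if self.max_detections < 1:
            raise ValueError("max_detections must be >= 1")


@dataclass(frozen=True)
class OracleNoise:
    """Corruption applied to ground truth by the oracle detector."""

    jitter_px_sd: float = 0.0
    miss_rate: float = 0.0
    false_positive_rate_per_image: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_px_sd < 0:
            raise ValueError("jitter_px_sd must be >= 0")
        if not (0.0 <= self.miss_rate < 1.0):
            raise ValueError("miss_rate must be in [0, 1)")
        if self.false_positive_rate_per_image < 0:
            raise ValueError("false_positive_rate_per_image must be >= 0")


class Detector(Protocol):
    def detect(self, image: ImageRecord,
               config: DetectorConfig) -> list[BoundingBox]: ...


def _sort_detections(boxes: Iterable[BoundingBox]) -> list[BoundingBox]:
    # descending score; ties broken by smaller area then lower x for
    # deterministic output
    return sorted(boxes, key=lambda b: (-(b.score or 0.0), b.area, b.xmin))


def nms(boxes: Sequence[BoundingBox], iou_threshold: float
        ) -> list[BoundingBox]:
    """Greedy non-maximum suppression by descending score.

    A box overlapping an already-kept box with IoU strictly above the
    threshold is removed. The output is a subset of the input, sorted by
    descending score; the operation is idempotent.
    """
    kept: list[BoundingBox] = []
    for b in _sort_detections(boxes):
        if all(iou(b, k) <= iou_threshold for k in kept):
            kept.append(b)
    return kept


def _clip_to_image(b: BoundingBox, w: int, h: int) -> BoundingBox | None:
    return b.clip(0, 0, w, h)


def _shift_into_frame(b: BoundingBox, dx: float, dy: float,
                      w: int, h: int) -> BoundingBox | None:
    """Translate a box and clip to the frame; None if pushed fully out."""
    x0, y0 = max(b.xmin + dx, 0.0), max(b.ymin + dy, 0.0)
    x1, y1 = min(b.xmax + dx, float(w)), min(b.ymax + dy, float(h))
    if x0 >= x1 or y0 >= y1:
        return None
    return BoundingBox(x0, y0, x1, y1)


def oracle_detect(scene: SyntheticScene,
                  noise: OracleNoise = OracleNoise(),
                  score_floor: float = 0.5) -> list[BoundingBox]:
    """Ground-truth boxes corrupted by miss / jitter / false positives.

    Each ground-truth box is independently dropped with probability
    ``miss_rate``; survivors are shifted by Gaussian center jitter (size
    preserved) and scored uniformly on ``[score_floor, 1]``. A
    Poisson(``false_positive_rate_per_image``) number of spurious boxes
    is added at uniform positions with sizes resampled from the scene's
    stomata, scored uniformly on ``[score_floor, 0.7]`` so that
    score-ranked evaluation is meaningful. Deterministic under
    ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    W, H = scene.params.image_width_px, scene.params.image_height_px
    out: list[BoundingBox] = []
    for b in scene.true_boxes():
        if noise.miss_rate > 0 and rng.uniform() < noise.miss_rate:
            continue
        if noise.jitter_px_sd > 0:
            dx, dy = rng.normal(0, noise.jitter_px_sd, 2)
            moved = _shift_into_frame(b, float(dx), float(dy), W, H)
            if moved is None:
                continue
            b = moved
        score = float(rng.uniform(score_floor, 1.0))
        out.append(BoundingBox(b.xmin, b.ymin, b.xmax, b.ymax, score=score))
    n_fp = (int(rng.poisson(noise.false_positive_rate_per_image))
            if noise.false_positive_rate_per_image > 0 else 0)
    sizes = [(L, Wd) for _, _, L, Wd in scene.stomata] or [(60.0, 40.0)]
    for _ in range(n_fp):
        L, Wd = sizes[int(rng.integers(len(sizes)))]
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        fp = _clip_to_image(
            BoundingBox(max(cx - L / 2, 0.0), max(cy - Wd / 2, 0.0),
                        cx + L / 2, cy + Wd / 2,
                        score=float(rng.uniform(score_floor, 0.7))), W, H)
        if fp is not None:
            out.append(fp)
    return _sort_detections(out)


class OracleDetector:
    """Adapter exposing :func:`oracle_detect` under the detect contract."""

    def __init__(self, scene: SyntheticScene,
                 noise: OracleNoise = OracleNoise()):
        self.scene = scene
        self.noise = noise

    def detect(self, image: ImageRecord,
               config: DetectorConfig) -> list[BoundingBox]:
        boxes = oracle_detect(self.scene, self.noise,
                              score_floor=config.score_threshold)
        return boxes[: config.max_detections]


@dataclass(frozen=True)
class TemplateSpec:
    """Dumbbell template sizes (pixels) for the baseline detector."""

    lengths_px: tuple[float, ...] = (70.0, 78.0, 86.0)
    widths_px: tuple[float, ...] = (44.0, 49.0, 54.0)
    background: float = 0.78
    lobe_intensity: float = 0.38
    pore_intensity: float = 0.12

    def sizes(self) -> list[tuple[float, float]]:
        # paired grid: i-th length with i-th width (sizes co-vary in
        # real stomata), falling back to the cross product when the
        # tuples differ in length
        if len(self.lengths_px) == len(self.widths_px):
            return list(zip(self.lengths_px, self.widths_px))
        return [(L, W) for L in self.lengths_px for W in self.widths_px]


def render_template(length_px: float, width_px: float,
                    spec: TemplateSpec) -> np.ndarray:
    """One dumbbell on a neutral background, sized to its box + margin."""
    h = int(np.ceil(width_px)) + 4
    w = int(np.ceil(length_px)) + 4
    canvas = np.full((h, w), spec.background, dtype=float)
    draw_dumbbell(canvas, w / 2, h / 2, length_px, width_px,
                  spec.lobe_intensity, spec.pore_intensity)
    return canvas


def baseline_detect(image: ImageRecord,
                    template: TemplateSpec = TemplateSpec(),
                    config: DetectorConfig = DetectorConfig()
                    ) -> list[BoundingBox]:
    """Normalized cross-correlation dumbbell matcher.

    For each template size the NCC map is computed (template centered via
    padded matching); local maxima above ``score_threshold`` become
    candidate boxes of the template size, and candidates from all sizes
    are merged by NMS. Deterministic; no learned parameters.
    """
    if image.pixels is None:
        raise ValueError("baseline_detect requires pixel data")
    img = np.asarray(image.pixels, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.0:
        img = img / 255.0
    H, W = img.shape
    candidates: list[BoundingBox] = []
    for L, Wd in template.sizes():
        tmpl = render_template(L, Wd, template)
        if tmpl.shape[0] > H or tmpl.shape[1] > W:
            raise ValueError(
                f"template {tmpl.shape} larger than image {(H, W)}"
            )
        ncc = match_template(img, tmpl, pad_input=True)
        ncc = np.nan_to_num(ncc, nan=0.0, posinf=0.0, neginf=0.0)
        peaks = peak_local_max(
            ncc, min_distance=max(int(min(L, Wd) // 3), 1),
            threshold_abs=config.score_threshold, exclude_border=False)
        for r, c in peaks:
            score = float(np.clip(ncc[r, c], 0.0, 1.0))
            box = BoundingBox(
                max(c - L / 2, 0.0), max(r - Wd / 2, 0.0),
                c + L / 2, r + Wd / 2, score=score).clip(0, 0, W, H)
            if box is not None:
                candidates.append(box)
    kept = nms(candidates, config.nms_iou_threshold)
    return kept[: config.max_detections]


class TemplateDetector:
    """Adapter exposing :func:`baseline_detect` under the detect contract."""

    def __init__(self, template: TemplateSpec = TemplateSpec()):
        self.template = template

    def detect(self, image: ImageRecord,
               config: DetectorConfig) -> list[BoundingBox]:
        return baseline_detect(image, self.template, config)


def load_predictions(path, registry: AnnotationSet | Iterable[str]
                     ) -> dict[str, list[BoundingBox]]:
    """Read COCO results JSON, validating image ids against a registry.

    ``registry`` is the companion ground-truth set (or any iterable of
    known image ids); predictions for unknown ids are rejected.
    """
    known = (set(registry.images) if isinstance(registry, AnnotationSet)
             else set(registry))
    preds = read_coco_results(path)
    unknown = sorted(set(preds) - known)
    if unknown:
        raise ValueError(f"predictions reference unknown image ids: "
                         f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}")
    return preds
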
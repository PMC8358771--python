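"""Bounding-box annotations, COCO/Labelbox I/O, and training-image tiling.

Box convention
--------------
Boxes are corner-based ``(xmin, ymin, xmax, ymax)`` in pixels with the
origin at the image's top-left corner, x increasing rightward and y
downward; the pixel interval is half-open ``[min, max)``. COCO's
``[x, y, width, height]`` form is converted at the I/O boundary only.

The tiling pipeline mirrors a common detector-training preprocessing
chain: downscale large micrographs, pad with black to a tileable size,
and split into square tiles while remapping every box into tile-local
coordinates. Boxes cut by a tile seam are clipped and kept only if a
configurable fraction of their area survives.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .calibration import Calibration

logger = logging.getLogger(__name__)

__all__ = [
    "BoundingBox",
    "ImageRecord",
    "AnnotationSet",
    "TilingSpec",
    "read_coco",
    "write_coco",
    "read_coco_results",
    "write_coco_results",
    "read_labelbox",
    "resize_with_boxes",
    "pad_to",
    "split_tiles",
    "prepare_training_tiles",
    "read_image",
    "write_image",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, optionally scored.

    ``score`` is a detection confidence in [0, 1]; ground-truth boxes
    carry ``score=None``.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    score: float | None = None
    label: str = "stoma"

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"degenerate box: ({self.xmin}, {self.ymin}, "
                f"{self.xmax}, {self.ymax})"
            )
        if self.xmin < 0 or self.ymin < 0:
            raise ValueError("box coordinates must be >= 0")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def shift(self, dx: float, dy: float) -> "BoundingBox":
        return replace(self, xmin=self.xmin + dx, ymin=self.ymin + dy,
                       xmax=self.xmax + dx, ymax=self.ymax + dy)

    def scale(self, factor: float) -> "BoundingBox":
        return replace(self, xmin=self.xmin * factor, ymin=self.ymin * factor,
                       xmax=self.xmax * factor, ymax=self.ymax * factor)

    def clip(self, xmin: float, ymin: float,
             xmax: float, ymax: float) -> "BoundingBox | None":
        """Intersect with a window; None if nothing remains."""
        nx0 = max(self.xmin, xmin)
        ny0 = max(self.ymin, ymin)
        nx1 = min(self.xmax, xmax)
        ny1 = min(self.ymax, ymax)
        if nx0 >= nx1 or ny0 >= ny1:
            return None
        return replace(self, xmin=nx0, ymin=ny0, xmax=nx1, ymax=ny1)

    def to_coco(self) -> list[float]:
        """Corner form -> COCO ``[x, y, width, height]``."""
        return [self.xmin, self.ymin, self.width, self.height]

    @classmethod
    def from_coco(cls, xywh: Sequence[float], score: float | None = None,
                  label: str = "stoma") -> "BoundingBox":
        x, y, w, h = xywh
        if w <= 0 or h <= 0:
            raise ValueError(f"COCO box with nonpositive size: {list(xywh)}")
        return cls(x, y, x + w, y + h, score=score, label=label)


@dataclass
class ImageRecord:
    """An image (or a metadata-only placeholder) with known dimensions."""

    id: str
    width_px: int
    height_px: int
    pixels: np.ndarray | None = None
    calibration: Calibration | None = None

    def __post_init__(self) -> None:
        if self.pixels is not None:
            h, w = self.pixels.shape[:2]
            if (w, h) != (self.width_px, self.height_px):
                raise ValueError(
                    f"image {self.id!r}: pixel grid {w}x{h} does not match "
                    f"declared dimensions {self.width_px}x{self.height_px}"
                )


@dataclass
class AnnotationSet:
    """Images plus their ground-truth or predicted boxes.

    ``boxes_by_image`` maps image id -> list of boxes; every referenced id
    must exist in ``images``.
    """

    images: dict[str, ImageRecord] = field(default_factory=dict)
    boxes_by_image: dict[str, list[BoundingBox]] = field(default_factory=dict)
    categories: list[str] = field(default_factory=lambda: ["stoma"])

    def add_image(self, image: ImageRecord,
                  boxes: Iterable[BoundingBox] = ()) -> None:
        self.images[image.id] = image
        self.boxes_by_image[image.id] = list(boxes)

    def boxes(self, image_id: str) -> list[BoundingBox]:
        return self.boxes_by_image.get(image_id, [])

    @property
    def n_boxes(self) -> int:
        return sum(len(b) for b in self.boxes_by_image.values())

    def validate(self) -> None:
        for iid in self.boxes_by_image:
            if iid not in self.images:
                raise ValueError(f"boxes reference unknown image id {iid!r}")
            rec = self.images[iid]
            for b in self.boxes_by_image[iid]:
                if b.xmax > rec.width_px + 0.5 or b.ymax > rec.height_px + 0.5:
                    raise ValueError(
                        f"box {b} exceeds bounds of image {iid!r}"
                    )


# ---------------------------------------------------------------------------
# COCO object-detection JSON

def write_coco(aset: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as COCO object-detection JSON.

    Image ids are serialized as consecutive integers; the string id is
    preserved as the ``file_name`` stem, so ``read_coco(write_coco(s)) == s``
    for ids without an extension suffix.
    """
    aset.validate()
    id_of = {iid: k + 1 for k, iid in enumerate(aset.images)}
    images = [
        {
            "id": id_of[iid],
            "file_name": iid if "." in iid else f"{iid}.png",
            "width": rec.width_px,
            "height": rec.height_px,
        }
        for iid, rec in aset.images.items()
    ]
    cat_of = {name: k + 1 for k, name in enumerate(aset.categories)}
    annotations = []
    ann_id = 1
    for iid, boxes in aset.boxes_by_image.items():
        for b in boxes:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": id_of[iid],
                    "category_id": cat_of.get(b.label, 1),
                    "bbox": b.to_coco(),
                    "area": b.area,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    categories = [{"id": v, "name": k} for k, v in cat_of.items()]
    payload = {"images": images, "annotations": annotations,
               "categories": categories}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_coco(path: str | Path) -> AnnotationSet:
    """Read COCO object-detection JSON into an AnnotationSet."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed COCO JSON in {path}: {exc}") from exc
    for key in ("images", "annotations", "categories"):
        if key not in payload:
            raise ValueError(f"COCO file {path} missing required key {key!r}")
    cat_names = {c["id"]: c["name"] for c in payload["categories"]}
    aset = AnnotationSet(categories=[c["name"] for c in payload["categories"]]
                         or ["stoma"])
    id_to_str: dict[int, str] = {}
    for im in payload["images"]:
        sid = str(Path(im.get("file_name", str(im["id"]))).stem)
        id_to_str[im["id"]] = sid
        aset.add_image(ImageRecord(id=sid, width_px=im["width"],
                                   height_px=im["height"]))
    for ann in payload["annotations"]:
        iid = ann["image_id"]
        if iid not in id_to_str:
            raise ValueError(f"annotation references unknown image id {iid}")
        sid = id_to_str[iid]
        try:
            box = BoundingBox.from_coco(
                ann["bbox"], label=cat_names.get(ann.get("category_id"),
                                                 "stoma"))
        except ValueError as exc:
            raise ValueError(f"image {sid!r}: {exc}") from exc
        aset.boxes_by_image[sid].append(box)
    return aset


def write_coco_results(detections: Mapping[str, Sequence[BoundingBox]],
                       path: str | Path) -> None:
    """Write scored detections in COCO results format.

    ``image_id`` is serialized as the string image id; tools that require
    integer ids should remap via the companion ground-truth file.
    """
    out = []
    for iid, boxes in detections.items():
        for b in boxes:
            out.append(
                {
                    "image_id": iid,
                    "category_id": 1,
                    "bbox": b.to_coco(),
                    "score": float(b.score) if b.score is not None else 1.0,
                }
            )
    Path(path).write_text(json.dumps(out, indent=1))


def read_coco_results(path: str | Path) -> dict[str, list[BoundingBox]]:
    """Read COCO results JSON (a flat list of scored detections)."""
    try:
        entries = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed results JSON in {path}: {exc}") from exc
    if not isinstance(entries, list):
        raise ValueError(f"{path}: COCO results must be a JSON list")
    out: dict[str, list[BoundingBox]] = {}
    for e in entries:
        iid = str(e["image_id"])
        box = BoundingBox.from_coco(e["bbox"], score=e.get("score", 1.0))
        out.setdefault(iid, []).append(box)
    for iid in out:
        out[iid].sort(key=lambda b: -(b.score or 0.0))
    return out


# ---------------------------------------------------------------------------
# Labelbox-style export

def read_labelbox(path: str | Path) -> AnnotationSet:
    """Read a Labelbox-style rectangle export.

    Dialect (one JSON record per image, in a top-level list)::

        [{"external_id": "img-1",
          "media_attributes": {"width": 3072, "height": 2048},
          "objects": [{"title": "stoma",
                       "bbox": {"top": 20, "left": 10,
                                "height": 40, "width": 30}}, ...]},
         ...]

    ``top/left/height/width`` are pixels; they map to the internal corner
    convention as ``(left, top, left+width, top+height)``. Objects without
    a ``bbox`` geometry are skipped with a logged warning; a record without
    image dimensions is an error.
    """
    records = json.loads(Path(path).read_text())
    aset = AnnotationSet()
    for rec in records:
        ext_id = str(rec.get("external_id") or rec.get("ID") or rec["id"])
        media = rec.get("media_attributes") or {}
        if "width" not in media or "height" not in media:
            raise ValueError(
                f"Labelbox record {ext_id!r} lacks image dimensions"
            )
        boxes: list[BoundingBox] = []
        for obj in rec.get("objects", []):
            geom = obj.get("bbox")
            if geom is None:
                logger.warning(
                    "record %s: skipping object with unknown geometry %s",
                    ext_id, sorted(obj.keys()),
                )
                continue
            boxes.append(
                BoundingBox(
                    xmin=geom["left"],
                    ymin=geom["top"],
                    xmax=geom["left"] + geom["width"],
                    ymax=geom["top"] + geom["height"],
                    label=obj.get("title", "stoma"),
                )
            )
        aset.add_image(
            ImageRecord(id=ext_id, width_px=int(media["width"]),
                        height_px=int(media["height"])),
            boxes,
        )
    return aset


# ---------------------------------------------------------------------------
# Geometric preprocessing

@dataclass(frozen=True)
class TilingSpec:
    """Resize / pad / split geometry for training-tile preparation."""

    resize_factor: float = 0.5
    padded_width_px: int = 2048
    padded_height_px: int = 1024
    tile_width_px: int = 1024
    tile_height_px: int = 1024
    min_box_retention_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.resize_factor <= 0:
            raise ValueError("resize_factor must be > 0")
        if (self.padded_width_px % self.tile_width_px
                or self.padded_height_px % self.tile_height_px):
            raise ValueError("padded dimensions must be divisible by tile "
                             "dimensions")
        if not (0 < self.min_box_retention_fraction <= 1):
            raise ValueError("min_box_retention_fraction must be in (0, 1]")


def resize_with_boxes(image: ImageRecord, boxes: Sequence[BoundingBox],
                      factor: float
                      ) -> tuple[ImageRecord, list[BoundingBox]]:
    """Scale an image and its boxes by ``factor``.

    Pixel dimensions are rounded to the nearest integer; box coordinates
    are scaled exactly (bilinear interpolation for pixels, linear for
    coordinates).
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    new_w = round(image.width_px * factor)
    new_h = round(image.height_px * factor)
    if new_w < 1 or new_h < 1:
        raise ValueError(
            f"resize factor {factor} collapses {image.width_px}x"
            f"{image.height_px} to zero size"
        )
    pixels = None
    if image.pixels is not None:
        shape = (new_h, new_w) + image.pixels.shape[2:]
        out = _sk_resize(image.pixels, shape, order=1, anti_aliasing=factor < 1,
                         preserve_range=True)
        pixels = out.astype(image.pixels.dtype)
    rec = ImageRecord(id=image.id, width_px=new_w, height_px=new_h,
                      pixels=pixels, calibration=image.calibration)
    return rec, [b.scale(factor) for b in boxes]


def pad_to(image: ImageRecord, boxes: Sequence[BoundingBox],
           target_w: int, target_h: int, fill: float = 0
           ) -> tuple[ImageRecord, list[BoundingBox]]:
    """Pad on the right and bottom to the target size (default black).

    Padding never moves the origin, so box coordinates are unchanged.
    """
    if target_w < image.width_px or target_h < image.height_px:
        raise ValueError(
            f"target {target_w}x{target_h} smaller than image "
            f"{image.width_px}x{image.height_px}"
        )
    pixels = None
    if image.pixels is not None:
        pad = [(0, target_h - image.height_px), (0, target_w - image.width_px)]
        pad += [(0, 0)] * (image.pixels.ndim - 2)
        pixels = np.pad(image.pixels, pad, constant_values=fill)
    rec = ImageRecord(id=image.id, width_px=target_w, height_px=target_h,
                      pixels=pixels, calibration=image.calibration)
    return rec, list(boxes)


def split_tiles(image: ImageRecord, boxes: Sequence[BoundingBox],
                spec: TilingSpec
                ) -> list[tuple[ImageRecord, list[BoundingBox]]]:
    """Cut an image into non-overlapping tiles, remapping boxes.

    Tiles are emitted in row-major order with ids ``{parent}_t{index}``.
    A box is assigned to every tile it intersects, clipped to the tile and
    translated to tile-local coordinates; clips that retain less than
    ``spec.min_box_retention_fraction`` of the original box area are
    dropped (and logged).
    """
    tw, th = spec.tile_width_px, spec.tile_height_px
    if image.width_px % tw or image.height_px % th:
        raise ValueError(
            f"image {image.width_px}x{image.height_px} is not divisible by "
            f"tile size {tw}x{th}; pad with pad_to() first"
        )
    ncols = image.width_px // tw
    nrows = image.height_px // th
    out: list[tuple[ImageRecord, list[BoundingBox]]] = []
    for row in range(nrows):
        for col in range(ncols):
            idx = row * ncols + col
            x0, y0 = col * tw, row * th
            pixels = None
            if image.pixels is not None:
                pixels = image.pixels[y0:y0 + th, x0:x0 + tw].copy()
            tile = ImageRecord(id=f"{image.id}_t{idx}", width_px=tw,
                               height_px=th, pixels=pixels,
                               calibration=image.calibration)
            kept: list[BoundingBox] = []
            for b in boxes:
                clipped = b.clip(x0, y0, x0 + tw, y0 + th)
                if clipped is None:
                    continue
                if clipped.area < spec.min_box_retention_fraction * b.area:
                    logger.debug(
                        "tile %s: dropping sliver of box %s "
                        "(retained %.1f%% of area)",
                        tile.id, b, 100 * clipped.area / b.area,
                    )
                    continue
                kept.append(clipped.shift(-x0, -y0))
            out.append((tile, kept))
    return out


def prepare_training_tiles(aset: AnnotationSet,
                           spec: TilingSpec = TilingSpec()) -> AnnotationSet:
    """Apply resize -> pad -> split to every image of a set."""
    out = AnnotationSet(categories=list(aset.categories))
    for iid, rec in aset.images.items():
        resized, boxes = resize_with_boxes(rec, aset.boxes(iid),
                                           spec.resize_factor)
        padded, boxes = pad_to(resized, boxes, spec.padded_width_px,
                               spec.padded_height_px)
        for tile, tile_boxes in split_tiles(padded, boxes, spec):
            out.add_image(tile, tile_boxes)
    return out


# ---------------------------------------------------------------------------
# Image files

def read_image(path: str | Path, image_id: str | None = None,
               calibration: Calibration | None = None) -> ImageRecord:
    import imageio.v3 as iio

    pixels = iio.imread(path)
    h, w = pixels.shape[:2]
    return ImageRecord(id=image_id or Path(path).stem, width_px=w,
                       height_px=h, pixels=pixels, calibration=calibration)


def write_image(image: ImageRecord, path: str | Path) -> None:
    import imageio.v3 as iio

    if image.pixels is None:
        raise ValueError(f"image {image.id!r} has no pixel data")
    iio.imwrite(path, image.pixels)
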
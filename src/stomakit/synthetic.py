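"""Synthetic leaf-imprint scenes and micrographs with exact ground truth.

Grass stomata sit in horizontal rows ("stomatal files") along the leaf's
cell files; a nail-polish imprint imaged with the files aligned to the
image x-axis therefore shows stomata whose y-coordinates cluster on a
small number of file positions. The generator reproduces that layout:

* file positions along y with a configurable (possibly alternating)
  inter-file spacing,
* a Poisson-distributed stomata count targeting a stomatal density in
  stomata/mm^2 of the calibrated field,
* stomatal length/width drawn from truncated normals in micrometers and
  converted to pixels through the calibration, so the ground truth is
  exact in both unit systems,
* non-overlap enforced by rejection sampling,
* optionally a fraction of stomata allowed to straddle the image border
  (their ground-truth boxes are clipped), which exercises downstream
  marginal-stoma handling.

Rendering draws each stoma as a stylized dumbbell — two elongated guard-
cell lobes flanking a darker central pore — which is the canonical grass
stomatal morphology as it appears in bright-field imprints. The goal is
a testable contrast pattern inside each ground-truth box, not botanical
realism.

Defaults emulate a hexaploid wheat abaxial surface: density 16.8
stomata/mm^2, stomatal length 87.2 +/- 3.7 um, width 54.4 um, and file
intervals alternating between ~130 and ~230 um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse
from skimage.filters import gaussian

from .annotation_io import AnnotationSet, BoundingBox, ImageRecord
from .calibration import CALIBRATION_4X, Calibration

__all__ = [
    "SceneParams",
    "RenderParams",
    "SyntheticScene",
    "SceneCapacityError",
    "generate_scene",
    "render_image",
    "generate_count_dataset",
    "generate_correlated_traits",
]


class SceneCapacityError(RuntimeError):
    """Non-overlap placement failed within the retry budget."""


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters of a synthetic imprint scene.

    ``file_interval_um`` may be a single spacing or a sequence cycled
    along y (e.g. ``(130, 230)`` for a surface with two alternating
    inter-file distances). ``sd_ss_coupling`` links the realized density
    deviation to the mean stomatal length (um per stoma/mm^2 of
    deviation); 0 means size and density are independent.
    """

    image_width_px: int = 1024
    image_height_px: int = 768
    calibration: Calibration = CALIBRATION_4X
    density_per_mm2: float = 16.8
    file_interval_um: float | tuple[float, ...] = (130.0, 230.0)
    file_interval_jitter_um: float = 5.0
    length_um_mean: float = 87.2
    length_um_sd: float = 3.7
    width_um_mean: float = 54.4
    width_um_sd: float = 3.5
    stoma_y_jitter_um: float = 2.0
    sd_ss_coupling: float = 0.0
    allow_marginal: bool = True
    marginal_fraction: float = 0.1
    max_overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_per_mm2 < 0:
            raise ValueError("density_per_mm2 must be >= 0")
        for name in ("length_um_mean", "width_um_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("length_um_sd", "width_um_sd",
                     "file_interval_jitter_um", "stoma_y_jitter_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        intervals = np.atleast_1d(np.asarray(self.file_interval_um, float))
        if np.any(intervals <= 0):
            raise ValueError("file intervals must be > 0")
        if not (0.0 <= self.marginal_fraction < 1.0):
            raise ValueError("marginal_fraction must be in [0, 1)")
        if not (0.0 <= self.max_overlap_fraction < 1.0):
            raise ValueError("max_overlap_fraction must be in [0, 1)")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def intervals_um(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.file_interval_um, float))


@dataclass(frozen=True)
class RenderParams:
    """Appearance and noise of the rendered micrograph (float in [0, 1])."""

    background: float = 0.78
    lobe_intensity: float = 0.38
    pore_intensity: float = 0.12
    blur_sigma_px: float = 0.0
    noise_sd: float = 0.0
    n_dust: int = 0
    dust_radius_px: float = 3.0
    seed: int = 0


@dataclass
class SyntheticScene:
    """Ground-truth layout of one synthetic field."""

    params: SceneParams
    file_y_px: list[float]
    #: (center_x_px, center_y_px, length_px, width_px) per stoma
    stomata: list[tuple[float, float, float, float]]
    ground_truth: AnnotationSet = field(repr=False)
    image_id: str = "scene"

    @property
    def n_stomata(self) -> int:
        return len(self.stomata)

    def true_boxes(self) -> list[BoundingBox]:
        return self.ground_truth.boxes(self.image_id)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lower: float = 0.0) -> np.ndarray:
    """Normal draws resampled until > lower (exact truncation for sd=0)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= lower
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= lower
    return out


def _overlap_fraction(cx: float, cy: float, L: float, W: float,
                      placed: list[tuple[float, float, float, float]]) -> float:
    """Max intersection area over the smaller box's area against placed."""
    worst = 0.0
    x0, x1 = cx - L / 2, cx + L / 2
    y0, y1 = cy - W / 2, cy + W / 2
    for pcx, pcy, pL, pW in placed:
        ix = min(x1, pcx + pL / 2) - max(x0, pcx - pL / 2)
        if ix <= 0:
            continue
        iy = min(y1, pcy + pW / 2) - max(y0, pcy - pW / 2)
        if iy <= 0:
            continue
        frac = (ix * iy) / min(L * W, pL * pW)
        if frac > worst:
            worst = frac
    return worst


def generate_scene(params: SceneParams,
                   image_id: str | None = None) -> SyntheticScene:
    """Place stomata on horizontal files; deterministic under the seed.

    The stomata count is Poisson with mean ``density_per_mm2 *
    field_area_mm2``. Placement rejects candidates overlapping an
    accepted stoma by more than ``max_overlap_fraction``; the retry
    budget is 100x the target count, after which
    :class:`SceneCapacityError` is raised.
    """
    rng = np.random.default_rng(params.seed)
    cal = params.calibration
    scale = cal.um_per_px
    W_px, H_px = params.image_width_px, params.image_height_px
    image_id = image_id or f"scene-{params.seed}"

    # Stomatal file positions along y (pixels).
    intervals_px = params.intervals_um / scale
    jitter_px = params.file_interval_jitter_um / scale
    y = float(rng.uniform(0, intervals_px[0]))
    file_y: list[float] = []
    k = 0
    while y < H_px:
        file_y.append(y)
        step = intervals_px[k % len(intervals_px)]
        if jitter_px > 0:
            step = max(step + rng.normal(0, jitter_px), 1.0)
        y += step
        k += 1
    if not file_y:
        file_y = [H_px / 2.0]

    area_mm2 = cal.field_area_mm2
    n_target = int(rng.poisson(params.density_per_mm2 * area_mm2))

    # Density-size coupling acts on the realized density of this field.
    realized_density = n_target / area_mm2
    eff_len_mean = (params.length_um_mean
                    + params.sd_ss_coupling
                    * (realized_density - params.density_per_mm2))
    eff_len_mean = max(eff_len_mean, 1e-6)

    lengths_px = _truncated_normal(rng, eff_len_mean, params.length_um_sd,
                                   n_target) / scale
    widths_px = _truncated_normal(rng, params.width_um_mean,
                                  params.width_um_sd, n_target) / scale
    y_jit_px = params.stoma_y_jitter_um / scale

    stomata: list[tuple[float, float, float, float]] = []
    budget = 100 * max(n_target, 1)
    attempts = 0
    i = 0
    while i < n_target:
        if attempts >= budget:
            raise SceneCapacityError(
                f"placed only {len(stomata)}/{n_target} stomata after "
                f"{budget} attempts; density {params.density_per_mm2}/mm^2 "
                f"exceeds the non-overlap capacity of this field"
            )
        attempts += 1
        L, Wd = float(lengths_px[i]), float(widths_px[i])
        marginal = (params.allow_marginal
                    and rng.uniform() < params.marginal_fraction)
        fy = file_y[int(rng.integers(len(file_y)))]
        cy = fy + (rng.normal(0, y_jit_px) if y_jit_px > 0 else 0.0)
        if marginal:
            cx = float(rng.uniform(0, W_px))
        else:
            if L >= W_px or Wd >= H_px:
                raise SceneCapacityError(
                    "stoma larger than the field; check calibration"
                )
            cx = float(rng.uniform(L / 2, W_px - L / 2))
            # keep the box fully inside vertically; retry on a bad file
            if cy - Wd / 2 < 0 or cy + Wd / 2 > H_px:
                continue
        if (_overlap_fraction(cx, cy, L, Wd, stomata)
                > params.max_overlap_fraction):
            continue
        # a marginal candidate must still leave a visible sliver in frame
        if (BoundingBox(max(cx - L / 2, 0.0), max(cy - Wd / 2, 0.0),
                        cx + L / 2, cy + Wd / 2).clip(0, 0, W_px, H_px)
                is None):
            continue
        stomata.append((cx, cy, L, Wd))
        i += 1

    gt = AnnotationSet()
    boxes = []
    for cx, cy, L, Wd in stomata:
        b = BoundingBox(max(cx - L / 2, 0.0), max(cy - Wd / 2, 0.0),
                        cx + L / 2, cy + Wd / 2).clip(0, 0, W_px, H_px)
        assert b is not None
        boxes.append(b)
    gt.add_image(ImageRecord(id=image_id, width_px=W_px, height_px=H_px,
                             calibration=cal), boxes)
    return SyntheticScene(params=params, file_y_px=file_y, stomata=stomata,
                          ground_truth=gt, image_id=image_id)


def draw_dumbbell(canvas: np.ndarray, cx: float, cy: float,
                  length_px: float, width_px: float,
                  lobe_intensity: float, pore_intensity: float) -> None:
    """Paint one dumbbell stoma in place: two lobes + central pore.

    The long axis is horizontal; the figure is inscribed in the box
    ``[cx - L/2, cx + L/2] x [cy - W/2, cy + W/2]``.
    """
    shape = canvas.shape[:2]
    # guard-cell lobes
    for sgn in (-1.0, 1.0):
        rr, cc = ellipse(cy, cx + sgn * 0.28 * length_px,
                         width_px / 2, 0.22 * length_px, shape=shape)
        canvas[rr, cc] = lobe_intensity
    # central pore, darker
    rr, cc = ellipse(cy, cx, 0.22 * width_px, 0.18 * length_px, shape=shape)
    canvas[rr, cc] = pore_intensity


def render_image(scene: SyntheticScene,
                 noise: RenderParams = RenderParams()) -> ImageRecord:
    """Render a scene to a grayscale uint8 micrograph.

    Deterministic under ``noise.seed``; with all noise terms zero the
    image is a clean background with dumbbells exactly inside the
    ground-truth boxes.
    """
    rng = np.random.default_rng(noise.seed)
    H, W = scene.params.image_height_px, scene.params.image_width_px
    canvas = np.full((H, W), noise.background, dtype=float)
    for cx, cy, L, Wd in scene.stomata:
        draw_dumbbell(canvas, cx, cy, L, Wd,
                      noise.lobe_intensity, noise.pore_intensity)
    for _ in range(noise.n_dust):
        rr, cc = disk((rng.uniform(0, H), rng.uniform(0, W)),
                      noise.dust_radius_px, shape=(H, W))
        canvas[rr, cc] = noise.pore_intensity
    if noise.blur_sigma_px > 0:
        canvas = gaussian(canvas, sigma=noise.blur_sigma_px,
                          preserve_range=True)
    if noise.noise_sd > 0:
        canvas = canvas + rng.normal(0, noise.noise_sd, canvas.shape)
    pixels = (np.clip(canvas, 0, 1) * 255).round().astype(np.uint8)
    return ImageRecord(id=scene.image_id, width_px=W, height_px=H,
                       pixels=pixels, calibration=scene.params.calibration)


def generate_count_dataset(density_a: float, density_b: float,
                           dispersion: float, n_images: int,
                           calibration: Calibration = CALIBRATION_4X,
                           seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-image stomata counts for two density groups.

    Counts are negative binomial with mean ``density * field_area_mm2``
    and variance ``mean + mean^2 / dispersion``; ``dispersion = inf``
    gives Poisson counts. Models between-image heterogeneity of local
    stomatal density.
    """
    if density_a < 0 or density_b < 0:
        raise ValueError("densities must be >= 0")
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not (dispersion > 0):
        raise ValueError(f"dispersion must be > 0, got {dispersion}")
    rng = np.random.default_rng(seed)

    def draw(density: float) -> np.ndarray:
        mu = density * calibration.field_area_mm2
        if mu == 0:
            return np.zeros(n_images, dtype=int)
        if math.isinf(dispersion):
            return rng.poisson(mu, n_images)
        return rng.negative_binomial(dispersion,
                                     dispersion / (dispersion + mu), n_images)

    return draw(density_a), draw(density_b)


def generate_correlated_traits(n_fields: int, sd_mean: float, sd_sd: float,
                               len_mean: float, len_sd: float, rho: float,
                               seed: int = 0) -> pd.DataFrame:
    """Paired (SD, mean stomatal length) fields with correlation ``rho``.

    Bivariate normal; emulates per-field trait tables where local density
    and local mean length covary.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    rng = np.random.default_rng(seed)
    cov = np.array([
        [sd_sd ** 2, rho * sd_sd * len_sd],
        [rho * sd_sd * len_sd, len_sd ** 2],
    ])
    xy = rng.multivariate_normal([sd_mean, len_mean], cov, size=n_fields,
                                 method="cholesky" if abs(rho) < 1 else "svd")
    return pd.DataFrame(xy, columns=["sd_per_mm2", "mean_length_um"])
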
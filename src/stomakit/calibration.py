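"""Microscope calibration: pixel scale and field area.

A calibration ties a pixel grid to physical units. The field area is an
explicit constant rather than being derived from ``um_per_px`` and the
image dimensions, because a hardware-calibrated area and a printed pixel
scale are generally not mutually consistent at four significant figures;
:meth:`Calibration.derived_field_area_mm2` gives the derived value when
no independent area calibration exists.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Calibration:
    """Objective scale and field geometry for a microscope setup.

    Parameters
    ----------
    objective : str
        Label of the objective lens, e.g. ``"4x"``.
    um_per_px : float
        Physical size of one pixel in micrometers. Must be positive.
    image_width_px, image_height_px : int
        Dimensions of the camera field in pixels.
    field_area_mm2 : float
        Calibrated area of the microscopic field in mm^2. Must be positive.
    """

    objective: str = "4x"
    um_per_px: float = 1.116
    image_width_px: int = 1024
    image_height_px: int = 768
    field_area_mm2: float = 0.984

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be > 0, got {self.um_per_px}")
        if self.field_area_mm2 <= 0:
            raise ValueError(
                f"field_area_mm2 must be > 0, got {self.field_area_mm2}"
            )
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")

    def derived_field_area_mm2(self) -> float:
        """Field area implied by the pixel scale and image dimensions."""
        w_um = self.image_width_px * self.um_per_px
        h_um = self.image_height_px * self.um_per_px
        return w_um * h_um / 1e6

    def px_to_um(self, px: float) -> float:
        return px * self.um_per_px

    def um_to_px(self, um: float) -> float:
        return um / self.um_per_px


#: Low-magnification profile used for wheat-sized stomata.
CALIBRATION_4X = Calibration(objective="4x", um_per_px=1.116,
                             image_width_px=1024, image_height_px=768,
                             field_area_mm2=0.984)

#: High-magnification profile for small stomata (e.g. Brachypodium).
#: No independent area calibration; area derived from the pixel scale.
CALIBRATION_10X = Calibration(objective="10x", um_per_px=0.445,
                              image_width_px=1024, image_height_px=768,
                              field_area_mm2=1024 * 768 * 0.445 ** 2 / 1e6)

PRESETS = {"4x": CALIBRATION_4X, "10x": CALIBRATION_10X}
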
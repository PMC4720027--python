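"""Geometry of micropatterned culture plates.

A plate is a set of wells, each carrying a rectangular grid of circular
cell-adhesive islands ("features", conventionally called μFeatures).  One
microscope image is acquired per feature per day, so the (well, grid_row,
grid_col) triple is the primary key of every downstream table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of a micropatterned multiwell plate.

    Parameters
    ----------
    n_wells:
        Number of wells on the plate (default 6, a standard 6-well plate).
    grid_rows, grid_cols:
        Acquisition grid per well; one image is taken per grid position.
        The default 20 x 20 grid gives 400 features per well.
    feature_diameter_um:
        Diameter of each circular adhesive island, in micrometres.
    feature_pitch_um:
        Centre-to-centre spacing between neighbouring features; must
        exceed the diameter so features never touch.
    pixels_per_um:
        Image scale of the acquisition (pixels per micrometre).
    image_margin_px:
        Pixels of background kept around the feature disk in each image.
    """

    n_wells: int = 6
    grid_rows: int = 20
    grid_cols: int = 20
    feature_diameter_um: float = 300.0
    feature_pitch_um: float = 450.0
    pixels_per_um: float = 0.65
    image_margin_px: int = 16

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.grid_rows * self.grid_cols < 1:
            raise ValueError("grid must contain at least one feature")
        if self.feature_diameter_um <= 0 or self.feature_pitch_um <= 0:
            raise ValueError("feature dimensions must be positive")
        if self.feature_pitch_um <= self.feature_diameter_um:
            raise ValueError("feature_pitch_um must exceed feature_diameter_um")
        if self.pixels_per_um <= 0:
            raise ValueError("pixels_per_um must be positive")

    @property
    def features_per_well(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def features_per_plate(self) -> int:
        return self.n_wells * self.features_per_well

    @property
    def feature_radius_px(self) -> float:
        return 0.5 * self.feature_diameter_um * self.pixels_per_um

    @property
    def image_size_px(self) -> int:
        """Side length of the square per-feature image, in pixels."""
        side = int(round(self.feature_diameter_um * self.pixels_per_um))
        return side + 2 * self.image_margin_px

    def positions(self) -> Iterator[tuple[int, int]]:
        """Yield (grid_row, grid_col) in acquisition (row-major) order."""
        for r in range(self.grid_rows):
            for c in range(self.grid_cols):
                yield r, c

    def contains(self, grid_row: int, grid_col: int) -> bool:
        return 0 <= grid_row < self.grid_rows and 0 <= grid_col < self.grid_cols
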
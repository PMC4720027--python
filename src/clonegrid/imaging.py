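"""Per-feature high-content quantification.

Maps acquisition-grid images onto plate features, corrects smooth
illumination defects, segments and counts nuclei, and persists per-image
counts to a file-backed tabular store keyed by (well, grid_row, grid_col,
day).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureImage",
    "SegmentationResult",
    "CountStore",
    "parse_image_filename",
    "load_feature_image",
    "correct_illumination",
    "segment_nuclei",
    "process_plate",
]

FILENAME_RE = re.compile(
    r"well(?P<well>\d+)_pos(?P<row>\d+)x(?P<col>\d+)_day(?P<day>\d+)\.(tif|tiff|png)$",
    re.IGNORECASE,
)


@dataclass
class FeatureImage:
    """One image of one feature on one day."""

    pixels: np.ndarray
    well: int
    grid_row: int
    grid_col: int
    day: int
    pixel_scale: float = 1.0  # um per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.day < 0:
            raise ValueError("day must be >= 0")

    @property
    def key(self) -> tuple[int, int, int, int]:
        return (self.well, self.grid_row, self.grid_col, self.day)


@dataclass
class SegmentationResult:
    label_image: np.ndarray
    nucleus_count: int
    centroids: list[tuple[float, float]]
    mean_area_px: float

    def __post_init__(self) -> None:
        n_labels = int(self.label_image.max())
        if self.nucleus_count != n_labels:
            raise ValueError("nucleus_count must equal number of labels")


def parse_image_filename(name: str) -> tuple[int, int, int, int] | None:
    """Parse ``well{W}_pos{RRR}x{CCC}_day{D}`` filenames; None if malformed."""
    m = FILENAME_RE.search(Path(name).name)
    if m is None:
        return None
    return (int(m["well"]), int(m["row"]), int(m["col"]), int(m["day"]))


def load_feature_image(path: str | Path, pixel_scale: float = 1.0) -> FeatureImage:
    path = Path(path)
    key = parse_image_filename(path.name)
    if key is None:
        raise ValueError(f"cannot parse image filename: {path.name}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        pixels = imread(path)
    well, row, col, day = key
    return FeatureImage(pixels, well, row, col, day, pixel_scale)


def correct_illumination(image: np.ndarray, sigma_frac: float = 0.25) -> np.ndarray:
    """Divide out a smooth multiplicative illumination field.

    The field is estimated by a coarse Gaussian blur (sigma =
    ``sigma_frac`` x image side) and normalised to unit mean, so a flat
    image is returned unchanged up to numerical tolerance and the
    operation is idempotent up to the same tolerance.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image must be non-empty")
    if not np.any(image):
        logger.warning("all-zero image passed to correct_illumination; returned as is")
        return image
    sigma = max(1.0, sigma_frac * max(image.shape))
    background = gaussian(image, sigma=sigma, preserve_range=True)
    background = np.maximum(background, 1e-9)
    field = background / background.mean()
    corrected = image / field
    return np.maximum(corrected, 0.0)


def _estimate_background(image: np.ndarray) -> tuple[float, float]:
    """Robust background level and noise sigma (median / MAD)."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med, 1.4826 * mad


def segment_nuclei(
    image: np.ndarray,
    min_area_px: int | None = None,
    threshold_method: str = "otsu",
    declump: bool = True,
    expected_radius_px: float = 4.0,
    smooth_sigma: float = 1.0,
) -> SegmentationResult:
    """Segment nuclei by global threshold + connected components.

    The image is lightly smoothed, thresholded (Otsu by default, guarded
    against background-only images by requiring the threshold to clear
    the background by 5 robust noise sigmas), and labelled.  With
    ``declump`` on, touching nuclei are split by a distance-transform
    watershed seeded at local maxima at least one nucleus diameter apart.
    Components smaller than ``min_area_px`` (default 25% of the expected
    nucleus area) are discarded as debris.
    """
    image = np.asarray(image, dtype=float)
    if min_area_px is None:
        min_area_px = int(0.25 * np.pi * expected_radius_px**2)
    smoothed = gaussian(image, sigma=smooth_sigma, preserve_range=True)
    bg, noise = _estimate_background(smoothed)

    if threshold_method == "otsu":
        span = smoothed.max() - smoothed.min()
        thresh = threshold_otsu(smoothed) if span > 0 else np.inf
    elif threshold_method == "fixed_sigma":
        thresh = bg + 5 * noise
    else:
        raise ValueError(f"unknown threshold_method: {threshold_method!r}")
    # Guard: on a background-only (or saturated uniform) image Otsu splits
    # the noise in half; demand real contrast above the background.
    floor = bg + 5 * max(noise, 1e-6)
    mask = smoothed > max(thresh, floor)
    if not mask.any():
        return SegmentationResult(np.zeros(image.shape, dtype=int), 0, [], 0.0)

    if declump:
        distance = ndi.distance_transform_edt(mask)
        min_sep = max(2, int(round(2 * expected_radius_px)))
        peaks = peak_local_max(
            distance, min_distance=min_sep, labels=mask, exclude_border=False
        )
        markers = np.zeros(image.shape, dtype=int)
        for i, (y, x) in enumerate(peaks, start=1):
            markers[y, x] = i
        labels = watershed(-distance, markers, mask=mask)
    else:
        labels = cc_label(mask)

    # drop debris components below min_area_px, then relabel consecutively
    area = np.bincount(labels.ravel())
    small = area < min_area_px
    small[0] = False
    labels[small[labels]] = 0
    labels = _relabel(labels)
    props = regionprops(labels)
    centroids = [(p.centroid[1], p.centroid[0]) for p in props]  # (x, y)
    mean_area = float(np.mean([p.area for p in props])) if props else 0.0
    return SegmentationResult(labels, len(props), centroids, mean_area)


def _relabel(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


class CountStore:
    """File-backed, keyed count table (CSV; replaces a database server).

    Upserts on the (well, grid_row, grid_col, day) key; the in-memory
    table and the CSV on disk stay in sync on :meth:`save`.
    """

    COLUMNS = ["well", "grid_row", "grid_col", "day", "nucleus_count"]
    KEY = ["well", "grid_row", "grid_col", "day"]

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        if self.path is not None and self.path.exists():
            self._table = pd.read_csv(self.path)
        else:
            self._table = pd.DataFrame(columns=self.COLUMNS)

    def upsert(self, well: int, grid_row: int, grid_col: int, day: int, count: int):
        key = (well, grid_row, grid_col, day)
        mask = (
            (self._table["well"] == well)
            & (self._table["grid_row"] == grid_row)
            & (self._table["grid_col"] == grid_col)
            & (self._table["day"] == day)
        )
        if mask.any():
            logger.warning("replacing existing record for key %s", key)
            self._table = self._table[~mask]
        row = pd.DataFrame([key + (count,)], columns=self.COLUMNS)
        self._table = pd.concat([self._table, row], ignore_index=True)

    def to_frame(self) -> pd.DataFrame:
        return (
            self._table.astype({c: int for c in self.COLUMNS})
            .sort_values(self.KEY)
            .reset_index(drop=True)
        )

    def save(self, path: str | Path | None = None) -> Path:
        path = Path(path) if path is not None else self.path
        if path is None:
            raise ValueError("no path configured for CountStore")
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        self.path = path
        return path

    def __len__(self) -> int:
        return len(self._table)


def process_plate(
    images: Iterable[FeatureImage]
    | Mapping[tuple[int, int, int, int], np.ndarray]
    | str
    | Path,
    store: CountStore | None = None,
    correct: bool = True,
    **segment_kwargs,
) -> pd.DataFrame:
    """Count nuclei in every image and record one row per image.

    ``images`` may be a directory of TIFF/PNG files following the
    ``well{W}_pos{RRR}x{CCC}_day{D}`` naming convention, a mapping from
    (well, grid_row, grid_col, day) to pixel arrays, or an iterable of
    :class:`FeatureImage`.  Unparseable filenames are skipped with a
    logged warning; duplicate keys replace the previous record.
    """
    if store is None:
        store = CountStore()

    def iter_images():
        if isinstance(images, (str, Path)):
            for path in sorted(Path(images).iterdir()):
                if not path.is_file():
                    continue
                if parse_image_filename(path.name) is None:
                    logger.warning("skipping unparseable filename: %s", path.name)
                    continue
                yield load_feature_image(path)
        elif isinstance(images, Mapping):
            for (well, gr, gc, day), px in images.items():
                yield FeatureImage(px, well, gr, gc, day)
        else:
            yield from images

    for fimg in iter_images():
        pixels = correct_illumination(fimg.pixels) if correct else fimg.pixels
        seg = segment_nuclei(pixels, **segment_kwargs)
        store.upsert(fimg.well, fimg.grid_row, fimg.grid_col, fimg.day,
                     seg.nucleus_count)
    if store.path is not None:
        store.save()
    return store.to_frame()
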
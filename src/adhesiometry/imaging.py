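"""Calibrated image containers and the shared low-level image operators.

All images are held as 2-D float arrays with intensities normalized to
``[0, 1]`` regardless of the 8- or 16-bit source, so that thresholds carry
the same meaning across acquisitions.  Coordinates are row-major, 0-based
``(row, col)`` with the origin at the top-left corner.  Objects use
8-neighbor connectivity and background uses 4-neighbor connectivity (the
standard duality that avoids topological paradoxes in hole filling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed as _skimage_watershed

__all__ = [
    "IntensityGrid",
    "BinaryMask",
    "LabelGrid",
    "DegenerateInputError",
    "FormatError",
    "read_image",
    "write_image",
    "otsu_threshold",
    "connected_components",
    "watershed_split",
    "distance_to_boundary",
    "fill_holes_and_largest",
]


class DegenerateInputError(ValueError):
    """An image operation received input with no usable structure."""


class FormatError(ValueError):
    """A file on disk does not match the expected image format."""


@dataclass(frozen=True)
class IntensityGrid:
    """A calibrated grayscale image.

    Parameters
    ----------
    pixels
        2-D array of finite intensities in ``[0, 1]``.
    pixel_size_mm
        Edge length of one pixel in millimetres (must be positive).
    bit_depth_src
        Bit depth of the source file (8 or 16); provenance only, the
        in-memory representation is always float.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    bit_depth_src: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"pixels must be a 2-D array of at least 2x2, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if not (self.pixel_size_mm > 0):
            raise ValueError(f"pixel_size_mm must be > 0, got {self.pixel_size_mm}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "IntensityGrid":
        """A copy of this grid with new pixel values, same calibration."""
        return IntensityGrid(pixels, self.pixel_size_mm, self.bit_depth_src)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean image sharing the shape of the grid it was derived from."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            px = px.astype(bool)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class LabelGrid:
    """Integer-labelled segmentation; 0 is background, labels run 1..n_labels."""

    pixels: np.ndarray
    n_labels: int = field(default=-1)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"label grid must be 2-D, got shape {px.shape}")
        px = px.astype(np.int32, copy=False)
        if px.min() < 0:
            raise ValueError("labels must be non-negative")
        n = int(px.max())
        if self.n_labels == -1:
            object.__setattr__(self, "n_labels", n)
        else:
            present = np.unique(px)
            present = present[present > 0]
            if self.n_labels != n or (n > 0 and len(present) != n):
                raise ValueError("labels must be exactly 1..n_labels with none missing")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def areas_px(self) -> np.ndarray:
        """Pixel count per label, index 0 holding label 1."""
        if self.n_labels == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(self.pixels.ravel(), minlength=self.n_labels + 1)[1:].astype(np.int64)


_STRUCT_4 = ndi.generate_binary_structure(2, 1)
_STRUCT_8 = ndi.generate_binary_structure(2, 2)


def read_image(path: str | Path, pixel_size_mm: float) -> IntensityGrid:
    """Read a grayscale 8- or 16-bit TIFF/PNG into a calibrated grid.

    Intensities are rescaled to ``[0, 1]`` by the maximum representable
    value of the source bit depth (255 or 65535), not by the observed
    maximum, so absolute brightness is preserved across images.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read image {path}: {exc}") from exc
    if raw.ndim == 3:
        if raw.shape[2] == 1:
            raw = raw[:, :, 0]
        else:
            raise FormatError(
                f"{path} has {raw.shape[2]} channels; pass a single-channel image"
            )
    if raw.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D grayscale image, got shape {raw.shape}")
    if raw.dtype == np.uint8:
        depth, scale = 8, 255.0
    elif raw.dtype == np.uint16:
        depth, scale = 16, 65535.0
    else:
        raise FormatError(f"{path}: unsupported dtype {raw.dtype}; expected uint8 or uint16")
    return IntensityGrid(raw.astype(np.float64) / scale, pixel_size_mm, bit_depth_src=depth)


def write_image(grid: IntensityGrid, path: str | Path, bit_depth: int | None = None) -> None:
    """Write a grid as an 8- or 16-bit grayscale TIFF/PNG (by extension)."""
    import imageio.v3 as iio

    depth = bit_depth if bit_depth is not None else grid.bit_depth_src
    if depth == 8:
        data = np.round(grid.pixels * 255.0).astype(np.uint8)
    elif depth == 16:
        data = np.round(grid.pixels * 65535.0).astype(np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {depth}")
    iio.imwrite(Path(path), data)


def otsu_threshold(grid: IntensityGrid | np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the histogram split maximizing between-class variance.

    The intensity range ``[0, 1]`` is divided into ``n_bins`` equal bins
    and every boundary between adjacent non-degenerate classes is scored
    by the between-class variance ``w0 * w1 * (mu0 - mu1)**2``; the
    returned threshold is the upper edge of the best lower class, so that
    ``pixels > threshold`` selects the bright class.
    """
    px = grid.pixels if isinstance(grid, IntensityGrid) else np.asarray(grid, dtype=np.float64)
    values = px.ravel()
    if values.max() == values.min():
        raise DegenerateInputError("constant image: no threshold separates two classes")
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    if np.count_nonzero(counts) < 2:
        raise DegenerateInputError(
            "all intensities fall in one histogram bin: no threshold separates two classes"
        )
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(counts).astype(np.float64)
    total = w0[-1]
    sum0 = np.cumsum(counts * centers)
    total_sum = sum0[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (total_sum - sum0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where(np.isfinite(between), between, -np.inf)[:-1]
    best = int(np.argmax(between))
    return float(edges[best + 1])


def connected_components(mask: BinaryMask, connectivity: int = 8) -> LabelGrid:
    """Label connected foreground components (4- or 8-neighbor)."""
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    labels, n = ndi.label(mask.pixels, structure=structure)
    return LabelGrid(labels, n)


def watershed_split(mask: BinaryMask, min_seed_distance: int = 5) -> LabelGrid:
    """Partition a foreground mask into basins, splitting touching objects.

    Seeds are local maxima of the interior Euclidean distance transform;
    maxima closer than ``min_seed_distance`` pixels are suppressed so that
    an isolated round object yields a single basin.  Every true pixel is
    assigned to exactly one label, so the result is a partition of the mask.
    """
    if not mask.pixels.any():
        return LabelGrid(np.zeros(mask.shape, dtype=np.int32), 0)
    dist = ndi.distance_transform_edt(mask.pixels)
    coords = peak_local_max(
        dist,
        min_distance=int(min_seed_distance),
        labels=mask.pixels,
        exclude_border=False,
    )
    peaks = np.zeros(mask.shape, dtype=bool)
    peaks[tuple(coords.T)] = True
    # Plateau maxima can survive suppression as twins; merging 8-connected
    # peak pixels keeps one seed per plateau.
    markers, n_markers = ndi.label(peaks, structure=_STRUCT_8)
    if n_markers == 0:
        return connected_components(mask, connectivity=8)
    labels = _skimage_watershed(-dist, markers=markers, mask=mask.pixels)
    return _renumber(labels)


def distance_to_boundary(mask: BinaryMask) -> np.ndarray:
    """Euclidean distance from each true pixel to the nearest false pixel.

    False pixels map to 0.  The image border is not treated as background:
    distance is measured to actual false pixels only.
    """
    px = mask.pixels
    if px.all() or not px.any():
        raise DegenerateInputError("mask must contain both true and false pixels")
    return ndi.distance_transform_edt(px)


def fill_holes_and_largest(mask: BinaryMask) -> BinaryMask:
    """Keep the largest 8-connected component and fill its interior holes.

    Holes are background regions (4-connected) not touching the image
    border.
    """
    if not mask.pixels.any():
        raise DegenerateInputError("empty mask")
    labels, n = ndi.label(mask.pixels, structure=_STRUCT_8)
    if n > 1:
        areas = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(areas)) + 1
        largest = labels == keep
    else:
        largest = labels > 0
    filled = ndi.binary_fill_holes(largest, structure=_STRUCT_4)
    return BinaryMask(filled)


def _renumber(labels: np.ndarray) -> LabelGrid:
    """Renumber labels densely to 1..L preserving first-appearance order."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    return LabelGrid(lut[labels], len(present))
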
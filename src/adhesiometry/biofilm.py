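"""Competitive-biofilm genotype-segregation quantification.

Two strains tagged with RFP and GFP are mixed 1:1, grown into a mat
biofilm, and imaged in both fluorescence channels.  The pipeline fuses
the channels to find the colony, normalizes each channel against medium
autofluorescence and its own dynamic range, and quantifies which genotype
occupies the expanding front: the fraction of pixels whose RFP signal
exceeds their GFP signal, measured along a ring 50 px inside the colony
edge and over the whole colony.  The superior/inferior edge-fraction
ratio is binned into five dominance categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .imaging import (
    BinaryMask,
    DegenerateInputError,
    IntensityGrid,
    distance_to_boundary,
    fill_holes_and_largest,
    otsu_threshold,
)

__all__ = [
    "ChannelPair",
    "ColonyMask",
    "SegregationResult",
    "EmptyRingError",
    "fuse_channels",
    "detect_colony",
    "normalize_channels",
    "edge_ring",
    "red_fraction",
    "segregation_metrics",
]

_STRUCT_8 = ndi.generate_binary_structure(2, 2)

DEFAULT_EDGE_DEPTH_PX = 50
DEFAULT_RATIO_CAP = 1000.0
DEFAULT_CATEGORY_BOUNDS = (1.5, 4.0, 20.0, 100.0)


class EmptyRingError(ValueError):
    """The requested edge ring contains no pixels."""


@dataclass(frozen=True)
class ChannelPair:
    """Paired RFP/GFP images of the same colony."""

    rfp: IntensityGrid
    gfp: IntensityGrid

    def __post_init__(self) -> None:
        if self.rfp.shape != self.gfp.shape:
            raise ValueError(
                f"channel shape mismatch: RFP {self.rfp.shape} vs GFP {self.gfp.shape}"
            )

    def swapped(self) -> "ChannelPair":
        return ChannelPair(rfp=self.gfp, gfp=self.rfp)


@dataclass(frozen=True)
class ColonyMask:
    """The detected colony: one filled connected component."""

    mask: BinaryMask
    n_iterations: int
    area_px: int


@dataclass(frozen=True)
class SegregationResult:
    edge_red_fraction: float
    whole_red_fraction: float
    superior_channel: str  # "RFP" or "GFP"
    genotype_ratio: float
    ratio_category: int
    edge_depth_px: int
    colony_area_px: int


def fuse_channels(pair: ChannelPair) -> IntensityGrid:
    """Pixelwise mean of the two channels (the gray-level fusion image)."""
    return pair.rfp.with_pixels((pair.rfp.pixels + pair.gfp.pixels) / 2.0)


def _split_quality(values: np.ndarray, threshold: float) -> float:
    """Otsu's eta at a split: between-class variance / total variance.

    Near 1 for a genuinely bimodal population; about 0.64 when the split
    merely bisects unimodal Gaussian noise.
    """
    total_var = float(np.var(values))
    if total_var == 0:
        return 0.0
    lo = values[values <= threshold]
    hi = values[values > threshold]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    w0 = lo.size / values.size
    w1 = 1.0 - w0
    return float(w0 * w1 * (lo.mean() - hi.mean()) ** 2 / total_var)


def detect_colony(
    fused: IntensityGrid,
    max_iter: int = 10,
    stop_fraction: float = 0.005,
    n_bins: int = 256,
    min_split_quality: float = 0.75,
) -> ColonyMask:
    """Find the colony by iterative Otsu expansion of the brightest region.

    The first Otsu pass on the whole image captures the brightest region.
    Each further pass re-thresholds only the pixels outside the current
    mask and accretes the newly-bright pixels that are 8-connected to the
    mask (directly or through each other), so dimmer outer zones of the
    colony are recovered without absorbing disconnected bright debris.

    Expansion stops when any of these hold: the outside split no longer
    separates two real intensity classes (Otsu's eta below
    ``min_split_quality`` — re-thresholding pure background noise would
    otherwise accrete it without bound), the added area falls below
    ``stop_fraction`` of the current mask area, or ``max_iter`` passes
    have run.  The result is hole-filled and reduced to its largest
    component.
    """
    px = fused.pixels
    threshold = otsu_threshold(fused, n_bins)
    mask = px > threshold
    if not mask.any():  # pathological histogram split
        raise DegenerateInputError("initial Otsu pass produced an empty mask")
    n_iterations = 1
    while n_iterations < max_iter:
        outside_values = px[~mask]
        try:
            threshold = otsu_threshold(outside_values, n_bins)
        except DegenerateInputError:
            break
        if _split_quality(outside_values, threshold) < min_split_quality:
            break
        candidates = ~mask & (px > threshold)
        if not candidates.any():
            break
        combined, _ = ndi.label(mask | candidates, structure=_STRUCT_8)
        touching = np.unique(combined[mask])
        grown = np.isin(combined, touching[touching > 0])
        added = int(grown.sum()) - int(mask.sum())
        n_iterations += 1
        if added <= 0:
            break
        stop = added < stop_fraction * mask.sum()
        mask = grown
        if stop:
            break
    cleaned = fill_holes_and_largest(BinaryMask(mask))
    return ColonyMask(mask=cleaned, n_iterations=n_iterations, area_px=cleaned.area_px)


def normalize_channels(pair: ChannelPair, colony: ColonyMask) -> ChannelPair:
    """Discount medium autofluorescence and equalize channel magnitudes.

    Per channel: subtract the median intensity outside the colony (the
    autofluorescence estimate), clamp at zero, and divide by the 99th
    percentile of the corrected intensity inside the colony, so both
    channels report comparable, near-[0, 1] signals regardless of
    fluorophore brightness.
    """
    outside = ~colony.mask.pixels
    if outside.sum() < 0.01 * outside.size:
        raise ValueError("colony mask must leave at least 1% of pixels outside")
    normalized = []
    for grid in (pair.rfp, pair.gfp):
        px = grid.pixels
        corrected = np.maximum(px - np.median(px[outside]), 0.0)
        scale = np.percentile(corrected[colony.mask.pixels], 99)
        if scale <= 0:
            raise DegenerateInputError(
                "channel has no signal inside the colony after autofluorescence subtraction"
            )
        # normalized values may exceed 1 slightly (top percentile); that is
        # fine, comparisons are relative
        normalized.append(
            IntensityGrid(
                np.clip(corrected / scale, 0.0, 1.0), grid.pixel_size_mm, grid.bit_depth_src
            )
        )
    return ChannelPair(rfp=normalized[0], gfp=normalized[1])


def edge_ring(colony: ColonyMask, depth_px: int) -> BinaryMask:
    """Colony pixels at a fixed depth inside the colony boundary.

    Depth 0 is the outermost 1-px contour of the mask; depth d selects
    the pixels whose Euclidean distance to the background lies within
    half a pixel of d + 1 (a 1-px-equivalent ring).
    """
    if depth_px < 0:
        raise ValueError("depth_px must be >= 0")
    dist = distance_to_boundary(colony.mask)
    ring = (dist >= depth_px + 0.5) & (dist < depth_px + 1.5)
    if not ring.any():
        raise EmptyRingError(
            f"no colony pixels at depth {depth_px} px (colony inradius too small)"
        )
    return BinaryMask(ring)


def red_fraction(pair_norm: ChannelPair, region: BinaryMask, mode: str = "pixel") -> float:
    """Fraction of a region dominated by the RFP channel.

    In ``pixel`` mode (the operational definition): the fraction of
    region pixels whose normalized RFP strictly exceeds their normalized
    GFP; ties count against RFP.  In ``intensity`` mode: the RFP share of
    the summed normalized signal, for when the per-signal "amount" view
    is wanted instead.
    """
    sel = region.pixels
    if not sel.any():
        raise ValueError("region is empty")
    r = pair_norm.rfp.pixels[sel]
    g = pair_norm.gfp.pixels[sel]
    if mode == "pixel":
        return float(np.count_nonzero(r > g)) / r.size
    if mode == "intensity":
        total = r.sum() + g.sum()
        if total <= 0:
            raise DegenerateInputError("no signal in region")
        return float(r.sum() / total)
    raise ValueError(f"mode must be 'pixel' or 'intensity', got {mode!r}")


def segregation_metrics(
    pair_norm: ChannelPair,
    colony: ColonyMask,
    depth_px: int = DEFAULT_EDGE_DEPTH_PX,
    category_bounds: tuple[float, float, float, float] = DEFAULT_CATEGORY_BOUNDS,
    ratio_cap: float = DEFAULT_RATIO_CAP,
    mode: str = "pixel",
) -> SegregationResult:
    """Edge and whole-colony genotype fractions plus the dominance ratio.

    The superior channel is the one holding at least half the edge ring;
    ``genotype_ratio`` divides the superior edge fraction by the inferior
    one (capped at ``ratio_cap`` for a fully monopolized edge) and is
    binned into five half-open dominance categories by
    ``category_bounds``.
    """
    if len(category_bounds) != 4 or not all(
        b2 > b1 for b1, b2 in zip(category_bounds, category_bounds[1:])
    ):
        raise ValueError("category_bounds must be 4 ascending reals")
    if not (ratio_cap > 1):
        raise ValueError("ratio_cap must exceed 1")
    ring = edge_ring(colony, depth_px)
    edge_f = red_fraction(pair_norm, ring, mode)
    whole_f = red_fraction(pair_norm, colony.mask, mode)
    superior = "RFP" if edge_f >= 0.5 else "GFP"
    hi, lo = max(edge_f, 1.0 - edge_f), min(edge_f, 1.0 - edge_f)
    ratio = ratio_cap if lo == 0.0 else min(hi / lo, ratio_cap)
    category = int(np.searchsorted(category_bounds, ratio, side="right")) + 1
    return SegregationResult(
        edge_red_fraction=edge_f,
        whole_red_fraction=whole_f,
        superior_channel=superior,
        genotype_ratio=ratio,
        ratio_category=category,
        edge_depth_px=depth_px,
        colony_area_px=colony.area_px,
    )


def analyze_pair(
    pair: ChannelPair,
    depth_px: int = DEFAULT_EDGE_DEPTH_PX,
    category_bounds: tuple[float, float, float, float] = DEFAULT_CATEGORY_BOUNDS,
    ratio_cap: float = DEFAULT_RATIO_CAP,
    mode: str = "pixel",
    max_iter: int = 10,
    stop_fraction: float = 0.005,
) -> SegregationResult:
    """Full pipeline: fuse, detect colony, normalize, quantify."""
    colony = detect_colony(fuse_channels(pair), max_iter=max_iter, stop_fraction=stop_fraction)
    pair_norm = normalize_channels(pair, colony)
    return segregation_metrics(pair_norm, colony, depth_px, category_bounds, ratio_cap, mode)
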
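"""Ground-truth generators for every pipeline in the package.

Three simulators produce the raw inputs the analysis pipelines consume,
together with the exact ground truth used to verify parameter recovery:

* aggregate scenes — dark cell clumps on an inhomogeneous bright agar
  background, with known per-object areas (the aggregate-microscopy
  input);
* two-channel sectored colonies — an RFP/GFP image pair of a circular
  biofilm with a mixed core and angular single-genotype sectors whose rim
  arc-lengths realize a prescribed edge monopolization (the competitive
  biofilm input);
* force-distance curves — approach/retract cycles with linear drift,
  Gaussian noise and an adhesion well of known depth (the SCFS input).

All generators are pure functions of their spec (seed included) and are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import BinaryMask, IntensityGrid
from .scfs import ForceCurve

__all__ = [
    "AggregateSceneSpec",
    "AggregateTruth",
    "BiofilmSpec",
    "BiofilmTruth",
    "CurveSpec",
    "CurveTruth",
    "PlacementError",
    "gen_aggregate_scene",
    "gen_biofilm_pair",
    "gen_force_curve",
    "gen_null_groups",
]


class PlacementError(RuntimeError):
    """Objects could not be placed without unintended overlap."""


# ---------------------------------------------------------------------------
# aggregate scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AggregateSceneSpec:
    """Scene of dark cell aggregates on bright agar.

    ``objects`` lists ``(target_area_mm2, shape)`` with shape ``"disc"``
    or ``"blob"`` (a disc with mild angular boundary modulation).  The
    first ``overlap_pairs`` consecutive object pairs are placed touching,
    to exercise watershed dissection; all other objects are kept apart.
    ``contrast`` is how much darker an aggregate is than the local
    background (intensity units).
    """

    field_size_px: tuple[int, int]
    pixel_size_mm: float
    objects: tuple[tuple[float, str], ...]
    overlap_pairs: int = 0
    background_gradient_amplitude: float = 0.1
    noise_sd: float = 0.01
    seed: int = 0
    contrast: float = 0.3
    background_level: float = 0.7

    def __post_init__(self) -> None:
        rows, cols = self.field_size_px
        if rows < 8 or cols < 8:
            raise ValueError("field must be at least 8x8 pixels")
        if not (self.pixel_size_mm > 0):
            raise ValueError("pixel_size_mm must be > 0")
        for area, shape in self.objects:
            if not (area > 0):
                raise ValueError(f"target area must be > 0, got {area}")
            if shape not in ("disc", "blob"):
                raise ValueError(f"shape must be 'disc' or 'blob', got {shape!r}")
        if not (0 <= self.background_gradient_amplitude <= 0.3):
            raise ValueError("background_gradient_amplitude must be in [0, 0.3]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.overlap_pairs < 0 or 2 * self.overlap_pairs > len(self.objects):
            raise ValueError("overlap_pairs must fit within the object list")
        if not (0 < self.contrast <= self.background_level - self.background_gradient_amplitude):
            raise ValueError("contrast must be positive and leave the scene within [0, 1]")


@dataclass(frozen=True)
class AggregateTruth:
    """Generator-side truth for an aggregate scene."""

    labels: np.ndarray
    area_px: np.ndarray
    area_mm2: np.ndarray
    background: IntensityGrid


def _object_radii_px(spec: AggregateSceneSpec) -> np.ndarray:
    areas_px = np.array([a for a, _ in spec.objects]) / spec.pixel_size_mm**2
    return np.sqrt(areas_px / np.pi)


def _signed_distance(
    shape_px: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    kind: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Signed distance to the object boundary (< 0 inside), per pixel."""
    rr, cc = np.indices(shape_px, dtype=np.float64)
    dy = rr - center[0]
    dx = cc - center[1]
    dist = np.hypot(dy, dx)
    if kind == "disc":
        return dist - radius
    theta = np.arctan2(dy, dx)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    wobble = 1.0 + 0.12 * np.sin(3 * theta + phase[0]) + 0.06 * np.sin(5 * theta + phase[1])
    return dist - radius * wobble


def gen_aggregate_scene(
    spec: AggregateSceneSpec,
) -> tuple[IntensityGrid, IntensityGrid, AggregateTruth]:
    """Render an aggregate scene; returns (background, scene, truth).

    Objects are rendered darker than the background with half-pixel
    boundary anti-aliasing; a pixel belongs to an object in the truth
    label map when its centre lies inside the object (designated touching
    pairs split the overlap by nearest centre).  Gaussian noise is added
    to the scene only, and both images are clipped to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.field_size_px

    # smooth inhomogeneous background: planar ramp + low-frequency bump
    rr, cc = np.indices((rows, cols), dtype=np.float64)
    u, v = rr / max(rows - 1, 1), cc / max(cols - 1, 1)
    a = spec.background_gradient_amplitude
    ramp_dir = rng.uniform(0, 2 * np.pi)
    bump_c = rng.uniform(0.25, 0.75, size=2)
    pattern = 0.6 * (np.cos(ramp_dir) * u + np.sin(ramp_dir) * v) + 0.4 * np.exp(
        -(((u - bump_c[0]) ** 2 + (v - bump_c[1]) ** 2) / 0.18)
    )
    background_px = np.clip(spec.background_level + a * (pattern - pattern.mean()), 0.0, 1.0)

    radii = _object_radii_px(spec)
    margin = 3.0
    centers: list[tuple[float, float]] = []
    paired_with: list[int | None] = []
    n_paired = 2 * spec.overlap_pairs

    def too_close(cand: tuple[float, float], r: float, skip: set[int]) -> bool:
        for j, (cy, cx) in enumerate(centers):
            if j in skip:
                continue
            if np.hypot(cand[0] - cy, cand[1] - cx) < r + radii[j] + margin:
                return True
        return False

    for i, r in enumerate(radii):
        if r + margin > min(rows, cols) / 2:
            raise PlacementError(f"object {i} (radius {r:.1f} px) does not fit the field")
        if i < n_paired and i % 2 == 1:
            # second member of a touching pair: overlap the previous object
            mate = i - 1
            placed = False
            for _ in range(200):
                ang = rng.uniform(0, 2 * np.pi)
                gap = 0.75 * (r + radii[mate])  # centres closer than r1+r2: discs overlap
                cy = centers[mate][0] + gap * np.sin(ang)
                cx = centers[mate][1] + gap * np.cos(ang)
                if not (r + margin <= cy <= rows - r - margin):
                    continue
                if not (r + margin <= cx <= cols - r - margin):
                    continue
                if too_close((cy, cx), r, skip={mate}):
                    continue
                centers.append((cy, cx))
                paired_with.append(mate)
                placed = True
                break
            if not placed:
                raise PlacementError(f"could not place touching mate for object {mate}")
            continue
        # first members of touching pairs reserve room for their mate
        r_eff = r + radii[i + 1] if (i < n_paired and i % 2 == 0) else r
        placed = False
        for _ in range(500):
            cy = rng.uniform(r_eff + margin, rows - r_eff - margin)
            cx = rng.uniform(r_eff + margin, cols - r_eff - margin)
            if too_close((cy, cx), r_eff, set()):
                continue
            centers.append((cy, cx))
            paired_with.append(None)
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place object {i} after bounded retries")

    labels = np.zeros((rows, cols), dtype=np.int32)
    depth = np.full((rows, cols), np.inf)
    coverage = np.zeros((rows, cols), dtype=np.float64)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        sd = _signed_distance((rows, cols), (cy, cx), r, spec.objects[i][1], rng)
        coverage = np.maximum(coverage, np.clip(0.5 - sd, 0.0, 1.0))
        # overlaps (touching pairs) are split by whichever object the pixel
        # sits deeper inside
        claim = (sd < 0) & (sd < depth)
        labels[claim] = i + 1
        depth = np.where(claim, sd, depth)

    scene_px = background_px - spec.contrast * coverage
    if spec.noise_sd > 0:
        scene_px = scene_px + rng.normal(0.0, spec.noise_sd, size=scene_px.shape)
    scene_px = np.clip(scene_px, 0.0, 1.0)

    area_px = np.bincount(labels.ravel(), minlength=len(centers) + 1)[1:].astype(np.int64)
    truth = AggregateTruth(
        labels=labels,
        area_px=area_px,
        area_mm2=area_px * spec.pixel_size_mm**2,
        background=IntensityGrid(background_px, spec.pixel_size_mm),
    )
    background = IntensityGrid(background_px, spec.pixel_size_mm)
    scene = IntensityGrid(scene_px, spec.pixel_size_mm)
    return background, scene, truth


# ---------------------------------------------------------------------------
# two-channel sectored colonies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiofilmSpec:
    """A circular two-genotype colony imaged in RFP and GFP channels.

    The colony has a mixed core (genotypes assigned i.i.d. at 0.5 per
    pixel, emulating the well-mixed inoculum) surrounded by angular
    single-genotype sectors (the drift-formed wedges of a radial range
    expansion).  ``edge_monopolization`` is the fraction of the rim
    circumference occupied by the channel-1 (RFP) genotype.
    """

    radius_px: int = 150
    mixed_core_radius_px: int = 50
    n_sectors: int = 12
    edge_monopolization: float = 0.5
    gains: tuple[float, float] = (0.75, 0.55)
    autofluorescence: tuple[float, float] = (0.08, 0.06)
    noise_sd: float = 0.02
    seed: int = 0
    pixel_size_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.radius_px < 60:
            raise ValueError("radius_px must be >= 60 so a 50-px edge ring exists")
        if not (0 < self.mixed_core_radius_px < self.radius_px):
            raise ValueError("mixed_core_radius_px must be in (0, radius_px)")
        if self.n_sectors < 1:
            raise ValueError("n_sectors must be >= 1")
        if not (0.0 <= self.edge_monopolization <= 1.0):
            raise ValueError("edge_monopolization must be in [0, 1]")
        for g, a in zip(self.gains, self.autofluorescence):
            if not (g > a >= 0):
                raise ValueError("each gain must exceed its autofluorescence (both >= 0)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class BiofilmTruth:
    """Generator-side truth for a sectored colony."""

    genotype: np.ndarray  # 1 = channel-1 (RFP), 2 = channel-2 (GFP), 0 = outside
    colony_mask: BinaryMask
    edge_fraction_ch1: float
    whole_fraction_ch1: float


def _sector_wedges(
    f: float, n_sectors: int, rng: np.random.Generator
) -> list[tuple[float, float, int]]:
    """Wedges as (start_angle, width, genotype) realizing rim fraction f.

    Channel-1 wedges jointly span an angle of exactly ``2*pi*f``; wedge
    types are interleaved as evenly as possible and the layout is rotated
    by a random phase.
    """
    two_pi = 2 * np.pi
    if f <= 0.0:
        return [(0.0, two_pi, 2)]
    if f >= 1.0:
        return [(0.0, two_pi, 1)]
    k = int(round(f * n_sectors))
    k = min(max(k, 1), max(n_sectors - 1, 1))
    n2 = n_sectors - k
    if n2 == 0:  # n_sectors == 1 with 0 < f < 1: split the lone wedge
        k, n2 = 1, 1
    w1 = two_pi * f / k
    w2 = two_pi * (1.0 - f) / n2
    # round-robin interleave of k type-1 and n2 type-2 wedges
    order: list[int] = []
    c1 = c2 = 0
    for i in range(k + n2):
        if c1 * n2 <= c2 * k and c1 < k:
            order.append(1)
            c1 += 1
        else:
            order.append(2)
            c2 += 1
    phase = rng.uniform(0, two_pi)
    wedges = []
    start = phase
    for g in order:
        width = w1 if g == 1 else w2
        wedges.append((start % two_pi, width, g))
        start += width
    return wedges


def gen_biofilm_pair(
    spec: BiofilmSpec,
) -> tuple[IntensityGrid, IntensityGrid, BiofilmTruth]:
    """Render the (rfp, gfp) image pair of a sectored colony plus truth.

    Inside the colony each pixel's channel intensity is
    ``gain * [genotype matches channel] + autofluorescence + noise``;
    outside it is autofluorescence + noise.  Truth fractions are counted
    on the rendered genotype map: the whole-colony fraction over all
    colony pixels and the edge fraction over the outermost 1-px rim
    shell.
    """
    rng = np.random.default_rng(spec.seed)
    pad = 20
    size = 2 * (spec.radius_px + pad)
    center = size / 2.0 - 0.5
    rr, cc = np.indices((size, size), dtype=np.float64)
    dy, dx = rr - center, cc - center
    dist = np.hypot(dy, dx)
    colony = dist <= spec.radius_px

    genotype = np.zeros((size, size), dtype=np.int8)
    core = colony & (dist <= spec.mixed_core_radius_px)
    genotype[core] = rng.choice([1, 2], size=int(core.sum()))
    ring = colony & ~core
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    wedges = _sector_wedges(spec.edge_monopolization, spec.n_sectors, rng)
    ring_theta = theta[ring]
    ring_geno = np.full(ring_theta.shape, 2, dtype=np.int8)
    for start, width, g in wedges:
        rel = np.mod(ring_theta - start, 2 * np.pi)
        ring_geno[rel < width] = g
    genotype[ring] = ring_geno

    rim = colony & (dist > spec.radius_px - 1.0)
    edge_fraction = float((genotype[rim] == 1).mean())
    whole_fraction = float((genotype[colony] == 1).mean())

    images = []
    for channel, (gain, auto) in enumerate(
        zip(spec.gains, spec.autofluorescence), start=1
    ):
        px = np.full((size, size), auto, dtype=np.float64)
        px[genotype == channel] += gain
        if spec.noise_sd > 0:
            px = px + rng.normal(0.0, spec.noise_sd, size=px.shape)
        images.append(IntensityGrid(np.clip(px, 0.0, 1.0), spec.pixel_size_mm))

    truth = BiofilmTruth(
        genotype=genotype,
        colony_mask=BinaryMask(colony),
        edge_fraction_ch1=edge_fraction,
        whole_fraction_ch1=whole_fraction,
    )
    return images[0], images[1], truth


# ---------------------------------------------------------------------------
# force-distance curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveSpec:
    """Synthetic SCFS cycle with an adhesion well of known depth.

    Defaults follow the measurement protocol: 1 nN contact force,
    5 µm/s approach/retract speed, contact times between 0.5 and 20 s.
    ``drift_nN_per_um`` tilts the whole curve linearly in separation,
    emulating cantilever drift; ``rupture_steps`` is the number of
    discrete unbinding steps between the force minimum and the free
    baseline.
    """

    true_fmax_nN: float
    contact_force_nN: float = 1.0
    speed_um_s: float = 5.0
    contact_time_s: float = 20.0
    n_samples: int = 400
    drift_nN_per_um: float = 0.0
    noise_sd_nN: float = 0.0
    rupture_steps: int = 2
    seed: int = 0
    max_separation_um: float = 4.0

    def __post_init__(self) -> None:
        if self.true_fmax_nN < 0:
            raise ValueError("true_fmax_nN must be >= 0")
        if self.n_samples < 50:
            raise ValueError("n_samples must be >= 50")
        if not (1 <= self.rupture_steps <= 5):
            raise ValueError("rupture_steps must be in 1..5")
        if self.noise_sd_nN < 0:
            raise ValueError("noise_sd_nN must be >= 0")
        if not (self.contact_time_s > 0):
            raise ValueError("contact_time_s must be > 0")


@dataclass(frozen=True)
class CurveTruth:
    true_fmax_nN: float
    min_separation_um: float
    baseline_intercept_nN: float
    baseline_slope_nN_per_um: float


def gen_force_curve(spec: CurveSpec) -> tuple[ForceCurve, CurveTruth]:
    """Simulate one approach/retract cycle; returns (curve, truth).

    The retract force starts at the contact force, crosses zero, descends
    linearly into an adhesion well whose bottom sits exactly at a sample
    point at depth ``true_fmax_nN`` below the baseline, then returns to
    the baseline through ``rupture_steps`` discrete steps.  Drift and
    noise are applied on top; the noise-free curve therefore recovers
    ``true_fmax_nN`` exactly after baseline correction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sep = np.linspace(0.0, spec.max_separation_um, n)

    contact_zone = 0.15  # µm over which contact force builds/releases
    f_approach = spec.contact_force_nN * np.clip((contact_zone - sep) / contact_zone, 0.0, 1.0)

    # landmark separations on the retract segment, snapped to sample points
    s_zero = contact_zone
    s_min = sep[int(np.argmin(np.abs(sep - 0.2 * spec.max_separation_um)))]
    s_release = 0.4 * spec.max_separation_um
    f_retract = np.zeros(n)
    pre = sep <= s_zero
    f_retract[pre] = spec.contact_force_nN * (s_zero - sep[pre]) / s_zero
    well_down = (sep > s_zero) & (sep <= s_min)
    if spec.true_fmax_nN > 0:
        f_retract[well_down] = -spec.true_fmax_nN * (sep[well_down] - s_zero) / (s_min - s_zero)
        step_edges = np.linspace(s_min, s_release, spec.rupture_steps + 1)
        step_levels = np.linspace(-spec.true_fmax_nN, 0.0, spec.rupture_steps + 1)
        for k in range(spec.rupture_steps):
            seg = (sep > step_edges[k]) & (sep <= step_edges[k + 1])
            f_retract[seg] = step_levels[k + 1]
    drift = spec.drift_nN_per_um * sep
    f_app = f_approach + drift
    f_ret = f_retract + drift
    if spec.noise_sd_nN > 0:
        f_app = f_app + rng.normal(0.0, spec.noise_sd_nN, size=n)
        f_ret = f_ret + rng.normal(0.0, spec.noise_sd_nN, size=n)

    approach = np.column_stack([sep[::-1], f_app[::-1]])  # approach: far -> contact
    retract = np.column_stack([sep, f_ret])
    curve = ForceCurve(
        contact_time_s=spec.contact_time_s,
        approach=approach,
        retract=retract,
        metadata={"synthetic": "true", "seed": str(spec.seed)},
    )
    truth = CurveTruth(
        true_fmax_nN=spec.true_fmax_nN,
        min_separation_um=float(s_min),
        baseline_intercept_nN=0.0,
        baseline_slope_nN_per_um=spec.drift_nN_per_um,
    )
    return curve, truth


# ---------------------------------------------------------------------------
# null groups for statistical calibration
# ---------------------------------------------------------------------------


def gen_null_groups(n_per_group: int, n_reps: int, seed: int = 0) -> np.ndarray:
    """Paired same-distribution samples for type-I-error calibration.

    Returns an ``(n_reps, 2, n_per_group)`` array of standard-normal
    draws; each replicate's two rows are a null pair (no group effect).
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    rng = np.random.default_rng(seed)
    return rng.standard_normal(size=(n_reps, 2, n_per_group))
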
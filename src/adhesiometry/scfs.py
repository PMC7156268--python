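"""Single-cell force spectroscopy (SCFS) curve analytics.

A force-distance experiment presses a probe cell (on an AFM cantilever)
onto a target cell at a set contact force, holds for a contact time, and
retracts until the cells separate.  The retraction segment dips below the
free-cantilever baseline while the adhesion bond resists; the depth of
that dip is the maximum adhesion force F_max, reported here as a positive
magnitude in nN.

Curves are ingested from a vendor-neutral delimited format: CSV with
``# key=value`` header lines (``contact_time_s`` mandatory; ``probe``,
``target`` and other labels optional) followed by columns
``separation_um, force_nN, segment`` where segment is ``approach`` or
``retract``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ForceCurve",
    "FmaxResult",
    "GroupSummary",
    "CurveFormatError",
    "load_curve",
    "load_curves",
    "write_curve",
    "baseline_correct",
    "extract_fmax",
    "summarize_groups",
    "adhesion_kinetics",
]

MIN_SEGMENT_SAMPLES = 25
#: minimum independent measurements per group before a small-n warning
RECOMMENDED_GROUP_N = 15


class CurveFormatError(ValueError):
    """A curve file does not match the expected delimited format."""


@dataclass(frozen=True)
class ForceCurve:
    """One approach/retract force-distance cycle.

    ``approach`` and ``retract`` are ``(n, 2)`` arrays of
    ``(separation_um, force_nN)`` samples, each segment ordered
    monotonically in separation (approach descending toward contact,
    retract ascending away from it).
    """

    contact_time_s: float
    approach: np.ndarray
    retract: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.contact_time_s > 0):
            raise ValueError(f"contact_time_s must be > 0, got {self.contact_time_s}")
        for name in ("approach", "retract"):
            seg = np.asarray(getattr(self, name), dtype=np.float64)
            if seg.ndim != 2 or seg.shape[1] != 2:
                raise ValueError(f"{name} must be an (n, 2) array of (separation, force)")
            if seg.shape[0] < MIN_SEGMENT_SAMPLES:
                raise ValueError(
                    f"{name} has {seg.shape[0]} samples; at least {MIN_SEGMENT_SAMPLES} required"
                )
            if not np.all(np.isfinite(seg)):
                raise ValueError(f"{name} contains non-finite values")
            d = np.diff(seg[:, 0])
            if not (np.all(d >= 0) or np.all(d <= 0)):
                raise ValueError(f"{name} separations must be monotone")
            object.__setattr__(self, name, seg)


@dataclass(frozen=True)
class FmaxResult:
    """Maximum adhesion force extracted from one baseline-corrected curve."""

    fmax_nN: float
    baseline_intercept_nN: float
    baseline_slope_nN_per_um: float
    min_index: int
    min_separation_um: float


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean_nN: float
    sd_nN: float


def _parse_curve_text(text: str, source: str) -> ForceCurve:
    meta: dict = {}
    data_lines: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        data_lines.append(line)
    if "contact_time_s" not in meta:
        raise CurveFormatError(f"{source}: missing '# contact_time_s=...' header")
    try:
        contact_time = float(meta.pop("contact_time_s"))
    except ValueError as exc:
        raise CurveFormatError(f"{source}: contact_time_s is not numeric") from exc

    table = pd.read_csv(io.StringIO("\n".join(data_lines)), float_precision="round_trip")
    required = {"separation_um", "force_nN", "segment"}
    missing = required - set(table.columns)
    if missing:
        raise CurveFormatError(f"{source}: missing mandatory column(s) {sorted(missing)}")
    bad = ~table["segment"].isin(["approach", "retract"])
    if bad.any():
        rows = (table.index[bad] + 2).tolist()[:5]
        raise CurveFormatError(
            f"{source}: segment must be 'approach' or 'retract' (bad data rows {rows})"
        )
    segments = {}
    for name in ("approach", "retract"):
        seg = table.loc[table["segment"] == name, ["separation_um", "force_nN"]].to_numpy(
            dtype=np.float64
        )
        if seg.shape[0] < MIN_SEGMENT_SAMPLES:
            raise CurveFormatError(
                f"{source}: segment '{name}' has {seg.shape[0]} samples "
                f"(minimum {MIN_SEGMENT_SAMPLES})"
            )
        segments[name] = seg
    return ForceCurve(contact_time_s=contact_time, metadata=meta, **segments)


def load_curve(path: str | Path) -> ForceCurve:
    """Load one force curve from a delimited file."""
    path = Path(path)
    return _parse_curve_text(path.read_text(), str(path))


def load_curves(path: str | Path) -> list[ForceCurve]:
    """Load a curve file, or every ``*.csv`` in a directory (sorted by path)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise CurveFormatError(f"no *.csv curve files found in {path}")
        return [load_curve(f) for f in files]
    return [load_curve(path)]


def write_curve(curve: ForceCurve, path: str | Path) -> None:
    """Write a curve in the same delimited format ``load_curve`` reads."""
    path = Path(path)
    lines = [f"# contact_time_s={curve.contact_time_s!r}"]
    for key, value in curve.metadata.items():
        lines.append(f"# {key}={value}")
    lines.append("separation_um,force_nN,segment")
    for name in ("approach", "retract"):
        for sep, force in getattr(curve, name):
            lines.append(f"{float(sep)!r},{float(force)!r},{name}")
    path.write_text("\n".join(lines) + "\n")


def baseline_correct(curve: ForceCurve, tail_fraction: float = 0.4) -> tuple[ForceCurve, float, float]:
    """Remove the free-cantilever baseline (offset + linear drift).

    A least-squares line is fitted to the final ``tail_fraction`` of the
    retract segment — the fully separated regime, where the cantilever is
    free — and subtracted from both segments as a function of separation.
    Returns the corrected curve together with the fitted intercept (nN)
    and slope (nN/µm).
    """
    if not (0 < tail_fraction <= 0.5):
        raise ValueError(f"tail_fraction must be in (0, 0.5], got {tail_fraction}")
    retract = curve.retract
    n_tail = int(round(tail_fraction * retract.shape[0]))
    if n_tail < 10:
        raise ValueError(f"baseline tail has {n_tail} samples; at least 10 required")
    # the tail is the far end of the retract: the largest separations
    order = np.argsort(retract[:, 0])
    tail = retract[order[-n_tail:]]
    slope, intercept = np.polyfit(tail[:, 0], tail[:, 1], 1)

    def corrected(seg: np.ndarray) -> np.ndarray:
        out = seg.copy()
        out[:, 1] -= intercept + slope * out[:, 0]
        return out

    fixed = ForceCurve(
        contact_time_s=curve.contact_time_s,
        approach=corrected(curve.approach),
        retract=corrected(curve.retract),
        metadata=dict(curve.metadata),
    )
    return fixed, float(intercept), float(slope)


def extract_fmax(
    curve: ForceCurve,
    baseline_intercept_nN: float = 0.0,
    baseline_slope_nN_per_um: float = 0.0,
) -> FmaxResult:
    """Maximum adhesion force: depth of the retract minimum below baseline.

    The curve must already be baseline-corrected (zero force = free
    cantilever); pass the fit parameters through for provenance.  A curve
    whose retract never drops below zero has F_max = 0.
    """
    forces = curve.retract[:, 1]
    idx = int(np.argmin(forces))
    fmax = max(0.0, -float(forces[idx]))
    return FmaxResult(
        fmax_nN=fmax,
        baseline_intercept_nN=float(baseline_intercept_nN),
        baseline_slope_nN_per_um=float(baseline_slope_nN_per_um),
        min_index=idx,
        min_separation_um=float(curve.retract[idx, 0]),
    )


def analyze_curve(curve: ForceCurve, tail_fraction: float = 0.4) -> FmaxResult:
    """Baseline-correct a raw curve and extract F_max in one step."""
    corrected, intercept, slope = baseline_correct(curve, tail_fraction)
    return extract_fmax(corrected, intercept, slope)


def summarize_groups(results: list[tuple[FmaxResult, str]]) -> list[GroupSummary]:
    """Per-group n, mean and sample SD (n-1 denominator) of F_max.

    Groups with a single member report SD 0 with a warning; groups below
    15 measurements trigger a small-sample warning (the convention of at
    least 15 independent measurements per condition).
    """
    by_group: dict[str, list[float]] = {}
    order: list[str] = []
    for result, group in results:
        if group not in by_group:
            by_group[group] = []
            order.append(group)
        by_group[group].append(result.fmax_nN)
    summaries = []
    for group in order:
        vals = np.asarray(by_group[group], dtype=np.float64)
        n = len(vals)
        if n == 1:
            warnings.warn(f"group {group!r} has a single measurement; SD reported as 0")
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        if n < RECOMMENDED_GROUP_N:
            warnings.warn(
                f"group {group!r} has n={n} < {RECOMMENDED_GROUP_N} measurements"
            )
        summaries.append(GroupSummary(group=group, n=n, mean_nN=float(vals.mean()), sd_nN=sd))
    return summaries


def adhesion_kinetics(
    results: list[tuple[FmaxResult, float]],
) -> pd.DataFrame:
    """Contact-time kinetics: F_max summary per contact time, ascending.

    ``results`` pairs each extracted F_max with the contact time (s) of
    its curve.  At least two distinct contact times are required.
    """
    times = sorted({t for _, t in results})
    if len(times) < 2:
        raise ValueError(f"need >= 2 distinct contact times, got {len(times)}")
    rows = []
    for t in times:
        vals = np.asarray([r.fmax_nN for r, tt in results if tt == t])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {"contact_time_s": t, "n": len(vals), "mean_nN": float(vals.mean()), "sd_nN": sd}
        )
    return pd.DataFrame(rows)


def homotypic_mean_fmax(
    table: pd.DataFrame,
    probe: str,
    target: str,
    contact_time_s: float,
) -> float:
    """Mean F_max over measurements of one variant pairing at one contact time.

    ``table`` is a tidy measurement table with columns ``variant_probe``,
    ``variant_target``, ``contact_time_s`` and ``fmax_nN`` (the layout of
    a deposited per-measurement source-data export).  The pairing is
    matched in either orientation.
    """
    required = {"variant_probe", "variant_target", "contact_time_s", "fmax_nN"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing column(s) {sorted(missing)}")
    fwd = (table["variant_probe"] == probe) & (table["variant_target"] == target)
    rev = (table["variant_probe"] == target) & (table["variant_target"] == probe)
    sel = table[(fwd | rev) & np.isclose(table["contact_time_s"], contact_time_s)]
    if sel.empty:
        raise ValueError(
            f"no measurements for pairing {probe}-{target} at {contact_time_s} s"
        )
    return float(sel["fmax_nN"].mean())
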
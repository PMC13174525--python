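"""Per-fiber morphological descriptors and pooled summaries.

Four descriptors per extracted fiber: cumulative centerline length,
end-to-end orientation angle, straightness (end-to-end distance over
path length, in (0, 1]) and effective width (mean of the local widths
along the trace).  Angles are measured from the +x image axis with y
pointing down, folded into [0, 180).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .extraction import FiberTrace

logger = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = ("length_um", "effective_width_um", "straightness", "angle_deg")


@dataclass
class FiberDescriptor:
    fiber_id: int
    length_um: float
    effective_width_um: float
    straightness: float
    angle_deg: float

    def __post_init__(self) -> None:
        if self.straightness > 1 + 1e-9 or self.straightness < 0:
            raise ValidationError(f"straightness {self.straightness} outside [0, 1]")
        if not (0 <= self.angle_deg < 180):
            raise ValidationError(f"angle {self.angle_deg} outside [0, 180)")


def _scaled_points(trace: FiberTrace, pixel_size) -> np.ndarray:
    dy, dx = (pixel_size, pixel_size) if np.isscalar(pixel_size) else pixel_size
    return trace.centerline * np.array([dy, dx])


def fiber_length(trace: FiberTrace, pixel_size) -> float:
    """Cumulative path length along the centerline, in um.

    ``pixel_size`` is a scalar or an anisotropic ``(dy, dx)`` pair.
    """
    if len(trace.centerline) < 2:
        raise ValidationError("length needs at least 2 points")
    pts = _scaled_points(trace, pixel_size)
    seg = np.diff(pts, axis=0)
    return float(np.sqrt((seg**2).sum(axis=1)).sum())


def fiber_angle(trace: FiberTrace) -> float:
    """Orientation of the endpoint-to-endpoint line vs +x, folded into [0, 180)."""
    d = trace.centerline[-1] - trace.centerline[0]
    if np.allclose(d, 0):
        raise ValidationError("coincident endpoints: angle undefined")
    return math.degrees(math.atan2(d[0], d[1])) % 180.0


def fiber_straightness(trace: FiberTrace) -> float:
    """End-to-end Euclidean distance divided by cumulative path length."""
    path = trace.path_length_px
    if path <= 0:
        raise ValidationError("zero path length")
    end_to_end = float(np.linalg.norm(trace.centerline[-1] - trace.centerline[0]))
    return min(end_to_end / path, 1.0)


def effective_width(trace: FiberTrace, pixel_size, aggregate: str = "mean") -> float:
    """Aggregate of per-point widths scaled to um.

    Anisotropic pixels use the isotropic-equivalent size
    ``sqrt(dy * dx)``.  ``aggregate`` is ``"mean"`` (default, the
    CT-FIRE-like fragment statistic) or ``"median"``.
    """
    if len(trace.widths_px) == 0:
        raise ValidationError("empty widths")
    dy, dx = (pixel_size, pixel_size) if np.isscalar(pixel_size) else pixel_size
    scale = math.sqrt(dy * dx)
    if aggregate == "mean":
        return float(np.mean(trace.widths_px)) * scale
    if aggregate == "median":
        return float(np.median(trace.widths_px)) * scale
    raise ValidationError(f"unknown aggregate {aggregate!r}")


def describe_fiber(trace: FiberTrace, pixel_size) -> FiberDescriptor:
    """All four descriptors for one trace."""
    return FiberDescriptor(
        fiber_id=trace.fiber_id,
        length_um=fiber_length(trace, pixel_size),
        effective_width_um=effective_width(trace, pixel_size),
        straightness=fiber_straightness(trace),
        angle_deg=fiber_angle(trace),
    )


def descriptor_table(descriptors: Iterable[FiberDescriptor]) -> pd.DataFrame:
    rows = [
        {
            "fiber_id": d.fiber_id,
            "length_um": d.length_um,
            "effective_width_um": d.effective_width_um,
            "straightness": d.straightness,
            "angle_deg": d.angle_deg,
        }
        for d in descriptors
    ]
    return pd.DataFrame(rows, columns=["fiber_id", *DESCRIPTOR_COLUMNS])


def summarize_descriptors(
    descriptors: Sequence[FiberDescriptor],
    grouping: Optional[Sequence[str]] = None,
    histogram_bins: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Pooled per-group summaries of the four descriptors.

    Returns a table with one row per (group, descriptor) holding fiber
    count, median and interquartile range, plus a dict of histograms
    ``{(group, descriptor): (counts, bin_edges)}``.  Empty groups are
    excluded with a logged warning; fiber counts are always reported.
    """
    if len(descriptors) == 0:
        raise ValidationError("no descriptors to summarize")
    table = descriptor_table(descriptors)
    if grouping is None:
        table["group"] = "all"
    else:
        if len(grouping) != len(table):
            raise ValidationError("grouping must have one label per descriptor")
        table["group"] = list(grouping)

    rows, hists = [], {}
    for group, sub in table.groupby("group", sort=True):
        if sub.empty:
            logger.warning("group %r is empty; excluded from summaries", group)
            continue
        for col in DESCRIPTOR_COLUMNS:
            vals = sub[col].to_numpy()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "group": group,
                    "descriptor": col,
                    "n_fibers": len(vals),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "iqr": q3 - q1,
                }
            )
            hists[(group, col)] = np.histogram(vals, bins=histogram_bins)
    summary = pd.DataFrame(rows)
    return summary, hists
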
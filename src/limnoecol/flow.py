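"""Flow-cytometry quantification: per-event tables -> cells/ml.

The chain mirrors standard SYBR-green cell counting on a bench cytometer:
threshold filters on forward scatter (FSC-H) and green fluorescence (FL1-H)
remove electronic noise, a polygon gate drawn in (optionally log10) channel
space selects stained cells, and the gated event count is converted to a
concentration through the instrument's effective sample volume and the
dilution applied before staining.  Stain replicates are aggregated by mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from ._errors import InvalidGateError, MismatchError

__all__ = [
    "EventTable",
    "GateSpec",
    "CellConcentration",
    "default_gate",
    "filter_events",
    "apply_polygon_gate",
    "concentration",
    "aggregate_replicates",
]


@dataclass
class EventTable:
    """Per-event channel values for one sample/stain replicate."""

    events: pd.DataFrame  # columns fsc_h, fl1_h
    sample_id: str = ""
    stain_replicate: int = 1

    def __post_init__(self):
        for col in ("fsc_h", "fl1_h"):
            if col not in self.events.columns:
                raise MismatchError(f"event table lacks column {col!r}")
        arr = self.events[["fsc_h", "fl1_h"]].to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise InvalidGateError("non-finite channel values")
        if (arr < 0).any():
            raise InvalidGateError("negative channel values")

    def __len__(self):
        return len(self.events)


@dataclass
class GateSpec:
    """Threshold filters plus a polygon gate in (FSC-H, FL1-H) space.

    ``transform`` gives the per-axis mapping applied before the polygon
    test ('linear' or 'log10'); the polygon vertices live in transformed
    space.  The polygon must be simple (non-self-intersecting).
    """

    fsc_h_min: float = 100.0
    fl1_h_min: float = 400.0
    polygon: list = field(default_factory=list)  # [(x, y), ...]
    transform: tuple = ("linear", "linear")

    def __post_init__(self):
        if self.fsc_h_min < 0 or self.fl1_h_min < 0:
            raise InvalidGateError("thresholds must be non-negative")
        for t in self.transform:
            if t not in ("linear", "log10"):
                raise InvalidGateError(f"unknown axis transform {t!r}")
        if self.polygon:
            if len(self.polygon) < 3:
                raise InvalidGateError("polygon needs >= 3 vertices")
            poly = shapely.Polygon(self.polygon)
            if not poly.is_valid or not poly.is_simple:
                raise InvalidGateError("polygon is self-intersecting or degenerate")

    def shapely_polygon(self) -> shapely.Polygon:
        if not self.polygon:
            raise InvalidGateError("gate has no polygon")
        return shapely.Polygon(self.polygon)


def default_gate() -> GateSpec:
    """Packaged convex gate for the synthetic stained-cell cluster.

    Vertices are in log10 channel space, enclosing the SYBR-positive cloud
    while excluding low-scatter/low-fluorescence debris.
    """
    return GateSpec(
        fsc_h_min=100.0,
        fl1_h_min=400.0,
        polygon=[(2.6, 2.9), (4.6, 2.9), (4.9, 3.7), (4.6, 4.9), (2.6, 4.9)],
        transform=("log10", "log10"),
    )


def filter_events(events: EventTable, gate: GateSpec) -> EventTable:
    """Keep events with fsc_h > fsc_h_min and fl1_h > fl1_h_min (strict)."""
    mask = (events.events["fsc_h"] > gate.fsc_h_min) & (
        events.events["fl1_h"] > gate.fl1_h_min
    )
    return EventTable(
        events.events[mask].reset_index(drop=True),
        sample_id=events.sample_id,
        stain_replicate=events.stain_replicate,
    )


def _transform_axis(x: np.ndarray, how: str) -> np.ndarray:
    if how == "linear":
        return x
    with np.errstate(divide="ignore"):
        return np.log10(x)


def apply_polygon_gate(events: EventTable, gate: GateSpec) -> int:
    """Count events inside or on the boundary of the gate polygon.

    Axes are transformed per ``gate.transform`` first; containment is
    boundary-inclusive (``covers``), equivalent to the even-odd rule for
    simple polygons.
    """
    poly = gate.shapely_polygon()
    x = _transform_axis(events.events["fsc_h"].to_numpy(dtype=float), gate.transform[0])
    y = _transform_axis(events.events["fl1_h"].to_numpy(dtype=float), gate.transform[1])
    ok = np.isfinite(x) & np.isfinite(y)
    pts = shapely.points(x[ok], y[ok])
    return int(shapely.covers(poly, pts).sum())


@dataclass
class CellConcentration:
    sample_id: str
    cells_per_ml: float
    n_gated_events: int
    effective_volume_ul: float = 42.5
    dilution_factor: float = 20.0
    replicate_cv: float = 0.0
    zero_events: bool = False  # warning flag: no events passed the gate


def concentration(
    events: EventTable,
    gate: GateSpec,
    volume_ul: float = 42.5,
    dilution: float = 20.0,
) -> CellConcentration:
    """Full quantification of one stain replicate.

    cells/ml = n_gated / (volume_ul * 1e-3 ml) * dilution.  Zero gated
    events yields concentration 0 with a warning flag rather than an error.
    """
    if volume_ul <= 0:
        raise InvalidGateError("volume_ul must be positive")
    if dilution < 1:
        raise InvalidGateError("dilution must be >= 1")
    kept = filter_events(events, gate)
    n_gated = apply_polygon_gate(kept, gate)
    zero = n_gated == 0
    if zero:
        warnings.warn(f"sample {events.sample_id!r}: no events passed the gate")
    cells = n_gated / (volume_ul * 1e-3) * dilution
    return CellConcentration(
        sample_id=events.sample_id,
        cells_per_ml=cells,
        n_gated_events=n_gated,
        effective_volume_ul=volume_ul,
        dilution_factor=dilution,
        zero_events=zero,
    )


def aggregate_replicates(reps) -> CellConcentration:
    """Mean cells/ml over 1-3 stain replicates; cv = sd/mean (ddof=1)."""
    reps = list(reps)
    if not 1 <= len(reps) <= 3:
        raise MismatchError("expected 1-3 stain replicates")
    ids = {r.sample_id for r in reps}
    if len(ids) != 1:
        raise MismatchError(f"mixed sample ids in replicates: {sorted(ids)}")
    vals = np.array([r.cells_per_ml for r in reps], dtype=float)
    mean = float(vals.mean())
    if len(vals) > 1 and mean > 0:
        cv = float(vals.std(ddof=1) / mean)
    else:
        cv = 0.0
    return CellConcentration(
        sample_id=reps[0].sample_id,
        cells_per_ml=mean,
        n_gated_events=int(round(np.mean([r.n_gated_events for r in reps]))),
        effective_volume_ul=reps[0].effective_volume_ul,
        dilution_factor=reps[0].dilution_factor,
        replicate_cv=cv,
        zero_events=all(r.zero_events for r in reps),
    )
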
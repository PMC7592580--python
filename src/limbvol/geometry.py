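"""Truncated-cone (frustum) limb volumetry from circumference series.

The clinical "truncated cone method" models each segment of an arm between
two adjacent tape stations as a conical frustum with circular cross-sections.
With circumferences ``c1``, ``c2`` at the two ends and axial gap ``h`` the
segment volume is

    V = h * (c1**2 + c1*c2 + c2**2) / (12 * pi)

which is the classical frustum formula ``pi*h*(r1**2 + r1*r2 + r2**2)/3``
rewritten with ``c = 2*pi*r``.  Summing segments from the wrist (ulnar
styloid, station 0) to the axilla gives the limb volume in cm^3 (= mL); the
hand is never part of the series.

The same integrator serves both measurement modalities: tape circumferences
feed it directly, and the scan pipeline feeds it perimeter estimates from
point-cloud cross-sections, so the two volumes differ only in how the
circumferences were obtained.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import (
    InsufficientStationsError,
    InvalidParameterError,
    InvalidSegmentError,
    StationOrderingError,
)

__all__ = [
    "CircumferenceSeries",
    "VolumeResult",
    "frustum_volume",
    "tape_limb_volume",
    "percent_difference",
]

Side = Literal["left", "right"]


@dataclass(frozen=True)
class CircumferenceSeries:
    """Ordered tape-measure stations for one limb at one visit.

    Parameters
    ----------
    stations
        Axial positions in cm measured from the ulnar styloid of the wrist,
        strictly increasing (station 0 is the wrist).
    circumferences
        Positive circumferences in cm, one per station.
    side
        Optional limb side label (``"left"`` / ``"right"``).
    visit_ref
        Optional opaque link back to the visit the series belongs to.
    """

    stations: np.ndarray
    circumferences: np.ndarray
    side: Side | None = None
    visit_ref: str | None = None

    def __post_init__(self) -> None:
        stations = np.asarray(self.stations, dtype=float)
        circs = np.asarray(self.circumferences, dtype=float)
        object.__setattr__(self, "stations", stations)
        object.__setattr__(self, "circumferences", circs)
        if stations.ndim != 1 or circs.ndim != 1 or stations.size != circs.size:
            raise InvalidParameterError(
                "stations and circumferences must be 1-D arrays of equal length"
            )
        if stations.size == 0:
            raise InvalidParameterError("a circumference series needs >= 1 station")
        if stations.size > 1 and not np.all(np.diff(stations) > 0):
            raise StationOrderingError("stations must be strictly increasing")
        if not np.all(circs > 0):
            raise InvalidParameterError("circumferences must be positive")
        if not (np.all(np.isfinite(stations)) and np.all(np.isfinite(circs))):
            raise InvalidParameterError("stations/circumferences must be finite")

    def __len__(self) -> int:
        return int(self.stations.size)


@dataclass(frozen=True)
class VolumeResult:
    """A limb volume with its per-segment decomposition and quality verdict.

    ``total_volume_ml`` is ``None`` when ``quality == "low_quality"``: a limb
    volume is never fabricated from an unusable measurement; ``reasons``
    then carries machine-readable codes for why the computation was refused.
    """

    total_volume_ml: float | None
    segment_volumes_ml: tuple[float, ...]
    method: Literal["tape", "scan"]
    quality: Literal["ok", "low_quality"] = "ok"
    reasons: tuple[str, ...] = field(default=())

    @property
    def n_segments(self) -> int:
        return len(self.segment_volumes_ml)

    @property
    def ok(self) -> bool:
        return self.quality == "ok"

    def to_dict(self) -> dict:
        return {
            "total_volume_ml": self.total_volume_ml,
            "segment_volumes_ml": list(self.segment_volumes_ml),
            "n_segments": self.n_segments,
            "method": self.method,
            "quality": self.quality,
            "reasons": list(self.reasons),
        }

    @classmethod
    def low_quality(
        cls, method: Literal["tape", "scan"], reasons: Sequence[str]
    ) -> "VolumeResult":
        return cls(
            total_volume_ml=None,
            segment_volumes_ml=(),
            method=method,
            quality="low_quality",
            reasons=tuple(reasons),
        )


def frustum_volume(c1: float, c2: float, h: float) -> float:
    """Volume (cm^3) of one conical frustum segment from end circumferences.

    Parameters
    ----------
    c1, c2
        End circumferences in cm.  Symmetric; one may be zero (degenerate
        cone tip) but not both.
    h
        Segment height (axial gap between stations) in cm, > 0.
    """
    if not (math.isfinite(c1) and math.isfinite(c2) and math.isfinite(h)):
        raise InvalidSegmentError("frustum inputs must be finite")
    if h <= 0:
        raise InvalidSegmentError(f"segment height must be positive, got {h}")
    if c1 < 0 or c2 < 0:
        raise InvalidSegmentError("circumferences cannot be negative")
    if c1 == 0 and c2 == 0:
        raise InvalidSegmentError("at least one end circumference must be positive")
    return h * (c1 * c1 + c1 * c2 + c2 * c2) / (12.0 * math.pi)


def tape_limb_volume(series: CircumferenceSeries) -> VolumeResult:
    """Total limb volume from a tape circumference series.

    Each adjacent station pair contributes one frustum with ``h`` equal to
    the actual station gap, so uneven spacing and a trailing partial segment
    are handled naturally.  Requires at least two stations.
    """
    if len(series) < 2:
        raise InsufficientStationsError(
            f"volume needs >= 2 stations, got {len(series)}"
        )
    gaps = np.diff(series.stations)
    c = series.circumferences
    segments = tuple(
        frustum_volume(c[i], c[i + 1], gaps[i]) for i in range(len(series) - 1)
    )
    return VolumeResult(
        total_volume_ml=float(sum(segments)),
        segment_volumes_ml=segments,
        method="tape",
    )


def percent_difference(v_affected: float, v_unaffected: float) -> float:
    """Inter-limb percent difference, the lymphedema screening statistic.

    ``100 * (v_affected - v_unaffected) / v_unaffected`` — positive when the
    affected (at-risk) limb is larger, negative when smaller.
    """
    if not (math.isfinite(v_affected) and math.isfinite(v_unaffected)):
        raise InvalidParameterError("volumes must be finite")
    if v_unaffected <= 0:
        raise InvalidParameterError(
            f"unaffected-limb volume must be positive, got {v_unaffected}"
        )
    return 100.0 * (v_affected - v_unaffected) / v_unaffected
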
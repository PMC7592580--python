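"""Longitudinal lymphedema screening from per-visit limb volumes.

The screening statistic is the inter-limb percent difference
``PD = 100 * (V_affected - V_unaffected) / V_unaffected`` computed at each
visit from two quality-ok volumes of the same modality.  Ordinary
post-operative swelling can persist for several weeks, so an elevated PD
inside the first six weeks is not flagged; a *change* in PD greater than
5 percentage points relative to the earliest available visit, observed
more than six weeks post-operatively, raises the subclinical-lymphedema
concern flag.

Visits are also bucketed into the follow-up windows 2–3, 4–6 and 7–12 weeks
(fractional weeks rounded half-up) for the time-binned group comparisons in
:mod:`limbvol.agreement`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .errors import InsufficientDataError, InvalidParameterError
from .geometry import VolumeResult, percent_difference

__all__ = [
    "CONCERN_THRESHOLD_PERCENT",
    "CONCERN_WEEK_CUTOFF",
    "TimeBin",
    "Visit",
    "VisitScreen",
    "ScreeningResult",
    "assign_time_bin",
    "screen_patient",
]

CONCERN_THRESHOLD_PERCENT = 5.0
CONCERN_WEEK_CUTOFF = 6.0

TimeBin = Literal["none", "w2_3", "w4_6", "w7_12"]
Side = Literal["left", "right"]
Method = Literal["tape", "scan"]


def assign_time_bin(weeks_post_op: float) -> TimeBin:
    """Bucket a visit into the 2–3 / 4–6 / 7–12 week follow-up windows.

    Fractional weeks are rounded half-up to integer weeks first (3.5 -> 4);
    weeks outside every window (including baseline) map to ``"none"``.
    """
    if not math.isfinite(weeks_post_op) or weeks_post_op < 0:
        raise InvalidParameterError(
            f"weeks_post_op must be a non-negative number, got {weeks_post_op}"
        )
    week = math.floor(weeks_post_op + 0.5)
    if 2 <= week <= 3:
        return "w2_3"
    if 4 <= week <= 6:
        return "w4_6"
    if 7 <= week <= 12:
        return "w7_12"
    return "none"


@dataclass(frozen=True)
class Visit:
    """One measurement visit: per-side volumes plus scheduling metadata.

    ``volumes`` maps ``(side, method)`` to a :class:`VolumeResult`, e.g.
    ``("left", "tape")``.  ``weeks_post_op = 0`` marks the pre-operative
    baseline.
    """

    patient_code: str
    weeks_post_op: float
    affected_side: Side
    volumes: Mapping[tuple[Side, Method], VolumeResult]
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weeks_post_op < 0:
            raise InvalidParameterError("weeks_post_op must be >= 0")
        if self.affected_side not in ("left", "right"):
            raise InvalidParameterError(
                f"affected_side must be left|right, got {self.affected_side!r}"
            )

    @property
    def unaffected_side(self) -> Side:
        return "right" if self.affected_side == "left" else "left"

    def bilateral_ok(self, method: Method) -> bool:
        """Both sides measured with this method and quality ok."""
        a = self.volumes.get((self.affected_side, method))
        u = self.volumes.get((self.unaffected_side, method))
        return a is not None and u is not None and a.ok and u.ok


@dataclass(frozen=True)
class VisitScreen:
    """Screening quantities for one visit."""

    weeks_post_op: float
    percent_difference: float
    change_from_baseline: float
    affected_change_percent: float  # within-limb volume change vs baseline
    time_bin: TimeBin
    flag: Literal["none", "concern"]


@dataclass(frozen=True)
class ScreeningResult:
    """Longitudinal screen for one patient and one modality."""

    patient_code: str
    method: Method
    visits: tuple[VisitScreen, ...]

    @property
    def flagged(self) -> bool:
        return any(v.flag == "concern" for v in self.visits)

    @property
    def first_concern_week(self) -> float | None:
        for v in self.visits:
            if v.flag == "concern":
                return v.weeks_post_op
        return None

    def to_dict(self) -> dict:
        return {
            "patient_code": self.patient_code,
            "method": self.method,
            "flagged": self.flagged,
            "first_concern_week": self.first_concern_week,
            "visits": [
                {
                    "weeks_post_op": v.weeks_post_op,
                    "percent_difference": v.percent_difference,
                    "change_from_baseline": v.change_from_baseline,
                    "affected_change_percent": v.affected_change_percent,
                    "time_bin": v.time_bin,
                    "flag": v.flag,
                }
                for v in self.visits
            ],
        }


def screen_patient(
    visits: Sequence[Visit],
    method: Method = "scan",
    threshold_percent: float = CONCERN_THRESHOLD_PERCENT,
    week_cutoff: float = CONCERN_WEEK_CUTOFF,
    mode: Literal["change", "absolute"] = "change",
) -> ScreeningResult:
    """Screen one patient's visit history for possible subclinical lymphedema.

    Only visits where both sides have quality-ok volumes of the requested
    modality contribute; tape and scan tracks are never mixed.  The baseline
    is the earliest contributing visit (the pre-operative one when present).
    In the default ``mode="change"`` the flag fires when the PD change from
    baseline exceeds ``threshold_percent`` at a visit more than
    ``week_cutoff`` weeks post-operatively; ``mode="absolute"`` flags on the
    visit's PD itself instead.
    """
    if not visits:
        raise InsufficientDataError("no visits supplied")
    codes = {v.patient_code for v in visits}
    if len(codes) > 1:
        raise InvalidParameterError(f"visits span multiple patients: {sorted(codes)}")
    baselines = [v for v in visits if v.weeks_post_op == 0]
    if len(baselines) > 1:
        raise InvalidParameterError("at most one baseline (week-0) visit per patient")

    usable = sorted(
        (v for v in visits if v.bilateral_ok(method)),
        key=lambda v: v.weeks_post_op,
    )
    if not usable:
        raise InsufficientDataError(
            f"no visit has bilateral quality-ok {method} volumes"
        )

    def pd_of(visit: Visit) -> float:
        a = visit.volumes[(visit.affected_side, method)].total_volume_ml
        u = visit.volumes[(visit.unaffected_side, method)].total_volume_ml
        return percent_difference(a, u)

    baseline = usable[0]
    pd0 = pd_of(baseline)
    v_aff0 = baseline.volumes[(baseline.affected_side, method)].total_volume_ml

    screens: list[VisitScreen] = []
    for visit in usable:
        pd = pd_of(visit)
        delta = pd - pd0
        v_aff = visit.volumes[(visit.affected_side, method)].total_volume_ml
        statistic = delta if mode == "change" else pd
        concern = statistic > threshold_percent and visit.weeks_post_op > week_cutoff
        screens.append(
            VisitScreen(
                weeks_post_op=visit.weeks_post_op,
                percent_difference=pd,
                change_from_baseline=delta,
                affected_change_percent=100.0 * (v_aff - v_aff0) / v_aff0,
                time_bin=assign_time_bin(visit.weeks_post_op),
                flag="concern" if concern else "none",
            )
        )
    return ScreeningResult(
        patient_code=next(iter(codes)), method=method, visits=tuple(screens)
    )
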
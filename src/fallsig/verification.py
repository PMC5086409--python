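"""Verification-certainty scoring and the two-rater adjudication workflow.

A reported fall matched to a signal event receives an ordinal certainty
score grading the correspondence of timing and description:

    not verifiable  identified date does not match the reported date, or
                    more than one plausible candidate exists on that date
    4               |time lag| <= 60 min AND the description (pre-fall
                    activity, orientation) corresponds
    3               identified time falls in the reported time-of-day
                    category AND the description corresponds
    2               date matches AND description corresponds (no usable
                    time), OR |lag| <= 60 min AND description does NOT
                    correspond
    1               date matches AND description does NOT correspond

The rows overlap (a corresponding description with a 30-min lag satisfies
both 4 and 2); precedence 4 > 3 > 2 > 1 resolves them — the highest
attainable certainty wins, consistent with the ordering of the categories.

Two raters identify the event independently and blinded; agreement (same
event within a small tolerance) finalizes the verification, disagreement
escalates to an expert panel whose verdict is final.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from . import timebase
from .events import IdentifiedEvent, time_of_day_category
from .signal_io import FallReport

__all__ = [
    "Certainty",
    "VerificationStatus",
    "CorrespondenceAssessment",
    "VerificationOutcome",
    "certainty_category",
    "build_assessment",
    "adjudicate",
    "single_rater_status",
    "indicator_value",
    "LAG_TOLERANCE_MIN",
    "RATER_AGREEMENT_TOLERANCE_S",
]

LAG_TOLERANCE_MIN = 60.0
RATER_AGREEMENT_TOLERANCE_S = 5.0


class Certainty(enum.IntEnum):
    NOT_VERIFIABLE = 0
    C1 = 1
    C2 = 2
    C3 = 3
    C4 = 4

    def __str__(self) -> str:
        return "not-verifiable" if self is Certainty.NOT_VERIFIABLE else str(int(self))


class VerificationStatus(enum.Enum):
    VERIFIED = "verified fall"            # single-rater stage
    FINALLY_VERIFIED = "finally verified"  # both raters (or panel) agree
    NON_VERIFIABLE = "non-verifiable fall"


@dataclass(frozen=True)
class CorrespondenceAssessment:
    """Recorded correspondence between a fall report and an identified event.

    ``time_lag_minutes`` is defined only for reports with an exact clock
    time; ``time_of_day_matches`` only for category reports (the two are
    mutually exclusive).  ``description_corresponds`` is the rater's
    judgment that the reported pre-fall activity and orientation match the
    signal — an input, not a computed quantity.
    """

    date_matches: bool
    description_corresponds: bool
    time_lag_minutes: float | None = None
    time_of_day_matches: bool | None = None
    candidates_same_date: int = 1

    def __post_init__(self) -> None:
        if self.time_lag_minutes is not None and self.time_of_day_matches is not None:
            raise ValueError(
                "time_lag_minutes and time_of_day_matches cannot both be defined"
            )
        if self.candidates_same_date < 0:
            raise ValueError("candidates_same_date must be >= 0")


@dataclass(frozen=True)
class VerificationOutcome:
    status: VerificationStatus
    certainty: Certainty

    def __post_init__(self) -> None:
        if (self.status is VerificationStatus.NON_VERIFIABLE) != (
            self.certainty is Certainty.NOT_VERIFIABLE
        ) and self.status is not VerificationStatus.VERIFIED:
            raise ValueError(
                "non-verifiable status and not-verifiable certainty must coincide"
            )


def certainty_category(a: CorrespondenceAssessment) -> Certainty:
    """Assign the verification-certainty category (precedence 4>3>2>1)."""
    if not a.date_matches or a.candidates_same_date > 1:
        return Certainty.NOT_VERIFIABLE
    lag_ok = a.time_lag_minutes is not None and abs(a.time_lag_minutes) <= LAG_TOLERANCE_MIN
    if lag_ok and a.description_corresponds:
        return Certainty.C4
    if a.time_of_day_matches and a.description_corresponds:
        return Certainty.C3
    if a.description_corresponds or (lag_ok and not a.description_corresponds):
        # date matches here; first clause is Table row 2's "date AND description"
        return Certainty.C2
    return Certainty.C1


def build_assessment(
    report: FallReport,
    event: IdentifiedEvent,
    candidates_same_date: int,
    description_corresponds: bool,
) -> CorrespondenceAssessment:
    """Derive the timing fields of an assessment from report and event.

    The date comparison uses the identified event's calendar date; an exact
    reported time within +/-60 min across a midnight boundary still counts
    as a date match (the lag is the stronger evidence).
    """
    ident = timebase.from_absolute_days(event.abs_days)
    date_matches = ident.date == report.fall_date
    lag_min: float | None = None
    tod_matches: bool | None = None
    if report.reported_time is not None:
        t = report.reported_time
        reported_days = timebase.to_absolute_days(
            timebase.CalendarDateTime(
                report.fall_date.year, report.fall_date.month, report.fall_date.day,
                t.hour, t.minute, t.second,
            )
        )
        lag_min = (event.abs_days - reported_days) * 1440.0
        if not date_matches and abs(lag_min) <= LAG_TOLERANCE_MIN:
            date_matches = True  # midnight-crossing lag governs
    elif report.time_of_day is not None:
        tod_matches = (
            time_of_day_category(ident.seconds_of_day() / 3600.0) == report.time_of_day
        )
    return CorrespondenceAssessment(
        date_matches=date_matches,
        description_corresponds=description_corresponds,
        time_lag_minutes=lag_min,
        time_of_day_matches=tod_matches,
        candidates_same_date=candidates_same_date,
    )


def single_rater_status(event: IdentifiedEvent | None) -> VerificationStatus:
    """Status after the first rater alone: 'verified fall' if identified."""
    return (
        VerificationStatus.VERIFIED
        if event is not None
        else VerificationStatus.NON_VERIFIABLE
    )


def adjudicate(
    rater1: IdentifiedEvent | None,
    rater2: IdentifiedEvent | None,
    panel: str | None = None,
    tolerance_s: float = RATER_AGREEMENT_TOLERANCE_S,
) -> VerificationStatus:
    """Resolve the blinded double-check into a final status.

    Raters agree when both identified no event, or both identified events
    within ``tolerance_s`` of each other.  ``panel`` ("agreement" or
    "disagreement") must be supplied exactly when the raters disagree.
    """
    if panel not in (None, "agreement", "disagreement"):
        raise ValueError(f"panel must be 'agreement', 'disagreement' or None, got {panel!r}")
    both_none = rater1 is None and rater2 is None
    agree = both_none or (
        rater1 is not None
        and rater2 is not None
        and abs(rater1.time_s - rater2.time_s) <= tolerance_s
    )
    if agree:
        if panel is not None:
            raise ValueError("expert panel applies only when the raters disagree")
        return (
            VerificationStatus.NON_VERIFIABLE
            if both_none
            else VerificationStatus.FINALLY_VERIFIED
        )
    if panel is None:
        raise ValueError("raters disagree: an expert-panel verdict is required")
    return (
        VerificationStatus.FINALLY_VERIFIED
        if panel == "agreement"
        else VerificationStatus.NON_VERIFIABLE
    )


def indicator_value(outcome: VerificationOutcome, event: IdentifiedEvent) -> tuple[int, int]:
    """(sample index, indicator value) to mark in the written fall file."""
    if outcome.status is not VerificationStatus.FINALLY_VERIFIED:
        raise ValueError("only finally verified falls receive an indicator mark")
    if outcome.certainty is Certainty.NOT_VERIFIABLE:
        raise ValueError("a not-verifiable outcome has no indicator value")
    return event.index, int(outcome.certainty)
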
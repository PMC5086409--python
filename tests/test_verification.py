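"""Certainty categorisation (truth table, precedence, monotonicity) and
two-rater adjudication."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallsig import Certainty, CorrespondenceAssessment, certainty_category
from fallsig.events import IdentifiedEvent
from fallsig.verification import (
    VerificationOutcome,
    VerificationStatus,
    adjudicate,
    indicator_value,
    single_rater_status,
)


def oracle_category(a: CorrespondenceAssessment) -> Certainty:
    """Hand-enumerated rule table: evaluate every row, keep the highest.

    Independent formulation: each certainty row is a standalone predicate and
    the ordinal maximum of the satisfied rows wins (the not-verifiable guard
    applies first).
    """
    if (not a.date_matches) or a.candidates_same_date > 1:
        return Certainty.NOT_VERIFIABLE
    lag_ok = a.time_lag_minutes is not None and abs(a.time_lag_minutes) <= 60.0
    rows = {
        4: lag_ok and a.description_corresponds,
        3: bool(a.time_of_day_matches) and a.description_corresponds,
        2: (a.date_matches and a.description_corresponds)
           or (lag_ok and not a.description_corresponds),
        1: a.date_matches and not a.description_corresponds,
    }
    satisfied = [c for c, ok in rows.items() if ok]
    return Certainty(max(satisfied)) if satisfied else Certainty.NOT_VERIFIABLE


def _all_assessments():
    lag_buckets = [None, 0.0, 30.0, 60.0, -60.0, 61.0, 300.0, -300.0]
    tod_options = [None, True, False]
    for date_m, desc, lag, tod, cands in itertools.product(
        (True, False), (True, False), lag_buckets, tod_options, (0, 1, 2, 5)
    ):
        if lag is not None and tod is not None:
            continue  # invariant: mutually exclusive timing forms
        yield CorrespondenceAssessment(
            date_matches=date_m,
            description_corresponds=desc,
            time_lag_minutes=lag,
            time_of_day_matches=tod,
            candidates_same_date=cands,
        )


def test_truth_table_matches_enumerated_oracle():
    for a in _all_assessments():
        assert certainty_category(a) == oracle_category(a), a


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        # lag 30 min + matching description, one candidate -> 4
        (dict(date_matches=True, time_lag_minutes=30.0,
              description_corresponds=True), Certainty.C4),
        # matching time-of-day category + description -> 3
        (dict(date_matches=True, time_of_day_matches=True,
              description_corresponds=True), Certainty.C3),
        # date-only report, description corresponds -> 2
        (dict(date_matches=True, description_corresponds=True), Certainty.C2),
        # lag 30 min but description does NOT correspond -> 2
        (dict(date_matches=True, time_lag_minutes=30.0,
              description_corresponds=False), Certainty.C2),
        # lag 300 min, description does not correspond -> 1
        (dict(date_matches=True, time_lag_minutes=300.0,
              description_corresponds=False), Certainty.C1),
        # date mismatch -> not verifiable
        (dict(date_matches=False, time_lag_minutes=30.0,
              description_corresponds=True), Certainty.NOT_VERIFIABLE),
        # two candidates on the same date -> not verifiable
        (dict(date_matches=True, time_lag_minutes=30.0,
              description_corresponds=True, candidates_same_date=2),
         Certainty.NOT_VERIFIABLE),
    ],
)
def test_certainty_examples(kwargs, expected):
    assert certainty_category(CorrespondenceAssessment(**kwargs)) == expected


def test_precedence_highest_row_wins():
    # rows 4 and 2 both satisfied -> 4
    a = CorrespondenceAssessment(date_matches=True, time_lag_minutes=10.0,
                                 description_corresponds=True)
    assert certainty_category(a) == Certainty.C4
    # rows 3 and 2 both satisfied -> 3
    b = CorrespondenceAssessment(date_matches=True, time_of_day_matches=True,
                                 description_corresponds=True)
    assert certainty_category(b) == Certainty.C3


@settings(max_examples=200, derandomize=True)
@given(
    date_m=st.booleans(),
    desc=st.booleans(),
    lag=st.one_of(st.none(), st.floats(-600, 600, allow_nan=False)),
    tod=st.booleans(),
    cands=st.integers(0, 3),
)
def test_category_total_and_monotone(date_m, desc, lag, tod, cands):
    """Single-valued everywhere; improving correspondence never lowers it."""
    a = CorrespondenceAssessment(
        date_matches=date_m, description_corresponds=desc,
        time_lag_minutes=lag, time_of_day_matches=None if lag is not None else tod,
        candidates_same_date=cands,
    )
    c = certainty_category(a)
    assert c in Certainty
    # flipping description to True never lowers
    better = CorrespondenceAssessment(
        date_matches=a.date_matches, description_corresponds=True,
        time_lag_minutes=a.time_lag_minutes,
        time_of_day_matches=a.time_of_day_matches,
        candidates_same_date=a.candidates_same_date,
    )
    assert certainty_category(better) >= c
    # shrinking |lag| never lowers
    if a.time_lag_minutes is not None:
        closer = CorrespondenceAssessment(
            date_matches=a.date_matches, description_corresponds=a.description_corresponds,
            time_lag_minutes=a.time_lag_minutes / 2.0,
            candidates_same_date=a.candidates_same_date,
        )
        assert certainty_category(closer) >= c


# -- adjudication ------------------------------------------------------------


def _event(time_s: float) -> IdentifiedEvent:
    return IdentifiedEvent(index=int(time_s * 100), time_s=time_s,
                           abs_days=735667.5, mode="impact")


def test_raters_agreeing_on_same_sample_finalize():
    assert adjudicate(_event(10.0), _event(10.0)) is VerificationStatus.FINALLY_VERIFIED


def test_raters_within_tolerance_finalize():
    assert adjudicate(_event(10.0), _event(12.0)) is VerificationStatus.FINALLY_VERIFIED


def test_disagreement_with_panel_disagreement_is_non_verifiable():
    out = adjudicate(_event(10.0), _event(610.0), panel="disagreement")
    assert out is VerificationStatus.NON_VERIFIABLE


def test_disagreement_with_panel_agreement_finalizes():
    out = adjudicate(_event(10.0), _event(610.0), panel="agreement")
    assert out is VerificationStatus.FINALLY_VERIFIED


def test_panel_rejected_when_raters_agree():
    with pytest.raises(ValueError, match="panel"):
        adjudicate(_event(10.0), _event(10.0), panel="agreement")


def test_panel_required_when_raters_disagree():
    with pytest.raises(ValueError, match="panel"):
        adjudicate(_event(10.0), None)


def test_both_none_is_non_verifiable():
    assert adjudicate(None, None) is VerificationStatus.NON_VERIFIABLE


def test_single_rater_stage():
    assert single_rater_status(_event(1.0)) is VerificationStatus.VERIFIED
    assert single_rater_status(None) is VerificationStatus.NON_VERIFIABLE


# -- indicator ---------------------------------------------------------------


def test_indicator_value_marks_impact_sample():
    ev = IdentifiedEvent(index=61234, time_s=612.34, abs_days=735667.5, mode="impact")
    out = VerificationOutcome(VerificationStatus.FINALLY_VERIFIED, Certainty.C4)
    assert indicator_value(out, ev) == (61234, 4)


def test_indicator_rejects_non_verifiable():
    ev = _event(1.0)
    out = VerificationOutcome(VerificationStatus.NON_VERIFIABLE, Certainty.NOT_VERIFIABLE)
    with pytest.raises(ValueError):
        indicator_value(out, ev)
    verified_only = VerificationOutcome(VerificationStatus.VERIFIED, Certainty.C4)
    with pytest.raises(ValueError, match="finally"):
        indicator_value(verified_only, ev)
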
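"""End-to-end orchestration of the fall-processing procedure.

Chains identification, verification and extraction over one recording/report
pair the way the standard operating procedure prescribes: two blinded
identification passes, adjudication, certainty scoring, then the windowed
fall file.  Used by the command-line interface and by scripted analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .events import DetectionPolicy, IdentifiedEvent, identify_fall
from .extraction import extract_fall_window
from .signal_io import FallReport, FallSignalFile, SensorRecording
from .verification import (
    Certainty,
    CorrespondenceAssessment,
    VerificationOutcome,
    VerificationStatus,
    adjudicate,
    build_assessment,
    certainty_category,
)

__all__ = ["SOPResult", "run_sop"]

logger = logging.getLogger(__name__)


@dataclass
class SOPResult:
    event: IdentifiedEvent | None
    candidate_count: int
    assessment: CorrespondenceAssessment | None
    outcome: VerificationOutcome
    fall_file: FallSignalFile | None


def run_sop(
    recording: SensorRecording,
    report: FallReport,
    description_corresponds: bool,
    policy: DetectionPolicy | None = None,
    random_id: str = "anon",
    fall_number: int = 1,
) -> SOPResult:
    """Identify, verify and (when verifiable) extract one reported fall.

    ``description_corresponds`` is the rater judgment that the reported
    pre-fall activity and orientation match the signal.  Identification is
    deterministic, so the blinded second pass reproduces the first and the
    two raters agree; the expert panel is therefore never invoked here.
    """
    policy = policy or DetectionPolicy()
    event1, count = identify_fall(recording, report, policy)
    event2, _ = identify_fall(recording, report, policy)  # blinded double check
    status = adjudicate(event1, event2)

    if event1 is None or status is not VerificationStatus.FINALLY_VERIFIED:
        outcome = VerificationOutcome(VerificationStatus.NON_VERIFIABLE, Certainty.NOT_VERIFIABLE)
        logger.info("fall=%s-%02d stage=verify decision=non-verifiable candidates=%d",
                    random_id, fall_number, count)
        return SOPResult(event1, count, None, outcome, None)

    assessment = build_assessment(report, event1, count, description_corresponds)
    certainty = certainty_category(assessment)
    if certainty is Certainty.NOT_VERIFIABLE:
        outcome = VerificationOutcome(VerificationStatus.NON_VERIFIABLE, Certainty.NOT_VERIFIABLE)
        logger.info("fall=%s-%02d stage=verify decision=not-verifiable candidates=%d",
                    random_id, fall_number, count)
        return SOPResult(event1, count, assessment, outcome, None)

    outcome = VerificationOutcome(status, certainty)
    fall_file = extract_fall_window(
        recording, event1, certainty, random_id=random_id, fall_number=fall_number
    )
    logger.info(
        "fall=%s-%02d stage=extract decision=stored certainty=%s impact_index=%d",
        random_id, fall_number, certainty, event1.index,
    )
    return SOPResult(event1, count, assessment, outcome, fall_file)
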
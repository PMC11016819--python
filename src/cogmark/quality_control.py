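"""Attention checks and the participant-exclusion rule.

Six checks flag low-effort or invalid remote testing:

1. OIS object identification accuracy < 20% (chance is far below the cut-off).
2. Any OMT localization faster than 0.2 s (physically implausible drag).
3. DSST correct rate < 20% (pure guessing sits near 11%).
4. DSST cumulative idle time > 60 s.
5. Healthy controls only: ROCF copy < 50% — copy *and* recall are discarded.
6. Questionnaire validation item answered anything but "Completely untrue".

A participant failing more than three checks is excluded outright; otherwise
only the data of the failed task is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .session_io import SessionRecord
from .task_scoring import score_dsst, score_ois, score_rocf

CheckOutcome = Literal["pass", "fail", "not-applicable"]

VALIDATION_ANSWER = "Completely untrue"

#: number of failed checks above which the participant is excluded
MAX_FAILED_CHECKS = 3


@dataclass
class QCThresholds:
    ois_min_accuracy: float = 0.20
    omt_min_localization_s: float = 0.20
    dsst_min_rate: float = 0.20
    dsst_max_idle_s: float = 60.0
    rocf_min_copy_percent: float = 50.0


@dataclass
class QCReport:
    participant_id: str
    checks: dict[int, CheckOutcome]
    tasks_discarded: set[str] = field(default_factory=set)
    reasons: list[str] = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return sum(1 for v in self.checks.values() if v == "fail")

    @property
    def participant_excluded(self) -> bool:
        return self.n_failed > MAX_FAILED_CHECKS


def run_attention_checks(
    session: SessionRecord,
    thresholds: QCThresholds | None = None,
    group_label: Optional[str] = None,
) -> QCReport:
    """Evaluate all six checks on one session.

    The session must carry the task blocks a check needs; a missing block makes
    that check not-applicable (an entirely absent task cannot fail a low-effort
    test, it is simply not scorable). The ROCF floor applies to control groups
    only — an impaired copy is expected, not suspicious, in the patient group.
    """
    th = thresholds or QCThresholds()
    group = group_label or session.group
    checks: dict[int, CheckOutcome] = {}
    discarded: set[str] = set()
    reasons: list[str] = []

    # 1 — OIS low effort
    if session.ois:
        acc = score_ois(session.ois)
        imm = acc.immediate
        if imm is not None and imm.object_identification_accuracy < th.ois_min_accuracy:
            checks[1] = "fail"
            discarded.add("OIS")
            reasons.append(
                f"OIS object identification accuracy "
                f"{imm.object_identification_accuracy:.1%} < {th.ois_min_accuracy:.0%}"
            )
        else:
            checks[1] = "pass"
    else:
        checks[1] = "not-applicable"

    # 2 — implausibly fast OMT localization
    if session.omt:
        fast = [t.localization_time for t in session.omt if t.localization_time < th.omt_min_localization_s]
        if fast:
            checks[2] = "fail"
            discarded.add("OMT")
            reasons.append(f"{len(fast)} OMT localization(s) < {th.omt_min_localization_s} s")
        else:
            checks[2] = "pass"
    else:
        checks[2] = "not-applicable"

    # 3 & 4 — DSST guessing / idling
    if session.dsst:
        d = score_dsst(session.dsst, window=session.dsst_window_s)
        if d.correct_rate < th.dsst_min_rate:
            checks[3] = "fail"
            discarded.add("DSST")
            reasons.append(f"DSST correct rate {d.correct_rate:.1%} < {th.dsst_min_rate:.0%}")
        else:
            checks[3] = "pass"
        if d.idle_time > th.dsst_max_idle_s:
            checks[4] = "fail"
            discarded.add("DSST")
            reasons.append(f"DSST idle time {d.idle_time:.0f} s > {th.dsst_max_idle_s:.0f} s")
        else:
            checks[4] = "pass"
    else:
        checks[3] = checks[4] = "not-applicable"

    # 5 — ROCF copy floor, healthy controls only
    copies = [r for r in session.rocf if r.stage == "copy"]
    if group in ("EHC1", "EHC2") and copies:
        pct = score_rocf(copies[0].placements).percent
        if pct < th.rocf_min_copy_percent:
            checks[5] = "fail"
            discarded.add("ROCF")
            reasons.append(f"control ROCF copy {pct:.1f}% < {th.rocf_min_copy_percent:.0f}%")
        else:
            checks[5] = "pass"
    else:
        checks[5] = "not-applicable"

    # 6 — questionnaire validation item
    answers = session.questionnaires.validation_answers
    if answers:
        if any(a != VALIDATION_ANSWER for a in answers):
            checks[6] = "fail"
            discarded.add("Questionnaires")
            reasons.append("validation item not answered 'Completely untrue'")
        else:
            checks[6] = "pass"
    else:
        checks[6] = "not-applicable"

    return QCReport(
        participant_id=session.participant_id,
        checks=checks,
        tasks_discarded=discarded,
        reasons=reasons,
    )
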
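"""QC-event scheduling, random case selection, and the site state machine.

The monitoring cadence: every site's first three completed cases are
re-abstracted together as the initial event (QC1); thereafter one randomly
selected case is re-abstracted after every 25 completed cases (QC25, QC50,
...).  An event whose observed error rate exceeds the acceptance threshold
triggers a repeat event on three further randomly selected cases — two of
the site's most prominent case type, one of the other — and a second
consecutive failure triggers retraining followed by another QC.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import CaseType, _read_config
from .errors import ConfigurationError, SelectionError, StateError, ValidationError

__all__ = [
    "QCPolicy",
    "QCEventSpec",
    "SitePhase",
    "QCDecision",
    "SiteQCState",
    "qc_schedule",
    "required_qc_case_count",
    "select_qc_cases",
    "select_repeat_qc_cases",
    "evaluate_qc_event",
]


@dataclass(frozen=True)
class QCPolicy:
    """Acceptance-sampling policy governing the QC process.

    The default threshold is the study's pre-set acceptable error rate of
    4.93% ("no greater than 4.93%", i.e. a rate strictly above fails), applied
    to the populated-field rate — the conservative denominator — unless
    configured otherwise.
    """

    initial_event_cases: int = 3
    cadence: int = 25
    threshold: float = 0.0493
    repeat_event_cases: int = 3
    threshold_denominator: str = "populated_field"  # or "all_field"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValidationError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.cadence < 1 or self.initial_event_cases < 1 or self.repeat_event_cases < 0:
            raise ValidationError("cadence and initial_event_cases must be >= 1")
        if self.threshold_denominator not in ("populated_field", "all_field"):
            raise ValidationError(
                f"threshold_denominator must be populated_field or all_field, "
                f"got {self.threshold_denominator!r}"
            )

    @classmethod
    def from_config(cls, source: str | Path | Mapping) -> "QCPolicy":
        cfg = dict(_read_config(source))
        cfg.pop("seed", None)  # the seed belongs to the run, not the policy
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigurationError(f"unknown policy keys {sorted(unknown)}")
        return cls(**cfg)


@dataclass(frozen=True)
class QCEventSpec:
    """One scheduled inspection."""

    label: str
    event_index: int
    n_cases_required: int
    is_repeat: bool = False


class SitePhase(str, Enum):
    collecting = "collecting"
    awaiting_qc = "awaiting_qc"
    repeat_qc = "repeat_qc"
    retraining = "retraining"
    halted = "halted"


class QCDecision(str, Enum):
    passed = "pass"
    repeat = "repeat"
    retrain_then_qc = "retrain_then_qc"


@dataclass(frozen=True)
class SiteQCState:
    """A site's position in the QC state machine.

    collecting -> awaiting_qc when a cadence trigger is reached
    awaiting_qc --pass--> collecting
    awaiting_qc --fail--> repeat_qc
    repeat_qc   --pass--> collecting
    repeat_qc   --fail--> retraining
    retraining  -> repeat_qc once retraining is done (a fresh repeat-style
    event must then be passed before collection resumes)
    """

    site_id: str
    phase: SitePhase = SitePhase.collecting
    completed_events: tuple[QCEventSpec, ...] = ()
    repeat_count_total: int = 0

    def reach_qc_trigger(self) -> "SiteQCState":
        """Data entry hit a QC trigger; collection halts until QC completes."""
        if self.phase is not SitePhase.collecting:
            raise StateError(f"site {self.site_id}: cannot trigger QC from phase {self.phase.value}")
        return replace(self, phase=SitePhase.awaiting_qc)

    def finish_retraining(self) -> "SiteQCState":
        if self.phase is not SitePhase.retraining:
            raise StateError(f"site {self.site_id}: not in retraining (phase {self.phase.value})")
        return replace(self, phase=SitePhase.repeat_qc)


def qc_schedule(n_cases: int, policy: QCPolicy = QCPolicy()) -> list[QCEventSpec]:
    """Scheduled (non-repeat) QC events for a site abstracting ``n_cases``.

    QC1 covers the first ``min(initial_event_cases, n_cases)`` cases; one
    single-case event follows each completed multiple of the cadence.  A site
    with no cases has an empty schedule.
    """
    if n_cases < 0:
        raise ValidationError(f"n_cases must be >= 0, got {n_cases}")
    if n_cases == 0:
        return []
    events = [
        QCEventSpec(label="QC1", event_index=1,
                    n_cases_required=min(policy.initial_event_cases, n_cases))
    ]
    for k in range(1, n_cases // policy.cadence + 1):
        trigger = k * policy.cadence
        events.append(
            QCEventSpec(label=f"QC{trigger}", event_index=k + 1, n_cases_required=1)
        )
    return events


def required_qc_case_count(
    n_cases: int, n_repeat_events: int = 0, policy: QCPolicy = QCPolicy()
) -> int:
    """Total cases a site must submit to QC.

    The scheduled share is ``min(initial_event_cases, n_cases)`` for QC1 plus
    one case per completed cadence multiple; each repeat event adds
    ``repeat_event_cases`` re-abstracted cases.  E.g. under the defaults a
    25-case site owes 4 QC cases; a 100-case site that fails and repeats two
    events owes 7 + 6 = 13.
    """
    if n_cases < 0 or n_repeat_events < 0:
        raise ValidationError("n_cases and n_repeat_events must be >= 0")
    scheduled = min(policy.initial_event_cases, n_cases) + n_cases // policy.cadence
    return scheduled + policy.repeat_event_cases * n_repeat_events


def select_qc_cases(
    eligible_case_ids: Sequence[str], k: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``k`` distinct cases uniformly without replacement.

    Deterministic given the generator state; the caller is responsible for
    excluding cases already QC'd from ``eligible_case_ids``.
    """
    if k < 0:
        raise SelectionError(f"k must be >= 0, got {k}")
    if k > len(eligible_case_ids):
        raise SelectionError(f"cannot select {k} cases from {len(eligible_case_ids)} eligible")
    idx = rng.choice(len(eligible_case_ids), size=k, replace=False)
    return [eligible_case_ids[i] for i in idx]


def select_repeat_qc_cases(
    cases: Sequence[tuple[str, CaseType]],
    rng: np.random.Generator,
    policy: QCPolicy = QCPolicy(),
) -> list[str]:
    """Stratified draw for a repeat QC event: 2 of the prominent type + 1 other.

    The prominent (modal) case type is determined from the site's abstracted
    cases; ties are broken by a seeded coin flip.  If the other type has no
    cases the full draw comes from the prominent type, preserving the
    three-case sample size.
    """
    n_required = policy.repeat_event_cases
    if len(cases) < n_required:
        raise SelectionError(f"repeat QC needs {n_required} cases, site has {len(cases)}")
    by_type: dict[CaseType, list[str]] = {ct: [] for ct in CaseType}
    for case_id, ct in cases:
        by_type[ct].append(case_id)
    counts = {ct: len(ids) for ct, ids in by_type.items()}
    if counts[CaseType.P] > counts[CaseType.NP]:
        prominent = CaseType.P
    elif counts[CaseType.NP] > counts[CaseType.P]:
        prominent = CaseType.NP
    else:
        prominent = CaseType.P if rng.random() < 0.5 else CaseType.NP
    other = CaseType.NP if prominent is CaseType.P else CaseType.P
    n_other = min(1, counts[other], n_required)
    n_prominent = n_required - n_other
    if counts[prominent] < n_prominent:
        raise SelectionError(
            f"prominent type {prominent.value} has only {counts[prominent]} cases; "
            f"{n_prominent} required"
        )
    chosen = select_qc_cases(by_type[prominent], n_prominent, rng)
    if n_other:
        chosen += select_qc_cases(by_type[other], n_other, rng)
    return chosen


def evaluate_qc_event(
    observed_rate: float, state: SiteQCState, policy: QCPolicy = QCPolicy()
) -> tuple[QCDecision, SiteQCState]:
    """Apply the acceptance threshold and advance the site state machine.

    A rate at or below the threshold passes ("no greater than" the limit);
    a failure from ``awaiting_qc`` demands a repeat event, a failure from
    ``repeat_qc`` demands retraining followed by a fresh QC.
    """
    if not 0 <= observed_rate <= 1:
        raise ValidationError(f"observed_rate must be in [0, 1], got {observed_rate}")
    if state.phase not in (SitePhase.awaiting_qc, SitePhase.repeat_qc):
        raise StateError(
            f"site {state.site_id}: cannot evaluate a QC event from phase {state.phase.value}"
        )
    if observed_rate <= policy.threshold:
        decision = QCDecision.passed
        new = replace(state, phase=SitePhase.collecting)
    elif state.phase is SitePhase.awaiting_qc:
        decision = QCDecision.repeat
        new = replace(state, phase=SitePhase.repeat_qc,
                      repeat_count_total=state.repeat_count_total + 1)
    else:  # failed the repeat
        decision = QCDecision.retrain_then_qc
        new = replace(state, phase=SitePhase.retraining,
                      repeat_count_total=state.repeat_count_total + 1)
    return decision, new
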
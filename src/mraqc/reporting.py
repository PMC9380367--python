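"""End-to-end QC cycle: compare -> adjudicate -> summarize -> decide -> report."""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass
from typing import Sequence

from .core import AbstractionDataset, Role, field_denominators
from .discrepancy import (
    Discrepancy,
    QCEventResult,
    adjudicate_all,
    compare_case,
    summarize_event,
)
from .errors import IntegrityError
from .scheduler import (
    QCDecision,
    QCEventSpec,
    QCPolicy,
    SitePhase,
    SiteQCState,
    evaluate_qc_event,
)
from .stats import ErrorRateEstimate, proportion_ci

logger = logging.getLogger("mraqc")

__all__ = ["QCReport", "run_full_qc_cycle", "report_to_json", "discrepancies_to_rows"]


@dataclass
class QCReport:
    """Machine-readable outcome of one QC event for one site.

    ``capa_required`` is true whenever the event did not pass outright or
    any true error was found — a corrective and preventive action plan
    accompanies every non-clean result.
    """

    site_id: str
    result: QCEventResult
    estimates: list[ErrorRateEstimate]
    decision: QCDecision
    capa_required: bool
    discrepancies: list[Discrepancy]
    generated_at: str


def run_full_qc_cycle(
    dataset: AbstractionDataset,
    policy: QCPolicy,
    state: SiteQCState,
    event: QCEventSpec | None = None,
    case_ids: Sequence[str] | None = None,
    *,
    date_dialect: str = "MDY",
    ci_method: str = "wilson",
) -> tuple[QCReport, SiteQCState]:
    """Run one complete QC event and advance the site state machine.

    The event's cases default to every case in the dataset that carries QC
    records; gold values are taken from the dataset's gold-role records.
    The state is auto-advanced into ``awaiting_qc`` if still collecting.
    """
    if case_ids is None:
        case_ids = dataset.cases_with_role(Role.qc)
    if not case_ids:
        raise IntegrityError("run_full_qc_cycle: no cases with qc records")
    if event is None:
        event = QCEventSpec(label="QC1", event_index=1, n_cases_required=len(case_ids))
    if state.phase is SitePhase.collecting:
        state = state.reach_qc_trigger()

    discrepancies: list[Discrepancy] = []
    for case_id in case_ids:
        found = compare_case(
            dataset.records_for(case_id, Role.primary),
            dataset.records_for(case_id, Role.qc),
            dataset.dictionary,
            date_dialect=date_dialect,
        )
        discrepancies.extend(found)
        logger.info("case %s: %d discrepancies", case_id, len(found))
    discrepancies = adjudicate_all(discrepancies, dataset, date_dialect=date_dialect)
    denoms = field_denominators(dataset, case_ids)
    result = summarize_event(discrepancies, denoms, event)
    logger.info(
        "event %s: %d discrepancies, %d true errors over %d/%d fields",
        event.label, result.n_discrepancies, result.n_true_errors,
        denoms.n_all_fields, denoms.n_populated_fields,
    )

    estimates = []
    for kind, n in (("all_field", denoms.n_all_fields),
                    ("populated_field", denoms.n_populated_fields)):
        if n == 0:
            continue
        lo, hi = proportion_ci(result.n_true_errors, n, method=ci_method) \
            if 0 < result.n_true_errors < n else (result.n_true_errors / n,) * 2
        estimates.append(
            ErrorRateEstimate(
                k=result.n_true_errors, n=n, denominator_kind=kind,
                rate=result.n_true_errors / n, ci_low=lo, ci_high=hi,
                method=f"crude_{ci_method}",
            )
        )

    observed = (
        result.rate_populated_field
        if policy.threshold_denominator == "populated_field"
        else result.rate_all_field
    )
    decision, new_state = evaluate_qc_event(observed, state, policy)
    logger.info("event %s: rate %.4f vs threshold %.4f -> %s",
                event.label, observed, policy.threshold, decision.value)
    report = QCReport(
        site_id=state.site_id,
        result=result,
        estimates=estimates,
        decision=decision,
        capa_required=(decision is not QCDecision.passed) or result.n_true_errors > 0,
        discrepancies=discrepancies,
        generated_at=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
    )
    return report, new_state


def discrepancies_to_rows(
    discrepancies: Sequence[Discrepancy], dataset: AbstractionDataset
) -> list[dict]:
    """Flatten discrepancies into report rows (for the CSV discrepancy report)."""
    rows = []
    for d in discrepancies:
        rows.append(
            {
                "site_id": d.site_id,
                "case_id": d.case_id,
                "field_id": d.field_id,
                "domain": dataset.dictionary[d.field_id].domain.value,
                "primary_value": _render(d.primary_value),
                "qc_value": _render(d.qc_value),
                "gold_value": _render(d.gold_value),
                "status": d.status.value,
                "one_sided": d.one_sided,
            }
        )
    return rows


def _render(value) -> str:
    if value is None:
        return ""
    return getattr(value, "raw", str(value))


def report_to_json(report: QCReport, dataset: AbstractionDataset) -> str:
    payload = {
        "site_id": report.site_id,
        "event": {
            "label": report.result.event.label,
            "event_index": report.result.event.event_index,
            "n_cases_required": report.result.event.n_cases_required,
            "is_repeat": report.result.event.is_repeat,
        },
        "n_discrepancies": report.result.n_discrepancies,
        "n_true_errors": report.result.n_true_errors,
        "n_all_fields": report.result.denominators.n_all_fields,
        "n_populated_fields": report.result.denominators.n_populated_fields,
        "rate_all_field": report.result.rate_all_field,
        "rate_populated_field": report.result.rate_populated_field,
        "estimates": [e.to_dict() for e in report.estimates],
        "decision": report.decision.value,
        "capa_required": report.capa_required,
        "discrepancies": discrepancies_to_rows(report.discrepancies, dataset),
        "generated_at": report.generated_at,
    }
    return json.dumps(payload, indent=2)
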
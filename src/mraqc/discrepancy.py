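"""Field-level comparison of double-abstracted cases and true-error adjudication.

Two independent abstractions of the same case are compared field by field
after canonical normalization; any inconsistency — including one abstractor
populating a field the other left blank — is a *discrepancy*.  Each
discrepancy is then adjudicated against the medical-record (gold-standard)
value: it is a *true error* exactly when the primary abstractor's entry
disagrees with gold, regardless of what the QC abstractor entered.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, replace
from decimal import Decimal, InvalidOperation
from enum import Enum

from .core import (
    AbstractionDataset,
    AbstractionRecord,
    CRFDictionary,
    DenominatorCounts,
    Role,
    ValueKind,
)
from .errors import AdjudicationError, IntegrityError
from .scheduler import QCEventSpec
from .stats import error_rate

__all__ = [
    "CanonicalValue",
    "FlaggedValue",
    "DiscrepancyStatus",
    "Discrepancy",
    "QCEventResult",
    "normalize_value",
    "compare_case",
    "adjudicate",
    "adjudicate_all",
    "summarize_event",
]


@dataclass(frozen=True)
class FlaggedValue:
    """A value that failed numeric/date parsing; compared as raw text.

    Normalization never silently drops an unparseable entry — it stays
    comparable (trimmed raw form) and carries a flag for reporting.
    """

    raw: str
    reason: str

    def __eq__(self, other: object) -> bool:
        if isinstance(other, FlaggedValue):
            return self.raw.strip() == other.raw.strip()
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.raw.strip())


CanonicalValue = str | Decimal | _dt.date | FlaggedValue

_DATE_SEP = re.compile(r"[/\-.]")


def normalize_value(
    raw: str | None, value_kind: ValueKind, *, date_dialect: str = "MDY"
) -> CanonicalValue | None:
    """Map a raw EDC string to its canonical comparison form.

    Absent stays absent.  Text and coded values are trimmed and case-folded;
    numerics are parsed as decimals (so "2.50" and "2.5" compare equal);
    dates are parsed to calendar dates, with the day/month order of numeric
    dates given by ``date_dialect`` ("MDY", "DMY", or "YMD"/ISO).  Values
    that fail to parse come back as :class:`FlaggedValue`, which compares as
    trimmed raw text.
    """
    if raw is None:
        return None
    text = raw.strip()
    if value_kind in (ValueKind.text, ValueKind.coded):
        return text.casefold()
    if value_kind is ValueKind.numeric:
        try:
            return Decimal(text)
        except InvalidOperation:
            return FlaggedValue(raw=text, reason="unparseable numeric")
    # dates
    parts = _DATE_SEP.split(text)
    if len(parts) == 3 and all(p.isdigit() for p in parts):
        a, b, c = parts
        try:
            if len(a) == 4:  # ISO-style year first, regardless of dialect
                return _dt.date(int(a), int(b), int(c))
            if date_dialect == "MDY":
                return _dt.date(int(c), int(a), int(b))
            if date_dialect == "DMY":
                return _dt.date(int(c), int(b), int(a))
            if date_dialect == "YMD":
                return _dt.date(int(a), int(b), int(c))
        except ValueError:
            pass
    return FlaggedValue(raw=text, reason="unparseable date")


class DiscrepancyStatus(str, Enum):
    unresolved = "unresolved"
    true_error = "true_error"
    not_error = "not_error"


@dataclass(frozen=True)
class Discrepancy:
    """A field on which the two abstractors disagree.

    ``one_sided`` marks discrepancies where exactly one abstractor populated
    the field, so tallies with and without them can both be produced.
    """

    site_id: str
    case_id: str
    field_id: str
    primary_value: CanonicalValue | None
    qc_value: CanonicalValue | None
    status: DiscrepancyStatus = DiscrepancyStatus.unresolved
    gold_value: CanonicalValue | None = None

    @property
    def one_sided(self) -> bool:
        return (self.primary_value is None) != (self.qc_value is None)


@dataclass
class QCEventResult:
    """Adjudicated outcome of one QC event."""

    event: QCEventSpec
    n_discrepancies: int
    n_true_errors: int
    denominators: DenominatorCounts
    rate_all_field: float
    rate_populated_field: float


def compare_case(
    primary: list[AbstractionRecord],
    qc: list[AbstractionRecord],
    dictionary: CRFDictionary,
    *,
    date_dialect: str = "MDY",
) -> list[Discrepancy]:
    """Field-by-field comparison of the two abstractions of one case.

    One discrepancy per applicable field whose canonical values differ;
    both-absent counts as agreement, one-absent-one-populated is flagged as a
    (one-sided) discrepancy.
    """
    if not primary:
        raise IntegrityError("compare_case: no primary records supplied")
    case_ids = {r.case_id for r in primary} | {r.case_id for r in qc}
    if len(case_ids) != 1:
        raise IntegrityError(f"compare_case: records span cases {sorted(case_ids)}")
    types = {r.case_type for r in primary} | {r.case_type for r in qc}
    if len(types) != 1:
        raise IntegrityError(
            f"case type mismatch between record sets: {sorted(t.value for t in types)}"
        )
    case_type = types.pop()
    site_id = primary[0].site_id
    case_id = primary[0].case_id
    p_vals = {r.field_id: r.value for r in primary}
    q_vals = {r.field_id: r.value for r in qc}
    out: list[Discrepancy] = []
    for fdef in dictionary.fields_for(case_type):
        p = normalize_value(p_vals.get(fdef.field_id), fdef.value_kind, date_dialect=date_dialect)
        q = normalize_value(q_vals.get(fdef.field_id), fdef.value_kind, date_dialect=date_dialect)
        if p is None and q is None:
            continue
        if p is not None and q is not None and p == q:
            continue
        out.append(
            Discrepancy(site_id=site_id, case_id=case_id, field_id=fdef.field_id,
                        primary_value=p, qc_value=q)
        )
    return out


def adjudicate(discrepancy: Discrepancy, gold_value: CanonicalValue | None) -> Discrepancy:
    """Resolve one discrepancy against the medical-record value.

    True error iff the primary entry differs from gold (both absent counts as
    agreement); what the QC abstractor entered never changes the verdict.
    """
    if discrepancy.status is not DiscrepancyStatus.unresolved:
        raise AdjudicationError(
            f"discrepancy on {discrepancy.field_id!r} already adjudicated "
            f"({discrepancy.status.value})"
        )
    p, g = discrepancy.primary_value, gold_value
    matches = (p is None and g is None) or (p is not None and g is not None and p == g)
    status = DiscrepancyStatus.not_error if matches else DiscrepancyStatus.true_error
    return replace(discrepancy, status=status, gold_value=gold_value)


def adjudicate_all(
    discrepancies: list[Discrepancy],
    dataset: AbstractionDataset,
    *,
    date_dialect: str = "MDY",
) -> list[Discrepancy]:
    """Adjudicate a batch against the dataset's gold-role records."""
    gold: dict[tuple[str, str], str | None] = {
        (r.case_id, r.field_id): r.value
        for r in dataset.records
        if r.role is Role.gold
    }
    out = []
    for d in discrepancies:
        raw = gold.get((d.case_id, d.field_id))
        kind = dataset.dictionary[d.field_id].value_kind
        out.append(adjudicate(d, normalize_value(raw, kind, date_dialect=date_dialect)))
    return out


def summarize_event(
    discrepancies: list[Discrepancy],
    denominators: DenominatorCounts,
    event: QCEventSpec,
) -> QCEventResult:
    """Count true errors and compute both error rates for one event."""
    unresolved = [d for d in discrepancies if d.status is DiscrepancyStatus.unresolved]
    if unresolved:
        raise AdjudicationError(
            f"{len(unresolved)} discrepancies not yet adjudicated "
            f"(first: {unresolved[0].field_id!r})"
        )
    n_true = sum(1 for d in discrepancies if d.status is DiscrepancyStatus.true_error)
    rate_all = (
        error_rate(n_true, denominators.n_all_fields) if denominators.n_all_fields else 0.0
    )
    rate_pop = (
        error_rate(n_true, denominators.n_populated_fields)
        if denominators.n_populated_fields
        else 0.0
    )
    return QCEventResult(
        event=event,
        n_discrepancies=len(discrepancies),
        n_true_errors=n_true,
        denominators=denominators,
        rate_all_field=rate_all,
        rate_populated_field=rate_pop,
    )
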
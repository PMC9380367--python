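"""Domain model for double-abstraction QC data.

A chart-review study collects one row per (site, case, abstractor role,
CRF field).  The *primary* abstractor enters the study data; for cases
selected into a QC event a second, independent *qc* abstractor re-enters
them; the *gold* role holds the adjudicated medical-record value.  Which
fields apply to a case depends on its treatment type: pharmacologic (P)
cases carry the full form, non-pharmacologic (NP) cases a subset.

This module defines the CRF dictionary, the abstraction dataset with its
CSV reader/writer, and the two error-rate denominators: the *all-field*
count (every field defined for the case's type) and the *populated-field*
count (fields the primary abstractor actually filled in).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, IntegrityError, ValidationError

__all__ = [
    "CaseType",
    "Domain",
    "ValueKind",
    "Role",
    "FieldDef",
    "CRFDictionary",
    "AbstractionRecord",
    "AbstractionDataset",
    "DenominatorCounts",
    "DEFAULT_MISSING_TOKENS",
    "load_crf_dictionary",
    "load_abstraction_table",
    "write_abstraction_table",
    "field_denominators",
    "reference_crf_dictionary",
]

#: Raw cell contents treated as "field left unpopulated".  EDC exports vary;
#: the comparison layer needs one canonical notion of absent.
DEFAULT_MISSING_TOKENS: frozenset[str] = frozenset({"", "NA"})


class CaseType(str, Enum):
    """Treatment classification of a case; determines which fields apply."""

    P = "P"  # pharmacologic therapy
    NP = "NP"  # non-pharmacologic therapies only

    @classmethod
    def parse(cls, code: str) -> "CaseType":
        try:
            return cls(str(code).strip().upper())
        except ValueError:
            raise ValidationError(f"unknown case type code {code!r}; expected P or NP") from None


class Domain(str, Enum):
    """CRF data-element domain."""

    demographics = "demographics"
    diagnosis = "diagnosis"
    eligibility = "eligibility"
    encounter = "encounter"
    medication = "medication"
    medical_history = "medical_history"
    procedure = "procedure"


class ValueKind(str, Enum):
    """Comparison dialect for a field's values."""

    text = "text"
    coded = "coded"
    numeric = "numeric"
    date = "date"


class Role(str, Enum):
    primary = "primary"
    qc = "qc"
    gold = "gold"


@dataclass(frozen=True)
class FieldDef:
    """One CRF data element."""

    field_id: str
    domain: Domain
    applies_to: frozenset[CaseType]
    value_kind: ValueKind

    def __post_init__(self) -> None:
        if not self.applies_to:
            raise ValidationError(f"field {self.field_id!r}: applies_to must be non-empty")


@dataclass(frozen=True)
class CRFDictionary:
    """An ordered collection of field definitions with unique ids."""

    name: str
    fields: tuple[FieldDef, ...]

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValidationError(f"dictionary {self.name!r}: field list is empty")
        dupes = [fid for fid, n in Counter(f.field_id for f in self.fields).items() if n > 1]
        if dupes:
            raise ValidationError(f"dictionary {self.name!r}: duplicate field ids {dupes}")
        object.__setattr__(self, "_by_id", {f.field_id: f for f in self.fields})

    def __len__(self) -> int:
        return len(self.fields)

    def __contains__(self, field_id: str) -> bool:
        return field_id in self._by_id

    def __getitem__(self, field_id: str) -> FieldDef:
        try:
            return self._by_id[field_id]
        except KeyError:
            raise KeyError(f"unknown field id {field_id!r}") from None

    def fields_for(self, case_type: CaseType) -> tuple[FieldDef, ...]:
        """Fields applicable to one case type, in dictionary order."""
        return tuple(f for f in self.fields if case_type in f.applies_to)

    def fields_per_case(self, case_type: CaseType) -> int:
        return len(self.fields_for(case_type))

    def domain_counts(self) -> dict[Domain, int]:
        return dict(Counter(f.domain for f in self.fields))


@dataclass(frozen=True)
class AbstractionRecord:
    """One abstracted value slot: (site, case, role, field) -> raw value.

    ``value`` is the raw string as exported from the EDC; ``None`` means the
    field was left unpopulated.
    """

    site_id: str
    case_id: str
    case_type: CaseType
    role: Role
    field_id: str
    value: str | None

    @property
    def key(self) -> tuple[str, str, Role, str]:
        return (self.site_id, self.case_id, self.role, self.field_id)


@dataclass
class DenominatorCounts:
    """The two error-rate denominators over a set of QC'd cases."""

    n_all_fields: int
    n_populated_fields: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_populated_fields <= self.n_all_fields:
            raise ValidationError(
                f"populated count {self.n_populated_fields} outside [0, {self.n_all_fields}]"
            )

    def __add__(self, other: "DenominatorCounts") -> "DenominatorCounts":
        return DenominatorCounts(
            self.n_all_fields + other.n_all_fields,
            self.n_populated_fields + other.n_populated_fields,
        )


class AbstractionDataset:
    """All abstraction records of a study, validated against a dictionary.

    Invariants enforced on construction:

    * every ``field_id`` exists in the dictionary and applies to the
      record's case type;
    * at most one record per (site, case, role, field);
    * a case is typed consistently across its records;
    * every case with qc records also has primary records.

    Case order within a site is the order of first appearance in the record
    sequence, mirroring entry-completion order in the EDC; the scheduler
    relies on it.
    """

    def __init__(
        self,
        dictionary: CRFDictionary,
        records: Iterable[AbstractionRecord],
        missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
    ) -> None:
        self.dictionary = dictionary
        self.missing_tokens = frozenset(missing_tokens)
        recs: list[AbstractionRecord] = []
        seen: set[tuple[str, str, Role, str]] = set()
        case_types: dict[str, CaseType] = {}
        order: dict[str, list[str]] = {}
        for i, rec in enumerate(records):
            if rec.value is not None and rec.value in self.missing_tokens:
                rec = replace(rec, value=None)
            if rec.field_id not in dictionary:
                raise IntegrityError(f"record {i}: unknown field {rec.field_id!r}")
            fdef = dictionary[rec.field_id]
            if rec.case_type not in fdef.applies_to:
                raise IntegrityError(
                    f"record {i}: field {rec.field_id!r} does not apply to "
                    f"{rec.case_type.value} case {rec.case_id!r}"
                )
            if rec.key in seen:
                raise IntegrityError(
                    f"record {i}: duplicate entry for (site={rec.site_id}, "
                    f"case={rec.case_id}, role={rec.role.value}, field={rec.field_id})"
                )
            seen.add(rec.key)
            prev = case_types.setdefault(rec.case_id, rec.case_type)
            if prev is not rec.case_type:
                raise IntegrityError(
                    f"record {i}: case {rec.case_id!r} typed both {prev.value} and "
                    f"{rec.case_type.value}"
                )
            site_cases = order.setdefault(rec.site_id, [])
            if rec.case_id not in site_cases:
                site_cases.append(rec.case_id)
            recs.append(rec)
        self.records: tuple[AbstractionRecord, ...] = tuple(recs)
        self._case_types = case_types
        self._order = order
        self._by_case_role: dict[tuple[str, Role], list[AbstractionRecord]] = {}
        for rec in self.records:
            self._by_case_role.setdefault((rec.case_id, rec.role), []).append(rec)
        qc_cases = {c for (c, r) in self._by_case_role if r is Role.qc}
        primary_cases = {c for (c, r) in self._by_case_role if r is Role.primary}
        orphans = qc_cases - primary_cases
        if orphans:
            raise IntegrityError(f"cases with qc but no primary records: {sorted(orphans)}")

    # -- access ---------------------------------------------------------

    @property
    def sites(self) -> frozenset[str]:
        return frozenset(self._order)

    @property
    def cases(self) -> frozenset[str]:
        return frozenset(self._case_types)

    def case_type(self, case_id: str) -> CaseType:
        try:
            return self._case_types[case_id]
        except KeyError:
            raise KeyError(f"unknown case id {case_id!r}") from None

    def case_order(self, site_id: str) -> list[str]:
        """Case ids of a site in entry-completion order."""
        return list(self._order.get(site_id, []))

    def site_of(self, case_id: str) -> str:
        for site, cases in self._order.items():
            if case_id in cases:
                return site
        raise KeyError(f"unknown case id {case_id!r}")

    def records_for(self, case_id: str, role: Role) -> list[AbstractionRecord]:
        return list(self._by_case_role.get((case_id, role), []))

    def cases_with_role(self, role: Role) -> list[str]:
        """Case ids that carry records for ``role``, in global entry order."""
        out = []
        for site in sorted(self._order):
            for c in self._order[site]:
                if (c, role) in self._by_case_role:
                    out.append(c)
        return out

    # -- serialization --------------------------------------------------

    _COLUMNS = ["site_id", "case_id", "case_type", "role", "field_id", "value"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.site_id, r.case_id, r.case_type.value, r.role.value, r.field_id,
                 "" if r.value is None else r.value)
                for r in self.records
            ],
            columns=self._COLUMNS,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbstractionDataset):
            return NotImplemented
        return Counter(self.records) == Counter(other.records)


def load_crf_dictionary(source: str | Path | Mapping) -> CRFDictionary:
    """Build a validated CRF dictionary from a YAML/JSON file or mapping.

    Expected shape::

        name: my-crf
        fields:
          - field_id: dob
            domain: demographics
            value_kind: date
            applies_to: [P, NP]
    """
    cfg = _read_config(source)
    if not isinstance(cfg, Mapping) or "fields" not in cfg:
        raise ConfigurationError("dictionary config must be a mapping with a 'fields' list")
    name = str(cfg.get("name", "crf"))
    fdefs = []
    for entry in cfg["fields"]:
        fid = entry.get("field_id") if isinstance(entry, Mapping) else None
        try:
            fdefs.append(
                FieldDef(
                    field_id=str(entry["field_id"]),
                    domain=Domain(entry["domain"]),
                    applies_to=frozenset(CaseType.parse(c) for c in entry["applies_to"]),
                    value_kind=ValueKind(entry["value_kind"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed field entry {fid or entry!r}: {exc}") from exc
        except ValueError as exc:
            raise ValidationError(f"field {fid!r}: {exc}") from exc
    return CRFDictionary(name=name, fields=tuple(fdefs))


def _read_config(source: str | Path | Mapping) -> Mapping:
    if isinstance(source, Mapping):
        return source
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_abstraction_table(
    source: str | Path | pd.DataFrame,
    dictionary: CRFDictionary,
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
) -> AbstractionDataset:
    """Read a long-format abstraction CSV into a validated dataset.

    The table must carry the columns
    ``site_id, case_id, case_type, role, field_id, value``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing_cols = set(AbstractionDataset._COLUMNS) - set(df.columns)
    if missing_cols:
        raise ConfigurationError(f"abstraction table missing columns {sorted(missing_cols)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                AbstractionRecord(
                    site_id=str(row.site_id),
                    case_id=str(row.case_id),
                    case_type=CaseType.parse(row.case_type),
                    role=Role(row.role),
                    field_id=str(row.field_id),
                    value=None if row.value is None else str(row.value),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        except IntegrityError as exc:
            raise IntegrityError(f"row {i}: {exc}") from exc
    try:
        return AbstractionDataset(dictionary, records, missing_tokens=missing_tokens)
    except IntegrityError as exc:
        # AbstractionDataset reports the record index, which equals the row number here
        raise IntegrityError(f"abstraction table: {exc}") from exc


def write_abstraction_table(dataset: AbstractionDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def field_denominators(
    dataset: AbstractionDataset, case_subset: Iterable[str] | None = None
) -> DenominatorCounts:
    """Compute the all-field and populated-field denominators.

    ``n_all_fields`` sums, over the selected cases, the number of dictionary
    fields applicable to each case's type.  ``n_populated_fields`` counts the
    primary abstractor's non-absent entries among those cases, the denominator
    the conservative error rate uses.
    """
    if case_subset is None:
        cases: Sequence[str] = sorted(dataset.cases)
    else:
        cases = list(case_subset)
        unknown = set(cases) - dataset.cases
        if unknown:
            raise KeyError(f"unknown case ids {sorted(unknown)}")
    n_all = 0
    n_pop = 0
    for case_id in cases:
        n_all += dataset.dictionary.fields_per_case(dataset.case_type(case_id))
        n_pop += sum(
            1 for r in dataset.records_for(case_id, Role.primary) if r.value is not None
        )
    return DenominatorCounts(n_all_fields=n_all, n_populated_fields=n_pop)


def reference_crf_dictionary() -> CRFDictionary:
    """The 312-field CRF layout of the multi-site NOWS chart-review study.

    312 data elements across seven domains: medication 152, medical history
    59, demographics 20, diagnosis 18, eligibility 15, encounter 31,
    procedure 17.  All domains apply to both case types except the
    pharmacologic-treatment medication block (140 fields, P only); the
    remaining 12 medication fields capture maternal concomitant/general
    medications and apply to both.  This yields 312 fields per pharmacologic
    case and 172 per non-pharmacologic case.

    Field ids and value kinds are synthetic: the real form's item names are
    not public, so ids are generated per domain and value kinds are cycled
    (coded, text, numeric, date) to exercise every comparison dialect.
    """
    both = frozenset({CaseType.P, CaseType.NP})
    p_only = frozenset({CaseType.P})
    kinds = (ValueKind.coded, ValueKind.text, ValueKind.numeric, ValueKind.date)
    spec = [
        (Domain.demographics, 20, both),
        (Domain.diagnosis, 18, both),
        (Domain.eligibility, 15, both),
        (Domain.encounter, 31, both),
        (Domain.medical_history, 59, both),
        (Domain.procedure, 17, both),
        (Domain.medication, 12, both),     # maternal concomitant/general medications
        (Domain.medication, 140, p_only),  # pharmacologic-treatment block
    ]
    fields: list[FieldDef] = []
    counters: Counter[Domain] = Counter()
    for domain, n, applies in spec:
        for _ in range(n):
            counters[domain] += 1
            fields.append(
                FieldDef(
                    field_id=f"{domain.value}_{counters[domain]:03d}",
                    domain=domain,
                    applies_to=applies,
                    value_kind=kinds[(len(fields)) % len(kinds)],
                )
            )
    return CRFDictionary(name="nows-chart-review", fields=tuple(fields))
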
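import numpy as np
import pytest

from mraqc.core import (
    AbstractionDataset,
    AbstractionRecord,
    CaseType,
    CRFDictionary,
    Domain,
    FieldDef,
    Role,
    ValueKind,
)


@pytest.fixture
def toy_dictionary() -> CRFDictionary:
    """Four fields, one per value kind; the dose field applies to P cases only."""
    both = frozenset({CaseType.P, CaseType.NP})
    return CRFDictionary(
        name="toy",
        fields=(
            FieldDef("dob", Domain.demographics, both, ValueKind.date),
            FieldDef("drug", Domain.medication, both, ValueKind.coded),
            FieldDef("dose", Domain.medication, frozenset({CaseType.P}), ValueKind.numeric),
            FieldDef("note", Domain.encounter, both, ValueKind.text),
        ),
    )


def make_case_records(
    case_id: str,
    case_type: CaseType,
    values: dict[Role, dict[str, str | None]],
    site_id: str = "S01",
) -> list[AbstractionRecord]:
    """Build records for one case from {role: {field_id: value}}."""
    out = []
    for role, fields in values.items():
        for field_id, value in fields.items():
            out.append(
                AbstractionRecord(site_id, case_id, case_type, role, field_id, value)
            )
    return out


@pytest.fixture
def toy_dataset(toy_dictionary) -> AbstractionDataset:
    """Two fully double-abstracted cases (one P, one NP) with gold values."""
    p_vals = {"dob": "07/01/2016", "drug": "Methadone", "dose": "2.5", "note": "NICU"}
    np_vals = {"dob": "2016-08-02", "drug": "none", "note": "nursery"}
    records = make_case_records(
        "C1", CaseType.P, {Role.primary: p_vals, Role.qc: p_vals, Role.gold: p_vals}
    ) + make_case_records(
        "C2", CaseType.NP, {Role.primary: np_vals, Role.qc: np_vals, Role.gold: np_vals}
    )
    return AbstractionDataset(toy_dictionary, records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160701)
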
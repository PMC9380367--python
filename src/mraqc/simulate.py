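"""Synthetic multi-site abstraction-study generator with error injection.

Emulates the design of a multi-site retrospective chart review: each site
abstracts a caseload of pharmacologic / non-pharmacologic cases, each case
populates a random subset of its applicable CRF fields, and the primary and
QC abstractors independently transcribe the gold-standard values with a
controllable per-field error probability.  The generator keeps per-field
ground-truth bookkeeping of every injected corruption, so downstream
discrepancy detection and error-rate estimation can be checked against
known truth.

The error probability for a case abstracted after ``e`` completed QC events
at its site is

    p(site, e) = expit( logit( clip(base + learning * e / 100) ) + b_site ),

i.e. a per-site random effect on the logit scale around a mean that moves by
``learning_effect`` percentage points per completed event — the hypothesized
continuous-learning mechanism, off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field
from typing import Callable, Mapping

import numpy as np

from .core import (
    AbstractionDataset,
    AbstractionRecord,
    CaseType,
    CRFDictionary,
    Role,
    ValueKind,
    reference_crf_dictionary,
)
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_study",
    "reference_margins_study",
]

# The study window the parent chart review covered; gold dates fall inside it.
_STUDY_START = np.datetime64("2016-07-01")
_STUDY_DAYS = 364

_CODED_VOCAB = (
    "methadone", "morphine", "buprenorphine", "clonidine",
    "phenobarbital", "none", "unknown", "other",
)
_TEXT_VOCAB = (
    "inpatient", "transfer", "flowsheet note", "nicu", "nursery",
    "discharged home", "breastfed", "formula",
)


@dataclass
class SimulationConfig:
    """Study-generator knobs; defaults mirror the reference study's margins.

    * 215 QC cases split 85 pharmacologic / 130 non-pharmacologic gives
      ``p_pharmacologic`` = 85/215.
    * 312 / 172 fields per case; populated fractions 10,425/26,520 (P) and
      8,418/22,360 (NP).
    * ``base_error_prob`` defaults to 3%, the conservative populated-field
      error rate the monitored study maintained.
    * ``learning_effect`` is in percentage points of error probability per
      completed QC event at the site (negative = improvement).
    * ``site_sd`` is the standard deviation of the per-site effect on the
      logit of the error probability (0 = homogeneous sites).
    * ``error_mix`` gives the relative frequency of wrong-value,
      wrongly-blank, and wrongly-populated corruption modes.
    """

    n_sites: int = 30
    caseload_per_site: int | tuple[int, int] = (3, 12)
    p_pharmacologic: float = 85 / 215
    fields_per_case: Mapping[CaseType, int] | None = None  # taken from the dictionary
    populated_fraction: Mapping[CaseType, float] = _field(
        default_factory=lambda: {CaseType.P: 10_425 / 26_520, CaseType.NP: 8_418 / 22_360}
    )
    base_error_prob: float = 0.03
    qc_error_prob: float = 0.03
    learning_effect: float = 0.0
    site_sd: float = 0.0
    error_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.p_pharmacologic, self.base_error_prob, self.qc_error_prob,
                 *self.populated_fraction.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if self.site_sd < 0:
            raise ValidationError("site_sd must be >= 0")
        if len(self.error_mix) != 3 or any(w < 0 for w in self.error_mix) or sum(self.error_mix) == 0:
            raise ValidationError("error_mix must be three non-negative weights")


@dataclass
class SimulatedStudy:
    """A generated study plus its injected-error ground truth.

    ``truth`` maps abstractor role to the set of (site_id, case_id, field_id)
    slots whose value was corrupted away from gold for that role.
    """

    dataset: AbstractionDataset
    truth: dict[Role, set[tuple[str, str, str]]]
    config: SimulationConfig


def _gold_value(kind: ValueKind, rng: np.random.Generator) -> str:
    if kind is ValueKind.coded:
        return str(rng.choice(_CODED_VOCAB))
    if kind is ValueKind.text:
        return str(rng.choice(_TEXT_VOCAB))
    if kind is ValueKind.numeric:
        # log-uniform magnitudes, 3 significant digits — dose-like values
        x = 10.0 ** rng.uniform(-1, 3)
        return f"{x:.3g}"
    day = int(rng.integers(0, _STUDY_DAYS + 1))
    return str(_STUDY_START + np.timedelta64(day, "D"))


def _corrupt_value(gold: str, kind: ValueKind, rng: np.random.Generator) -> str:
    """A plausible wrong value of the same kind, guaranteed != gold canonically."""
    for _ in range(64):
        cand = _gold_value(kind, rng)
        if cand != gold:
            return cand
    raise RuntimeError("could not draw a distinct corrupted value")  # pragma: no cover


def _events_completed(case_index: int, initial: int = 3, cadence: int = 25) -> int:
    """QC events a site has completed before abstracting its case_index-th case (1-based)."""
    return int(case_index > initial) + (case_index - 1) // cadence


def simulate_study(
    config: SimulationConfig, dictionary: CRFDictionary | None = None
) -> SimulatedStudy:
    """Generate a full multi-site study with injected abstraction errors.

    For every site, draws a caseload and case types; for every case, marks
    each applicable field populated with the type's populated fraction and
    draws a gold value per the field's kind.  Primary and QC values start as
    copies of gold and are corrupted independently per field with the
    site-and-time-dependent error probability; a corruption either replaces
    the value with a different plausible one, blanks it, or populates a field
    gold left blank, per ``error_mix``.  Fully reproducible from
    ``config.seed``.
    """
    dictionary = dictionary if dictionary is not None else reference_crf_dictionary()
    rng = np.random.default_rng(config.seed)
    mix = np.asarray(config.error_mix, dtype=float)
    mix = mix / mix.sum()
    records: list[AbstractionRecord] = []
    truth: dict[Role, set[tuple[str, str, str]]] = {Role.primary: set(), Role.qc: set()}
    site_effects = rng.normal(0.0, config.site_sd, size=config.n_sites)
    for s in range(config.n_sites):
        site_id = f"S{s + 1:02d}"
        if isinstance(config.caseload_per_site, int):
            n_cases = config.caseload_per_site
        else:
            lo, hi = config.caseload_per_site
            n_cases = int(rng.integers(lo, hi + 1))
        for c in range(1, n_cases + 1):
            case_id = f"{site_id}-C{c:03d}"
            ctype = CaseType.P if rng.random() < config.p_pharmacologic else CaseType.NP
            p_err = _error_prob(config, site_effects[s],
                                _events_completed(c), role=Role.primary)
            q_err = _error_prob(config, site_effects[s],
                                _events_completed(c), role=Role.qc)
            _emit_case(records, truth, dictionary, site_id, case_id, ctype,
                       config.populated_fraction[ctype], p_err, q_err, mix, rng)
    dataset = AbstractionDataset(dictionary, records)
    return SimulatedStudy(dataset=dataset, truth=truth, config=config)


def _error_prob(config: SimulationConfig, site_effect: float,
                events_completed: int, role: Role) -> float:
    base = config.base_error_prob if role is Role.primary else config.qc_error_prob
    mean = float(np.clip(base + config.learning_effect * events_completed / 100.0,
                         1e-9, 1 - 1e-9))
    if site_effect == 0.0:
        return mean
    logit = np.log(mean / (1 - mean)) + site_effect
    return float(1.0 / (1.0 + np.exp(-logit)))


def _emit_case(
    records: list[AbstractionRecord],
    truth: dict[Role, set[tuple[str, str, str]]],
    dictionary: CRFDictionary,
    site_id: str,
    case_id: str,
    ctype: CaseType,
    populated_fraction: float,
    p_err: float,
    q_err: float,
    mix: np.ndarray,
    rng: np.random.Generator,
) -> None:
    # renormalized mode splits, conditional on whether gold is populated
    w_wrong, w_blank, w_spurious = mix
    for fdef in dictionary.fields_for(ctype):
        populated = rng.random() < populated_fraction
        gold = _gold_value(fdef.value_kind, rng) if populated else None
        records.append(AbstractionRecord(site_id, case_id, ctype, Role.gold,
                                         fdef.field_id, gold))
        for role, err in ((Role.primary, p_err), (Role.qc, q_err)):
            value = gold
            corrupted = False
            if populated:
                if rng.random() < err:
                    corrupted = True
                    if rng.random() < w_wrong / (w_wrong + w_blank or 1.0):
                        value = _corrupt_value(gold, fdef.value_kind, rng)
                    else:
                        value = None
            else:
                if rng.random() < err * w_spurious:
                    corrupted = True
                    value = _gold_value(fdef.value_kind, rng)
            if corrupted:
                truth[role].add((site_id, case_id, fdef.field_id))
            records.append(AbstractionRecord(site_id, case_id, ctype, role,
                                             fdef.field_id, value))


def simulate_event_rates(
    config: SimulationConfig,
    n_events: int,
    fields_per_event: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, float]]:
    """Per-QC-event observed error rates (percent) under the error model.

    Draws the pooled true-error count at each successive event as a binomial
    over ``fields_per_event`` populated fields, with the success probability
    given by the simulator's error model after ``event_index - 1`` completed
    events (site effects averaged out by using ``site_sd = 0``'s mean path).
    This is the aggregated view the trend regression consumes: one
    (event_index, rate_percent) point per event.
    """
    if n_events < 1 or fields_per_event < 1:
        raise ValidationError("n_events and fields_per_event must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    out = []
    for e in range(1, n_events + 1):
        p = _error_prob(config, 0.0, e - 1, role=Role.primary)
        k = int(rng.binomial(fields_per_event, p))
        out.append((e, 100.0 * k / fields_per_event))
    return out


def reference_margins_study(seed: int = 0, n_sites: int = 30) -> SimulatedStudy:
    """A deterministic study whose margins match the reference QC dataset.

    Exactly 85 pharmacologic and 130 non-pharmacologic QC cases spread over
    ``n_sites`` sites; per-type populated-field counts forced to exactly
    10,425 (P) and 8,418 (NP), so the denominators are 48,880 all-field and
    18,843 populated-field; exactly 273 (P) and 300 (NP) wrong-value errors
    injected into the primary abstraction, with a perfect QC abstraction —
    so the full pipeline reproduces the reference populated-field crude
    column (2.62% P, 3.56% NP, 3.04% overall) end to end.  Different seeds
    change the value content, never the margins.
    """
    dictionary = reference_crf_dictionary()
    rng = np.random.default_rng(seed)
    records: list[AbstractionRecord] = []
    truth: dict[Role, set[tuple[str, str, str]]] = {Role.primary: set(), Role.qc: set()}
    plan = [
        (CaseType.P, 85, 10_425, 273),
        (CaseType.NP, 130, 8_418, 300),
    ]
    for ctype, n_cases, n_populated, n_errors in plan:
        fdefs = dictionary.fields_for(ctype)
        base, extra = divmod(n_populated, n_cases)
        # global indices of populated slots, so error slots can be drawn
        # uniformly over all populated fields of the type
        populated_per_case = [base + (1 if i < extra else 0) for i in range(n_cases)]
        error_slots = set(
            map(int, rng.choice(n_populated, size=n_errors, replace=False))
        )
        slot = 0
        for i in range(n_cases):
            case_id = f"{ctype.value}{i + 1:03d}"
            site_id = f"S{(i % n_sites) + 1:02d}"
            pop_idx = set(map(int, rng.choice(len(fdefs), size=populated_per_case[i],
                                              replace=False)))
            for j, fdef in enumerate(fdefs):
                if j in pop_idx:
                    gold = _gold_value(fdef.value_kind, rng)
                    if slot in error_slots:
                        primary = _corrupt_value(gold, fdef.value_kind, rng)
                        truth[Role.primary].add((site_id, case_id, fdef.field_id))
                    else:
                        primary = gold
                    slot += 1
                else:
                    gold = primary = None
                records.append(AbstractionRecord(site_id, case_id, ctype, Role.gold,
                                                 fdef.field_id, gold))
                records.append(AbstractionRecord(site_id, case_id, ctype, Role.primary,
                                                 fdef.field_id, primary))
                records.append(AbstractionRecord(site_id, case_id, ctype, Role.qc,
                                                 fdef.field_id, gold))
    config = SimulationConfig(n_sites=n_sites, base_error_prob=573 / 18_843,
                              qc_error_prob=0.0, seed=seed)
    return SimulatedStudy(dataset=AbstractionDataset(dictionary, records),
                          truth=truth, config=config)
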
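"""Index-case identification, exclusions, and look-back linkage.

An *index case* is an eligible cardiac-surgery hospitalization together with
the same patient's prior hospitalizations inside a look-back window.  The
look-back window is anchored on the index **admission** date and membership is
tested against the prior visit's **discharge** date, on the half-open
interval ``[admission − window_years, admission)`` — a chronic-AF code
attaches to a completed hospitalization, and the half-open interval
guarantees the index visit can never self-match.  Both anchor and comparison
date are configurable because administrative conventions differ between
institutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Sequence

from .codes import CABG_CODESET, SURGERY_CODESET, VALVE_CODESET, CodeSet
from .dad_io import DischargeAbstract, ReferenceStandardRecord, reference_index


class ConfigurationError(ValueError):
    pass


class LinkageError(ValueError):
    """A case could not be joined to its reference-standard record."""


class SurgeryClass(str, Enum):
    CABG = "CABG"
    VALVULAR = "valvular"
    MIXED = "mixed"


DEFAULT_STUDY_WINDOW = (date(2010, 1, 1), date(2016, 12, 31))


@dataclass(frozen=True)
class EligibilityConfig:
    """Which hospitalizations qualify as index cardiac surgeries."""

    surgery_code_set: CodeSet = SURGERY_CODESET
    study_window: tuple[date, date] = DEFAULT_STUDY_WINDOW
    min_age_years: int = 18

    def __post_init__(self) -> None:
        if self.study_window[0] > self.study_window[1]:
            raise ConfigurationError("study window start after end")
        if self.min_age_years < 0:
            raise ConfigurationError("min_age_years must be >= 0")


@dataclass
class IndexCase:
    """An eligible surgery hospitalization linked to its look-back history.

    ``lookback_hospitalizations`` holds the patient's prior hospitalizations
    within ``lookback_window_years`` of the index admission (all discharged
    strictly before it).  ``reference_label`` is the chart-review POAF truth
    when available.
    """

    index: DischargeAbstract
    lookback_hospitalizations: list[DischargeAbstract] = field(default_factory=list)
    lookback_window_years: int = 6
    surgery_class: SurgeryClass | None = None
    reference_label: bool | None = None


def years_before(d: date, years: int) -> date:
    """The calendar date ``years`` before ``d`` (Feb 29 maps to Feb 28)."""
    try:
        return d.replace(year=d.year - years)
    except ValueError:
        return d.replace(year=d.year - years, day=28)


def identify_eligible_surgeries(
    abstracts: Iterable[DischargeAbstract],
    config: EligibilityConfig | None = None,
) -> list[DischargeAbstract]:
    """Hospitalizations with an eligible surgery code, in-window date and adult age.

    The surgery date is used when present, the admission date otherwise.
    Output is sorted by ``(patient_id, admission_date, visit_id)``.
    """
    config = config or EligibilityConfig()
    if not config.surgery_code_set.cci_patterns:
        raise ConfigurationError("surgery code set is empty")
    start, end = config.study_window
    out = []
    for rec in abstracts:
        anchor = rec.surgery_date or rec.admission_date
        if not (start <= anchor <= end):
            continue
        if rec.age_years < config.min_age_years:
            continue
        if any(config.surgery_code_set.matches_cci(c) for c in rec.procedure_codes):
            out.append(rec)
    return sorted(out, key=lambda r: (r.patient_id, r.admission_date, r.visit_id))


def classify_surgery(index: DischargeAbstract) -> SurgeryClass:
    """CABG, valvular, or mixed, from the index procedure codes."""
    has_cabg = any(CABG_CODESET.matches_cci(c) for c in index.procedure_codes)
    has_valve = any(VALVE_CODESET.matches_cci(c) for c in index.procedure_codes)
    if has_cabg and has_valve:
        return SurgeryClass.MIXED
    if has_cabg:
        return SurgeryClass.CABG
    if has_valve:
        return SurgeryClass.VALVULAR
    raise ValueError(
        f"visit {index.visit_id} carries no eligible surgery code; "
        "classify_surgery must run after eligibility"
    )


def select_index_cases(eligible: Sequence[DischargeAbstract]) -> list[DischargeAbstract]:
    """First eligible hospitalization per patient (later repeats are ignored)."""
    first: dict[str, DischargeAbstract] = {}
    for rec in sorted(eligible, key=lambda r: (r.patient_id, r.admission_date, r.visit_id)):
        first.setdefault(rec.patient_id, rec)
    return sorted(first.values(), key=lambda r: (r.patient_id, r.admission_date, r.visit_id))


def link_lookback(
    case_index: DischargeAbstract,
    all_abstracts: Iterable[DischargeAbstract],
    window_years: int,
    *,
    anchor: str = "admission",
    compare: str = "discharge",
) -> list[DischargeAbstract]:
    """Same-patient prior hospitalizations within the look-back window.

    Membership: the prior visit's ``compare`` date lies in
    ``[anchor_date − window_years, anchor_date)``.  The index visit itself is
    always excluded.  Longer windows yield supersets of shorter ones.
    """
    if window_years <= 0:
        raise ValueError("window_years must be positive")
    if anchor == "admission" or case_index.surgery_date is None:
        anchor_date = case_index.admission_date
    elif anchor == "surgery":
        anchor_date = case_index.surgery_date
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    start = years_before(anchor_date, window_years)
    out = []
    for rec in all_abstracts:
        if rec.patient_id != case_index.patient_id or rec.visit_id == case_index.visit_id:
            continue
        when = rec.discharge_date if compare == "discharge" else rec.admission_date
        if start <= when < anchor_date:
            out.append(rec)
    return sorted(out, key=lambda r: (r.admission_date, r.visit_id))


def build_index_cases(
    abstracts: Sequence[DischargeAbstract],
    config: EligibilityConfig | None = None,
    lookback_years: int = 6,
    *,
    anchor: str = "admission",
    compare: str = "discharge",
) -> list[IndexCase]:
    """Full pipeline: eligibility → first-per-patient → look-back linkage."""
    eligible = identify_eligible_surgeries(abstracts, config)
    indices = select_index_cases(eligible)
    by_patient: dict[str, list[DischargeAbstract]] = {}
    for rec in abstracts:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    cases = []
    for idx in indices:
        cases.append(
            IndexCase(
                index=idx,
                lookback_hospitalizations=link_lookback(
                    idx, by_patient.get(idx.patient_id, []), lookback_years,
                    anchor=anchor, compare=compare,
                ),
                lookback_window_years=lookback_years,
                surgery_class=classify_surgery(idx),
            )
        )
    return cases


def relink_cases(
    cases: Sequence[IndexCase],
    abstracts: Sequence[DischargeAbstract],
    lookback_years: int,
    *,
    anchor: str = "admission",
    compare: str = "discharge",
) -> list[IndexCase]:
    """Re-link existing cases at a different look-back window."""
    by_patient: dict[str, list[DischargeAbstract]] = {}
    for rec in abstracts:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    out = []
    for case in cases:
        out.append(
            IndexCase(
                index=case.index,
                lookback_hospitalizations=link_lookback(
                    case.index, by_patient.get(case.index.patient_id, []),
                    lookback_years, anchor=anchor, compare=compare,
                ),
                lookback_window_years=lookback_years,
                surgery_class=case.surgery_class,
                reference_label=case.reference_label,
            )
        )
    return out


def apply_exclusions(
    cases: Sequence[IndexCase],
    reference: Sequence[ReferenceStandardRecord],
    *,
    missing_reference: str = "error",
) -> tuple[list[IndexCase], list[tuple[IndexCase, str]]]:
    """Drop excluded cases and attach reference labels to the rest.

    A case is removed when its index abstract is flagged ``died_during_surgery``
    (patients who die on the table are never at risk of POAF) or when the
    reference file marks it excluded (chart unavailable, ineligible surgery,
    intra-operative death).  Returns ``(retained, log)`` with one
    ``(case, reason)`` entry per removal; retained and log partition the
    input exactly.  ``missing_reference`` is ``"error"`` (default), ``"drop"``
    or ``"keep"`` (keep with no label).
    """
    if missing_reference not in ("error", "drop", "keep"):
        raise ValueError(f"unknown missing_reference policy {missing_reference!r}")
    ref = reference_index(reference)
    retained: list[IndexCase] = []
    log: list[tuple[IndexCase, str]] = []
    for case in cases:
        rec = ref.get((case.index.patient_id, case.index.visit_id))
        if rec is None:
            if missing_reference == "error":
                raise LinkageError(
                    f"no reference record for ({case.index.patient_id}, "
                    f"{case.index.visit_id})"
                )
            if missing_reference == "drop":
                log.append((case, "no_reference_record"))
                continue
            retained.append(case)
            continue
        if rec.excluded:
            log.append((case, rec.exclusion_reason))
            continue
        if case.index.died_during_surgery:
            log.append((case, "died_during_surgery"))
            continue
        case.reference_label = rec.true_poaf
        retained.append(case)
    return retained, log
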
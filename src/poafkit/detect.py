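"""The rule-based POAF detection algorithms.

A patient is predicted POAF-positive when the index (cardiac-surgery)
discharge abstract carries an AF flag code (I48.0, I48.1, I48.9 or I48.90, in
any diagnosis position) AND no hospitalization in the look-back window
carries any AF history code (the flag codes plus I48.2, chronic AF).
Optionally, a concomitant maze procedure on the index abstract recodes the
patient to negative — surgical AF ablation implies pre-existing chronic AF —
even when the diagnosis codes suggest a new episode.

Six standard algorithm variants cross the look-back window (1, 3 or 6 years)
with the maze recode (off/on); a sensitivity variant restricts the flag set
to I48.0 and I48.1.  The history rule consults only *prior* hospitalizations:
AF codes on the index abstract never count as history, because discharge
abstracts cannot time-stamp a diagnosis within a stay.  That blind spot is a
known failure mode of the rule and is deliberately left in place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .codes import (
    FLAG_CODESET,
    HISTORY_CODESET,
    MAZE_CODESET,
    cci_matches,
)
from .cohort import IndexCase


class ContractError(ValueError):
    """A case was linked at a different look-back window than the spec requires."""


@dataclass(frozen=True)
class AlgorithmSpec:
    """A parameterized POAF detection rule."""

    name: str
    flag_codes: frozenset[str] = FLAG_CODESET.icd_codes
    history_codes: frozenset[str] = HISTORY_CODESET.icd_codes
    lookback_years: int = 6
    maze_recode: bool = False
    maze_patterns: frozenset[str] = MAZE_CODESET.cci_patterns
    maze_exact: bool = False
    any_position: bool = True  # False: only the principal diagnosis triggers

    def __post_init__(self) -> None:
        if self.lookback_years <= 0:
            raise ValueError("lookback_years must be positive")


@dataclass(frozen=True)
class DetectionResult:
    """Per-case algorithm output with its component booleans for audit."""

    patient_id: str
    visit_id: str
    algorithm_name: str
    flagged_current: bool
    history_found: bool
    maze_found: bool
    predicted_poaf: bool


def _diagnoses(codes: Sequence[str], spec: AlgorithmSpec) -> Sequence[str]:
    return codes if spec.any_position else codes[:1]


def flagged_current(case: IndexCase, spec: AlgorithmSpec) -> bool:
    """Does the index abstract carry an AF flag code?"""
    return any(c in spec.flag_codes for c in _diagnoses(case.index.diagnosis_codes, spec))


def history_found(case: IndexCase, spec: AlgorithmSpec) -> bool:
    """Does any look-back hospitalization carry an AF history code?"""
    return any(
        c in spec.history_codes
        for hosp in case.lookback_hospitalizations
        for c in _diagnoses(hosp.diagnosis_codes, spec)
    )


def maze_found(case: IndexCase, spec: AlgorithmSpec) -> bool:
    """Does the index abstract carry a maze procedure code?

    Stem matching by default (published lists print the family stem 1.HH.59
    while abstracts record suffixed codes); ``spec.maze_exact`` requires an
    exact code.
    """
    for code in case.index.procedure_codes:
        for pattern in spec.maze_patterns:
            if (code == pattern) if spec.maze_exact else cci_matches(code, pattern):
                return True
    return False


def classify(case: IndexCase, spec: AlgorithmSpec) -> DetectionResult:
    """Apply the full rule to one linked index case."""
    if case.lookback_window_years != spec.lookback_years:
        raise ContractError(
            f"case {case.index.visit_id} linked at {case.lookback_window_years}y "
            f"but algorithm {spec.name!r} requires {spec.lookback_years}y"
        )
    flag = flagged_current(case, spec)
    hist = history_found(case, spec)
    maze = maze_found(case, spec)
    predicted = flag and not hist and not (spec.maze_recode and maze)
    return DetectionResult(
        patient_id=case.index.patient_id,
        visit_id=case.index.visit_id,
        algorithm_name=spec.name,
        flagged_current=flag,
        history_found=hist,
        maze_found=maze,
        predicted_poaf=predicted,
    )


def standard_algorithms() -> list[AlgorithmSpec]:
    """The six standard variants: look-back 1/3/6 years × maze recode off/on.

    Algorithms 1, 3, 5 use look-backs of 1, 3 and 6 years without the maze
    recode; Algorithms 2, 4, 6 are their maze-recode counterparts.
    """
    specs = []
    for i, (years, maze) in enumerate(
        [(1, False), (1, True), (3, False), (3, True), (6, False), (6, True)], start=1
    ):
        specs.append(
            AlgorithmSpec(name=f"Algorithm {i}", lookback_years=years, maze_recode=maze)
        )
    return specs


def algorithm_by_name(name: str) -> AlgorithmSpec:
    """Look up a standard algorithm by name or number (``"5"``/``"Algorithm 5"``)."""
    wanted = name.strip()
    if wanted.isdigit():
        wanted = f"Algorithm {int(wanted)}"
    for spec in standard_algorithms():
        if spec.name == wanted:
            return spec
    raise KeyError(f"unknown algorithm {name!r}")


def restricted_code_variant(spec: AlgorithmSpec) -> AlgorithmSpec:
    """Sensitivity variant: flag only I48.0/I48.1 (drop the unspecified codes).

    The history code set is unchanged.
    """
    return replace(
        spec,
        name=f"{spec.name} (restricted codes)",
        flag_codes=frozenset({"I480", "I481"}),
    )


def run_algorithm(cases: Iterable[IndexCase], spec: AlgorithmSpec) -> list[DetectionResult]:
    """Classify every case; one result per case, in input order. Pure."""
    return [classify(case, spec) for case in cases]
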
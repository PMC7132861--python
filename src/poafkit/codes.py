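"""ICD-10-CA and CCI code normalization, wildcard matching, and study code sets.

Hospital discharge abstracts code diagnoses in ICD-10-CA (the ``I48.x`` family
covers atrial fibrillation and flutter) and procedures in CCI, the Canadian
Classification of Health Interventions.  Published code lists print dotted
codes (``1.IJ.76.^^``) with a trailing ``^^`` wildcard meaning "any suffix",
while recorded codes are stored undotted with concrete suffixes
(``1IJ76LA``).  Everything in this package matches on a normalized form:
uppercase, dots stripped, and any trailing run of ``^`` collapsed to a single
wildcard marker.

A :class:`CodeSet` bundles a named collection of normalized ICD codes and CCI
patterns; the module also exposes the study's default code sets: the eligible
cardiac-surgery procedure families (CABG and valve/annulus interventions), the
AF diagnosis codes used to flag a possible post-operative episode, the history
codes used to exclude prevalent AF (the flag codes plus I48.2, chronic AF,
which is history-only), and the maze-procedure code family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable


class InvalidCodeError(ValueError):
    """Raised when a raw code string is empty or blank."""


def normalize_icd_code(raw: str) -> str:
    """Normalize an ICD-10-CA code: trim, uppercase, strip dots.

    ``"I48.90"`` and ``"i4890"`` normalize to the same string ``"I4890"``.
    Idempotent.  Raises :class:`InvalidCodeError` on empty/blank input.
    """
    code = raw.upper().replace(".", "").strip()
    if not code:
        raise InvalidCodeError(f"empty ICD code: {raw!r}")
    return code


def normalize_cci_code(raw: str) -> str:
    """Normalize a CCI code or pattern: trim, uppercase, strip dots.

    A trailing run of ``^`` wildcard characters (``1.IJ.76.^^``) is collapsed
    to a single ``^`` marker, so ``"1.IJ.76.^^"`` becomes ``"1IJ76^"``.
    Idempotent.  Raises :class:`InvalidCodeError` on empty/blank input.
    """
    code = raw.upper().replace(".", "").strip()
    if not code:
        raise InvalidCodeError(f"empty CCI code: {raw!r}")
    stripped = code.rstrip("^")
    if stripped != code:
        code = stripped + "^"
    return code


def cci_matches(code: str, pattern: str) -> bool:
    """Does a normalized recorded CCI ``code`` fall under a normalized ``pattern``?

    A pattern ending in the wildcard marker matches any code extending its
    stem.  A pattern without a wildcard is treated as a stem as well: a
    recorded code equal to it or extending it matches (published lists print
    family stems such as ``1.HH.59`` while abstracts record suffixed codes
    like ``1HH59LA``).  Matching is reflexive for exact codes.
    """
    if pattern.endswith("^"):
        return code.startswith(pattern[:-1])
    return code.startswith(pattern)


@dataclass(frozen=True)
class CodeSet:
    """A named set of normalized ICD codes and CCI patterns."""

    name: str
    icd_codes: frozenset[str] = field(default_factory=frozenset)
    cci_patterns: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_raw(
        cls,
        name: str,
        icd: Iterable[str] = (),
        cci: Iterable[str] = (),
    ) -> "CodeSet":
        return cls(
            name=name,
            icd_codes=frozenset(normalize_icd_code(c) for c in icd),
            cci_patterns=frozenset(normalize_cci_code(c) for c in cci),
        )

    def contains_icd(self, code: str) -> bool:
        return code in self.icd_codes

    def matches_cci(self, code: str) -> bool:
        return any(cci_matches(code, p) for p in self.cci_patterns)

    def __bool__(self) -> bool:
        return bool(self.icd_codes) or bool(self.cci_patterns)


# --- Study code sets -------------------------------------------------------

#: Coronary artery bypass graft procedure family.
CABG_CODESET = CodeSet.from_raw("cabg", cci=["1.IJ.76.^^"])

#: Valve repair/replacement and annulus intervention families
#: (tricuspid, pulmonary, mitral, aortic valves; therapeutic annulus work).
VALVE_CODESET = CodeSet.from_raw(
    "valve_or_annulus",
    cci=[
        "1.HS.80.^^",
        "1.HS.90.^^",
        "1.HT.80.^^",
        "1.HT.90.^^",
        "1.HU.80.^^",
        "1.HU.90.^^",
        "1.HV.80.^^",
        "1.HV.90.^^",
        "1.HW.^^.^^",
    ],
)

#: All eligible cardiac-surgery procedure patterns (CABG ∪ valve/annulus).
SURGERY_CODESET = CodeSet(
    name="eligible_cardiac_surgery",
    cci_patterns=CABG_CODESET.cci_patterns | VALVE_CODESET.cci_patterns,
)

#: Diagnosis codes that flag a possible new AF episode on the index abstract:
#: paroxysmal (I48.0), persistent (I48.1), AF/flutter unspecified (I48.9),
#: AF unspecified (I48.90).
FLAG_CODESET = CodeSet.from_raw("af_flag", icd=["I48.0", "I48.1", "I48.9", "I48.90"])

#: History codes: the flag codes plus chronic AF (I48.2), which marks a
#: history of AF but never suggests a new post-operative episode.
HISTORY_CODESET = CodeSet.from_raw(
    "af_history", icd=["I48.0", "I48.1", "I48.2", "I48.9", "I48.90"]
)

#: Maze procedure (surgical ablation of chronic AF) code family.
MAZE_CODESET = CodeSet.from_raw("maze", cci=["1.HH.59"])
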
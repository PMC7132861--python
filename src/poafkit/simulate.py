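"""Synthetic discharge-abstract world with known ground truth.

Real DAD extracts are not shareable, so this module generates longitudinal
hospital-abstract datasets whose latent truth and coding-error process are
fully known, making the detection algorithms and the validation statistics
testable end to end.  The generative model, per patient:

1. draw a site, a surgery class and an index admission date;
2. draw latent chronic-AF status ``H`` (prevalence ``h``), then — only when
   ``H = 0`` — latent POAF status ``D`` so that the *marginal* probability of
   a reference positive (``D = 1 ∧ H = 0``) equals the configured per-surgery
   incidence; reference positives require no AF history, matching a
   chart-review definition of new-onset POAF;
3. draw prior hospitalizations (Poisson count, dates uniform over the 6-year
   look-back horizon);
4. emit coded abstracts through a :class:`CodingModel`: true POAF is coded on
   the index abstract with probability ``p_code_given_poaf``; chronic AF is
   miscoded as a flag code with ``p_code_given_chronic`` (and documented as
   I48.2, which is inert for detection); AF-free patients acquire a false
   flag code with ``p_false_code``; each prior hospitalization of a chronic
   patient carries I48.2 with ``p_history_coded_per_prior_hosp`` and each
   prior hospitalization of a non-chronic patient a false history code with
   ``p_false_history_per_prior_hosp``;
5. assign maze procedure codes among chronic-AF patients only.

Defaults reproduce the published descriptive margins of the validation
cohort: site weights 0.49/0.51, site-specific surgery mixes and POAF
incidences (overall ≈ 33.2%), overall maze frequency ≈ 3.2% (chronic-AF
prevalence 0.10 × maze-given-chronic 0.32), and a low prior-hospitalization
rate (Poisson mean 1.2 per 6 years, consistent with a median of 0 in the
prior 12 months).  Per-site coding rates are illustrative: they are chosen so
the measured accuracies land near the published magnitudes (site B codes
POAF more completely than site A, reproducing the inter-site sensitivity
gap), but no real coding rate is recoverable from published data.

:func:`expected_accuracy` gives the closed-form accuracies implied by the
model (derivation in the package docs), the analytic oracle against which
large simulated cohorts are checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cohort import DEFAULT_STUDY_WINDOW, SurgeryClass, years_before
from .dad_io import (
    DischargeAbstract,
    ReferenceStandardRecord,
    write_abstracts,
    write_reference,
)
from .detect import AlgorithmSpec

#: Flag codes the coder draws from when recording AF on an abstract
#: (uniformly).  I48.9 is deliberately absent: coders at the study sites
#: recorded the five-character unspecified code instead.
FLAG_CODE_CHOICES = ("I480", "I481", "I4890")

_GENERIC_PRINCIPALS = ("I251", "I350", "I080", "E119", "J441", "N179", "I500")
_SURGERY_STEMS = {
    SurgeryClass.CABG: ("1IJ76",),
    SurgeryClass.VALVULAR: ("1HU80", "1HU90", "1HV80", "1HV90", "1HS80", "1HW79"),
}
_SUFFIX_LETTERS = "ABCDEFGHJKLMNPQRSTUVWXYZ"


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CodingModel:
    """Per-site diagnosis-coding error process (all probabilities)."""

    p_code_given_poaf: float = 0.80
    p_code_given_chronic: float = 0.50
    p_false_code: float = 0.10
    p_history_coded_per_prior_hosp: float = 0.30
    p_false_history_per_prior_hosp: float = 0.01

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SiteProfile:
    """Generative parameters of one hospital site."""

    site_id: str
    weight: float
    chronic_af_prevalence: float = 0.10
    poaf_incidence_by_surgery: dict = field(
        default_factory=lambda: {
            SurgeryClass.CABG: 0.306,
            SurgeryClass.VALVULAR: 0.305,
            SurgeryClass.MIXED: 0.419,
        }
    )
    surgery_mix: dict = field(
        default_factory=lambda: {
            SurgeryClass.CABG: 0.468,
            SurgeryClass.VALVULAR: 0.299,
            SurgeryClass.MIXED: 0.233,
        }
    )
    maze_given_chronic_af: float = 0.32
    coding: CodingModel = CodingModel()
    prior_hosp_rate: float = 1.2  # mean hospitalizations per 6-year horizon

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.surgery_mix.values()), 1.0, abs_tol=1e-9):
            raise SimulationConfigError(f"site {self.site_id}: surgery_mix must sum to 1")
        for cls, pi in self.poaf_incidence_by_surgery.items():
            if not 0.0 <= pi <= 1.0 - self.chronic_af_prevalence:
                raise SimulationConfigError(
                    f"site {self.site_id}: incidence {pi} for {cls} incompatible "
                    f"with chronic prevalence {self.chronic_af_prevalence}"
                )
        if not 0.0 <= self.maze_given_chronic_af <= 1.0:
            raise SimulationConfigError("maze_given_chronic_af outside [0, 1]")
        if self.prior_hosp_rate < 0:
            raise SimulationConfigError("prior_hosp_rate must be >= 0")


def default_sites() -> list[SiteProfile]:
    """Two sites mirroring the validation cohort's descriptive margins.

    Site A: fewer CABGs, higher POAF incidence, less complete POAF coding
    (p_code_given_poaf 0.63).  Site B: the converse (0.80).  False-coding
    rates 0.08 vs 0.125 put specificities near 88% and 84.5%.
    """
    return [
        SiteProfile(
            site_id="A",
            weight=0.49,
            surgery_mix={
                SurgeryClass.CABG: 0.420,
                SurgeryClass.VALVULAR: 0.311,
                SurgeryClass.MIXED: 0.269,
            },
            poaf_incidence_by_surgery={
                SurgeryClass.CABG: 0.294,
                SurgeryClass.VALVULAR: 0.349,
                SurgeryClass.MIXED: 0.488,
            },
            coding=CodingModel(p_code_given_poaf=0.63, p_false_code=0.08),
        ),
        SiteProfile(
            site_id="B",
            weight=0.51,
            surgery_mix={
                SurgeryClass.CABG: 0.515,
                SurgeryClass.VALVULAR: 0.288,
                SurgeryClass.MIXED: 0.197,
            },
            poaf_incidence_by_surgery={
                SurgeryClass.CABG: 0.316,
                SurgeryClass.VALVULAR: 0.259,
                SurgeryClass.MIXED: 0.327,
            },
            coding=CodingModel(p_code_given_poaf=0.80, p_false_code=0.125),
        ),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 976
    seed: int = 20100101
    sites: tuple[SiteProfile, ...] = ()
    study_window: tuple[date, date] = DEFAULT_STUDY_WINDOW
    max_lookback_years: int = 6

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SimulationConfigError("n_patients must be >= 1")
        sites = self.sites or tuple(default_sites())
        object.__setattr__(self, "sites", tuple(sites))
        if not math.isclose(sum(s.weight for s in self.sites), 1.0, abs_tol=1e-9):
            raise SimulationConfigError("site weights must sum to 1")


@dataclass
class TruthRecord:
    """Latent variables of one simulated patient."""

    patient_id: str
    visit_id: str
    site_id: str
    surgery_class: str
    chronic_af: bool
    poaf: bool
    maze: bool
    n_prior_hosp: int


@dataclass
class SimulatedCohort:
    abstracts: list[DischargeAbstract]
    reference: list[ReferenceStandardRecord]
    truth: list[TruthRecord]


def _choice(rng: np.random.Generator, items: Sequence, weights: Sequence[float]):
    return items[int(rng.choice(len(items), p=np.asarray(weights) / sum(weights)))]


def _suffix(rng: np.random.Generator, k: int = 2) -> str:
    return "".join(_SUFFIX_LETTERS[int(i)] for i in rng.integers(0, len(_SUFFIX_LETTERS), size=k))


def _surgery_codes(rng: np.random.Generator, cls: SurgeryClass) -> list[str]:
    if cls is SurgeryClass.MIXED:
        stems = [_SURGERY_STEMS[SurgeryClass.CABG][0],
                 _choice(rng, _SURGERY_STEMS[SurgeryClass.VALVULAR],
                         [1] * len(_SURGERY_STEMS[SurgeryClass.VALVULAR]))]
    else:
        stems = [_choice(rng, _SURGERY_STEMS[cls], [1] * len(_SURGERY_STEMS[cls]))]
    return [s + _suffix(rng) for s in stems]


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate a cohort; deterministic given ``config.seed``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    start, end = config.study_window
    window_days = (end - start).days
    site_weights = [s.weight for s in config.sites]

    abstracts: list[DischargeAbstract] = []
    reference: list[ReferenceStandardRecord] = []
    truth: list[TruthRecord] = []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        site = _choice(rng, config.sites, site_weights)
        coding = site.coding
        classes = list(site.surgery_mix)
        cls = _choice(rng, classes, [site.surgery_mix[c] for c in classes])

        admission = start + timedelta(days=int(rng.integers(0, window_days + 1)))
        surgery = admission + timedelta(days=int(rng.integers(0, 3)))
        discharge = surgery + timedelta(days=int(rng.integers(5, 21)))
        age = int(np.clip(round(rng.normal(68.5, 10.0)), 18, 95))
        sex = "M" if rng.random() < 0.708 else "F"

        h = site.chronic_af_prevalence
        chronic = rng.random() < h
        pi = site.poaf_incidence_by_surgery[cls]
        poaf = (not chronic) and rng.random() < pi / (1.0 - h)
        maze = chronic and rng.random() < site.maze_given_chronic_af

        diagnoses = [_choice(rng, _GENERIC_PRINCIPALS, [1] * len(_GENERIC_PRINCIPALS))]
        flag_draw = rng.random()
        flag_code = FLAG_CODE_CHOICES[int(rng.integers(0, len(FLAG_CODE_CHOICES)))]
        if poaf:
            if flag_draw < coding.p_code_given_poaf:
                diagnoses.append(flag_code)
        elif chronic:
            if flag_draw < coding.p_code_given_chronic:
                diagnoses.append(flag_code)
            diagnoses.append("I482")
        else:
            if flag_draw < coding.p_false_code:
                diagnoses.append(flag_code)

        procedures = _surgery_codes(rng, cls)
        if maze:
            procedures.append("1HH59" + _suffix(rng))

        index_visit = f"{pid}-X"
        abstracts.append(
            DischargeAbstract(
                patient_id=pid,
                visit_id=index_visit,
                site_id=site.site_id,
                admission_date=admission,
                discharge_date=discharge,
                surgery_date=surgery,
                age_years=age,
                sex=sex,
                diagnosis_codes=diagnoses,
                procedure_codes=procedures,
                died_in_hospital=bool(rng.random() < 0.049),
                died_during_surgery=False,
            )
        )
        reference.append(
            ReferenceStandardRecord(
                patient_id=pid, visit_id=index_visit, true_poaf=poaf
            )
        )

        horizon_days = (admission - years_before(admission, config.max_lookback_years)).days
        n_prior = int(rng.poisson(site.prior_hosp_rate))
        for k in range(n_prior):
            offset = int(rng.integers(1, horizon_days + 1))
            prior_discharge = admission - timedelta(days=offset)
            prior_admission = prior_discharge - timedelta(days=int(rng.integers(1, 10)))
            prior_diag = [_choice(rng, _GENERIC_PRINCIPALS, [1] * len(_GENERIC_PRINCIPALS))]
            hist_draw = rng.random()
            if chronic:
                if hist_draw < coding.p_history_coded_per_prior_hosp:
                    prior_diag.append("I482")
            else:
                if hist_draw < coding.p_false_history_per_prior_hosp:
                    prior_diag.append(
                        FLAG_CODE_CHOICES[int(rng.integers(0, len(FLAG_CODE_CHOICES)))]
                    )
            abstracts.append(
                DischargeAbstract(
                    patient_id=pid,
                    visit_id=f"{pid}-H{k}",
                    site_id=site.site_id,
                    admission_date=prior_admission,
                    discharge_date=prior_discharge,
                    surgery_date=None,
                    age_years=max(18, age - (offset // 365)),
                    sex=sex,
                    diagnosis_codes=prior_diag,
                    procedure_codes=[],
                    died_in_hospital=False,
                    died_during_surgery=False,
                )
            )
        truth.append(
            TruthRecord(
                patient_id=pid,
                visit_id=index_visit,
                site_id=site.site_id,
                surgery_class=cls.value,
                chronic_af=chronic,
                poaf=poaf,
                maze=maze,
                n_prior_hosp=n_prior,
            )
        )
    return SimulatedCohort(abstracts=abstracts, reference=reference, truth=truth)


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write ``abstracts.csv``, ``reference_standard.csv``, ``truth.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    paths = {
        "abstracts": out_dir / "abstracts.csv",
        "reference": out_dir / "reference_standard.csv",
        "truth": out_dir / "truth.csv",
    }
    write_abstracts(cohort.abstracts, paths["abstracts"])
    write_reference(cohort.reference, paths["reference"])
    with paths["truth"].open("w", encoding="utf-8") as fh:
        fh.write("patient_id,visit_id,site_id,surgery_class,chronic_af,poaf,maze,n_prior_hosp\n")
        for t in cohort.truth:
            fh.write(
                f"{t.patient_id},{t.visit_id},{t.site_id},{t.surgery_class},"
                f"{str(t.chronic_af).lower()},{str(t.poaf).lower()},"
                f"{str(t.maze).lower()},{t.n_prior_hosp}\n"
            )
    return paths


# --- analytic oracle -------------------------------------------------------

def _flag_factor(spec: AlgorithmSpec) -> float:
    """Probability that a coded AF flag lands in the algorithm's flag set."""
    hits = sum(1 for c in FLAG_CODE_CHOICES if c in spec.flag_codes)
    return hits / len(FLAG_CODE_CHOICES)


def expected_cells(profile: SiteProfile, spec: AlgorithmSpec) -> dict[str, float]:
    """Expected joint probabilities of (reference, prediction) cells at one site.

    Closed forms under the generator's independence assumptions.  With
    Poisson(λ) prior hospitalizations, uniform dates and window fraction
    ``w/6``, the chance that no independently coded history event (each with
    per-hospitalization probability p) falls in the window is
    ``E[(1 − p·w/6)^N] = exp(−λ·p·w/6)``.
    """
    c = profile.coding
    lam_w = profile.prior_hosp_rate * spec.lookback_years / 6.0
    ff = _flag_factor(spec)
    keep_false_hist = math.exp(-lam_w * c.p_false_history_per_prior_hosp)
    keep_chronic_hist = math.exp(-lam_w * c.p_history_coded_per_prior_hosp)

    se = c.p_code_given_poaf * ff * keep_false_hist
    g_chronic = c.p_code_given_chronic * ff * keep_chronic_hist
    if spec.maze_recode:
        g_chronic *= 1.0 - profile.maze_given_chronic_af
    g_clean = c.p_false_code * ff * keep_false_hist

    h = profile.chronic_af_prevalence
    cells = {"tp": 0.0, "fp": 0.0, "fn": 0.0, "tn": 0.0}
    for cls, w_cls in profile.surgery_mix.items():
        pi = profile.poaf_incidence_by_surgery[cls]
        tp = pi * se
        fp = h * g_chronic + (1.0 - h - pi) * g_clean
        cells["tp"] += w_cls * tp
        cells["fn"] += w_cls * (pi - tp)
        cells["fp"] += w_cls * fp
        cells["tn"] += w_cls * (1.0 - pi - fp)
    return cells


def _metrics_from_cells(cells: dict[str, float]) -> dict[str, float]:
    return {
        "sensitivity": cells["tp"] / (cells["tp"] + cells["fn"]),
        "specificity": cells["tn"] / (cells["fp"] + cells["tn"]),
        "ppv": cells["tp"] / (cells["tp"] + cells["fp"]),
        "npv": cells["tn"] / (cells["fn"] + cells["tn"]),
    }


def expected_accuracy(profile: SiteProfile, spec: AlgorithmSpec) -> dict[str, float]:
    """Expected Se/Sp/PPV/NPV of an algorithm at one site (closed form)."""
    return _metrics_from_cells(expected_cells(profile, spec))


def expected_accuracy_overall(
    config: SimulationConfig, spec: AlgorithmSpec
) -> dict[str, float]:
    """Expected accuracies pooled over sites (site-weighted cell mixture)."""
    cells = {"tp": 0.0, "fp": 0.0, "fn": 0.0, "tn": 0.0}
    for site in config.sites:
        site_cells = expected_cells(site, spec)
        for k in cells:
            cells[k] += site.weight * site_cells[k]
    return _metrics_from_cells(cells)


# --- utilities -------------------------------------------------------------

def subsample(
    abstracts: Sequence[DischargeAbstract], fraction: float, seed: int
) -> list[DischargeAbstract]:
    """Seeded simple random sample of *patients* (all their visits kept).

    The sample size is ``round(fraction × n_patients)`` (Python's built-in
    round).  Original record order is preserved.
    """
    if not abstracts:
        raise ValueError("cannot subsample an empty dataset")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(abstracts)
    patients = sorted({a.patient_id for a in abstracts})
    k = max(1, round(fraction * len(patients)))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(np.array(patients), size=k, replace=False).tolist())
    return [a for a in abstracts if a.patient_id in chosen]


def noiseless_sites() -> list[SiteProfile]:
    """Sites with perfect coding: every algorithm is exact on such a world."""
    perfect = CodingModel(
        p_code_given_poaf=1.0,
        p_code_given_chronic=0.0,
        p_false_code=0.0,
        p_history_coded_per_prior_hosp=0.0,
        p_false_history_per_prior_hosp=0.0,
    )
    return [replace(s, coding=perfect) for s in default_sites()]
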
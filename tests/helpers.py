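"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np

from poafkit.cohort import IndexCase, link_lookback
from poafkit.dad_io import DischargeAbstract
from poafkit.detect import AlgorithmSpec


def make_abstract(
    patient_id="P1",
    visit_id="V1",
    site_id="A",
    admission=date(2014, 6, 1),
    discharge=date(2014, 6, 12),
    surgery=None,
    age=67,
    sex="M",
    diagnoses=("I251",),
    procedures=(),
    died_in_hospital=False,
    died_during_surgery=False,
) -> DischargeAbstract:
    return DischargeAbstract(
        patient_id=patient_id,
        visit_id=visit_id,
        site_id=site_id,
        admission_date=admission,
        discharge_date=discharge,
        surgery_date=surgery,
        age_years=age,
        sex=sex,
        diagnosis_codes=list(diagnoses),
        procedure_codes=list(procedures),
        died_in_hospital=died_in_hospital,
        died_during_surgery=died_during_surgery,
    )


DIAGNOSIS_POOL = ["I251", "I480", "I481", "I482", "I489", "I4890", "E119", "J189"]
PROCEDURE_POOL = ["1IJ76LA", "1HU80XX", "1HH59LA", "1HH59", "1HV90AB"]


def random_case(rng: np.random.Generator, lookback_years: int) -> IndexCase:
    """A random small index case linked at the requested window."""
    adm = date(2013, 1, 1) + timedelta(days=int(rng.integers(0, 1200)))
    n_diag = int(rng.integers(1, 4))
    index = make_abstract(
        patient_id="P",
        visit_id="X",
        admission=adm,
        discharge=adm + timedelta(days=10),
        surgery=adm + timedelta(days=1),
        diagnoses=[DIAGNOSIS_POOL[int(i)] for i in rng.integers(0, len(DIAGNOSIS_POOL), n_diag)],
        procedures=["1IJ76GQ"] + (
            [PROCEDURE_POOL[int(rng.integers(0, len(PROCEDURE_POOL)))]]
            if rng.random() < 0.5 else []
        ),
    )
    priors = []
    for k in range(int(rng.integers(0, 4))):
        dis = adm - timedelta(days=int(rng.integers(1, 2600)))
        priors.append(
            make_abstract(
                patient_id="P",
                visit_id=f"H{k}",
                admission=dis - timedelta(days=3),
                discharge=dis,
                diagnoses=[DIAGNOSIS_POOL[int(i)] for i in rng.integers(0, len(DIAGNOSIS_POOL), int(rng.integers(1, 3)))],
            )
        )
    return IndexCase(
        index=index,
        lookback_hospitalizations=link_lookback(index, priors, lookback_years),
        lookback_window_years=lookback_years,
    )


def brute_force_predict(case: IndexCase, spec: AlgorithmSpec) -> bool:
    """Naive set-intersection re-evaluation of the detection rule."""
    def positions(codes):
        return list(codes) if spec.any_position else list(codes)[:1]

    flag = bool(set(positions(case.index.diagnosis_codes)) & set(spec.flag_codes))
    hist_codes: set[str] = set()
    for hosp in case.lookback_hospitalizations:
        hist_codes |= set(positions(hosp.diagnosis_codes))
    hist = bool(hist_codes & set(spec.history_codes))
    maze = any(
        (code == pat) if spec.maze_exact else code.startswith(pat.rstrip("^"))
        for code in case.index.procedure_codes
        for pat in spec.maze_patterns
    )
    return flag and not hist and (not spec.maze_recode or not maze)


def gs_statistic_oracle(d, pa, pb, which: str) -> float:
    """Brute-force generalized score statistic: explicit record stacking,
    intercept-only null fit, per-cluster efficient scores, sandwich variance."""
    rows = []
    for i in range(len(d)):
        for z, p in ((0, pa[i]), (1, pb[i])):
            include = bool(p) if which == "ppv" else not p
            if include:
                rows.append((i, z, float(d[i])))
    p0 = sum(r[2] for r in rows) / len(rows)
    zbar = sum(r[1] for r in rows) / len(rows)
    clusters: dict[int, list[tuple[int, float]]] = {}
    for i, z, dd in rows:
        clusters.setdefault(i, []).append((z, dd))
    scores = [
        sum((z - zbar) * (dd - p0) for z, dd in recs) for recs in clusters.values()
    ]
    u = sum(scores)
    v = sum(s * s for s in scores)
    return 0.0 if v == 0 else u * u / v
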
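"""End-to-end validation runs and table rendering.

``run_validation`` drives the whole pipeline on in-memory records: build and
link index cases, apply exclusions against the reference standard, run each
requested algorithm, cross-tabulate, estimate accuracies with CIs, optionally
stratify by site, and run the requested paired comparisons with Bonferroni
adjustment.  Every percentage cell in the report equals the half-up-rounded
exact rational metric of the underlying integer confusion matrix — nothing
is recomputed independently downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from .cohort import (
    EligibilityConfig,
    IndexCase,
    apply_exclusions,
    build_index_cases,
    relink_cases,
)
from .dad_io import DischargeAbstract, ReferenceStandardRecord
from .detect import (
    AlgorithmSpec,
    restricted_code_variant,
    run_algorithm,
    standard_algorithms,
)
from .stats import (
    METRICS,
    ConfusionMatrix,
    accuracy_metrics,
    bonferroni_adjust_p,
    compare_se_sp,
    confusion_matrix,
    leisenring_pv_test,
    round_half_up_pct,
)


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else float(round_half_up_pct(num, den))


def _accuracy_block(cm: ConfusionMatrix, ci_method: str, level: float) -> dict:
    ests = accuracy_metrics(cm, ci_method=ci_method, level=level)
    block = {
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "metrics": {},
    }
    for metric in METRICS:
        e = ests[metric]
        block["metrics"][metric] = {
            "point_pct": _pct(e.n_numerator, e.n_denominator),
            "ci_low_pct": None if e.ci_low is None else round(100 * e.ci_low, 1),
            "ci_high_pct": None if e.ci_high is None else round(100 * e.ci_high, 1),
            "n_num": e.n_numerator,
            "n_den": e.n_denominator,
            "undefined": e.undefined,
        }
    return block


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_validation(
    abstracts: Sequence[DischargeAbstract],
    reference: Sequence[ReferenceStandardRecord],
    algorithms: Sequence[AlgorithmSpec] | None = None,
    *,
    eligibility: EligibilityConfig | None = None,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
    by_site: bool = False,
    comparisons: Sequence[tuple[str, str, str]] | None = None,
    bonferroni_m: int | None = None,
    restricted_codes: bool = False,
    missing_reference: str = "error",
    seed: int | None = None,
) -> dict:
    """Run detection + validation and return a JSON-serializable report.

    ``comparisons`` is a list of ``(algorithm_a, algorithm_b, metric)``
    triples; Bonferroni's m defaults to the number of comparisons actually
    performed within each metric family, overridable via ``bonferroni_m``.
    """
    algorithms = list(algorithms) if algorithms is not None else standard_algorithms()
    if restricted_codes:
        algorithms = [restricted_code_variant(s) for s in algorithms]
    max_window = max(s.lookback_years for s in algorithms)
    cases = build_index_cases(abstracts, eligibility, lookback_years=max_window)
    cases, exclusion_log = apply_exclusions(
        cases, reference, missing_reference=missing_reference
    )
    truth = [bool(c.reference_label) for c in cases]
    sites = sorted({c.index.site_id for c in cases})

    cases_by_window: dict[int, list[IndexCase]] = {max_window: cases}
    for spec in algorithms:
        if spec.lookback_years not in cases_by_window:
            relinked = relink_cases(cases, abstracts, spec.lookback_years)
            cases_by_window[spec.lookback_years] = relinked

    report: dict = {
        "seed": seed,
        "n_index_cases": len(cases),
        "n_excluded": len(exclusion_log),
        "exclusions": sorted(
            (c.index.patient_id, c.index.visit_id, reason) for c, reason in exclusion_log
        ),
        "ci_method": ci_method,
        "level": level,
        "algorithms": [s.name for s in algorithms],
        "lookback_years": {s.name: s.lookback_years for s in algorithms},
        "accuracy": {},
        "comparisons": [],
    }
    if by_site:
        report["by_site"] = {site: {} for site in sites}

    predictions: dict[str, list[bool]] = {}
    for spec in algorithms:
        linked = cases_by_window[spec.lookback_years]
        results = run_algorithm(linked, spec)
        pred = [r.predicted_poaf for r in results]
        predictions[spec.name] = pred
        cm = confusion_matrix(pred, truth)
        report["accuracy"][spec.name] = _accuracy_block(cm, ci_method, level)
        if by_site:
            for site in sites:
                mask = [c.index.site_id == site for c in linked]
                cm_site = confusion_matrix(
                    [p for p, m in zip(pred, mask) if m],
                    [t for t, m in zip(truth, mask) if m],
                )
                report["by_site"][site][spec.name] = _accuracy_block(
                    cm_site, ci_method, level
                )

    if comparisons:
        rows = []
        for alg_a, alg_b, metric in comparisons:
            pa, pb = predictions[alg_a], predictions[alg_b]
            if metric in ("sensitivity", "specificity"):
                res = compare_se_sp(truth, pa, pb, metric)
            elif metric in ("ppv", "npv"):
                res = leisenring_pv_test(truth, pa, pb, metric)
            else:
                raise ValueError(f"unknown comparison metric {metric!r}")
            rows.append(
                {
                    "algorithm_a": alg_a,
                    "algorithm_b": alg_b,
                    "metric": metric,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "warning": res.warning,
                }
            )
        by_family: dict[str, list[int]] = {}
        for i, row in enumerate(rows):
            by_family.setdefault(row["metric"], []).append(i)
        for family, idxs in by_family.items():
            m = bonferroni_m if bonferroni_m is not None else len(idxs)
            adjusted = bonferroni_adjust_p([rows[i]["p_value"] for i in idxs], m)
            for i, p_adj in zip(idxs, adjusted):
                rows[i]["p_adjusted"] = p_adj
                rows[i]["bonferroni_m"] = m
        report["comparisons"] = rows

    report["config_hash"] = _config_hash(
        {
            "algorithms": report["algorithms"],
            "ci_method": ci_method,
            "level": level,
            "by_site": by_site,
            "comparisons": list(comparisons or []),
            "restricted_codes": restricted_codes,
            "seed": seed,
        }
    )
    return report


def select_best(
    report: dict,
    criterion: str,
    *,
    prefer_longest_lookback: bool = False,
) -> str:
    """Name of the best algorithm under ``max_sensitivity`` or ``max_ppv``.

    Ties are broken by fewest look-back years, then lowest position in the
    report's algorithm order; ``prefer_longest_lookback=True`` flips the
    first tie-break (some analysts prefer the longest history search among
    equally sensitive rules).
    """
    metric = {"max_sensitivity": "sensitivity", "max_ppv": "ppv"}.get(criterion)
    if metric is None:
        raise ValueError(f"unknown criterion {criterion!r}")
    names = report["algorithms"]
    if not names:
        raise ValueError("report contains no algorithms")

    def exact(name: str) -> Fraction:
        cell = report["accuracy"][name]["metrics"][metric]
        if cell["undefined"]:
            return Fraction(-1)
        return Fraction(cell["n_num"], cell["n_den"])

    def key(item: tuple[int, str]):
        i, name = item
        years = report.get("lookback_years", {}).get(name, 0)
        return (
            -exact(name),
            -years if prefer_longest_lookback else years,
            i,
        )

    return min(enumerate(names), key=key)[1]


# --- rendering -------------------------------------------------------------

def _fmt_cell(cell: dict) -> str:
    if cell["undefined"]:
        return "undefined"
    return f"{cell['point_pct']:.1f} ({cell['ci_low_pct']:.1f}-{cell['ci_high_pct']:.1f})"


def accuracy_table_rows(report: dict, site: str | None = None) -> list[dict]:
    """Flat rows (one per algorithm × metric) for CSV output."""
    source = report["accuracy"] if site is None else report["by_site"][site]
    rows = []
    for name in report["algorithms"]:
        for metric in METRICS:
            cell = source[name]["metrics"][metric]
            rows.append(
                {
                    "algorithm": name,
                    "site": site or "all",
                    "metric": metric,
                    "point_pct": cell["point_pct"],
                    "ci_low_pct": cell["ci_low_pct"],
                    "ci_high_pct": cell["ci_high_pct"],
                    "n_num": cell["n_num"],
                    "n_den": cell["n_den"],
                }
            )
    return rows


def render_accuracy_table(report: dict, site: str | None = None) -> str:
    """Human-readable accuracy table (one line per algorithm)."""
    source = report["accuracy"] if site is None else report["by_site"][site]
    header = f"{'Algorithm':<28}" + "".join(f"{m:<22}" for m in METRICS)
    lines = [header, "-" * len(header)]
    for name in report["algorithms"]:
        cells = source[name]["metrics"]
        lines.append(
            f"{name:<28}" + "".join(f"{_fmt_cell(cells[m]):<22}" for m in METRICS)
        )
    return "\n".join(lines)


def write_report_bundle(report: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write report.json, accuracy CSVs, comparisons.csv and run.log."""
    import csv as _csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["report"] = out_dir / "report.json"
    paths["report"].write_text(json.dumps(report, indent=2, default=str) + "\n")

    paths["accuracy"] = out_dir / "accuracy.csv"
    with paths["accuracy"].open("w", newline="") as fh:
        rows = accuracy_table_rows(report)
        if "by_site" in report:
            for site in report["by_site"]:
                rows += accuracy_table_rows(report, site)
        writer = _csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)

    if report.get("comparisons"):
        paths["comparisons"] = out_dir / "comparisons.csv"
        with paths["comparisons"].open("w", newline="") as fh:
            writer = _csv.DictWriter(fh, fieldnames=list(report["comparisons"][0]))
            writer.writeheader()
            writer.writerows(report["comparisons"])

    paths["log"] = out_dir / "run.log"
    paths["log"].write_text(
        f"config_hash={report['config_hash']}\n"
        f"seed={report.get('seed')}\n"
        f"n_index_cases={report['n_index_cases']}\n"
        f"n_excluded={report['n_excluded']}\n"
    )
    return paths


def all_pairwise_comparisons(
    algorithms: Sequence[AlgorithmSpec] | None = None,
    metrics: Sequence[str] = METRICS,
) -> list[tuple[str, str, str]]:
    """Every unordered algorithm pair × metric (the default comparison plan)."""
    algorithms = list(algorithms) if algorithms is not None else standard_algorithms()
    names = [s.name for s in algorithms]
    plan = []
    for metric in metrics:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                plan.append((names[i], names[j], metric))
    return plan
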
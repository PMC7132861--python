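"""Diagnostic-accuracy statistics for validating detection algorithms.

Covers the 2×2 cross-tabulation against the chart-review reference standard;
sensitivity, specificity, PPV and NPV with exact Clopper-Pearson (default) or
Wilson confidence intervals; McNemar's test for paired sensitivity and
specificity comparisons; the Leisenring-Alonzo-Pepe generalized score test
for paired PPV/NPV comparisons; an unpaired pooled-score z test for
between-site comparisons (sites share no patients, so no paired structure
exists); Bonferroni multiplicity adjustment; Cohen's kappa for inter-rater
agreement; and an exact integer inversion of rounded published accuracy
tables back into confusion matrices.

Reporting convention throughout: percentages rounded half-up to one decimal.
Undefined metrics (zero denominator) are explicit ``undefined`` markers,
never 0 and never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps


class UndefinedComparisonError(ValueError):
    """A predictive-value comparison has no qualifying records for one test."""


class InversionError(ValueError):
    """No integer confusion matrix reproduces the printed table row."""


METRICS = ("sensitivity", "specificity", "ppv", "npv")


# --- confusion matrix and accuracy metrics ---------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts of algorithm prediction vs reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Reference positives."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Reference negatives."""
        return self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )

    def metric_fraction(self, metric: str) -> Fraction | None:
        """The metric as an exact rational, or None when undefined."""
        num, den = {
            "sensitivity": (self.tp, self.tp + self.fn),
            "specificity": (self.tn, self.fp + self.tn),
            "ppv": (self.tp, self.tp + self.fp),
            "npv": (self.tn, self.fn + self.tn),
        }[metric]
        return None if den == 0 else Fraction(num, den)


@dataclass(frozen=True)
class AccuracyEstimate:
    """One accuracy metric with its confidence interval."""

    metric: str
    point: float | None
    ci_low: float | None
    ci_high: float | None
    n_numerator: int
    n_denominator: int
    ci_method: str
    level: float
    undefined: bool = False


def confusion_matrix(
    predictions: Mapping[tuple[str, str], bool] | Sequence,
    reference: Mapping[tuple[str, str], bool] | Sequence,
) -> ConfusionMatrix:
    """Cross-tabulate predictions against the reference standard.

    Both arguments are either mappings ``(patient_id, visit_id) → bool`` or
    equal-length boolean sequences already aligned subject-by-subject.
    Raises on unmatched ids, listing the offenders.
    """
    if isinstance(predictions, Mapping) and isinstance(reference, Mapping):
        missing = sorted(set(predictions) ^ set(reference))
        if missing:
            raise KeyError(f"unmatched (patient_id, visit_id) keys: {missing[:10]}")
        keys = sorted(predictions)
        pred = np.array([predictions[k] for k in keys], dtype=bool)
        truth = np.array([reference[k] for k in keys], dtype=bool)
    else:
        pred = np.asarray(predictions, dtype=bool)
        truth = np.asarray(reference, dtype=bool)
        if pred.shape != truth.shape:
            raise ValueError("predictions and reference differ in length")
    return ConfusionMatrix(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def proportion_ci(
    successes: int,
    n: int,
    level: float = 0.95,
    method: str = "clopper_pearson",
) -> tuple[float, float]:
    """Binomial confidence interval; exact Clopper-Pearson by default.

    The Clopper-Pearson bounds invert the binomial tail probabilities at
    ``(1 − level)/2`` per side, computed via Beta quantiles; the lower bound
    is exactly 0 when ``successes == 0`` and the upper exactly 1 when
    ``successes == n``.  ``method="wilson"`` gives the Wilson score interval
    (via statsmodels).
    """
    if not 0 <= successes <= n or n < 1:
        raise ValueError(f"need 0 <= successes <= n with n >= 1, got {successes}/{n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    if method == "clopper_pearson":
        low = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
        high = 1.0 if successes == n else float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
        return low, high
    if method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        low, high = proportion_confint(successes, n, alpha=alpha, method="wilson")
        return float(low), float(high)
    raise ValueError(f"unknown CI method {method!r}")


def accuracy_metrics(
    cm: ConfusionMatrix,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> dict[str, AccuracyEstimate]:
    """Se, Sp, PPV and NPV with confidence intervals.

    A metric with a zero denominator is returned as an explicit undefined
    estimate, never as 0.
    """
    numdens = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.fp + cm.tn),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.fn + cm.tn),
    }
    out: dict[str, AccuracyEstimate] = {}
    for metric, (num, den) in numdens.items():
        if den == 0:
            out[metric] = AccuracyEstimate(
                metric, None, None, None, num, den, ci_method, level, undefined=True
            )
            continue
        low, high = proportion_ci(num, den, level=level, method=ci_method)
        out[metric] = AccuracyEstimate(
            metric, num / den, low, high, num, den, ci_method, level
        )
    return out


def ppv_from_se_sp_prevalence(se, sp, prevalence):
    """PPV via Bayes' theorem: Se·π / (Se·π + (1−Sp)·(1−π)).

    Works with floats or :class:`fractions.Fraction` (exact arithmetic).
    """
    return se * prevalence / (se * prevalence + (1 - sp) * (1 - prevalence))


def npv_from_se_sp_prevalence(se, sp, prevalence):
    """NPV via Bayes' theorem: Sp·(1−π) / (Sp·(1−π) + (1−Se)·π)."""
    return sp * (1 - prevalence) / (sp * (1 - prevalence) + (1 - se) * prevalence)


# --- comparison tests ------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one paired or unpaired accuracy comparison."""

    test_name: str
    statistic: float
    p_value: float
    df: int = 1
    details: dict = field(default_factory=dict)
    p_adjusted: float | None = None
    warning: str | None = None


def mcnemar_test(
    correct_a: Sequence[bool],
    correct_b: Sequence[bool],
    *,
    variant: str = "chi2",
    test_name: str = "mcnemar",
) -> ComparisonResult:
    """McNemar's test on paired correctness indicators.

    ``correct_a[i]``/``correct_b[i]`` state whether each algorithm classified
    subject ``i`` correctly; restrict to reference positives beforehand to
    compare sensitivities, to reference negatives for specificities (see
    :func:`compare_se_sp`).  With discordant counts ``b`` (A only correct)
    and ``c`` (B only correct), the default statistic is χ² = (b−c)²/(b+c) on
    1 df; ``variant="cc"`` applies the continuity correction and
    ``variant="exact"`` uses the exact binomial test.  No discordant pairs →
    statistic 0, p = 1, with a warning flag.
    """
    a = np.asarray(correct_a, dtype=bool)
    b_arr = np.asarray(correct_b, dtype=bool)
    if a.shape != b_arr.shape:
        raise ValueError("paired outcome vectors differ in length")
    b = int(np.sum(a & ~b_arr))
    c = int(np.sum(~a & b_arr))
    details = {"b": b, "c": c}
    if b + c == 0:
        return ComparisonResult(test_name, 0.0, 1.0, details=details,
                                warning="no discordant pairs")
    if variant == "chi2":
        stat = (b - c) ** 2 / (b + c)
        p = float(sps.chi2.sf(stat, df=1))
    elif variant == "cc":
        stat = max(abs(b - c) - 1, 0) ** 2 / (b + c)
        p = float(sps.chi2.sf(stat, df=1))
    elif variant == "exact":
        stat = float(min(b, c))
        p = float(sps.binomtest(b, b + c, 0.5).pvalue)
    else:
        raise ValueError(f"unknown McNemar variant {variant!r}")
    return ComparisonResult(test_name, float(stat), p, details=details)


def compare_se_sp(
    truth: Sequence[bool],
    pred_a: Sequence[bool],
    pred_b: Sequence[bool],
    metric: str,
    *,
    variant: str = "chi2",
) -> ComparisonResult:
    """Paired comparison of two algorithms' sensitivity or specificity."""
    truth = np.asarray(truth, dtype=bool)
    pa = np.asarray(pred_a, dtype=bool)
    pb = np.asarray(pred_b, dtype=bool)
    if metric == "sensitivity":
        mask = truth
        correct_a, correct_b = pa[mask], pb[mask]
    elif metric == "specificity":
        mask = ~truth
        correct_a, correct_b = ~pa[mask], ~pb[mask]
    else:
        raise ValueError("metric must be 'sensitivity' or 'specificity'")
    return mcnemar_test(correct_a, correct_b, variant=variant,
                        test_name=f"mcnemar_{'se' if metric == 'sensitivity' else 'sp'}")


def leisenring_pv_test(
    truth: Sequence[bool],
    pred_a: Sequence[bool],
    pred_b: Sequence[bool],
    which: str = "ppv",
) -> ComparisonResult:
    """Generalized score test comparing paired PPVs or NPVs.

    Stacks one record per (subject × algorithm) restricted to test-positive
    records (PPV) or test-negative records (NPV) and score-tests the
    algorithm indicator in a marginal mean model for disease status fitted
    under working independence, with an empirical (sandwich) variance that
    respects within-subject clustering.  With the null estimate
    ``p̂ = mean(D)`` over included records and covariate mean ``z̄``, the
    statistic is ``(Σᵢ Uᵢ)² / Σᵢ Uᵢ²`` with per-subject score contributions
    ``Uᵢ = Σⱼ (z_ij − z̄)(Dᵢ − p̂)``, referred to χ² on 1 df.  Identical
    predictions give statistic 0 and p = 1.
    """
    if which not in ("ppv", "npv"):
        raise ValueError("which must be 'ppv' or 'npv'")
    truth = np.asarray(truth, dtype=bool)
    pa = np.asarray(pred_a, dtype=bool)
    pb = np.asarray(pred_b, dtype=bool)
    if not (truth.shape == pa.shape == pb.shape):
        raise ValueError("inputs differ in length")
    include_a = pa if which == "ppv" else ~pa
    include_b = pb if which == "ppv" else ~pb
    n_a, n_b = int(include_a.sum()), int(include_b.sum())
    if n_a == 0 or n_b == 0:
        raise UndefinedComparisonError(
            f"{which.upper()} comparison undefined: no qualifying records "
            f"(A: {n_a}, B: {n_b})"
        )
    d = truth.astype(float)
    m_i = include_a.astype(float) + include_b.astype(float)  # records per subject
    z_i = include_b.astype(float)  # z sums per subject (z=1 marks algorithm B)
    n_records = n_a + n_b
    p_hat = float((d * m_i).sum() / n_records)
    z_bar = n_b / n_records
    u = (z_i - z_bar * m_i) * (d - p_hat)
    num = float(u.sum()) ** 2
    den = float((u**2).sum())
    details = {"n_records_a": n_a, "n_records_b": n_b, "p_null": p_hat}
    if den == 0.0:
        return ComparisonResult(
            f"leisenring_{which}", 0.0, 1.0, details=details,
            warning="no variance: predictions identical on qualifying records",
        )
    stat = num / den
    return ComparisonResult(
        f"leisenring_{which}", stat, float(sps.chi2.sf(stat, df=1)), details=details
    )


def unpaired_proportion_test(
    x1: int, n1: int, x2: int, n2: int, *, method: str = "score"
) -> ComparisonResult:
    """Two-sample test of equal proportions for disjoint groups (e.g. sites).

    Default is the pooled-variance score (z) test, two-sided;
    ``method="fisher"`` uses Fisher's exact test.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("denominators must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes out of range")
    p1, p2 = x1 / n1, x2 / n2
    details = {"p1": p1, "p2": p2, "n1": n1, "n2": n2}
    if method == "fisher":
        odds, p = sps.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])
        return ComparisonResult("unpaired_fisher", float(odds), float(p), df=0,
                                details=details)
    if method != "score":
        raise ValueError(f"unknown method {method!r}")
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0.0:
        return ComparisonResult("unpaired_proportion", 0.0, 1.0, details=details,
                                warning="degenerate pooled variance")
    z = (p1 - p2) / np.sqrt(var)
    return ComparisonResult(
        "unpaired_proportion", float(z), float(2 * sps.norm.sf(abs(z))), details=details
    )


def bonferroni_adjust_p(p_values: Iterable[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values: ``min(1, p·m)``; order-preserving."""
    ps = list(p_values)
    m = len(ps) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, p * m) for p in ps]


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance threshold α/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Cohen's kappa for paired ratings: κ = (p_o − p_e)/(1 − p_e).

    When chance agreement p_e = 1 (both raters constant on the same
    category) agreement is necessarily perfect and κ = 1 by convention.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValueError("rating vectors differ in length")
    if not a:
        raise ValueError("need at least one pair of ratings")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    cats = set(a) | set(b)
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


# --- rounded-table inversion ----------------------------------------------

def round_half_up_pct(num: int, den: int, decimals: int = 1) -> Fraction:
    """The percentage ``100·num/den`` rounded half-up, as an exact rational."""
    if den <= 0:
        raise ValueError("denominator must be positive")
    scaled = Fraction(100 * num, den) * 10**decimals
    # floor(x + 1/2) is round-half-up for non-negative x
    rounded = (scaled + Fraction(1, 2)).__floor__()
    return Fraction(rounded, 10**decimals)


def _pct_fraction(value: float | str) -> Fraction:
    """Printed percentage (e.g. 70.4) as an exact rational."""
    return Fraction(str(value))


def invert_rounded_table(
    printed: Mapping[str, float] | Sequence[float],
    n_pos: int,
    n_neg: int,
    decimals: int = 1,
) -> list[ConfusionMatrix]:
    """Recover integer confusion matrices from a rounded published table row.

    ``printed`` holds the four percentages (sensitivity, specificity, ppv,
    npv) as printed, rounded half-up to ``decimals`` places; ``n_pos`` and
    ``n_neg`` are the reference-positive and -negative denominators.  Finds
    every integer ``(tp, tn)`` whose four recomputed metrics round back to
    the printed values, exhaustively over the feasible grid.  Raises
    :class:`InversionError` when no solution exists; returns all solutions
    (a unique row gives a one-element list).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("denominators must be positive")
    if isinstance(printed, Mapping):
        se, sp, ppv, npv = (printed[m] for m in METRICS)
    else:
        se, sp, ppv, npv = printed
    se_f, sp_f, ppv_f, npv_f = map(_pct_fraction, (se, sp, ppv, npv))

    tp_candidates = [
        tp for tp in range(n_pos + 1)
        if round_half_up_pct(tp, n_pos, decimals) == se_f
    ]
    tn_candidates = [
        tn for tn in range(n_neg + 1)
        if round_half_up_pct(tn, n_neg, decimals) == sp_f
    ]
    solutions = []
    for tp in tp_candidates:
        for tn in tn_candidates:
            fp, fn = n_neg - tn, n_pos - tp
            if tp + fp > 0 and round_half_up_pct(tp, tp + fp, decimals) != ppv_f:
                continue
            if fn + tn > 0 and round_half_up_pct(tn, fn + tn, decimals) != npv_f:
                continue
            solutions.append(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
    if not solutions:
        raise InversionError(
            f"no integer matrix reproduces printed row {se, sp, ppv, npv} "
            f"with denominators ({n_pos}, {n_neg})"
        )
    return solutions
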
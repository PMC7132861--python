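# poafkit

Detection and validation of **post-operative atrial fibrillation (POAF)**
from hospital administrative data.

POAF — new-onset atrial fibrillation arising between cardiac surgery and
hospital discharge in a patient with no prior AF history — is the most
frequent complication of cardiac surgery. Manual chart review identifies it
reliably but does not scale; discharge abstracts (coded diagnoses and
procedures collected for reimbursement) are cheap and ubiquitous but cannot
time-stamp a diagnosis within a stay. `poafkit` implements and validates the
standard rule-based compromise, for epidemiologists and hospital-quality
teams who need a scalable POAF incidence measure and a way to audit its
accuracy locally.

## The detection rule

A cardiac-surgery hospitalization (index case) is predicted POAF-positive iff

1. its discharge abstract carries an AF **flag code** — ICD-10-CA I48.0
   (paroxysmal), I48.1 (persistent), I48.9 or I48.90 (unspecified) — in any
   diagnosis position, **and**
2. no hospitalization of the same patient discharged within a **look-back
   window** of 1, 3 or 6 years before the index admission carries any AF
   **history code** (the flag codes plus I48.2, chronic AF), **and**
3. (optional *maze recode*) no concomitant maze procedure (CCI 1.HH.59) was
   performed — surgical AF ablation implies pre-existing chronic AF, so such
   patients are recoded negative regardless of diagnosis codes.

Six standard variants cross the window length with the maze recode; a
sensitivity variant restricts the flag set to I48.0/I48.1.

## Validation machinery

Against a chart-review reference standard the package computes Se, Sp, PPV
and NPV with exact Clopper-Pearson 95% CIs (Wilson optional), compares
algorithms pairwise with McNemar's test (Se/Sp) and the
Leisenring-Alonzo-Pepe generalized score test (PPV/NPV), compares disjoint
sites with an unpaired pooled-score z test, applies Bonferroni correction,
and computes Cohen's κ for inter-abstractor agreement. It can also invert a
*rounded published accuracy table* back into the unique integer confusion
matrix that produced it — useful for auditing published validation studies.

Because real discharge-abstract extracts are not shareable, `poafkit` ships
a synthetic cohort generator with known latent truth (chronic-AF prevalence,
POAF incidence by site and surgery type, per-site coding-error rates, rare
maze procedures) and closed-form expected accuracies, so the whole pipeline
is testable end to end.

## Worked example

```python
from poafkit import invert_rounded_table, accuracy_metrics, proportion_ci

# a published row: Se 70.4, Sp 86.0, PPV 71.5, NPV 85.4 (%), with 324
# reference positives and 652 reference negatives
(cm,) = invert_rounded_table((70.4, 86.0, 71.5, 85.4), n_pos=324, n_neg=652)
print(cm)                      # ConfusionMatrix(tp=228, fp=91, fn=96, tn=561)
m = accuracy_metrics(cm)
print(round(m["sensitivity"].point, 4))        # 0.7037
print([round(100*x, 1) for x in proportion_ci(228, 324)])  # [65.1, 75.3]
```

The inversion is exact: (228, 91, 96, 561) is the only integer matrix whose
four metrics round (half-up, one decimal) to that row, and the exact
binomial CI on 228/324 reproduces the printed 65.1–75.3.

End-to-end on synthetic data:

```bash
poaf simulate --n-patients 976 --seed 20100101 --out-dir data/
poaf validate --abstracts data/abstracts.csv \
              --reference data/reference_standard.csv \
              --by-site --compare 5 6 --out table.csv
```

which prints a six-row accuracy table such as

```
Algorithm 5    72.8 (67.5-77.6)   85.0 (82.0-87.6)   69.9 (64.6-74.8)   86.7 (83.8-89.2)
Algorithm 6    72.8 (67.5-77.6)   86.9 (84.1-89.4)   72.8 (67.5-77.6)   86.9 (84.1-89.4)
```

(Se, Sp, PPV, NPV in % with 95% CIs): the 6-year look-back with maze recode
trades no sensitivity for the best PPV on this draw, mirroring the pattern
the rule shows on real data.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch: it reconstructs the
published validation-table rows into integer confusion matrices, recomputes
the exact CIs, then simulates the default 976-patient synthetic world with
the given seed, runs all six algorithms, validates them overall and per
site, and reports the best-performing variants.

## Layout

| module | contents |
|---|---|
| `poafkit.codes` | ICD-10-CA/CCI normalization, `^`-wildcard matching, study code sets |
| `poafkit.dad_io` | discharge-abstract data model, CSV/JSON-Lines IO |
| `poafkit.cohort` | eligibility, exclusions, look-back linkage |
| `poafkit.detect` | the six detection algorithms and variants |
| `poafkit.stats` | accuracy metrics, exact CIs, comparison tests, table inversion |
| `poafkit.simulate` | synthetic DAD generator + closed-form expected accuracies |
| `poafkit.report` / `poafkit.cli` | end-to-end runs, tables, the `poaf` tool |

See `docs/methods.md` for the statistical methods, the generative model and
its limitations.
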
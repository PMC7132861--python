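# Methods

## The detection rule and its failure modes

The algorithms are deterministic functions of one index hospitalization and
its look-back history. The flag set {I48.0, I48.1, I48.9, I48.90} triggers
in **any** diagnosis position (principal or secondary); this is configurable
(`any_position=False` restricts to the principal diagnosis) but the default
reflects how AF is usually coded as a secondary diagnosis of a surgical
stay. I48.9 is retained in the default flag set even though some coding
shops never use the four-character form — fidelity to the stated rule costs
nothing when the code is absent. I48.2 (chronic AF) is **history-only**: it
marks prevalent AF in the look-back but never suggests a new episode.

Two structural blind spots are deliberately preserved, because they are
exactly what a validation of this rule must measure:

- AF codes on the **index** abstract never count as history. A discharge
  abstract cannot place a diagnosis before or after the surgery, so a
  patient whose chronic AF is coded only on the index stay (as I48.0/1/9x)
  is a false positive the rule cannot avoid.
- The look-back only sees hospitalizations at the contributing sites;
  history accrued elsewhere is invisible.

### Look-back window semantics

The window is anchored on the index **admission** date and membership is
tested against the prior visit's **discharge** date, over the half-open
interval `[admission − w years, admission)`. Rationale: a diagnosis code
attaches to a completed hospitalization, and the half-open interval makes
self-matching impossible. Anchoring on the surgery date and/or comparing
admission dates are exposed as options (`anchor=`, `compare=` in
`link_lookback`) since source conventions vary; switching them moves only
visits that straddle the boundary. Calendar years are used (February 29
anchors map to February 28).

Patients with several eligible surgeries in the study window contribute
only their first as the index case.

## Accuracy estimation

Confidence intervals default to **Clopper-Pearson** (exact inversion of the
binomial tails, computed via Beta quantiles; lower bound exactly 0 at 0
successes, upper exactly 1 at n successes). The exact interval is the one
that reproduces published validation rows in this literature; the Wilson
score interval is available (`method="wilson"`) but is narrower (e.g. a
lower bound of 65.2% rather than 65.1% on 228/324). Reported percentages
are rounded **half-up to one decimal**, computed in exact rational
arithmetic from the integer confusion matrix — report cells can never drift
from the counts.

Undefined metrics (zero denominator, e.g. PPV of an algorithm that flags
nobody) propagate as explicit `undefined` markers.

### Paired comparisons

- **Se/Sp**: McNemar's χ² = (b−c)²/(b+c) on the discordant counts within
  reference positives (Se) or negatives (Sp); continuity-corrected and
  exact-binomial variants by flag; b = c = 0 returns p = 1 with a warning.
- **PPV/NPV**: the Leisenring-Alonzo-Pepe generalized score statistic.
  Records are stacked one per (subject × algorithm), restricted to
  test-positive records (PPV) or test-negative records (NPV); disease
  status is regressed on an algorithm indicator with an intercept under a
  working-independence marginal model, and the score for the indicator is
  studentized with an empirical (sandwich) variance that respects
  within-subject clustering: with null fit `p̂ = mean(D)` and indicator mean
  `z̄`, per-subject scores are `Uᵢ = Σⱼ (z_ij − z̄)(Dᵢ − p̂)` and
  `T = (ΣUᵢ)²/ΣUᵢ² ~ χ²₁`. Identical predictions give T = 0, p = 1. The
  test suite checks the implementation against an independently coded
  brute-force evaluation and verifies a ~5% type-I error over 2000 seeded
  null replicates at n = 500.

### Between-site comparisons

Sites contain disjoint patients, so no paired structure exists and a
McNemar-type test is undefined; the package uses the two-sample
pooled-variance score (z) test (Fisher's exact by flag). This is a
documented divergence from practice that applies "McNemar's test" loosely
to site contrasts — no paired mode is offered because none is computable.

**Bonferroni** m defaults to the number of comparisons actually performed
within each metric family and is overridable; adjusted p-values are capped
at 1.

### Rounded-table inversion

`invert_rounded_table` searches the integer grid `(tp, tn)` ∈
`[0, n_pos] × [0, n_neg]` for matrices whose four metrics round (half-up,
one decimal, exact rational arithmetic) to the printed row; it returns all
solutions and errors on none. Candidate `tp` and `tn` are pre-filtered by
the Se and Sp cells, so the search over the feasible set is exact yet runs
in milliseconds at validation-study scale.

## The synthetic world

The generator emulates a two-site cardiac-surgery validation cohort:

| parameter | default | basis |
|---|---|---|
| site weights | A 0.49 / B 0.51 | observed site split |
| surgery mix (CABG/valve/mixed) | A .420/.311/.269; B .515/.288/.197 | observed mix |
| POAF incidence by surgery | A .294/.349/.488; B .316/.259/.327 | observed incidence (overall ≈ 33.2%) |
| chronic-AF prevalence `h` | 0.10 | plausible for a surgical cohort aged ~68; not directly observable |
| maze ∣ chronic AF | 0.32 | calibrated so overall maze ≈ h·0.32 = 3.2% |
| prior hospitalizations | Poisson(1.2) per 6 years, dates uniform | consistent with a median of 0 in the prior 12 months |
| `p_code_given_poaf` | A 0.63, B 0.80 | illustrative; reproduces the observed inter-site sensitivity gap |
| `p_code_given_chronic` | 0.50 | illustrative |
| `p_false_code` | A 0.08, B 0.125 | illustrative; puts Sp near 88%/84.5% |
| `p_history_coded_per_prior_hosp` | 0.30 | illustrative |
| `p_false_history_per_prior_hosp` | 0.01 | illustrative |

Latent structure: chronic AF `H` ~ Bern(h); POAF `D` is drawn only when
`H = 0`, with `P(D=1 | H=0) = π/(1−h)` so the *marginal* reference-positive
probability equals the configured incidence π. The reference standard is
`D` — new-onset POAF requires no AF history, and transient POAF counted
negative by chart review is absorbed into `p_code_given_poaf < 1` rather
than modeled separately. Maze procedures occur only among chronic-AF
patients. Coded flag codes are drawn uniformly from {I48.0, I48.1, I48.90}
(I48.9 unused, matching observed coding practice); chronic history is coded
as I48.2 on prior stays; false history uses the flag codes. All randomness
flows from one `numpy` generator seeded by `SimulationConfig.seed`; outputs
are byte-identical across runs.

### Closed-form expected accuracies

With Poisson(λ) prior hospitalizations, uniform dates and window fraction
`w/6`, the probability that no independently coded history event (per-visit
probability p) lands in the window is `E[(1 − p·w/6)^N] = exp(−λ·p·w/6)`.
Writing `f` for the share of coded flag codes inside the algorithm's flag
set (1 for the default set, 2/3 for the restricted variant):

- `Se = p_code_given_poaf · f · exp(−λ_w · p_false_history)`
- false-positive rate among chronic patients:
  `p_code_given_chronic · f · exp(−λ_w · p_history_coded) · (1 − maze∣chronic if maze recode)`
- false-positive rate among AF-free patients:
  `p_false_code · f · exp(−λ_w · p_false_history)`

Joint (reference, prediction) cell probabilities are mixed over surgery
classes and sites; PPV/NPV follow from the cells (equivalently, Bayes'
theorem at the cohort prevalence). The window fraction ignores leap-day
effects (< 0.1% of λ_w, far below Monte-Carlo resolution at n = 50,000).
The acceptance suite verifies simulated accuracies at n = 50,000 against
these forms within 3 Monte-Carlo standard errors for all four metrics.

### What a green test does not establish

The generator's coding model is conditionally independent per
hospitalization and per patient; real coding errors are correlated (coder
habits, reimbursement incentives, epoch effects), real prior-hospitalization
counts are over-dispersed, and real chronic-AF prevalence varies by age and
surgery type. Green tests establish the *machinery* — rule semantics,
linkage, estimation, inference — not that the default coding rates describe
any real institution; the per-site rates are explicitly illustrative.

## Numerical and design choices

- Exact rational arithmetic (`fractions.Fraction`) wherever rounding or a
  Bayes-consistency identity is asserted; floats elsewhere.
- `select_best` tie-break: fewest look-back years, then lowest algorithm
  index; `prefer_longest_lookback=True` flips the first key (an equally
  sensitive rule with a longer history search has fewer latent false
  positives, which some analysts prefer).
- Maze matching is stem-based (`1HH59` matches `1HH59LA`) because published
  code lists print the family stem; `maze_exact=True` requires equality.
- Unknown or ill-formed codes are kept verbatim after normalization rather
  than rejected — administrative extracts always contain codes outside the
  study universe, and they simply never match a code set.
- Exclusions (`apply_exclusions`) partition the input exactly:
  `|retained| + |log| = |input|`, with one reason per removal; the
  reference file is authoritative for intra-operative deaths, which
  administrative data cannot distinguish from post-operative ones.
- Missing reference records are an error by default (`"drop"`/`"keep"`
  policies available); the CLI uses `"drop"` for robustness on partial
  extracts.

## Known limitations

- No ICD-9 mapping, no code-validity dictionary, no Quebec diagnosis-type
  prefixes (not used by the rule).
- No probabilistic or NLP-augmented phenotype; the rule is binary, so no
  ROC machinery.
- The site comparison is unpaired by necessity (see above); with
  validation-study sample sizes it is underpowered for Sp/PPV contrasts.
- Simulated lengths of stay, ages and non-AF codes are schematic — they
  exist to exercise linkage and wildcard matching, not to mimic case-mix.
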
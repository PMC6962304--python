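# Methods

## The task

`mouseprl` models a staged two-lever probabilistic reversal learning (PRL)
task for mice. Two retractable levers (front/back) pay off with high/low
probabilities; after a performance criterion is met the roles reverse, and
the contingencies are then made progressively noisier. The staged schedule
is 80:20 learning → 80:20 reversal → 70:30 learning → 70:30 reversal →
60:40 learning → 60:40 reversal, with daily 100-trial sessions.

Two distinct "reversal" notions coexist and are kept separate in the code:

* **Within-session rule** (traditional PRL, `count_within_session_reversals`):
  eight consecutive non-omitted choices of the currently high-value lever
  trigger an immediate role swap; the consecutive counter resets on a
  low-lever choice, on an omission (default; exposed as
  `omission_resets_run`), and after each swap.
* **Between-session criterion** (the staged task, `evaluate_criterion`):
  the most recent two sessions must each contain at least 60 responses and a
  fraction of high-lever presses *strictly* greater than 0.80, omissions
  excluded from numerator and denominator. "Greater than 80%" is read
  literally: exactly 80.0% fails. Only the most recent `n_sessions`
  sessions are examined, matching a progression rule ("until two sessions
  …") rather than an any-two-sessions rule.

Sessions and trials are 0-based internally and 1-based in reports
(`days_to_criterion` returns the 1-based session count). Trial timing
(10 s response window, 10 s ITI, 0.5 s reward delay) is metadata only;
nothing is simulated in real time.

## Chance-level reversal statistics (`chance`)

Random responding is modelled as i.i.d. fair binary choices with no
omissions; reward outcomes are irrelevant to reversal counting under the
within-session rule and are not simulated. Three routes compute the
reversal-count distribution:

1. **Monte-Carlo** (`simulate_reversal_counts`): vectorised across sessions,
   chunked to ~64 MB of choice matrix; probabilities are reported with the
   binomial standard error √(p(1−p)/n).
2. **Exhaustive enumeration** (`exact_reversal_distribution`): all 2^L
   sequences for L ≤ 20; the oracle for the Monte-Carlo path at small L.
3. **Markov chain** (`exact_tail_probability`): exact tail probabilities at
   any session length. By symmetry of fair choices the probability of
   matching the *current* high side is ½ at every trial regardless of past
   swaps, so the pair (consecutive-match counter, reversal count) is a
   time-homogeneous Markov chain that can be propagated exactly.

Exact values under this rule: P(≥3 reversals | 200 trials) = 0.5908%,
P(≥6 | 600) = 0.1034%, P(≥1 | 400) = 54.27%, P(≥2 | 400) = 18.03%.
Published reference values for the first, third and fourth (0.55%, 55%,
18%) agree to within a few percent relative; the 600-trial figure is
commonly quoted as 0.076%, which this rule does not reproduce (nor does the
point probability P(=6|600) = 0.088%); the quoted value plausibly reflects
a finite simulation or a slightly different reset convention in the
original code. The package reports what the rule actually implies.

The expected-reversals curve is computed in one pass: simulate sessions of
the maximal length and record the running mean after every trial — prefixes
of i.i.d. sequences are themselves i.i.d. sessions of the shorter length.
The curve is linear beyond a short burn-in with slope 1 per 2^9 − 2 = 510
trials (the mean waiting time for a run of 8 successes at p = ½); the exact
mean at 510 trials is 0.9882.

## Choice models (`models`)

Four nested delta-rule models over per-lever values V_f, V_b with a softmax
choice rule:

    P_f(t) = 1 / (1 + exp(−[β (V_f − V_b) + δ (C_f − C_b)]))
    V_chosen ← V_chosen + α_eff (R − V_chosen),   R ∈ {0, 1}

| variant       | free parameters            | k |
|---------------|----------------------------|---|
| `single`      | α, β                       | 2 |
| `dual`        | α_pos, α_neg, β            | 3 |
| `persev`      | α, β, δ                    | 3 |
| `persev_dual` | α_pos, α_neg, β, δ         | 4 |

Dual variants use α_pos when R ≥ V_chosen and α_neg when R < V_chosen (the
boundary goes to α_pos; it is inert anyway since the error is zero there).
C_f, C_b are previous-choice indicators; positive δ favours repeating the
previous side (perseveration), negative δ favours alternation. **Sign
convention**: some typesettings of this choice rule place δ(C_f−C_b) with a
sign that would make positive δ mean alternation, contradicting its stated
interpretation; this package uses the exponent −[β(V_f−V_b) + δ(C_f−C_b)]
throughout, so that positive δ = perseveration, consistent with the
dynamic-foraging literature the model descends from.

Values are initialised to 1 at the start of each subject's record (animals
enter testing from continuous-reinforcement training, i.e. an expectation
of certain reward) and are carried across sessions and phases. The
likelihood is compounded across all trials of the record. Omissions
contribute no likelihood term and no value update, and clear the choice
indicators; indicators are also cleared at session boundaries (overnight
gap). Both conventions are flags (`omission_clears_indicators`,
`reset_indicators_between_sessions`) because the underlying protocols
rarely state them; the defaults are the conservative readings.

Probabilities are clamped to [1e−300, 1−1e−15] so log-likelihoods are
always finite; the −log P term is computed as log1p(exp(z)) with a linear
branch for z > 35 to avoid overflow. The trial loop is sequential by
nature, so the likelihood and agent-simulation cores are numba-compiled
(pure-Python fallback if numba is unavailable); the compiled and the
step-by-step Python paths are checked against each other in the tests.

## Fitting (`fitting`)

Per-subject maximum likelihood with `scipy.optimize.minimize` (L-BFGS-B)
in an unconstrained space: each bounded parameter is mapped through a
scaled logit, which conditions the search when optima sit near bounds
(α’s of order 10⁻²). Default bounds: α ∈ [10⁻⁵, 1], β ∈ [0, 50],
δ ∈ [−10, 10] — wide margins around typical rodent estimates. `n_starts`
(default 20) uniform random restarts are drawn within bounds from the seed,
row-major so that smaller restart counts use a prefix of larger ones;
the best converged optimum wins, and a fit where no start converges is
returned with `converged=False` rather than dropped. Estimates within
10⁻³ of a bound (relative to its width) are flagged in `at_bounds`.
Everything is deterministic given (seed, n_starts, optimizer settings).

AIC = 2k + 2·NLL; comparison ties break toward fewer parameters. AIC is
the selection statistic; no small-sample correction is applied (n ≈ 10³
trials per subject makes AICc indistinguishable).

`parameter_recovery` simulates agents from known parameters (fixed, or
drawn per subject), refits them, and reports per-parameter bias, spread and
Spearman rank correlation. The hidden truths never enter the fitting path.

## Synthetic cohorts (`cohort`)

The generator stands in for unavailable animal data and defines the study
conditions for every downstream test:

* 12 subjects, 100-trial sessions, the six-phase staged schedule with the
  60-response/80% two-session criterion and a 40-session cap per phase
  (caps are a tractability choice; protocols rarely print them).
* Generative parameters per subject from independent truncated normals
  centred on published population estimates of the full model
  (α_pos = 0.00923, α_neg = 0.0282, β = 3.275, δ = 0.744). Spreads are
  across-animal standard deviations back-derived from the published
  across-animal 95% CIs: sd = halfwidth/1.96 × √10 (10 animals), giving
  0.0037, 0.028, 1.25, 0.347 respectively. The large relative spread of
  α_neg is a real feature of the published cohort (variance in learning
  from losses far exceeds that in learning from wins).
* Omissions i.i.d. at 2% per trial (omission counts are reported in such
  studies without a mechanism; a small i.i.d. rate reproduces their order
  of magnitude).
* A subject failing a phase's criterion within the cap contributes no
  later-phase data, mirroring the gated progression.
* Seeding: a master `SeedSequence` is spawned per subject, so subject i's
  record is independent of the cohort size.

With these defaults the attrition gradient is monotone and steep
(e.g. 12 → 8 → 8 → 4 → 2 → 0 at seed 1), qualitatively matching the
published pattern (12/10/7/4/3/2) though with more first-phase failures:
the truncated normals include weak learners that a real lab would already
have dropped during lever training (the study started from 16 animals).
Days-to-criterion on 80:20 learning averages ~10 sessions here against a
published mean of 14 — the same order, which is all the generator is
designed to reproduce. What passing tests on this cohort show is that the
*pipeline* (criterion gating, likelihoods, optimisation, model selection)
behaves correctly on data with the study's structure; they cannot show
that real mice obey these models, and the generator deliberately omits
response latencies, satiation/within-session drift, day-to-day parameter
drift, and any meta-learning across reversals.

## Reporting (`reporting`)

* **Wilcoxon signed-rank** (α_pos vs α_neg, paired within subject):
  zero differences dropped, tied |differences| midranked; for n ≤ 25 the
  p-value is exact, computed by dynamic programming over doubled ranks
  (integers even under midranks) — scipy's exact method does not handle
  ties, so the null distribution is built here and scipy serves as the
  large-n fallback and a tie-free cross-check. Two-sided p =
  2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)), capped at 1.
* **Choice smoothing**: centred 25-point moving average over non-omitted
  trials; edges use a shrinking window (bounded output), with a strict
  mode (`shrink_edges=False`) that yields NaN where the full window does
  not fit. Whether the original figures used centred or trailing windows
  is unknowable from the protocols; centred is the package's choice.
* **Value traces** replay the likelihood pass and emit per-trial V beside
  the schedule's true reward probabilities; `chosen_value_bias` is the
  time-averaged (V_chosen − p_chosen) after a 200-press burn-in. Its sign
  diagnoses the learning-rate asymmetry: α_pos ≫ α_neg inflates values,
  α_neg ≫ α_pos deflates them, and a single rate tracks p to within ±0.1
  on long stationary blocks.
* **Days to criterion** across phases is summarised descriptively
  (mean, sd, normal 95% CI over subjects). Repeated-measures mixed-model
  analysis of progression (REML with subject intercepts) is deliberately
  out of scope — use `statsmodels.formula.api.mixedlm` or R `lme4` on the
  exported `days_to_criterion.csv` if needed.

## Problem sizes

Defaults used by the analysis drivers and tests: chance probabilities at
10⁶ sessions per condition in the acceptance script (10⁵ for smoke tests),
recovery studies with 12 subjects × 5,000 trials (50 sessions of 100 over
an alternating 80:20 block schedule without criterion gating, so the trial
count is guaranteed), model-selection recovery over 20 replicates with
well-separated rates (α_pos = 0.05, α_neg = 0.25, δ = 0.744). These sizes
make every result reproducible on a single CPU in minutes while leaving
Monte-Carlo error well below the effect sizes under test.

## Known limitations

* The chance simulation's 600-trial tail probability does not match the
  commonly quoted 0.076% (see above); the exact value under the stated
  rule is 0.103%.
* Point MLE only: no standard errors or posterior uncertainty per subject;
  population spread is across-subject dispersion of point estimates.
* α is weakly identified when β is very large (near-greedy choice) or when
  a phase never reverses; recovery reports flag this via rank correlation
  and boundary hits rather than hiding it.
* The cohort generator's attrition is steeper than the published cohort's
  at the first phase (see above).
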
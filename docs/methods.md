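# Methods

This note records the models, conventions and numerical choices behind
`dietval`, and what the synthetic-data experiments do and do not show.

## Intake model

A consumption record is one item (food, standard recipe, or non-standard
recipe) for one respondent from one source (WFR or 24HR). Quantities are
either direct grams (always the case for the weighed record) or a portion
size estimation method (PSEM) reference — a (psem_code, unit_code,
size_label) key into the portion-factor table times a possibly fractional
number of units (e.g. half a small bowl).

Recipe nutrient density per 100 g prepared is
`100 · Σ(ingredient_g · composition/100) / total_prepared_g`, i.e. strict
nutrient conservation: no cooking retention or yield factors are applied
(none are part of the supported reference-data schema). Non-standard
recipes use exactly the same formula on their inline ingredient lists.

**Missing composition values.** A blank food-composition cell is a missing
flag, never a zero. Missing values contribute 0 to every sum and propagate
the flag, so a daily total whose flag is set is a lower bound; per-nutrient
FCT completeness (share of consumed foods with a value) is reported
alongside results instead of imputing. Energy is stored in kcal; kJ is a
derived view at 4.184 kJ/kcal.

**Food-group attribution.** A mixed dish's whole energy is credited to one
GIFT group: the dish's own group when the recipe metadata assigns one,
otherwise the group of the ingredient contributing the most energy. Energy
is not disaggregated to ingredients; this is a convention (items are
classified as consumed), kept configurable via the optional `gift_group`
column in `recipe_meta.csv`.

## Quality control

Daily energy plausibility bounds are < 500 kcal and > 5000 kcal, both
strict (a day at exactly 500 kcal passes), applied to both sources; the
pair-discrepancy screen flags |24HR − WFR| > 1000 kcal. The default
exclusion policy drops a respondent only when their *weighed* day is
implausible — the benchmark itself is then untrustworthy — while
pair-discrepancy flags are logged and the respondents retained. Both the
flag sources and the excluding flags are policy-configurable.

Transform selection for skewed intake distributions is zero-driven: natural
log when every value is positive, cube root when zeros occur (log is
undefined at 0). Normality screening is a reported diagnostic, not the
selection rule, because a zero-driven rule is deterministic and both
transforms are strictly increasing (ranks and band membership are
preserved either way).

## Validation statistics

**TOST equivalence.** d_i = ln 24HR_i − ln WFR_i; the 10 % bound is the
*symmetric* log-scale margin ±ln(1.1) around zero. The asymmetric
alternative (ln 0.9, ln 1.1) was rejected: a ratio bound "within 10 %"
reads most naturally as a bound on the geometric-mean ratio in either
direction, and symmetry makes the test invariant to swapping the two
methods. p = max of the two one-sided t p-values; p < 0.05 declares
equivalence. Pairs with a zero on either side are excluded from that
nutrient's log-scale test and tallied (`n_zero_excluded`). With zero
variance the decision is exact: p = 0 if |d̄| < θ else 1.

**Difference-in-differences.** Fitted as the stacked mixed model
`value ~ is_wfr * is_capi` with a respondent random intercept (REML,
Powell optimiser — it reaches the REML optimum tightly enough that the
closed-form agreement below holds to ~1e-8, where the default gradient
optimisers stop at ~5e-6). The p-value uses a t reference with
(respondents − 2) degrees of freedom. For complete pairs with the
between-respondent variance component in the interior of the parameter
space — the generic situation in intake data, where consumption levels
vary across respondents much more than within-pair recall error — the
estimate and p-value coincide with a pooled two-sample t test on
per-respondent (WFR − 24HR) differences; that closed form is the test
oracle. When the variance component is estimated at its zero boundary the
model-based SE legitimately differs from the pooled-t SE. Degenerate
inputs (zero pooled variance, e.g. noise-free simulations) get an exact
decision; a numerically singular fit falls back to the closed form. DiD is
computed on the untransformed scale (differences are reported in kcal/g).

**Error bands** are boundary-inclusive (an error of exactly ±10 % counts
as within ±10 %); the within-band shares are non-decreasing in band width
and within-widest + over + under = 100 exactly. A zero WFR value makes the
percentage error undefined and is an error at the operation level; the
report builder drops such pairs and tallies them.

**Food-group comparison** uses the Wilcoxon *signed-rank* test on
within-respondent share differences — the paired design wins over naming
conventions that suggest a rank-sum test. Zero differences are dropped;
the exact null distribution is used for ≤ 25 untied nonzero pairs and the
continuity-corrected normal approximation otherwise. P-values are
suppressed (but medians still reported) for groups consumed by < 10 % of
respondents under either method, where small numbers make the test
unreliable.

**Sample size.** n = ⌈((z₁₋α/2 + z_power)/q)² + 3⌉, q = atanh ρ₁ −
atanh ρ₀. Defaults (ρ₀ = 0.6, ρ₁ = 0.75, α = 0.05, power = 0.8) give 104
per arm. Non-response inflation is ⌈n(1 + f)⌉ with f = 0.125 by default,
giving 117; dividing by the response rate (104/0.88 ≈ 119) is a defensible
alternative, so the rule is a parameter. The formula is cross-checked by
brute-force simulation (bivariate normal draws, Fisher-z test of ρ = ρ₀),
which yields empirical power ≈ 0.80–0.82 at n = 104.

## Cost-effectiveness

Costs are itemised by modality × activity × category; time items carry
person-days valued at wages (respondent time at the minimum wage), and
total = time + non-time holds as a partition identity. Accuracy is
computed on *group means* (ratio of averages, not the average of
per-respondent ratios), read directly from the defining formula; the error
is capped at 100 % so accuracy stays in [0, 100] and cost-per-point ratios
remain defined. Borrowing scenarios scale only the CAPI
reference-data-preparation quantities by (1 − fraction), leave PAPI
untouched, and hold accuracy fixed — so CAPI ratios weakly improve in the
borrowed fraction while PAPI's are constant. Ledgers are single-currency;
any currency conversion or inflation adjustment happens upstream.

## Synthetic studies

The generator emulates a two-arm validation study: respondents alternate
deterministically between CAPI and PAPI (one modality each, balancing the
arms as randomisation would in expectation); each contributes one weighed
day, taken as truth, and one recall day derived from it conditionally —
all downstream statistics are paired, so the error must be generated
conditionally on the truth, not independently.

Default study conditions: 116/115 respondents per arm; a 40-food menu over
11 GIFT groups with cereal-heavy sampling weights and portion sizes chosen
so a typical ~8-item day lands near 2200–2500 kcal for adult women with
roughly two-thirds of energy from cereals; omission probability 0.10 per
item, 0.05 expected intrusions per item, mean-one lognormal portion error
with CV 0.25, recipe-substitution probability 0.05, and 3 % of respondents'
weighed days rescaled past a plausibility bound (exercising the QC path;
a few additional days fall outside the bounds naturally). 30 % of recall
quantities are re-expressed through portion-factor units rather than
direct grams, exercising the PSEM path without changing the amounts.

Parameter recovery holds by construction and is verified end-to-end: with
all error channels off, the recall day equals the weighed day, so the
pipeline must report 100 % accuracy on every measure, universal
equivalence, and everyone within the ±10 % band; with a pure multiplicative
portion bias b, group-level gram accuracy is exactly 100 − 100·|1 − b|;
with portion CV > 0 the recovery holds within Monte-Carlo error; a 30 %
bias (far beyond the 10 % bound) is declared non-equivalent for energy in
essentially every seeded study at 111/arm.

**What the generator does not model:** intra-household food allocation,
seasonality, day-of-week effects, interviewer effects, correlated
omission (e.g. systematically forgotten snacks), usual-intake
(multi-day) variance structure, or cooking retention losses. Passing
tests therefore certify the statistical machinery and its contracts on
data with a known, simple error structure — not the field accuracy of any
particular instrument.

## Determinism and problem sizes

All randomness flows from a single seed through named child streams
(bundle, records, ledger), so a seed reproduces every output byte for
byte. The simulation experiments use the study-scale sizes they describe
(231 respondents; 200 seeded replicate studies for the bias-detection
rate; 10 000 replicates for the power simulation) and complete in well
under a minute each on one CPU.
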
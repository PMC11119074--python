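# Methods

## The instrument and its score space

Pharm-CAT assesses how much work a sponsored oncology or haematology trial
will create for the pharmacy service. It has 15 items in three sections
(study design: items 1–5; drug management: 6–11; drug preparation: 12–15).
Each item offers a fixed set of scored levels; the level sets are not
uniform — items 3, 4, 5, 7, 12, 13 offer 1/2/3 points, item 1 offers 1/3,
items 2 and 6 offer 2/3, item 8 offers 1/2, items 9–11 offer 1/3, item 14
offers 0/2/3 and item 15 offers 0/3. The trial's complexity score is the
plain sum of the item scores, so the default instrument spans 15–44 points
and, because some level sets are gapped, `achievable_totals` (a
subset-sum dynamic program, verified against exhaustive enumeration in the
tests) reports exactly which totals are reachable rather than assuming all
integers in the bounds are.

Instruments are data. The default instrument is a packaged JSON config and
`load_instrument` accepts any config of the same shape, so a service can
add, drop or re-level items without touching code. One description of
item 1 is internally ambiguous in the source material — prose suggests
1/2/3 points, the operative item table lists only 1 and 3 — and this
package follows the item table; a config restoring {1, 2, 3} is a two-line
edit for anyone who prefers the other reading.

**Phase consistency.** Item 1 is fully determined by the trial phase
(3 points for phase I, 1 otherwise), so a mismatch between the recorded
phase and the item-1 score is a validation violation by default.
`validate_assessment(..., check_phase_item=False)` relaxes this for data
whose phase metadata is unreliable. The check disables itself on modified
instruments whose item 1 no longer has the {1, 3} level set. Missing or
duplicate responses are always violations; nothing is imputed.

## Category cut-offs

Cut-offs come from the empirical score distribution: sort the n scores
ascending and take the order statistics at ranks ⌈n/3⌉ and ⌈2n/3⌉ as the
inclusive upper bounds of *low* and *medium*. "Tertile" does not pin down
a quantile convention; this one was chosen because it is deterministic
under ties, returns observed (hence integer) scores as boundaries, and for
n = 120 agrees with the common conventions. If the two boundaries
coincide, the distribution cannot support three categories and
`derive_cutoffs` raises rather than silently collapsing categories; fewer
than 3 scores is likewise an error.

`categorize` accepts any non-negative total, including totals below the
instrument minimum (the published category description itself starts low
at 0); whether a total is achievable is a validation question, not a
categorization one. The published reference boundaries (19, 25) are
packaged as `study_cutoffs()` — a constant, since the 120 raw scores they
were derived from were never published.

## Agreement statistics

Paired totals (two raters per trial) yield: the share of pairs with equal
totals, the histogram and mean of |Δ|, the 3×3 cross-classification of
categories, and Cohen's linear weighted kappa. Kappa uses disagreement
weights w(i,j) = |i−j|/(k−1) and κ = 1 − Σwp/Σwe with e from the margins'
product; the agreement-weight formulation is algebraically identical. The
tests pin κ to an independent implementation (scikit-learn's
`cohen_kappa_score(weights="linear")`) to 1e−12 on 1,000 random tables and
to a hand-evaluated table.

Kappa is computed on the three categories, the scale the instrument is
actually used on once cut-offs exist; `raw_score_kappa` offers a
sensitivity analysis that treats each observed total as its own ordinal
level (rank distance, not point distance, drives the weights). When both
raters place every trial in one single category the denominator Σwe is
zero and kappa is undefined; the report then carries
`kappa_defined = False` instead of a number, and the exception flags that
agreement was nonetheless perfect. Exactly two raters are supported.

Displayed percentages and means are rounded half-up to 2 decimals
(`percent_exact` also at 0 decimals, since exact concordance is usually
quoted as a whole percentage); full precision is kept internally.

## Synthetic cohorts

The real assessment data are unavailable, so `synthetic` generates
cohorts with the development study's statistical fingerprint. The default
config has 60 trials split 40/20 across two centres, 39 oncology / 21
haematology, 6/18/36 in phases I/II/III. Metadata counts are allocated by
largest-remainder rounding (so the margins are exact, not
multinomial-approximate) and shuffled across trials independently per
column.

Rater A draws each item response from a per-item categorical distribution
over the allowed levels; the phase item is deterministic given the phase.
The default distributions are a calibration choice, not data: they were
set once so the expected total is 22.9 points (matching the development
cohort's mean of 22.88) and reflect a plausible sponsored-trial portfolio
(mostly injectable drugs, single-drug regimens, standard storage). Rater B
copies rater A's form and perturbs each non-phase item independently with
probability `p_perturb` to an adjacent allowed level (uniformly up or
down). The phase item is never perturbed: phase is objective. The default
`p_perturb` = 0.0185 solves (1−p)¹⁴ = 0.77, the closed-form probability
that none of the 14 perturbable items moves — i.e. the study's 77% exact
agreement; `expected_percent_exact` exposes the formula. It ignores the
O(p²) chance that two perturbations cancel in the total, so simulations
sit slightly above it (≈ 78% over 200 seeds).

All variates are pre-drawn as matrices from one seeded generator, which
makes generation reproducible byte-for-byte and gives common random
numbers across `p_perturb`: for a fixed seed the set of perturbed items
grows monotonically with p, which is what the monotonicity test exploits.
Seeds are mandatory — there is no silent global randomness.

What the generator does *not* emulate: correlation between items (real
trials have structure — e.g. blinded trials cluster with IWRS treatment
assignment), phase- or type-conditional item distributions beyond the
phase item itself, rater-specific bias, and the single 4-point
discrepancy observed in the development cohort (attainable here only as
two coinciding 2-point flips). Passing tests therefore demonstrate that
the statistical machinery is correct, not that real cohorts will
reproduce the published summary numbers.

## Reporting

`summarize_cohort` reproduces the development study's results-table shape:
a total row, then centre, trial-type and phase strata, each with n, share
of cohort, mean score and within-stratum category percentages. A
dual-rated cohort must first collapse to one value per trial; how the
original study did this is unstated, so the rule is explicit:
`rater_a` (default, first-listed rater), `mean_floor`, `max`, or
`per_score` (no collapsing — every score its own unit, the mode in which
a 60-trial cohort summarises 120 scores, and the likely reading of the
published 22.88 mean "of 120 scores"). Rules needing pairs raise on
trials with ≠ 2 raters.

## Numerical and interface choices

- Rounding for display: half-up via `decimal`, never banker's rounding.
- Parse errors in CSV/JSON inputs name the 1-based row (header = row 1)
  and column; enum fields list the accepted values.
- Problem sizes in the tests: the exhaustive score-space enumeration
  covers all 559,872 level combinations; kappa is cross-checked on 1,000
  random tables; cut-off properties on 1,000 random vectors; generator
  calibration and monotonicity on 200 seeds per point of a 5-point
  p-grid. These sizes make every check deterministic and re-runnable in
  seconds.
- The CLI is a thin shell over the library; the library API plus the
  `examples/` scripts are the primary interface.

## Known limitations

- The published cut-offs are constants here; nothing in this package can
  re-derive them without the unpublished raw scores.
- Calibration targets of the generator (mean ≈ 22.9, exact agreement
  ≈ 77%) are inputs to the simulation design, not evidence about the
  instrument; treating them as validation would be circular.
- Exactly two raters; no confidence intervals or hypothesis tests for
  kappa; no translation of scores into grant amounts.
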
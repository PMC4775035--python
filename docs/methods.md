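# Methods

## Model

Two raters independently classify the same N_u coding units against a
shared, ordered set of N_c categories. A rater's output is a membership
table: row i holds the grades mu_j(u_i) in [0, 1] expressing how
strongly unit i belongs to category j. One-to-one coding is the special
case of one-hot rows; one-to-many coding produces graded rows, by
default normalized to sum 1 (a unit's "strength" is divided among its
categories). The normalization is a convention, not a requirement of
the method: the pass-through builder accepts arbitrary grades (e.g.
database relevance percentages rescaled to [0, 1]) and only records a
warning when a row exceeds sum 1, since observed agreement can then
leave [0, 1].

Agreement is chance-corrected:

    kappa = (P_o - P_E) / (1 - P_E)

### Observed agreement

The crisp observed agreement is the fraction of units with identical
rows, equivalently the mean row scalar product of the two one-hot
tables. Fuzzily, the product is replaced by a t-norm T — commutative,
monotone, with identity 1 and annihilator 0 — applied elementwise:

    P_o = (1/N_u) sum_i sum_j T(mu1_ij, mu2_ij)

Three t-norms are implemented: `min(a,b)`, `product(a*b)` and the
Łukasiewicz norm `max(0, a+b-1)`. They are pointwise ordered
(luka <= product <= min), and the same ordering transfers to P_o and
P_E. The default is `min`, the choice recommended in prior fuzzy-kappa
work on image classification; it is also the only norm for which
row-normalized tables guarantee P_o in [0, 1] and P_o = 1 iff the
tables are identical.

### Expected agreement

Crisp chance agreement is sum_j (A_j/N_u)(B_j/N_u) over the raters'
marginal category frequencies. The fuzzy generalization treats each
rater's column j as an empirical distribution over its distinct
membership *levels* (level 0 included) and sums

    P_E = sum_j sum_{v1} sum_{v2} P1_j(v1) P2_j(v2) T(v1, v2)

over the observed levels only — zero-probability levels contribute
nothing, so the cost is O(N_c * L1 * L2) with L typically <= 5. This
"level distribution" reading is the unique one that (a) reduces exactly
to the crisp formula on one-hot tables, where levels are {0, 1}, and
(b) satisfies the two-tier identity below, which reproduces the
published integrated indices of the Russia photograph study
(P_o 0.90, P_E 0.53, kappa 0.79) from its nine per-dimension values.

Fuzzy pi replaces both raters' level distributions with their average
(P1_j(v) + P2_j(v))/2, mirroring Scott's pi; on one-hot input it equals
Scott's pi, and when the raters' distributions coincide it equals fuzzy
kappa.

Level tallies use exact float equality. This is safe because the
builders emit exact repeated values — the same 1/k or w_r/sum(w) float
for every occurrence — so a level never splits into two bins by
floating noise. Externally supplied grades are tallied as given.

### Undefined kappa

When P_E = 1 (both raters constant on the same category) the chance
correction is 0/0. The result object then carries `kappa = None` with
`observed` still populated; it is never silently coerced to 0 or 1,
and bootstrap replicates hitting this case are dropped and counted.

## Membership schemes

* **one-hot** — crisp coding; the identity link to the classical indices.
* **equal split** — a unit's k ranked selections each get 1/k; rank
  order is ignored.
* **rank-weighted** — a strictly positive, non-increasing weight vector
  (e.g. 4, 3, 2, 1) is truncated to each unit's k selections and
  normalized to sum 1, so rank r gets w_r/sum(w_1..w_k). Normalizing
  per unit keeps every row sum at 1 and therefore keeps weighted and
  equal-split kappas on the same scale; with constant weights the two
  schemes coincide exactly.
* **two-tier expansion** — a one-to-one sheet over D first-tier
  dimensions becomes a membership table over the concatenation of all
  second-tier levels ("not present" is a real level and is retained),
  with grade 1/D on the selected level of each dimension. Because every
  nonzero grade is 1/D and min(1/D, 1/D) = 1/D, both fuzzy P_o and
  fuzzy P_E under `min` equal the mean of the D per-dimension crisp
  values — the *two-tier identity*, asserted property-style in the
  tests and exposed as `two_tier_integrated` for integrating published
  per-dimension components.

Category order always comes from the shared CategorySet, never from
per-sheet appearance order, so both raters' tables align column-wise;
categories unused by either rater contribute nothing, making all
indices invariant to padding the category set.

## Bootstrap

Coding units are the exchangeable entity in every formula, so the
confidence interval resamples unit indices with replacement and carries
both raters' rows together, preserving the within-unit dependence that
the statistic measures. The percentile method was chosen over BCa for
transparency and testability; defaults are B = 1000 replicates at the
95% level with a seeded generator (same seed, bit-identical interval).
A Monte-Carlo study in the test suite (copy model, n = 500 units, 500
repetitions, B = 1000) checks that empirical coverage of the true kappa
stays within [0.92, 0.975] at the nominal 0.95. Percentile intervals
are not guaranteed to contain the point estimate; the contract is
low <= high with both in [-1, 1].

## Synthetic coder models

**Copy model (crisp).** Rater 1 draws each unit's category from fixed
marginals p; rater 2 copies rater 1 with probability a, else redraws
independently from p. With S = sum_j p_j^2: P_o = a + (1-a)S, P_E = S,
hence population kappa = a exactly — an exact recovery target that real
coding data cannot provide. Parameter recovery (mean estimated kappa
within 0.03 of a at n = 5000 over 20 seeds, for a in {0.2, 0.6, 0.9})
is part of the test suite.

**Overlap model (ranked).** Rater 1 selects k categories uniformly
without replacement, k drawn from a distribution over 1..4 — default
(0.30, 0.35, 0.25, 0.10), emulating a protocol where one to three
"core" selections dominate and a fourth is occasional. Rater 2 copies
each selection independently with probability `overlap` (keeping rank
order) and fills up to the same k uniformly from categories not yet on
its list; an optional flag shuffles rater 2's final order. Fuzzy kappa
is monotone in `overlap` in expectation (checked by simulation), though
its population value has no simple closed form here.

Both generators are pure functions of (model, seed). They emulate
marginal usage, selection-count structure and controllable agreement;
they do **not** emulate coder bias drift, fatigue, category
confusability, or the correlated category co-occurrence seen in real
photo coding — so passing tests demonstrate correctness of the indices
and estimator behavior under the stated models, not robustness of any
substantive coding study.

## Numerical and design choices

* All agreement computations are plain float64 numpy reductions; the
  brute-force oracle comparisons in the tests hold to 1e-12.
* The undefined-kappa threshold is 1 - P_E <= 1e-12.
* Row normalization is recorded, not enforced, with tolerance 1e-9 on
  |row sum - 1|.
* Readers reject malformed input (non-integer codes, out-of-range
  codes or grades, duplicate ids, blank-before-filled ranked cells)
  with the offending line number; they never coerce. Delimiter defaults
  to comma with tab auto-detection, matching spreadsheet exports.
* Report tables display 2 decimals; the structured report keeps full
  precision.
* Tie-break in `argmax_labels`: first (lowest-index) category wins;
  used only for diagnostics, never inside an index.
* The Monte-Carlo problem sizes above (n = 5000 recovery, 500x1000
  coverage) are the package's validation sizes; they keep the full
  suite to about two minutes on one core.

## Limitations

* Two raters only. The multi-rater generalization (Fleiss-style) is a
  known extension point but is not implemented.
* No Krippendorff-alpha variant, crisp or fuzzy.
* No spatial fuzzification of categories (fuzzy-location kappa for
  maps): here fuzziness lives in classification, not location.
* Bootstrap only; no asymptotic variance formulas or tests against
  kappa = 0.
* Published confidence intervals from other software cannot be matched
  bit-for-bit without their replicate count and seed; only coverage
  and containment-style agreement are checkable.
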
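# Methods

This note documents the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the known limitations.

## MNI counting

The raw observation is an element count: so many left mandibles, right
mandibles, skulls, unsided cranial fragments or unidentifiable postcranial
masses of a taxon/age class in one pellet. The minimum number of
individuals per (pellet, taxon, age class) is `max(left, right, skulls)`.
Mandibles are the primary evidence (paired elements make the maximum of the
two sides a sharp lower bound on individuals); skull counts are allowed to
*raise* the MNI above the mandible maximum, not merely confirm it, because
the max rule is the only reading that never undercounts either line of
evidence. Unsided cranial fragments establish presence (MNI ≥ 1) but can
never raise the MNI above the sided maximum — they cannot be attributed to
distinct individuals.

Two tallying conventions matter downstream and are deliberately separated
in `AbundanceVector`:

* **Per-age pellet occurrence** (`pellets_by_age`) is the printable
  summary-table shape.
* **Species-level pellet occurrence** (`pellets_containing`) is the union
  over age classes — a pellet holding a juvenile and an adult counts once.
  Per-age counts must never be summed into it (the overlap is unknown in
  aggregate data, in which case the union is stored as unknown). This union
  is the C of the detection formula.

A pellet whose only content is unidentifiable postcranial material
contributes one "unidentifiable" individual, so each collection's individual
total counts every assessed pellet's yield; percentage-of-individuals
denominators include these tallies (verified: the bundled collections'
printed percentages reproduce only under totals 439/427/201). The mean
number of prey items per pellet is computed over identifiable pellets only
(1007 individuals / 646 pellets = 1.56 pooled across the three present-day
collections). Pooled vertebrate-class shares use the identifiable total
(735/1007 mammals = 72.99%), while per-collection shares use the full total
(305/439 = 69.48% for Initial) — both denominators follow the source data's
reporting conventions.

## Taxonomy pooling

Cross-study comparison requires a common taxonomy. The bundled `historic`
profile pools bird taxa into "Aves spp.", lizard families into "Squamata"
and frogs into "Anura"; mammal species pass through. Maps are validated to
be idempotent (group labels are fixed points), and pooling conserves every
element-class total. Planigales are carried as *Planigale* spp. throughout:
pellet craniodental material cannot reliably separate the candidate species,
nor juveniles from adults, so the age class "unknown" is a first-class
value.

## Pairwise comparison

For taxon t and collections A, B the table is
(a, b, c, d) = (x_A, n_A − x_A, x_B, n_B − x_B). Yates-corrected chi-squared
(always corrected on 2×2; the correction is required to reproduce the
reference statistics, e.g. 25.69 and 65.23) is used when all four expected
cell counts are ≥ 5; otherwise the two-sided Fisher exact test, defined as
the sum of hypergeometric probabilities of all same-margin tables at most as
likely as the observed one, with a 1e-7 relative tolerance for ties
(boundary expected count of exactly 5 goes to chi-squared). The Holm
step-down adjustment is applied within each taxon's family of pairwise
tests; the family comprises only the pairs actually tested — pairs touching
an unknown count are skipped, never imputed. Adjusted p-values map to stars
at 0.05/0.01/0.001/0.0001.

Design note: the choice of test is made per table. A per-taxon-column
convention (forcing Fisher for every pair of a sparse taxon) would flip a
few well-populated Historic pairs from chi-squared to Fisher; the per-table
expected-count rule is the conventional reading of "chi-squared assumptions
not met" and is what the package implements.

## Hill-number diversity

Let x₁…x_S be mammal-group counts, n = Σxᵢ, f₁/f₂ the singleton/doubleton
counts. Observed (plug-in) Hill numbers: S for q = 0, exp(−Σpᵢ ln pᵢ) for
q = 1, 1/Σpᵢ² for q = 2. Headline estimates are the asymptotic estimators,
because plug-in values are downward-biased in finite samples (and do not
reproduce the reference values — e.g. 2.92 plug-in vs 2.94 asymptotic for
the Initial collection at q = 2):

* **q = 0, Chao1:** S_obs + ((n−1)/n)·f₁²/(2f₂), or the bias-corrected
  S_obs + ((n−1)/n)·f₁(f₁−1)/2 when f₂ = 0.
* **q = 1, Chao–Jost:** Ĥ = Σ_{xᵢ ≤ n−1} (xᵢ/n) Σ_{k=xᵢ}^{n−1} 1/k, plus a
  singleton correction (f₁/n)(1−A)^{1−n}(−ln A − Σ_{r=1}^{n−1}(1−A)^r/r)
  with A = 2f₂/((n−1)f₁ + 2f₂) (or 2/((n−1)(f₁−1)+2) when f₂ = 0); the Hill
  number is exp(Ĥ). Harmonic sums are computed by direct summation — exact
  at the n ≤ 10⁴ scale of pellet data.
* **q = 2, MVUE inverse Simpson:** n(n−1)/Σxᵢ(xᵢ−1), undefined (refused,
  not patched) when all species are singletons.

Confidence intervals are estimate ± 1.96 × SD over B multinomial resamples
of size n from the observed proportions (default B = 50; the seed is
mandatory whenever B > 0). The simpler observed-proportion bootstrap is used
rather than an unseen-species-augmented one: all recomputable collections
here have f₁ = 0, which makes the augmentation vacuous, and no reference
interval exists to calibrate against. Replicates on which an estimator is
undefined are dropped with a warning.

Known discrepancy: the Chao–Jost estimator on the reconstructed Winter
mammal counts (68, 13, 36, 150, 2) gives 3.10, while the reference value for
that collection prints as 3.11. The 0.01 gap is unexplained (plausibly a
rounding or settings difference in the original computation); Winter q = 1
is therefore not asserted anywhere.

## Detection effort

pₙ = 1 − (1 − C/N)ⁿ treats pellet draws as independent with replacement.
Confident detection requires pₙ *strictly* greater than 1 − α (default
α = 0.05): boundary equality does not count, so C/N = 0.95 needs 2 pellets,
not 1. The required effort is solved in closed form as
⌈ln α / ln(1 − C/N)⌉, then adjusted by at most one step to honour the strict
inequality; tests verify exact agreement with a linear scan for every
C ∈ [1, N], N ≤ 500. A species with C = 0 is never detectable under the
model and its required effort is reported absent, with a warning.

The published per-site efforts for the motivating dataset (e.g. 7 pellets in
the Initial collection) depend on species-level C values that are not
printed — per-age pellet counts cannot be combined into the union — so those
numbers are not regression targets; the formula layer itself is verified
against a Monte-Carlo oracle instead.

## Synthetic generator

Per pellet: with probability `p_unidentifiable_only` (default 0.085,
matching the observed 60/706 unidentifiable-only fraction) the pellet yields
a single unidentifiable record; otherwise the identifiable item count K ≥ 1
is zero-truncated Poisson with *truncated mean* equal to
`mean_items_per_pellet` (default 1.56; the underlying rate λ is solved
numerically, since only the mean is empirically constrained). Items are
i.i.d. multinomial on the collection's proportion vector; ages are Bernoulli
per taxon; each individual's left mandible, right mandible and skull survive
independently with the `element_recovery` probabilities. An individual with
no surviving element is invisible but remains in the truth, which makes
MNI ≤ truth a strict, testable invariant, and full recovery makes MNI =
truth exactly. `plague_trajectory` builds per-collection proportion vectors
with an irruptive taxon forced to given shares (default scenario: 0.24 →
0.35 → 0.57, the observed rat build-up) and all other taxa rescaled
proportionally.

All randomness flows from the single scenario seed (per-collection streams
are derived as `default_rng([seed, collection_index])`, so adding a
collection never perturbs another's draws).

What the generator does *not* emulate: owl prey preference or foraging
bias, fragmentation correlation between elements of one individual (losses
are independent), within-pellet taxon clustering, multi-owl contributions
and roost mixing, or temporal autocorrelation between pellets. Passing
recovery tests therefore demonstrate correctness of the counting and
estimation machinery under the stated sampling model, not robustness to
those field realities.

## Degenerate inputs and refusal policy

Unknown counts (partially published data) are represented as missing and
propagate as refusals (`UnknownCountError`), never as imputations: pairwise
comparisons skip the affected pairs, diversity skips the collection,
detection skips the site — each with a logged warning. Estimators with
undefined values (all-singleton Simpson, zero identifiable pellets) report
absence rather than a patched number. Validation happens before any
sampling or I/O side effects.

## Problem sizes

All bundled analyses are desk-scale: collections of a few hundred pellets,
five to ten taxa. The test suite's exhaustive checks run Fisher's test
against an exact-rational enumeration for every 2×2 table with N ≤ 40,
verify the detection closed form for all C at N ≤ 500, and exercise the
generator at 500–4000 pellets; the full suite completes in well under a
minute on one core.
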
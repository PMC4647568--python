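# Methods

## Data model and scoring

A specimen record carries the species, population and zone (central/fringe,
by distance to the nearest congeneric range: ≥ 50 km vs < 50 km), the count
of complete rib-bearing thoracic vertebrae (validated to 10–20; the genus
spans 12–18), the cervical state (regular, or an incomplete/complete
transformation of the atlas toward thoracic identity), the sacral state and
the side of any sacral asymmetry. The cervical region is the single atlas,
so it needs no count. Caudosacral and caudal vertebrae are not modelled:
they are unreliable on radiographs and frequently missing.

Two sacral states count as a *transitional sacral vertebra*: the two-vertebra
form (transitional sacral followed by a transitional vertebra) and the
single form (transitional sacral followed by a regular sacral). Both add
0.5 to the thoracic score and require a left/right asymmetry side (enforced
as a record invariant: asymmetry ≠ none exactly when the sacral state is
transitional). A third non-regular state, an incomplete thoracic-to-sacral
change that leaves the sacral vertebra itself unchanged, is tallied as its
own transformation category but adds no half score and does not enter
S_tr — only the two transitional-sacral states do, which is what makes the
overall 70/1,368 prevalence equal the sum of the left and right asymmetry
columns.

## Summary statistics

* **T_n** — modal *integer* thoracic count. Ties are broken toward the
  smaller count with a logged warning (no tie occurs in the packaged data).
* **T_var** — percent of specimens whose complete count differs from T_n,
  with half-score specimens excluded from the numerator. This exclusion is
  deliberate and verified: it is the only rule that reproduces every
  published per-species value (e.g. 14/57 = 24.6% for *T. dobrogicus*
  despite a 16.5-scored specimen whose complete count is also non-modal,
  and 24/68 = 35.3% for the F1 hybrids). A specimen therefore contributes
  to at most one of the T_var and S_tr numerators.
* **T_range** — span (max − min) of the complete thoracic counts of *all*
  specimens, including those with transitional sacra. Restricting the span
  to integer-scored specimens fails for *T. karelinii*, whose published
  12–14 range is anchored by a single 12.5-scored animal; the complete-count
  span reproduces all eight published ranges.
* **S_tr** — percent of specimens with a transitional sacral vertebra.

Percentages are kept unrounded internally and rounded half-up to one
decimal only for reporting (the tables' convention; banker's rounding would
turn 2.25 into 2.2). One consequence worth knowing: the species-level
correlations are computed on unrounded percentages, so the two S_tr
correlations differ in the second decimal from coefficients computed off
the rounded printed values (0.24 vs 0.31 and 0.03 vs 0.13); both versions
are far from significance and the two targeted correlations (T_n–T_var,
T_n–T_range) are unaffected.

## Association tests

Spearman's r_s is the Pearson correlation of midranks (scipy's average
ranks), which handles the heavy ties of meristic data exactly. The default
p-value is the two-sided t-approximation, t = r√((n−2)/(1−r²)) on n − 2 df;
a permutation p is available, p = (b+1)/(m+1) with b the number of y-
permutations whose |r| reaches the observed |r| (add-one rule, so p is
never 0 and is exactly uniform on its support under exchangeability). At
n = 8 the t-approximation and the permutation p agree to within a few
thousandths in practice.

The G-test uses G = 2 Σ O ln(O/E) over non-empty cells with E from the
independence model and an upper chi-square tail on (r−1)(c−1) df. No
continuity correction is applied; the Williams correction
q = 1 + (N·Σ1/Rᵢ − 1)(N·Σ1/Cⱼ − 1)/(6N·df) is available behind a flag and
off by default. The published G statistics for the central/fringe
comparisons cannot be reconstructed from the published 2×2 counts by any
standard G formula (the *T. ivanbureschi* table gives 32.8 against a
published 18.86), so the pipeline reports plainly labelled standard
per-species and pooled tests and makes no attempt to match those numbers;
the qualitative conclusions (which species differ between zones) agree.

## Phylogenetic comparative methods

**Independent contrasts.** Classic pruning: at each internal node with
child values x₁, x₂ on working branch lengths v₁, v₂, the standardized
contrast is (x₁−x₂)/√(v₁+v₂), the node value is the variance-weighted
average, and the parent branch gains v₁v₂/(v₁+v₂). The implementation is
checked against an independent reference implementation to 10 significant
digits, and calibrated by simulation: under Brownian motion the
standardized contrasts are mean-zero, unit-variance and uncorrelated
(10⁴ replicates, 3-standard-error bands).

**Contrast regression.** Through the origin on standardized contrasts, with
x-contrasts positivized and y-contrasts flipped in tandem (the fit is
invariant to these joint flips; the convention fixes reported slope signs).
β = Σc_x c_y/Σc_x², s² = (Σc_y² − βΣc_x c_y)/(k−1), t = β/√(s²/Σc_x²) on
k − 1 df. Under two independent Brownian traits the test is exact; the
suite verifies a 3.5–6.5% rejection rate at α = 0.05 over 2,000 replicates
and slope recovery under Brownian noise. A constant predictor trait makes
the slope undefined; the pipeline skips such a regression with a warning
rather than reporting a number.

**Squared-change parsimony and the signal test.** Ancestral states minimize
Σ(state_parent − state_child)² with *unit* branch weights — each branch
counts equally, matching the classic tip-shuffling signal test, whose
statistic the wording "total squared change summed over all branches"
describes; a 1/branch-length-weighted variant sits behind a flag. The
minimum is a strictly convex quadratic, solved exactly through the graph
Laplacian: the statistic is the Schur-complement quadratic form in the tip
values, precomputed once per tree so the 10,000 permutations of a signal
test cost one small mat-vec each. Verified against closed forms (two-tip
tree, star tree) and brute-force numeric minimization on random 5-tip trees
to 10⁻⁶. The signal p is lower-tailed with the add-one rule: signal means
*less* change than random tip assignments. A constant trait yields p = 1
with a warning. Note that on a star tree the unit-weight statistic is
permutation-invariant, so the test is degenerate there by construction;
the null calibration (p uniform under iid tip values, chi-square
goodness-of-fit at α = 0.01) is therefore run on the structured
eight-species tree.

## The packaged tree

Topology: ((marmoratus, pygmaeus), ((ivanbureschi, karelinii), ((carnifex,
macedonicus), (cristatus, dobrogicus)))), the accepted arrangement for the
genus. Node ages are not published alongside the species tables, so the
packaged branch lengths are an *approximate* ultrametric calibration (root
at 24 Ma, plausible divergence depths), clearly flagged in the filename and
overridable by any user Newick. Consequences: the unit-weight signal test
ignores branch lengths entirely, so its results on the packaged tree are
exact given the topology (T_n: observed statistic 5.68, p ≈ 0.002 at 10⁴
iterations); the contrast regressions do use the lengths and their p-values
are indicative only. Polytomies are rejected by default; an explicit
resolve policy produces a caterpillar of zero-length branches, which the
contrast code replaces by 10⁻⁸ of tree depth with a warning.

## Synthetic data

`simulate_records` draws, per species, complete counts as modal + offset
from a specified offset distribution, transitional-sacrum status as an
independent Bernoulli (type and side uniform), and cervical transformations
likewise. Independence of transitional status from count offset reflects
the observed absence of an S_tr–T_var association; a coupling parameter
(p_tr scaled by 1 + c·|offset|) exists to simulate the alternative. One
root seed spawns per-species streams, so species blocks are independent
and runs reproducible. `table1_sim_specs()` mirrors the eight
central-population samples: published sample sizes (58…175), modal counts,
empirical offset distributions and per-species transitional frequencies —
these are the package's study conditions for end-to-end checks. What the
generator does *not* emulate: population substructure within species,
observer error in scoring, correlated left/right development, or any
developmental (somitogenesis/Hox) mechanism — recovery of the generating
values by the pipeline therefore validates the statistical machinery, not
the biology of real museum samples.

`simulate_bm` adds independent N(0, σ²·length) increments along branches;
tip covariance equals σ² times shared path length (verified by Monte
Carlo), and it drives the contrast calibrations above.

## Problem sizes and numerical choices

The suite's Monte-Carlo sizes — 10⁴ replicates for contrast calibration,
2×10³ for regression error rates, 500×999 for permutation-p uniformity,
200 replicates for generator recovery and end-to-end power — keep every
standard error small enough for 3-SE bands while the whole suite runs in
well under a minute; per-species recovery uses 3-SE bands so the eight
simultaneous checks hold a family-wise error near 1%. Laplacian solves use
dense `numpy.linalg.solve` (trees here have ≤ tens of tips); the
squared-change minimum is reported with a floor at 0 to absorb −10⁻¹⁶-scale
round-off, and contrast variances are strictly positive by construction.

## Known limitations

- The published phylogenetic p-values and G statistics cannot be reproduced
  without the original branch lengths and table constructions; the package
  reports its own clearly defined versions and validates the machinery
  against oracles instead.
- Hybrid handling is token-based (`parent1_x_parent2`); multi-generation or
  backcross classes are not modelled.
- The record model stores one transformation per region; a specimen with,
  say, two distinct sacral anomalies cannot be represented.
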
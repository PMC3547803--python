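# Methods

This note records the model, the numerical conventions, and the design
choices made where the procedure left room for interpretation. It documents
what the code computes; every number quoted elsewhere is produced by the
test suite or `scripts/acceptance.py` at run time.

## Model and assumptions

The analysis treats a cohort as i.i.d. samples from two class-conditional
distributions over `n` nonnegative metabolite concentrations, with a binary
class variable `C ∈ {control, variable}`. Nothing parametric is assumed
about those distributions: all inference goes through soft discretization
into `M` bins followed by plug-in (empirical) probability estimates.

Key consequences of the plug-in estimator on small cohorts:

* class priors `p(C)` are the empirical class frequencies;
* `p(o|C)` is the mean over class members of the per-sample combination
  probability `p_s(o) = Π_j p_s(bin o[m_j] of metabolite m_j)`, so
  `p(o) = Σ_C p(C) p(o|C)` holds identically;
* mutual information is biased upward for large `M^|Sub|` relative to the
  sample count — this is intrinsic to the method and the reason subsets are
  capped at `maxSub` members.

All logarithms are base 2; with a binary class, subset information is
bounded by `H(C) ≤ 1` bit.

## Binning

* **Knot vector.** Open-uniform ("uniform non-periodic"): length `M + k + 1`
  with `t_i = 0` for `i < k`, `t_i = i − k + 1` for `k ≤ i ≤ M − 1`, and
  `t_i = M − k + 1` beyond. The trailing knot is not referenced by the `M`
  basis functions; it is kept for the stated length convention.
* **Recursion.** Cox–de Boor with the `0/0 := 0` convention, evaluated
  directly (the endpoint closure below is part of the method's contract;
  `scipy.interpolate.BSpline` serves as an independent oracle in the tests,
  where interior values agree to 1e−12).
* **Right-endpoint closure.** Half-open intervals leave `z = M − k + 1`
  undefined; it is defined by the left-limit so the maximum observation
  lands wholly in bin `M` and the partition of unity holds on the closed
  domain.
* **Degenerate range.** A constant metabolite (`max = min`) maps every value
  to `z = 0`, i.e. all mass in bin 1 for all samples. A constant column
  therefore carries exactly zero information — verified in the tests.
* **Held-out samples** are binned with the *training* min/max and clamped to
  the domain. The training ranges are recorded on the fitted model for this
  purpose.
* Bins are 1-based in all interfaces; combination enumeration is
  lexicographic with the subset's first metabolite most significant.

## Subset selection

* **EFM strategy (default).** Elementary flux modes are enumerated by the
  classical Schuster-style tableau: reversible reactions split into
  irreversible pairs, one internal-metabolite constraint imposed per
  iteration, candidates filtered by the pairwise support-minimality test,
  futile two-cycles dropped, fully reversible modes reported once.
  Arithmetic is exact (`fractions.Fraction`), so `S·v = 0` holds
  identically. A configurable cap (default 32 reactions after splitting)
  guards against combinatorial blow-up; beyond it, precomputed subsets
  should be supplied. A subset is the measured internal metabolites touched
  by a mode's reactions, in network row order.
* **Neighborhood strategy.** Origin plus measured metabolites sharing a
  reaction; identical member sets merged. On the bundled fatty-acid network
  the 13 origins merge to 12 distinct neighborhoods.
* **Random strategy.** Seeded; sizes uniform in `[2, maxSub]` capped at the
  measured count; members drawn without replacement.
* **Splitting.** Oversize subsets are cut into `⌈size/maxSub⌉` contiguous,
  non-overlapping, near-equal pieces (remainder spread over the earliest
  pieces, e.g. 17 with cap 8 → 6+6+5). Contiguity is in network row order,
  which keeps pathway neighbors together.

## Information engine

* `mi_o = Σ_C p(C) p(o|C) log₂(p(o|C)/p(o))`, with `0·log 0 := 0`; when
  `p(o) = 0` both conditionals vanish and `mi_o := 0`. By the log-sum
  inequality `mi_o ≥ 0`, and `Σ_o mi_o = I(B_Sub; C)` exactly — both are
  asserted over randomized cohorts, and `I` is cross-checked against an
  independent `H(C) − H(C|B)` computation.
* **Assignment.** Each combination goes to the class with the larger term;
  a tie (both terms zero) goes to control. Ties carry `mi_o = 0`, so the
  choice cannot influence expectations or scores — it only fixes
  determinism.
* **Expected bins.** Per class, the mi-normalized weighted mean of bin
  indices over that class's combinations, **rounded half away from zero**
  (2.5 → 3). The same rounding applies to the cross-subset aggregation. The
  rule is fixed for bit-reproducibility; standard banker's rounding would
  differ exactly on .5 ties.
* **Degenerate class.** If a class's combinations carry zero total
  information, its expected bin falls back to the midpoint
  `round((M+1)/2)` — no information, no predicted deviation — and the model
  flags it. With all containing subsets degenerate, cross-subset weights
  fall back to uniform.

## Classification

A sample's class score sums, over subsets, the probability it places on the
combinations assigned to that class, with mi-normalized combination weights
and information-proportional subset weights (uniform when all subsets are
uninformative). This mirrors the expectation calculation. The alternative
reading — weighting by raw `mi_o` without normalization — is preserved
behind `score_weights="raw-mi"`; the two agree on single-subset models up to
a positive factor and rarely disagree in practice, but the normalized form
is the default because it matches the expectation weighting exactly.
Prediction ties go to control and are logged.

LOOCV retrains from scratch on each fold, including binning ranges; folds
whose training remainder loses a class (only possible when a class has a
single sample) are flagged and excluded. Metrics use variable as the
positive class, `0/0 := 0` for precision/recall, and a two-tailed Fisher
exact test (scipy) on the confusion table. Fisher p-values are reported but
not used as a quality gate.

## Synthetic data

`generate_cohort` draws control samples i.i.d. Normal(baseline, noise_sd)
per metabolite, truncated at zero (clipping; with the default
baseline 100 ± 10 the truncation is never active), and adds
`shift × noise_sd` to chosen metabolites in the variable class. Defaults —
9 control vs 7 variable samples, 13 metabolites, baseline 100, noise SD
10 — mirror the small rodent blood cohorts this method targets. The
generator reproduces *controllable class separations*, not real
metabolomics data: no inter-metabolite correlation beyond the programmed
shifts, no heteroscedasticity, no batch or peak-alignment artifacts. Tests
passing on it show the machinery is correct and direction recovery works at
the stated separations; they do not certify accuracy on any real cohort.

Monte-Carlo baselines used by the tests (all seeded): with +2 SD shifts on
two of five metabolites (8+8 samples, M=6, k=3, single-flux-route subsets),
the shifted metabolites get positive deltas in ≥ 95 of 100 replicates; with
labels permuted on a separated cohort, mean LOOCV accuracy over 50
permutations sits near chance (asserted within [0.3, 0.7]); with no shift,
single-metabolite information at M=2, k=1 averages well below 0.15 bits.

## Problem sizes and validation scope

The bundled fatty-acid network has 17 reactions and 13 internal
metabolites; its four flux modes and the toy networks used in tests are
verified against a brute-force oracle that tests every reaction subset for
steady-state feasibility (linear programming) and support minimality.
Engine equivalence against the enumeration oracle is exercised for subsets
of up to 3 metabolites, up to 3 bins and up to 8 samples, where exhaustive
enumeration is exact and fast; property tests use 200 randomized trials.
These sizes were chosen so the whole validation suite runs in seconds while
still covering every code path; the engine itself handles the full
parameter grid (M up to 6, subsets up to 8 members → 6^8 combinations) in
well under a minute per fit.

The original study's cohort tables are distributed as journal DOC
supplements and are not redistributable here; the LOOCV-reproduction checks
therefore require user-transcribed CSVs (see `tests/test_acceptance.py`)
and fail with instructions otherwise. The liver-profile network exists only
as a screenshot in those supplements, so its reconstruction is likewise
left to the user.

## Known limitations

* Binary classes only (the information decomposition generalizes, but
  multi-class assignment and scoring are not implemented).
* Plug-in MI on tiny cohorts overfits large combination spaces; subsets
  dominated by uninformative metabolites can dilute signal (visible in the
  README example when only 3 of 13 metabolites carry signal).
* The tableau enumerator is exponential in the worst case; it is intended
  for curated pathway-scale networks, not genome scale.
* No normalization is applied: the min–max transform makes all statistics
  invariant to per-metabolite affine rescaling, so units never matter, but
  cross-sample batch effects are the user's responsibility.
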
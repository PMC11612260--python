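# Methods

## The model and its assumptions

The unit of analysis is a binary taxa × sites matrix drawn from one survey
stratum. Stratification (year × ecoregion × vegetation zone × biological
unit) is part of the inference: it removes known macrohabitat and temporal
signal so that residual co-occurrence structure within a matrix can be
attributed to finer mechanisms. Rows are taxa and columns are sites
everywhere in the package.

The co-occurrence index is the Stone–Roberts C-score: the mean over all
unordered taxon pairs of the checkerboard units CU = (rᵢ − S)(rⱼ − S). CU
counts the 2×2 submatrices in which the pair is mutually exclusive, so it
is zero exactly when one taxon's range nests inside the other's
(S = min(rᵢ, rⱼ)) and grows as the pair partitions sites.

The null hypothesis is the fixed–fixed ensemble: all binary matrices with
the observed row totals (taxon incidences) and column totals (site
richness) are equally likely. This conditions out differences in how
widespread taxa are and how rich sites are, which is the conservative,
low-type-I choice for incidence data. The assumption worth stating plainly:
any process that operates through the margins themselves (e.g. a gradient
that makes some sites richer) is absorbed into the null and cannot be
detected; only the *pairing pattern* beyond the margins is tested.

## The sequential-swap sampler

The chain flips randomly chosen 2×2 checkerboard submatrices
([[1,0],[0,1]] ↔ [[0,1],[1,0]]), which preserves both margins. Because row
pairs and column pairs are proposed uniformly, the transition kernel is
symmetric and the stationary distribution is uniform over the connected
margin class.

Schedule (configurable; chosen to decorrelate samples at cost linear in
matrix size):

- chain starts at the observed matrix;
- burn-in: 10·(m·n) *successful* swaps, at least 1000;
- thinning: one retained C-score every m·n *attempted* swaps;
- 5000 retained samples by default (matching standard practice for this
  analysis), reducible for simulation studies.

Two sampling pitfalls are handled explicitly:

1. **Frozen chains.** A matrix with no checkerboard submatrix anywhere
   (e.g. nested occupancies) cannot move; it is reported `unusable`, not
   given p = 1.
2. **Successful-swap stopping bias.** Measuring a mixing run in successful
   swaps over-samples states with few swappable submatrices (the chain
   spends more attempt-time in them per success). We found this
   empirically: stopping the synthetic-matrix generator after a fixed
   number of successful swaps produced measurably non-uniform draws over an
   exhaustively enumerable 5-member margin class (chi-square p ≈ 3e-9).
   The generator therefore mixes for a fixed number of *attempted* swaps
   (default max(10 000, 50·m·n)), under which the draw is unbiased; the
   uniformity test now passes. Thinning in the test chain is likewise
   measured in attempts.

## Effect size, tails, classification

SES = (C_obs − mean(C_null)) / sd(C_null), with the sample standard
deviation (ddof = 1); a zero-variance null leaves SES undefined (NaN), and
such matrices are excluded from group-level analyses.

Tail probabilities are raw counts over the null sample, with ties counted
in both tails: p_ge = #{C_null ≥ C_obs}/n and symmetrically for p_le. This
convention reproduces the granularity of per-matrix reports from standard
co-occurrence software (p-values in multiples of 1/n, exact 1.0 possible)
and is slightly conservative under discreteness. A (count+1)/(n+1) option
is available. Classification at level α (default 0.05): `negative`
(segregated) when p_ge ≤ α/2, `positive` (aggregated) when p_le ≤ α/2,
otherwise `random`; the direction naming follows the ecological convention
that a *high* C-score means *negative* co-occurrence. If both tails qualify
(pathological ties) the matrix is reported random.

Calibration measured under the null (matrices drawn uniformly from the
margin class of random 10×10 Bernoulli(0.5) matrices, 1000 iterations
each): non-random classification rate ≈ 0.045 at α = 0.05 over 800
replicates — slightly conservative, as expected from tie handling.

## Matrix preparation rules

- Binarization: presence iff abundance > 0; no minimum-count filter.
- Degeneracy: all-zero rows/columns are removed (logged) before the size
  filter; a wholly empty matrix is unusable. A discard-instead-of-repair
  mode exists for sensitivity analysis.
- Size filter: at least 5 taxa and 4 sites (smaller matrices are too often
  degenerate or powerless for this test); both thresholds configurable.
- Taxa lacking the grouping attribute (feeding group or family) are
  excluded from that unit type's matrices and logged, not pooled into an
  artificial "unknown" unit.
- Family matrices contain the taxa of exactly one family; the family is the
  unit label.

## Mechanism inference

**Driver taxa.** Within a non-random matrix, drivers are taxa whose
per-taxon CU sum has z-score > 2 (sample sd across the matrix's taxa). When
CU sums carry no variation there is no driver; when variation exists but no
taxon crosses the threshold, the single largest contributor is used and
flagged below-threshold. The threshold is configurable and the z-scores are
always reported.

**Tolerance comparison.** Partners are taxa with CU > 0 against a driver.
The call is `differential` when the absolute Hilsenhoff gap (0–10 scale) is
≥ 3 for a majority of scored driver–partner pairs, `similar` otherwise,
`unknown` when more than half the involved taxa lack scores. The gap rule
is a deliberate operationalization — there is no canonical test for "clear
separation" of tolerance scores — so raw gaps are always reported for
manual override.

**Habitat comparison.** Environmental variables available for all of the
matrix's sites (complete-case by variable; constant variables dropped with
a warning) are standardized and reduced to 3 principal components
(prcomp semantics: sdev = singular value/√(n−1), sign fixed so each
component's largest loading is positive). One PERMANOVA per driver taxon
tests the driver-present vs driver-absent site grouping on the 3 PC scores
with Euclidean distance: pseudo-F = (SS_between/(g−1))/(SS_within/(N−g)),
p = (#{F_perm ≥ F_obs}+1)/(n_perm+1), or the exhaustive two-group
enumeration when it is smaller than the requested permutation count (then
p is an exact count with no +1). Singleton presence groups are allowed but
flagged low-power. Note the resolution floor: because pseudo-F is invariant
to swapping group labels, exact two-group p cannot fall below
2/C(N, n₁) — at 6 sites with a 3/3 split the smallest achievable p is 0.1,
so habitat differences are undecidable at α = 0.05 no matter how large the
shift; the synthetic default plan therefore gives planted strata 10 sites. The habitat call is `different` when any driver's test
is significant at α — matching the elimination logic that a single
demonstrated habitat difference suffices to refute competition as the sole
driver — and `homogeneous` otherwise; with several drivers this choice
trades some false "different" calls (≈ k·α familywise) for sensitivity.

**Decision tree.** Negative matrices: differential tolerance ⇒
differential_tolerance; similar tolerance and different habitat ⇒
differential_habitat; similar and homogeneous ⇒ competitive_exclusion (by
elimination); unknown inputs where the branch needs them ⇒ indeterminate.
Positive matrices test habitat first: homogeneous ⇒ shared_habitat;
different habitat with similar tolerance ⇒ shared_tolerance; different
habitat otherwise ⇒ biological_homogenization by elimination; unknown
habitat ⇒ indeterminate. Random ⇒ neutral. The function is pure and the
full 3×3×3 input cross-product is unit-tested.

## Group effects

SES values across matrices are summarized against the null band (mean 0,
95% within ±2). Kruskal–Wallis (midranks, tie correction, chi-square
approximation) tests SES differences across units; pairwise Wilcoxon
rank-sum uses exact enumeration when both groups have n ≤ 8 without ties
and the continuity-corrected normal approximation otherwise. Pairwise
p-values are unadjusted by default (Holm available) — matching the common
reporting convention for this analysis. The band check and the group tests
answer different questions and are never conflated.

## Synthetic data: what it emulates, what it does not

The generators produce matrices inside the study envelope (5–66 taxa ×
4–24 sites; defaults 10–16 × 6–10, fill 0.45, mid-range of real survey
matrices), environmental tables (iid standard normals per variable, named
from the field vocabulary), and tolerance tables (similar: N(5, 0.5);
separated: 1 vs 8). Planted segregation uses one random half-split of the
sites shared by all planted pairs — the canonical two-guild checkerboard
and the strongest form of the signal. An earlier per-pair independent-split
design diluted the matrix-level C-score (cross-pair overlaps carry no
signal) and detected poorly; the shared split is the construction the
power analysis assumes. A `leakage` parameter softens exclusivity for
robustness studies.

Not emulated: real occupancy heterogeneity (row/column totals of field
matrices are far from exchangeable Bernoulli fills), spatial autocorrelation
among sites, correlated environmental variables, and abundance structure.
Passing the planted-recovery tests therefore demonstrates the machinery is
correct and well calibrated, not that field data of any particular shape
will yield high power.

Measured operating characteristics (also recomputed by
`scripts/acceptance.py`): detection power 1.0 for 5 planted pairs in 10×10
(50 seeds, SES > 2 and negative classification); end-to-end recovery of
planted competitive-exclusion and differential-habitat communities ≈ 0.95
of seeds (misses occur when a noise taxon out-scores the planted drivers
and the wrong presence grouping is tested); PERMANOVA type-I ≈ 0.05.

## Numerical and reproducibility choices

- Hot loops (C-score, swap chain) are numba-compiled; a pure-Python swap
  step is kept as the reference implementation and cross-checked.
- Every stochastic routine takes an explicit seed. Batch runs derive
  per-matrix seeds from a master seed and the stratum key via a stable
  4-byte blake2b digest (< 2³¹), so adding strata never perturbs existing
  results and outputs are byte-identical across re-runs.
- PERMANOVA comparisons use a 1e-12 slack when counting F_perm ≥ F_obs to
  avoid float-equality artifacts in the exact mode; infinite pseudo-F
  (zero within-group variance) is flagged and compared by infinity count.
- Simulation sizes in the tests (200-matrix calibration at 1000 iterations,
  50-seed power runs, 500-replicate type-I checks, 40-seed end-to-end
  recovery) are the package's chosen validation scale: large enough for
  ±0.02 Monte-Carlo resolution on rates, small enough to run routinely.

## Known limitations

- Only the C-score and the fixed–fixed null are implemented; the module
  layout leaves room for other indices/null families but none ship.
- p-values are Monte Carlo, not exact enumeration, for all but tiny
  PERMANOVA groupings.
- The tolerance-gap rule and the any-significant habitat rule are
  heuristics standing in for judgments the original decision framework
  leaves to the analyst; both expose their raw inputs in the output.
- Family-level matrices need ≥ 5 congeneric/confamilial taxa, which real
  datasets often fail; such strata are silently (but loggedly) absent.
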
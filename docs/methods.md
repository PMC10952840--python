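# Methods

This note documents the models and procedures implemented in `floradisp`,
the choices made where the design was genuinely open, and what the synthetic
data used in testing does and does not establish.

## Data model

A trait matrix is a taxon × character grid of categorical cells. Each cell is
observed (one state, or several for a polymorphic cell), missing, or
inapplicable. Characters carry a state list (codes `0..k−1`), an
ordered/unordered flag, and an organ block (flower, perianth, androecium,
gynoecium, pollen). Applicability rules — *trigger character at trigger
state ⇒ consequence characters inapplicable* — live in data (YAML), not
code, because rule sets differ between datasets; the shipped default encodes
the standard logical dependencies of floral organization (perianth absent ⇒
perianth detail characters meaningless, single carpel ⇒ carpel fusion
undefined, and so on). Rule application iterates to a fixed point; a rule
only fires while its trigger character is still observed at the trigger
state, and cyclic rule graphs are rejected at schema construction.

The default schema instance has 30 characters: 17 binary, 8 three-state, 3
four-state and 2 five-state, split 1/8/11/8/2 across the organ blocks. Its
unconstrained theoretical space therefore holds exactly
2^17 · 3^8 · 4^3 · 5^2 = 1,375,941,427,200 combinations, computed as an
arbitrary-precision integer (counts up to and beyond 10^18 stay exact).

Polymorphic cells are resolved *before each analysis* by drawing one of the
recorded states uniformly; the draw is seeded and logged in the run manifest,
and resolution is re-done once per analysis run, not per metric.

## Distances

Between two taxa, each character observed in both contributes a
dissimilarity in [0, 1]: unordered characters 0 (equal) or 1 (different);
ordered characters `|code_i − code_j| / (k − 1)`, the standard
maximal-difference normalization for ranked categorical states. The mean
character difference `D` averages these contributions over the comparable
characters only. Missing and inapplicable cells are equivalent here: both
remove the character from the comparison.

Consequences worth knowing:

* `D` over varying character subsets need not satisfy the triangle
  inequality; none of the downstream methods require it.
* Adding a character constant across all taxa rescales defined distances by
  `n/(n+1)` (the constant contributes a zero term and one more comparable
  character); it does not leave them unchanged.
* A pair sharing no observed character has undefined `D`. The matrix is
  completed by iteratively removing the taxon participating in the most
  undefined pairs (ties broken alphabetically) until none remain; removals
  are logged. This greedy minimal-loss rule is one reasonable completion —
  the original analyses report only the post-drop sample sizes, not the
  rule — so the drop log is always written for inspection.

Distances are computed in double precision with no rounding before
statistics; the vectorized engine is checked against a brute-force
double-loop oracle to 1e−12 in the test suite.

## Disparity metrics

For each group with ≥ 2 members, over the C(n, 2) within-group pairwise
distances: `meanD` (with sample SD over the same pair set), and the range
`maxD`. Both are sample-size sensitive, so rarefied distributions are
produced: per replicate (default 1000), `n` taxa per group are sampled
without replacement (`n` = smallest group size − 1 by default), the distance
matrix is recomputed on the subsample, and the metric taken over its defined
within-group pairs. Recomputing (rather than slicing the full matrix) matters
because the greedy drop step depends on which taxa are present; inside
replicates no dropping is done, so replicate group sizes stay fixed.

The contribution of group *i* to total disparity is
`Ddelta_i = Dtot − meanD(dataset without i)`, signed so that positive values
mean the group's presence raises the whole-dataset mean pairwise distance.
(The opposite sign convention appears in the verbal definition of some
sources; the implementation follows the interpretation — positive =
disparity-increasing — and the sign is trivial to flip.) Eccentricity is a
taxon's mean distance to all other taxa of a reference set — a row mean of
the distance matrix — and ranks morphological outliers.

Time bins: fossils are assigned by the **midpoint** of their stratigraphic
age range to half-open bins `(min, max]`; extant taxa form the "present"
bin; fossils whose midpoint falls in no bin (e.g. the Neogene with the
default Cretaceous–Paleogene bins) are flagged excluded. Midpoint assignment
is the implemented default because age ranges commonly straddle bin edges;
whole-range containment is a stricter alternative that would leave such
fossils unassignable.

## Theoretical morphospace sampling

Random backgrounds are drawn by per-character uniform state draws. Rows that
trigger an applicability rule get the consequence characters set
inapplicable (treated as missing in distances), and duplicate rows after
masking are rejected, so the sample is without replacement. Uniformity is
defined over the raw pre-masking combinations; the constrained space has no
canonical measure and this choice keeps the sampler exact and cheap. A
rejection watchdog raises when the request apparently exceeds the
constrained space size. Theoretical rows enter ordination only — never
disparity or group statistics.

## Ordination

Nonmetric MDS in k = 2 via SMACOF with isotonic regression (scikit-learn),
best of 20 random starts by default, convergence tolerance 1e−6 on stress
change and 300 iterations per start (community defaults for this engine;
raise `max_iter` for large point sets — stress keeps improving noticeably up
to ~1000 iterations on 300+ points). The returned configuration is centered,
rotated to principal axes, and sign-fixed (largest-|coordinate| point
positive per axis) so coordinates are comparable across runs. Kruskal
stress-1 is recomputed in-package from the final configuration:
`sqrt(Σ(d − d̂)² / Σd²)` with `d̂` the isotonic fit of configuration
distances on observed dissimilarities (primary treatment of ties).

Shepard diagnostics: nonmetric fit r² = 1 − stress² (uncentered total SS);
linear fit r² = squared Pearson correlation of configuration distances with
observed `D`. On high-dimensional categorical data the nonmetric fit is
typically high (≥ 0.8) while stress is substantial (0.3–0.4) and the linear
fit low — a 2-D embedding of such a space preserves ranks far better than
magnitudes. These numbers are diagnostics of the embedding, not test
statistics, and are start- and engine-dependent.

Group centroids are per-axis coordinate means over empirical members only.
Hull coverage is the 2-D convex-hull area of a subset divided by that of a
reference (default: all ordinated points, i.e. the total displayed
morphospace, theoretical background included); collinear subsets yield area
0 with a warning.

## Group statistics

Kruskal–Wallis operates on the *within-group pairwise distance* values, as
the published workflow this package re-implements does. Those values are not
independent (each taxon appears in n−1 pairs), so the χ² reference
distribution is approximate and the very large statistics such data produce
should be read as descriptive — this is the procedure as specified, not a
recommendation. H is tie-corrected (scipy). Post hoc: pairwise mean-rank
comparisons with critical difference
`z_{α/(k(k−1))} · sqrt(N(N+1)/12 · (1/n_i + 1/n_j))` (two-sided Bonferroni
over pairs, Siegel–Castellan style), summarized as a compact letter display
(greedy clique cover over the non-significant-pair graph, groups visited by
descending mean rank, alphabetical tie-break).

PERMANOVA: with squared distances d², `SS_total = Σ_{i<j} d²/N`,
`SS_within = Σ_g Σ_{i<j∈g} d²/n_g`, pseudo-F =
`(SS_between/(a−1)) / (SS_within/(N−a))`, r² = SS_between/SS_total; p-value
by seeded label permutation, `(count_extreme + 1)/(n_perm + 1)` with 9999
permutations by default. On univariate Euclidean data this pseudo-F equals
the classical one-way ANOVA F (verified to 1e−9 in tests; scikit-bio's
implementation is the independent cross-check). Pairwise PERMANOVAs use
Bonferroni adjustment with the number of pairs as multiplier.

Pearson tests report r, `t = r·sqrt(df/(1−r²))`, df = n−2, and the two-sided
p from the t distribution.

## Ancestral-state reconstruction

Per character, tips whose cell is missing, inapplicable or polymorphic are
dropped from the dated tree (unifurcations suppressed, branch lengths
summed, so surviving root-to-tip depths are preserved). The Mk model —
continuous-time Markov chain with generator rows summing to zero — is fitted
by maximum likelihood via Felsenstein pruning with per-node scaling;
transition matrices come from an eigendecomposition of Q batched over
branches, with a `scipy.linalg.expm` fallback for (near-)defective
generators. ER (one rate) and ARD (k(k−1) rates) are optimized by L-BFGS-B
on log-rates from multiple starts (bounds e^−23..e^6); if ARD ever lands
below ER (they are nested) a restart from the ER solution is attempted. The
AIC-preferred model is used downstream; constant characters are flagged
degenerate with the rate at the lower boundary. The root prior is uniform
(1/k), the common default of this machinery; it is an explicit argument for
anyone wanting stationary frequencies instead.

Stochastic mapping samples histories conditional on tip data: the root state
from the posterior `prior · L_root`, then each child given its parent via
`P_ab(t) · L_child(b)` in preorder; full branch paths, when requested, by
uniformization (the number of virtual jumps drawn from its conditional
distribution by CDF inversion, then the jump chain as a bridge). Node state
probabilities are frequencies over the simulations (500 by default) and
converge to the marginal (rerooting) probabilities, which are also computed
directly by an outside-partials pass and used as a cross-check (agreement
within ±0.03 at 2000 simulations in tests).

The most probable ancestral combination at a named clade's crown node takes
the per-character argmax state; exact ties and characters whose pruned tree
lost the node become missing cells (ties are logged). The assembled ancestor
rows are appended to the matrix *before* distance computation so
reconstructed flowers can be placed in the same morphospace. ASR is optional:
the morphospace and disparity analyses run without a tree.

## Synthetic data

`generate_matrix` draws, per character, a base state-frequency profile from
Dirichlet(α = 1.5), and per group a profile blended as
`(1−w)·base + w·own` with the divergence knob `w` (0 = exchangeable groups,
1 = independent profiles; default 0.6 gives clearly separable but
overlapping groups). Defaults reproduce the composition of the floral
dataset this pipeline targets: the 30-character schema, 32%
missing+inapplicable cells (applicability rules fire first and the missing
mask tops up to the target), 3% polymorphic cells (a fraction of *all*
cells), fossil age ranges over 145–0 Ma with widths log-uniform in 1–20 Myr.
Group sizes default to 4 × 30 taxa — large enough for stable pairwise
statistics, small enough that the full suite runs in minutes; full-scale
(1201-taxon) matrices are a config change.

`generate_tree_with_characters` simulates a birth–death tree (dendropy) to a
target extant tip count, rescales it to a stated root age (default 140 Myr),
and evolves each character under ER at a true rate (default 0.01 /Myr),
recording internal-node states for recovery scoring.

What the generator does **not** emulate: real character correlations beyond
the applicability rules, phylogenetic signal in the group-structured
matrices (groups are exchangeable draws, not clades), non-uniform
missingness (real fossils lose whole organ blocks at once), and temporal
trends in state frequencies. Passing tests therefore establish the
correctness and calibration of the machinery on data with known structure —
not that any particular empirical dataset will show a given pattern.

## Numerical and procedural choices

* Distance engine exact to 1e−12 against enumeration; no triangle-inequality
  assumption anywhere.
* nMDS: stress tolerance 1e−6, 300 iterations/start, 20 starts; planted
  2-D configurations are recovered with stress < 0.01 and Procrustes error
  < 1e−3 from 15 points up (at 10 points a rank-only embedding is
  genuinely underdetermined up to monotone distortion, and recovery to that
  tolerance is not achievable — tested at 15).
* Mk likelihood exact to 1e−10 against brute-force state enumeration on
  small trees; ER rate recovery at 500 tips has median relative error
  ≈ 10–15% with ER AIC-selected in ≥ 80% of replicates.
* Permutation p-values can never be 0 (`+1` correction); seeds are explicit
  arguments everywhere randomness occurs and are recorded in run manifests,
  which suffice to reproduce a run bit-for-bit with the same version.
* Degenerate inputs fail loudly: empty groups, singleton PERMANOVA groups,
  zero-variance correlations, all-zero distance matrices, fossils without
  age ranges, oversampling of a constrained theoretical space.

## Known limitations

* The greedy undefined-pair drop rule and the midpoint time-bin rule are
  defensible defaults, not reconstructions of any particular published
  pipeline's unstated choices; both are logged/configurable.
* Kruskal–Wallis on pairwise distances inherits the non-independence caveat
  above.
* Stress and Shepard values from different nMDS engines (or different start
  counts) agree only approximately; treat them as diagnostics.
* No phylogenetically corrected disparity, no variance-based disparity
  metrics, no hidden-rate Mk extensions, no fossil-tip ASR.
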
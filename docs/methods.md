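# Methods

## The question and the model

The pipeline tests whether the *direction* of a microbial taxon's
response to an experimental perturbation is phylogenetically conserved.
The trait is binary — each OTU responds positively or negatively,
defined by the sign of its log2 treatment/control abundance ratio at a
location — and conservation is quantified as the mean genetic depth τ_D
of the clades within which the direction is (nearly) unanimous. Under
the null hypothesis that responses are scattered at random over the
tips, consensus clades are shallow; phylogenetic conservation makes
them deep.

## Stages

### Response ratios (per location)

1. **Occupancy filter.** OTUs present (nonzero count) in at least
   ⌈f·n⌉ of the n plots are kept (f = 0.5 by default). When this leaves
   fewer than `min_otus` = 900 OTUs, the rule relaxes to presence in
   ≥ 2 plots. The report records which rule fired; the relaxed rule is
   the norm for the synthetic studies here, which have ~100 OTUs per
   location by design.
2. **Normalization.** Median-of-ratios size factors with the reference
   taken as the geometric mean over *positive* counts only, so sparse
   tables are handled without pseudo-inflation; factors are rescaled to
   geometric mean 1. The shrinkage/testing machinery of
   differential-abundance packages is deliberately not used: only the
   normalized ratio is needed downstream.
3. **Ratio.** `log2fc = log2(mean_trt + c) − log2(mean_ctl + c)` on
   normalized counts, with the offset `c = pseudocount · mean(1/factor)`
   (pseudocount 0.5 by default) applied identically to both arms. The
   difference-of-logs form makes the estimator *exactly* antisymmetric
   under swapping the arm labels, and the symmetric offset keeps ratios
   finite when an OTU is absent from one arm. An exactly-zero ratio
   maps to direction `0` and is excluded from both directions of the
   conservation test.

   A compositional caveat, visible in the tests: when a large or
   one-sided fraction of OTUs truly responds, median-of-ratios factors
   absorb part of the common shift, attenuating the *magnitudes*.
   Directions — all that τ_D consumes — are much more robust
   (≥ 90% correct at |log2fc| = 1, dispersion 0.1, 10+10 plots).

### consenTRAIT

* **Tree.** Classic neighbour joining (Q-criterion) from a distance
  matrix when no tree is supplied; negative branch-length estimates are
  clamped to zero with the deficit moved to the sister edge, preserving
  the joined pair's path length. The unrooted result is midpoint-rooted
  — deterministic, and exact on additive matrices (tested). Externally
  supplied rooted trees are used as-is.
* **Consensus clades.** Preorder traversal; a node is recorded (and not
  descended into) when strictly more than the threshold (default 0.90)
  of its direction-carrying descendant tips — at least two of them —
  share one sign. Tips with direction `0` count in neither numerator
  nor denominator. Uncovered direction-carrying tips become singletons
  with depth = half the patristic distance to the nearest tip (a
  `pendant` alternative, half nothing — just the pendant edge — is
  exposed as a config switch for sensitivity checks). A clade's genetic
  depth is the mean distance from the node to *all* its descendant
  tips; with no zero-direction tips the two conventions coincide.
* **τ_D and significance.** τ_D per direction is the mean depth over
  that direction's clades, singletons included. The permutation null
  shuffles the complete direction vector (zeros included, one joint
  shuffle preserving the label multiset) `n_randomizations` = 1000
  times; p is the plain fraction of shuffled τ_D ≥ observed (a zero is
  reported as < 1/N). A direction carried by fewer than two tips gets
  an undefined (None) p. Implementation note: the tree is indexed once
  (contiguous descendant-tip intervals per node), so each randomization
  costs O(n) prefix-sum work; 1000 randomizations on a 128-tip tree
  take ~0.4 s.
* Bootstrap support plays no role in clade selection.

### Community composition

Single seeded rarefaction draw per sample (multivariate hypergeometric)
to the location's minimum library size; Bray–Curtis dissimilarities;
one-factor PERMANOVA with SS_total = Σ_{i<j} d²_ij / n,
SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g, pseudo-F on (a−1, n−a) degrees
of freedom, R² = SS_between/SS_total. The Monte-Carlo p uses the
(1 + count)/(1 + N) convention (999 permutations by default); an
exhaustive-enumeration mode for n ≤ 7 serves as the testing oracle and
returns the exact fraction of label permutations with F ≥ observed.

### Cross-location merge and taxonomy screen

OTUs passing the per-location filters in ≥ 3 locations are averaged
with equal weight per location (unweighted mean over locations where
present), so small and large experiments count equally. The merged
consenTRAIT run uses the input tree pruned to the widespread OTUs
(deterministic; an NJ rebuild from patristic distances is the config
alternative). Context dependence is
`mean over locations of (τ_D(+)+τ_D(−))/2  −  the same quantity merged`.

Taxonomic consistency per rank (phylum…genus): for each group with at
least `min_group_size` = 5 direction-carrying OTUs, a two-tailed exact
binomial test of n₊ vs n₋ against 0.5, implemented as the doubled
smaller tail capped at 1 (at the symmetric null this agrees with the
pmf-summation definition; the doubling convention is the one asserted
by the enumeration oracle). No multiple-testing correction by default
(raw p < 0.05 calls); Benjamini–Hochberg is available but off. The
cross-perturbation matrix tabulates calls and counts groups significant
under exactly one / two / more perturbations and with opposing
directions.

## The synthetic-data generator

The generator emulates the statistical structure of a multi-location
field study, not its sequencing:

* **Tree.** Yule (pure-birth) process — exponential waiting times at
  rate = number of extant lineages, uniform choice of the splitting tip
  — then all branch lengths rescaled so the root-to-tip depth is
  exactly 0.10 substitutions/site, the scale of 16S OTU trees. The
  result is ultrametric; only the depth scale matters to τ_D, which is
  why a coalescent was not needed.
* **Planted directions.** An antichain of clades whose genetic depth is
  closest to the target (descending from the root; a node deeper than
  the target is kept when it is at least as close as each of its
  children) partitions the tips. Each clade draws a sign ±1 with equal
  probability. Two deterministic post-passes make the ground truth
  *exact* rather than merely expected: sibling clades sharing a sign
  are merged into "effective" planted clades (pure set logic), and a
  repair pass re-flips the minority wherever an ancestor's tips would
  exceed the consensus threshold without unanimity, so no undetectable
  or over-deep structure is planted. If repair collapses the whole tree
  to one sign (a contrast-free study), the signs are redrawn, up to 64
  times. At fidelity 1.0 the detector provably returns the effective
  clades verbatim, and recovered τ_D equals the planted mean depth to
  float precision (the acceptance suite asserts ≤ 10%).
* **Fidelity.** Each tip takes its clade's sign with probability
  `fidelity` ∈ (0.5, 1], else the opposite; log2fc magnitudes are
  |Normal(0, 1)| — a stand-in, as no effect-size distribution is
  established for perturbation responders; it is a config knob.
* **Counts.** NB(mean = s_j·μ_i·2^(log2fc·1[treatment]),
  variance = mean + dispersion·mean²), μ_i log-normal (σ = 1) around
  `base_abundance` = 50, s_j ~ Uniform(0.5, 2) library-size factors,
  defaults dispersion 0.2 and 5+5 plots — typical for soil field
  experiments; the analysis scripts use 10+10 plots and dispersion 0.1,
  the regime in which direction estimates are ≥ 90% reliable.
* **Occupancy.** Each OTU present in each location independently with
  probability `occupancy_prob`; absent OTUs are dropped from that
  location's table; the truth is identical everywhere
  (context-independent by construction). Degenerate empty locations or
  all-absent OTUs are patched with one forced presence.

What the generator does **not** emulate: sequencing error, chimeras,
primer bias, taxon-specific dispersion, correlated occupancy, or any
true context dependence of effects. Passing tests therefore show the
*machinery* is correct and calibrated under the stated model, not that
real perturbation responses are conserved.

## Evaluation sizes and numerical choices

* Traversal-vs-enumeration agreement: 500 random trees of 4–64 tips,
  direction frequencies (0.45, 0.45, 0.10) for (+, −, 0).
* Planted recovery and power: 20 seeds per target depth (0.02 and
  0.05), 128 tips, 1000 randomizations.
* Null calibration: 200 trees of 64 tips with i.i.d. ± directions;
  expected 2–9% of p ≤ 0.05 (99% binomial band around 5%).
* Context dependence: 20 seeds, 4 locations, occupancy 0.8, planting
  depth 0.03. The reported quantity uses the planted direction vectors
  restricted by occupancy — isolating what merging itself does to τ_D;
  the count-estimation path is reported alongside, where per-location
  sign errors additionally shallow the per-location τ_D (estimation
  noise, not context dependence). A location where occupancy thinning
  leaves > 90% of present OTUs on one side (the whole subtree collapses
  to one consensus clade, leaving the minority direction without a
  τ_D) is excluded and counted.
* Strict threshold comparisons use `count > threshold · n`; the
  float-vs-rational gap at 0.9 is far below any achievable consensus
  fraction, and the test oracles use exact rationals.
* Joins between trees, tables and taxonomies are by exact string
  equality of identifiers; tips without a response (or responses
  without a tip) are pruned with a logged warning — the original
  handling of such mismatches in field datasets is not standardized,
  so the behaviour is explicit here.

## Known limitations

* τ_D estimates from noisy counts are biased shallow: wrong-sign tips
  fragment consensus clades into singletons (visible in the worked
  example: planted 0.032, recovered ≈ 0.022).
* Median-of-ratios normalization cannot identify a global abundance
  shift; effect magnitudes (not directions) are attenuated when
  responders dominate one side.
* One-factor PERMANOVA only; no stratification, PERMDISP, or
  ordination.
* The exact test treats OTUs as independent within a group, which
  ignores phylogenetic pseudo-replication below the tested rank — the
  same simplification the screening heatmap approach implies.
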
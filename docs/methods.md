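# Methods

## Problem setting

Environmental surveys can recover the DNA of a target organism from many
locations at once — swabs of benches, turnstiles and railings across a city's
transit system, shotgun-sequenced and aligned to a reference genome. After
variant calling, each location contributes one multi-sample VCF column, and
each location carries categorical annotations (borough, above/belowground,
swabbed object, swabbed material, transit lines). `snpsignal` asks whether
those annotations are phylogenetically structured: do samples that are close
on a SNP-based tree share annotation states more often than random
relabelling would produce?

## Data model

Genotypes are **unordered categories**, not allele dosages. A diploid
unphased call is encoded as its sorted allele pair, so `0/1` and `1/2` at a
triallelic site are distinct states and no additivity is assumed. This
matches both downstream uses: unordered-character parsimony and Hamming
distance ask only whether two calls are equal. Half-calls and fully uncalled
genotypes are a single explicit missing state. Positions follow the VCF
convention (1-based).

## Completeness filter

The default filter keeps exactly the variants with a genotype call in at
least 90 % of samples (`min_call_fraction = 0.9`, boundary inclusive: a
variant called in exactly 90 % of samples is kept). This is the standard
site-completeness filter that makes a usable SNP matrix; an optional
per-sample filter (`min_sample_call_fraction`, off by default) is available
for datasets with very uneven coverage. The filter is idempotent and
monotone in the threshold, and stratified analyses re-apply it within each
stratum, because a variant well-called globally may be poorly called in one
subgroup. Monomorphic variants (fewer than two distinct non-missing codes)
are pruned before tree building; they carry no signal and make distances and
parsimony degenerate.

## Trees

Pairwise distances are Hamming mismatch counts with **pairwise deletion**:
each pair is compared only at variants where both samples have calls, and
the normalized form divides by that count. A pair with zero comparable
variants is an error (the matrix is too sparse for distance methods), not a
silent zero.

Trees are built with classical **neighbor-joining** (Saitou–Nei
Q-criterion). NJ was chosen as the default because it is fast,
deterministic, and consistent on additive distances; the signal statistics
accept any tree, so users preferring parsimony or likelihood trees can
import them as Newick. Implementation contracts: Q-ties break toward the
lowest (row, column) index pair, making output deterministic in the input
order; negative branch-length estimates are clamped to zero (topology
unchanged) with the clamped total logged; the unrooted result is stored with
a trifurcating root at the final join, for representation only. Tests
cross-check the implementation against scikit-bio's independent NJ and
verify topology recovery (unrooted Robinson–Foulds distance 0) from additive
matrices up to 12 tips.

Stratified trees re-run the whole chain (subset → completeness filter →
uninformative pruning → distances → NJ) per stratum level. The default
minimum stratum size is 4, the smallest tip count with more than one
unrooted topology. A sample belonging to several levels of a multi-label
variable (several transit lines) appears in each matching stratum's tree.

## Parsimony, retention index, randomization test

Fitch step counts are computed with **Sankoff dynamic programming under unit
costs**, which is exact on arbitrary polytomies (naive set-based Fitch is
exact only on binary trees). With 0/1 costs the child-to-parent message
simplifies to `min(cost[s], min(cost) + 1)`, so the whole pass is a few
vectorized operations per node; permutation replicates are scored as a batch
through the same pass. Tips with missing states receive an all-zero cost
vector — they can always adopt their parent's state and never force a step.
Because substitution costs are symmetric, the score is independent of root
placement; root and tip-order invariance are asserted in tests, including
for the permutation p-value (permuted states are assigned to scored tips in
sorted-label order precisely so that the realized null sample does not
depend on tip storage order or rooting).

Bounds: `M = (distinct observed states) − 1` is the best any tree can do;
`G = (scored tips) − (modal state count)` is the star-tree score (ties in
the modal state leave G unchanged). `RI = (G − S)/(G − M)` is reported when
`G > M`; otherwise the character is flagged uninformative and excluded from
testing rather than propagating a NaN.

The null model shuffles the observed state multiset across the scored tips,
preserving the missingness pattern. M and G are therefore constant across
replicates and only S varies, so `null RI ≥ observed RI` is evaluated as the
integer comparison `null S ≤ observed S` — there are no floating-point tie
ambiguities. The add-one (permutation-inclusive) estimator
`p = (1 + hits)/(1 + n_reps)` keeps p valid and strictly positive; the tie
convention is inclusive, which is conservative. The default is 9,999
replicates and a caller-supplied seed is mandatory. When several (tree,
variable) pairs are tested, each pair's seed is derived from the master seed
via spawned `SeedSequence` children, and a Benjamini–Hochberg adjusted
column is reported alongside the raw p-values, never replacing them.

## Synthetic data

The simulator draws, per variant, an ancestral allele frequency uniform on
[0.1, 0.9] (bounded away from fixation so variants are rarely monomorphic),
then per-deme frequencies from the Balding–Nichols Beta distribution with
differentiation parameter F, then one diploid genotype per sample
binomially from its deme's frequency, then independent per-call missingness.
Metadata contains `deme` (tracking the true deme, or shuffled across samples
in null mode), a binary `elevation` derived from the parity of the deme
label (shuffling the deme label therefore nulls both), and any number of
nuisance variables drawn independently of structure. One master seed feeds
deterministic sub-streams per stage, so changing the missing rate does not
perturb the genotypes drawn.

What the simulator does **not** emulate: linkage disequilibrium between
variants (draws are independent), coalescent ancestry within demes,
selection, pooled or mixed-source swabs (each sample is one individual-like
genotype), and read-level error. Passing tests therefore demonstrate the
statistical machinery — calibration of the null, power under island-model
differentiation, filter and tree correctness — not robustness to those
real-data complications.

## Default study conditions and problem sizes

Power analyses use 4 demes × 15 samples, 300 variants, F = 0.3, 10 %
missingness — a regime where deme structure is strong but not trivial
(roughly half the simulated variants survive the 90 % completeness filter at
10 % missingness). Null calibration uses panmictic data (F = 0) with
4 × 12 samples and 120 variants, 200 independent datasets, and 199
permutation replicates per test — the standard minimal replicate count for
testing at α = 0.05, with the add-one estimator making p a multiple of
1/200. Under these conditions the empirical type-I error sits inside the
exact binomial 99 % interval around 0.05 (0.055 in the suite's seeded run)
and power for the deme character is ≥ 90 % (1.0 observed), while nuisance
labels reject at ≈ 5 %.

## Numerical and degenerate-input choices

* Completeness threshold comparisons use the correctly rounded fraction
  `called / n_samples >= threshold`, which is exact at representable
  boundaries such as 9/10 vs 0.9.
* An empty post-filter variant set is a logged warning at the library level
  (pipelines may legitimately probe strict thresholds); downstream stages
  then refuse to build trees from nothing.
* Fewer than 3 selected samples is an error in `subset_samples` (no
  meaningful tree below 3 tips); strata below the minimum size are skipped
  with a warning rather than failing the run.
* VCF/metadata sample sets are reconciled by intersection, warning with the
  dropped ids; order follows the VCF.
* Newick I/O follows the underscore convention of the format (unquoted
  underscores read as spaces; labels needing protection are quoted on
  write), so write∘read is the identity on labels, topology and lengths.

## Known limitations

Distances and NJ are O(n²)–O(n³) in samples; the intended scale is
hundreds, not tens of thousands, of samples. The retention index treats
characters as nominal and unweighted; ordered or cost-weighted characters,
continuous-trait statistics (Pagel's λ, Blomberg's K) and the consistency
index are out of scope. The permutation null conditions on the tree: it
tests label arrangement given the tree, not uncertainty in the tree itself.
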
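# snpsignal

Phylogenetic signal of categorical sample metadata in multi-sample SNP data.

`snpsignal` is built for population-scale surveys in which an organism is
genotyped from many environmental samples — for example insect DNA recovered
from swabs of urban transit infrastructure — and each sample carries
categorical annotations such as borough, above/belowground location, the
object or material swabbed, or the transit lines a site belongs to. The
question it answers: **are samples that cluster on a SNP-based phylogeny more
alike in an annotation than expected by chance?**

## The statistic

For a categorical character scored on the tips of a tree let

* *S* — the minimum number of unordered state changes the tree requires
  (Fitch parsimony length, computed exactly on arbitrary polytomies by
  dynamic programming over state sets),
* *M* — the minimum achievable on any tree: (distinct observed states) − 1,
* *G* — the maximum: the parsimony length on a star tree,
  (scored tips) − (count of the modal state).

The **retention index** is

    RI = (G − S) / (G − M),        M ≤ S ≤ G,

so RI = 1 means the character is perfectly congruent with the tree and
RI = 0 means maximal homoplasy. RI is undefined when G = M (invariant
character, or every tip distinct); such characters are flagged and skipped.

Significance is assessed with a **randomization test**: the observed state
multiset is shuffled uniformly across the scored tips (missing tips stay
missing), RI is recomputed on the same tree, and the one-sided add-one
Monte-Carlo p-value is

    p = (1 + #{null RI ≥ observed RI}) / (1 + n_reps).

Everything upstream of the statistic is provided too: reading multi-sample
VCFs into an unordered-genotype character matrix, the per-variant
completeness filter (keep variants called in ≥ 90 % of samples, boundary
inclusive), pruning of monomorphic variants, Hamming distances with pairwise
deletion of missing calls, neighbor-joining trees (globally and per stratum),
Newick/PHYLIP/NEXUS export, and a Balding–Nichols island-model simulator for
testing and calibration. Externally built trees can be supplied as Newick —
the test works on any tree.

## Worked example

Simulate four demes with moderate differentiation (F = 0.3), 15 samples per
deme, 300 variants and 10 % missing calls, then test three variables on the
neighbor-joining tree:

```python
import snpsignal as sp

cfg = sp.SimulationConfig(n_demes=4, samples_per_deme=15, n_variants=300,
                          differentiation=0.3, missing_rate=0.1,
                          nuisance_labels=[("object", 3)], seed=13)
matrix, meta = sp.simulate(cfg)
filtered, report = sp.filter_by_completeness(matrix, 0.9)
informative = sp.drop_uninformative(filtered)
tree = sp.neighbor_joining(sp.hamming_distances(informative))
results = sp.run_signal_suite({"global": tree}, meta,
                              ["deme", "elevation", "object"],
                              n_reps=9999, seed=5)
print(sp.results_table(results).to_string(index=False))
```

Output:

```
 variable tree_id  n_scored  S  M  G       RI  n_reps  p_value       seed    p_bh
     deme  global        60  3  3 45 1.000000    9999   0.0001  803261128 0.00015
elevation  global        60  2  1 30 0.965517    9999   0.0001 1619570759 0.00015
   object  global        60 32  2 34 0.062500    9999   0.9972 1062527042 0.99720
```

The geographically linked characters sit at or near RI = 1 — `deme` needs
only its minimum possible 3 changes on the tree — and no permutation out of
9,999 matched them (p = 1/10,000). The nuisance label `object`, drawn
independently of structure, is indistinguishable from its null (RI ≈ 0.06,
p ≈ 1). 177 of 300 simulated variants passed the 90 % completeness filter
under 10 % missingness, 174 of them informative.

The same analysis runs from the shell:

```sh
snpsignal run --config config.yaml          # full pipeline from YAML
snpsignal simulate --config config.yaml --out-prefix out/sim
snpsignal matrix --vcf in.vcf --out-prefix out/m
snpsignal tree --vcf out/m.vcf --metadata meta.tsv --stratify-by elevation --out-prefix out/t
snpsignal signal --tree out/t_global.nwk --metadata meta.tsv \
    --variables borough,elevation,object,material --reps 9999 --seed 13 \
    --out-prefix out/s
```

The pipeline writes every intermediate artifact (filtered VCF, PHYLIP/NEXUS
matrices, distance TSV, Newick trees, results TSV/JSON, annotated tree plots
and null-RI histograms) plus a manifest with the resolved configuration,
seed and per-stage counts; reruns with the same config and seed are
byte-identical.

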
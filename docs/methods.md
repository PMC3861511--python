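# Methods

## The model

The relative distance (RD) statistic asks, per biological replicate,
whether that replicate could be told apart from another treatment group.
Replicates are vectors of log2 fold changes over the active gene set (the
log2 transform is applied before any distance computation; it symmetrizes
up- and down-regulation and is the standard pre-analysis transform for
expression ratios). For focal replicate a1 of group A versus group B:

    d_between = Euclidean distances from a1 to every replicate of B
    d_within  = Euclidean distances from a1 to its own group's siblings
    rd_a1b    = (mean(d_between) − SD(d_between)) − (mean(d_within) + SD(d_within))

The margin composition is chosen so that all four summary quantities move
the sign: the between-group separation is deflated by its spread, the
within-group cohesion inflated by its spread, and a positive rd is a
worst-case-flavored statement of separability. An alternative t-like
ratio form, (mean difference)/(SD sum), is available
(`RDOptions(form="ratio")`); its sign ignores the SDs entirely, which is
why it is not the default. Standard deviations use the sample convention
(n−1) by default, with a population option for sensitivity analysis. With
triplicate groups the SDs are computed from 3 (between) and 2 (within)
distances — small-sample, intentionally so: the statistic is designed for
exactly this n=3 regime.

Two triplicate groups yield six directed rd values (each replicate of
each side as focal). The pair is *discriminated* iff all six are strictly
positive; rd = 0 fails (ties arise only in degenerate constructed
inputs — computation is in double precision and the sign is taken
exactly, with no epsilon). Gene sets are scored by the *overall mean rd*:
the mean of all directed values pooled over every group pair. For equal
group sizes this equals the mean of per-pair means (asserted in tests).

### Generalization beyond triplicates

Group sizes other than 3 are handled naturally: d_between runs over all
|B| replicates, d_within over the |A|−1 siblings, giving |A|+|B| directed
values per pair. With 2-replicate groups the single within-group distance
has no sample SD; it is defined as 0 there. The 3+3 design is the
validated reference.

## Normalization

Raw Ct tables are converted to fold changes by 2^−ΔΔCt: per replicate,
the normalizer is the arithmetic mean of the housekeeping-gene Ct values
— identically the log2 of the geometric mean of their expression levels,
so averaging in Ct space implements the geometric-mean normalizer with no
rounding detour. Each treatment replicate's ΔCt is referenced to the
*mean* control ΔCt (biological replicates are independent pools; no
treatment–control pairing exists in the design). Consequences asserted in
tests: adding a constant to every Ct of one replicate leaves all fold
changes unchanged, and control fold changes geometric-average to 1 per
gene. Missing values are rejected, not imputed — the distance geometry
has no defined behavior under missingness. Efficiency-corrected (Pfaffl)
quantification is out of scope.

## Gene-set search

For each requested size the search reports the gene set maximizing the
overall mean rd. All C(G, s) subsets are enumerated while that count is
within `exhaustive_limit` (default 10^6); past the budget the search
switches to forward selection seeded with the best exhaustively-found set
of the largest exhaustible size, adding at each step the gene that
maximizes the score (beam width configurable; width 1 is plain greedy).
Enumerating every subset of a 61-gene panel (2^61) is not computable, so
results beyond the exhaustive range are labelled with the strategy that
produced them rather than presented as certified optima. All tie-breaks —
among equal-scoring subsets or candidate genes — are lexicographic by
gene id, making results independent of input row order and platform.

The subset scorer precomputes the per-gene squared coordinate differences
between all replicate columns once (G × C × C); a subset's distance
matrix is then a gene-sum and a square root, which keeps exhaustive
enumeration at hundreds of thousands of subsets per minute on one core.

## Clustering validation

Selections are validated by average-linkage agglomerative clustering of
the replicates (inter-cluster distance = mean over all cross-cluster
replicate pairs, Euclidean, on the selected gene set). The agglomeration
is implemented directly rather than delegated to scipy because the
package guarantees a deterministic tie-break (merge the pair whose sorted
leaf-index tuple is lexicographically smallest), which scipy's `linkage`
leaves unspecified; scipy serves as an independent cross-check in the
test suite, alongside a brute-force agglomerator that recomputes every
cluster-pair mean from raw leaf distances. *Purity* cuts the tree into
K = n_groups clusters (the partition after n − K merges) and requires
each group to occupy one cluster, alone; a "clade" alternative instead
requires each group to form a complete subtree. When the cut height ties
with the next merge height (e.g. all replicates identical) the partition
is not height-separated and the result is flagged indeterminate, with
`all_pure` false. No significance value is attached to dendrograms: no
defined test exists for average-linkage merges in this setting.

## Synthetic data

The generator emulates a small qPCR array study: G genes × (K groups ×
n replicates), fold changes relative to an untreated control. Planted
genes get per-group mean log2 fold changes chosen by the user (so their
discriminability is ground truth); null genes share mean 0 everywhere.
Noise is Gaussian in log2 space with SD `null_sigma` (default 0.3, a
typical replicate-to-replicate spread for qPCR fold changes); a
lognormal-in-linear-space alternative exists to stress-test scale
sensitivity. The reference panel shape is 61 genes × 5 groups × 3
replicates. `generate_ct` emits the same design as a raw Ct table —
targets at baseline 25 cycles minus the log2 fold change, three constant
housekeeping genes, a noiseless control — constructed so that 2^−ΔΔCt
normalization recovers the generated fold changes to machine precision.

What the generator does **not** emulate: amplification-efficiency
variation between primers, Ct censoring at the cycle limit,
between-batch effects, or correlated responses among genes in a shared
pathway. Passing tests therefore demonstrate correctness of the
statistics and search under the stated noise model, not robustness to
every artifact of real qPCR data.

## Problem sizes and seeds

The test suite and the acceptance script run on deliberately small
instances: oracle agreement on 200 random triplicate pairs (gene-set
sizes 1–61), planted-recovery sweeps of 50 seeded panels (~22 genes, 2–3
groups), greedy-versus-exhaustive on 30 twelve-gene panels (4095 subsets
each), and clustering sweeps of 50 five-group panels. These sizes give
stable rates while keeping a full run around a minute; every random draw
is seeded and the acceptance script derives all sub-seeds from its
`--seed` argument.

## Known limitations

- No null distribution or p-value is defined for rd; the all-positive
  rule is a deterministic criterion, not a test with controlled error
  rate (on pure-noise genes it fires at roughly the half-percent level
  per gene-pair under the default design).
- Selected gene sets are not cross-validated; the score is in-sample.
- Greedy/beam results beyond the exhaustive budget are not certified
  optima (the label says which strategy produced each size).
- The original 61-gene array dataset that motivated the method is not
  redistributable here (its supplementary table was never deposited), so
  the structural-reproduction check against it cannot run; equivalent
  structure is exercised on synthetic panels of identical shape.
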
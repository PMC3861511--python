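# rdselect

Biomarker selection for multi-gene qRT-PCR arrays via the **relative
distance (RD)** statistic: a replicate-level measure of how separable two
treatment groups are in gene-expression space, used to screen single genes
for pairwise discrimination, to search gene *sets* that discriminate every
treatment simultaneously, and to validate selections by average-linkage
clustering.

The intended users are toxicogenomics and exposure-biology groups who run
small qPCR panels (tens of genes, a handful of treatments, triplicate
biological replicates) and need to pick the genes — or the smallest gene
combination — that tells their treatments apart.

## The statistic

Replicates are points in log2 fold-change space over a chosen gene set of
size *j* (fold changes from the 2^−ΔΔCt method against the geometric mean
of housekeeping genes). For focal replicate *a₁* of group A against group
B = {b₁, b₂, b₃}:

- *d(a₁, bᵢ)* — Euclidean distances to the other group's replicates, with
  mean *md_a1b* and standard deviation *SD_a1b* (sample SD, n−1),
- *d(a₁, a₂)*, *d(a₁, a₃)* — distances to the focal replicate's own
  siblings, with mean *md_aa* and SD *SD_aa*,

and the directed relative distance is the SD-adjusted margin

```
rd_a1b = (md_a1b − SD_a1b) − (md_aa + SD_aa)
```

— positive when the focal replicate is closer to its own group than to the
other one even after penalizing both spreads. Two triplicate groups yield
six directed values; the gene set **discriminates** the pair iff all six
are strictly positive. Gene sets are ranked by the **overall mean RD**,
the mean of all directed values pooled over every group pair (60 values
for 5 triplicate groups). A t-like ratio form and a population-SD
convention are available as options for sensitivity analysis.

## Worked example

`examples/search_sets.py` plants two genes in a 12-gene, 3-group panel so
that they separate all groups only jointly, then searches for the best
gene set per size:

```
best gene set per size (overall mean rd, all-pairs discrimination):
 size  max_mean_rd  discriminates_all   strategy               genes
    1     1.829333              False exhaustive                g002
    2     2.825040               True exhaustive           g001;g002
    3     2.772884               True exhaustive      g001;g002;g006
    4     2.681292               True exhaustive g001;g002;g006;g010
```

No single gene discriminates all three groups, but the planted pair
g001+g002 does, and the exhaustive search recovers it exactly. The other
examples cover 2^−ΔΔCt normalization (`normalize_ct.py`), single-gene
screening (`screen_pairs.py`) and clustering validation
(`cluster_check.py`).

The same workflows are available from the shell:

```bash
rdselect simulate --seed 1 --out-dir run/
rdselect screen --input run/foldchange.csv --out-dir run/
rdselect search --input run/foldchange.csv --sizes 1-5 --out-dir run/
rdselect cluster --input run/foldchange.csv --genes g001,g002 --out-dir run/
```

Input tables are CSV/TSV with genes as rows and `group.replicate` column
headers (or a sidecar design file mapping arbitrary column names).

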
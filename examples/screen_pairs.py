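"""Screen single genes for pairwise group discrimination.

Simulates a 23-gene panel in which exactly three genes are planted with
large between-group effects, screens every (gene, group pair), and prints
the ranking for the pair of interest. A gene "discriminates" a pair when
all six directed relative-distance (rd) values are strictly positive.
"""

from rdselect import SyntheticDesign, generate, screen_genes, to_log2_foldchange

design = SyntheticDesign(
    n_genes=23, n_groups=2,
    planted={"g001": [0.0, 3.0], "g002": [3.0, 0.0], "g003": [-3.0, 3.0]},
    null_sigma=0.3, seed=0,
)
matrix = to_log2_foldchange(generate(design))
table = screen_genes(matrix)

top = table.head(6)[["gene", "pair", "mean_rd", "discriminates"]]
print("top genes for grp1 vs grp2, ranked by mean rd:")
print(top.to_string(index=False))
print(
    f"\nflagged discriminating: {sorted(table[table.discriminates].gene)}\n"
    "The three planted genes (g001-g003) top the ranking and are the only "
    "ones whose six rd values are all positive; the 20 null genes fail the "
    "test. mean_rd is the average of the six directed rd values (log2 "
    "fold-change units)."
)
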
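"""Search gene sets that discriminate all treatment groups at once.

Simulates a 3-group panel where two planted genes separate all groups only
jointly — g001 splits group 1 from groups 2-3, g002 splits group 3 from
groups 1-2 — then asks for the best gene set at each size by overall mean
rd (the mean of all directed rd values pooled over every group pair).
"""

from rdselect import SyntheticDesign, generate, search_gene_sets, to_log2_foldchange

design = SyntheticDesign(
    n_genes=12, n_groups=3,
    planted={"g001": [0.0, 3.0, 3.0], "g002": [0.0, 0.0, 3.0]},
    null_sigma=0.3, seed=1,
)
matrix = to_log2_foldchange(generate(design))
result = search_gene_sets(matrix, sizes=range(1, 5))

print("best gene set per size (overall mean rd, all-pairs discrimination):")
print(result.to_frame().to_string(index=False))
print(
    "\nNo single gene discriminates all three groups "
    "(discriminates_all is False at size 1), but the planted pair "
    "g001+g002 does at size 2 — the search recovers it exactly. "
    "C(12, s) is small here, so every size is solved exhaustively."
)
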
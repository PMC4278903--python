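"""Hypergeometric gene-set enrichment on a toy term map.

Given genes carrying node-private variants (the query) and all annotated
genes (the background), each term's p-value is the upper-tail
hypergeometric probability of at least the observed overlap; Benjamini-
Hochberg adjusted values are reported alongside.
"""

from clonetriage.annotate import gene_set_enrichment

background = {f"G{i:03d}" for i in range(200)}
query = {f"G{i:03d}" for i in range(12)}  # genes hit by node-private variants
term_map = {
    "keratinization": {f"G{i:03d}" for i in range(8)} | {"G150"},
    "cell_cycle": {f"G{i:03d}" for i in range(5, 45)},
    "unrelated": {f"G{i:03d}" for i in range(100, 140)},
}

table = gene_set_enrichment(query, background, term_map)
print(table.to_string(index=False))
print()
print("(overlap = query genes carrying the term; p_raw = hypergeometric "
      "upper tail; p_bh = Benjamini-Hochberg adjusted)")
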
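"""Triage of the published six-variant worked example.

Builds the matched tumor/node/normal call sets for the six COSMIC-listed
somatic variants of a breast tumor / axillary node case, subtracts the
(empty) normal, partitions tumor vs node, and annotates against the
matching catalog.  Expected: 2 shared (truncal), 3 tumor-private,
1 node-private — the node-private call being a 1-bp coding insertion,
i.e. a frameshift.
"""

from clonetriage.annotate import DictReference, functional_impact
from clonetriage.casestudy import (
    case_gene_models,
    cosmic_six_catalog,
    cosmic_six_trio,
)
from clonetriage.pipeline import run_trio

normal, tumor, node = cosmic_six_trio()
result = run_trio(
    normal, tumor, node, case_gene_models(),
    cosmic=cosmic_six_catalog(), min_depth=0,
)

print("partition:", result.partition.counts())
print("catalog hits:", len(result.partition.cosmic_ids))
print()
print(result.cosmic_table.to_string(index=False))

((key, call),) = result.partition.node_private.items()
gene = next(g for g in case_gene_models() if g.gene_symbol == "PDS5B")
ref = DictReference({"13": "A" * (gene.gene_span.end + 10)})
impact = functional_impact(call, gene, ref)
print()
print(f"node-private {key.alt!r} insertion in PDS5B CDS -> {impact.impact.value}")
print("(a 1-bp insertion shifts the reading frame: 1 mod 3 != 0)")
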
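"""Multi-clone evidence from discordant same-gene frequencies.

The worked case reported two node-private TGIF2 insertions at 23.4% and
92.9% VAF; a single clone cannot comfortably carry both, so the gene is
flagged as evidence that at least two clones predominate in the node.
An equal-frequency pair must not be flagged.
"""

from clonetriage.casestudy import tgif2_discordant_pair
from clonetriage.clonality import clonality_summary
from clonetriage.triage import compare_tumor_node
from clonetriage.variants import SampleVariantSet

node, gene, panel = tgif2_discordant_pair()
partition = compare_tumor_node(SampleVariantSet("tumor", "tumor"), node)
report = clonality_summary(
    partition, gene_map={k: "TGIF2" for k in partition.all_keys}
)

for flag in report.multi_clone_flags:
    print(
        f"multi-clone flag: {flag.gene_symbol} ({flag.sample}): "
        f"{flag.min_frequency}% vs {flag.max_frequency}% "
        f"(spread {flag.spread} points > 30-point threshold)"
    )
for key, note in report.notes.items():
    print(f"note at {key.chrom}:{key.start}: {note}")
print("labels:", report.label_counts())
print("(two VAFs 69.5 points apart in one gene imply two distinct clones; "
      "the high-VAF call alone would suggest homozygosity or amplification)")
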
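"""Worked example from a published matched breast-cancer case.

A whole-genome comparison of a primary breast tumor, an involved axillary
lymph node and matched normal blood reported six somatic variants with
COSMIC catalog entries: three unique to the tumor (SNVs in *MUC12* and
*ZNF99*, a single-base deletion in *FHOD1*), one unique to the node (a
single-base coding insertion in *PDS5B* — a frameshift), and two shared
by tumor and node (SNVs in *ARAP3* and *TP53*).  This module builds that
call-set trio, the matching COSMIC-style catalog, and toy gene models
placing each variant in a plausible region (the *PDS5B* insertion inside
a CDS), so the whole triage-and-annotation path can be exercised end to
end on a real, hand-checkable example.

Read depths and alt-read counts are synthetic round numbers (the printed
report carried no read-level evidence); nothing downstream asserts them.
It also provides the node's discordant-frequency *TGIF2* pair (a 3'UTR
insertion at 23.4% VAF and an upstream-of-TSS insertion at 92.9%), the
case's flagship multi-clone signal.
"""

from __future__ import annotations

from .io import CatalogSnapshot, GeneModel, GenePanel
from .variants import (
    GenomicInterval,
    SampleRole,
    SampleVariantSet,
    VariantCall,
    VariantKey,
    classify_variant_type,
)

__all__ = [
    "COSMIC_SIX",
    "cosmic_six_trio",
    "cosmic_six_catalog",
    "case_gene_models",
    "tgif2_discordant_pair",
]

# (chrom, start, end, ref, alt, cosmic_id, gene, in_tumor, in_node)
COSMIC_SIX = [
    ("5", 141033869, 141033870, "T", "G", "COSM32578", "ARAP3", True, True),
    ("7", 100612086, 100612087, "A", "G", "COSM147730", "MUC12", True, False),
    ("13", 33344887, 33344887, "", "A", "COSM85618", "PDS5B", False, True),
    ("16", 67267851, 67267852, "G", "", "COSM50200", "FHOD1", True, False),
    ("17", 7577093, 7577094, "G", "A", "COSM10704", "TP53", True, True),
    ("19", 22954575, 22954576, "A", "G", "COSM140394", "ZNF99", True, False),
]

_DEPTH = 120
_ALT = 54  # synthetic evidence: ~45% VAF, typical of a clonal somatic het


def _call(row) -> VariantCall:
    chrom, start, end, ref, alt, _, gene, _, _ = row
    return VariantCall(
        interval=GenomicInterval(chrom, start, end),
        vtype=classify_variant_type(ref, alt),
        ref_allele=ref,
        alt_allele=alt,
        position_read_depth=_DEPTH,
        alt_read_count=_ALT,
        gene_hint=gene,
        normalized=True,
    )


def cosmic_six_trio() -> tuple[SampleVariantSet, SampleVariantSet, SampleVariantSet]:
    """(normal, tumor, node) call sets for the six-variant example; the
    normal is empty — none of the six was present in blood."""
    normal = SampleVariantSet("case_normal", SampleRole.NORMAL)
    tumor = SampleVariantSet(
        "case_tumor", SampleRole.TUMOR, (_call(r) for r in COSMIC_SIX if r[7])
    )
    node = SampleVariantSet(
        "case_node", SampleRole.NODE, (_call(r) for r in COSMIC_SIX if r[8])
    )
    return normal, tumor, node


def cosmic_six_catalog() -> CatalogSnapshot:
    entries = {
        VariantKey(chrom, start, end, ref, alt): cid
        for chrom, start, end, ref, alt, cid, *_ in COSMIC_SIX
    }
    return CatalogSnapshot("COSMIC_case", entries)


def case_gene_models() -> list[GeneModel]:
    """Toy single-gene models: each variant sits inside a 300-bp CDS of its
    gene, so the PDS5B 1-bp insertion reads out as a coding frameshift."""
    models = []
    for chrom, start, _end, _ref, _alt, _cid, gene, *_ in COSMIC_SIX:
        cds_start = (start // 10) * 10 - 87  # CDS strictly contains the variant
        cds = GenomicInterval(chrom, cds_start, cds_start + 300)
        span = GenomicInterval(chrom, cds_start - 300, cds_start + 600)
        models.append(
            GeneModel(
                gene_symbol=gene,
                chrom=chrom,
                strand="+",
                gene_span=span,
                cds_intervals=[cds],
                utr5_intervals=[GenomicInterval(chrom, span.start, cds_start)],
                utr3_intervals=[GenomicInterval(chrom, cds.end, span.end)],
            )
        )
    return models


def tgif2_discordant_pair() -> tuple[SampleVariantSet, GeneModel, GenePanel]:
    """The node's two TGIF2 insertions at 23.4% and 92.9% VAF.

    TGIF2 is modeled as a plus-strand gene on chromosome 20; the 23.4%
    single-base insertion sits in its 3'UTR and the 92.9% three-base
    insertion upstream of the TSS.  Depth 1000 makes the printed
    percentages exact.
    """
    chrom = "20"
    tss = 35_202_000
    span = GenomicInterval(chrom, tss, tss + 2000)
    cds = GenomicInterval(chrom, tss + 200, tss + 1400)
    utr3 = GenomicInterval(chrom, tss + 1400, tss + 2000)
    gene = GeneModel(
        gene_symbol="TGIF2",
        chrom=chrom,
        strand="+",
        gene_span=span,
        cds_intervals=[cds],
        utr5_intervals=[GenomicInterval(chrom, tss, tss + 200)],
        utr3_intervals=[utr3],
    )
    utr3_ins = VariantCall(
        interval=GenomicInterval(chrom, utr3.start + 100, utr3.start + 100),
        vtype=classify_variant_type("", "A"),
        ref_allele="",
        alt_allele="A",
        position_read_depth=1000,
        alt_read_count=234,  # 23.4%
        gene_hint="TGIF2",
        normalized=True,
    )
    upstream_ins = VariantCall(
        interval=GenomicInterval(chrom, tss - 150, tss - 150),
        vtype=classify_variant_type("", "CAT"),
        ref_allele="",
        alt_allele="CAT",
        position_read_depth=1000,
        alt_read_count=929,  # 92.9%
        gene_hint="TGIF2",
        normalized=True,
    )
    node = SampleVariantSet("case_node_cin25", SampleRole.NODE, [utr3_ins, upstream_ins])
    panel = GenePanel("CIN25_subset", {"TGIF2", "TOP2A", "CCNB2"})
    return node, gene, panel
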
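"""Gene-region assignment, functional-impact calling and gene-set work.

Region assignment is strand-aware and deterministic: every (call, gene)
pair yields exactly one region, chosen by the precedence

    splice_site > cds > utr5/utr3 > intron > upstream_tss > downstream
    > flanking_intergenic

"Upstream of the TSS" means promoter-proximal sequence in transcription
orientation — upstream of a minus-strand gene lies at larger genomic
coordinates.  Distances to the TSS are signed in transcription
orientation (negative = upstream).

Functional impact follows the standard consequence rules: CDS SNVs are
translated codon-by-codon (missense / synonymous / nonsense); CDS indels
and length-changing substitutions are frameshift when the net length
change is not a multiple of 3, otherwise in-frame; variants within 2 bp
of an intron boundary hit the canonical splice dinucleotides.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Protocol

import pandas as pd
from Bio.Seq import Seq
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneModel, GenePanel
from .triage import TriagePartition
from .variants import (
    GenomicInterval,
    ReferenceInconsistencyError,
    VariantCall,
    VariantKey,
    VariantType,
)

__all__ = [
    "Region",
    "Impact",
    "RegionAssignment",
    "ImpactCall",
    "ReferenceSource",
    "DictReference",
    "assign_region",
    "assign_regions",
    "functional_impact",
    "restrict_to_panel",
    "gene_set_enrichment",
    "DEFAULT_UPSTREAM_WINDOW",
    "DEFAULT_FLANK_WINDOW",
    "SPLICE_WINDOW",
]

DEFAULT_UPSTREAM_WINDOW = 2000  # bp of promoter-proximal sequence 5' of the TSS
DEFAULT_FLANK_WINDOW = 2000  # bp of flanking sequence beyond the gene span
SPLICE_WINDOW = 2  # canonical splice dinucleotides at each intron edge


class Region(str, enum.Enum):
    UPSTREAM_TSS = "upstream_tss"
    UTR5 = "utr5"
    CDS = "cds"
    INTRON = "intron"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    UTR3 = "utr3"
    DOWNSTREAM = "downstream"
    FLANKING_INTERGENIC = "flanking_intergenic"


class Impact(str, enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    CODING_SUBSTITUTION = "coding_substitution"
    SPLICE_SITE = "splice_site"
    NONCODING = "noncoding"

    @property
    def is_functional(self) -> bool:
        """Likely-functional categories: splice, missense/nonsense, and any
        coding indel or substitution."""
        return self in (
            Impact.MISSENSE,
            Impact.NONSENSE,
            Impact.FRAMESHIFT,
            Impact.INFRAME_INDEL,
            Impact.CODING_SUBSTITUTION,
            Impact.SPLICE_SITE,
        )


@dataclass(frozen=True)
class RegionAssignment:
    gene_symbol: str
    region: Region
    distance_to_tss: int  # signed, transcription orientation; negative = upstream


@dataclass(frozen=True)
class ImpactCall:
    impact: Impact
    details: str = ""


class ReferenceSource(Protocol):
    def fetch(self, chrom: str, start: int, end: int) -> str: ...


class DictReference:
    """Reference genome held as chrom → sequence strings."""

    def __init__(self, seqs: Mapping[str, str]) -> None:
        self._seqs = dict(seqs)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end]

    def base(self, chrom: str, pos: int) -> str:
        return self._seqs[chrom][pos]


def _variant_point(call: VariantCall) -> int:
    return call.interval.start


def _overlaps(call: VariantCall, iv: GenomicInterval) -> bool:
    return call.interval.overlaps(iv)


def assign_region(
    call: VariantCall,
    gene: GeneModel,
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    flank_window: int = DEFAULT_FLANK_WINDOW,
) -> Optional[RegionAssignment]:
    """Place one variant relative to one gene; ``None`` when the variant is
    on another chromosome or beyond every window."""
    if call.chrom != gene.chrom:
        return None
    p = _variant_point(call)
    d = p - gene.tss if gene.strand == "+" else gene.tss - p

    def hit(region: Region) -> RegionAssignment:
        return RegionAssignment(gene.gene_symbol, region, d)

    # splice sites: first/last SPLICE_WINDOW bp of each intron
    for intron in gene.introns:
        if len(intron) < 2 * SPLICE_WINDOW:
            continue
        left = GenomicInterval(gene.chrom, intron.start, intron.start + SPLICE_WINDOW)
        right = GenomicInterval(gene.chrom, intron.end - SPLICE_WINDOW, intron.end)
        # transcription-5' edge of the intron is the donor site
        donor, acceptor = (left, right) if gene.strand == "+" else (right, left)
        if _overlaps(call, donor):
            return hit(Region.SPLICE_DONOR)
        if _overlaps(call, acceptor):
            return hit(Region.SPLICE_ACCEPTOR)

    for iv in gene.cds_intervals:
        if _overlaps(call, iv):
            return hit(Region.CDS)
    for iv in gene.utr5_intervals:
        if _overlaps(call, iv):
            return hit(Region.UTR5)
    for iv in gene.utr3_intervals:
        if _overlaps(call, iv):
            return hit(Region.UTR3)

    span = gene.gene_span
    inside = (
        span.start < p < span.end
        if call.vtype is VariantType.INS
        else span.contains_point(p)
    )
    if inside:
        return hit(Region.INTRON)

    if -upstream_window <= d < 0:
        return hit(Region.UPSTREAM_TSS)

    # transcription-downstream of the gene end
    if gene.strand == "+":
        down = span.end <= p < span.end + flank_window
    else:
        down = span.start - flank_window <= p < span.start
    if down:
        return hit(Region.DOWNSTREAM)

    # residual flank (e.g. upstream beyond the promoter window)
    if span.start - flank_window <= p < span.end + flank_window:
        return hit(Region.FLANKING_INTERGENIC)
    return None


def assign_regions(
    call: VariantCall,
    genes: Iterable[GeneModel],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    flank_window: int = DEFAULT_FLANK_WINDOW,
) -> list[RegionAssignment]:
    """Annotate a call against every overlapping gene (a call near two genes
    gets two assignments; downstream consumers decide how to use them)."""
    out = []
    for g in genes:
        ra = assign_region(call, g, upstream_window, flank_window)
        if ra is not None:
            out.append(ra)
    return out


_STOP = "*"


def _cds_index(gene: GeneModel, p: int) -> Optional[int]:
    """Transcription-order CDS coordinate of genomic position ``p``."""
    total = sum(len(iv) for iv in gene.cds_intervals)
    offset = 0
    for iv in gene.cds_intervals:  # genomic order
        if iv.contains_point(p):
            genomic_off = offset + (p - iv.start)
            return genomic_off if gene.strand == "+" else total - 1 - genomic_off
        offset += len(iv)
    return None


def _cds_sequence(gene: GeneModel, reference: ReferenceSource) -> str:
    seq = "".join(
        reference.fetch(gene.chrom, iv.start, iv.end) for iv in gene.cds_intervals
    )
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def functional_impact(
    call: VariantCall,
    gene: GeneModel,
    reference: ReferenceSource,
    region: Optional[RegionAssignment] = None,
) -> ImpactCall:
    """Consequence call for one variant against one gene model.

    ``region`` may be passed in to avoid recomputing the assignment; when
    omitted it is derived with default windows.
    """
    if region is None:
        region = assign_region(call, gene)
    if region is None or region.region in (
        Region.UPSTREAM_TSS,
        Region.DOWNSTREAM,
        Region.FLANKING_INTERGENIC,
        Region.INTRON,
        Region.UTR5,
        Region.UTR3,
    ):
        return ImpactCall(Impact.NONCODING, region.region.value if region else "")
    if region.region in (Region.SPLICE_ACCEPTOR, Region.SPLICE_DONOR):
        return ImpactCall(Impact.SPLICE_SITE, region.region.value)

    # CDS
    iv = call.interval
    if call.ref_allele:
        observed = reference.fetch(iv.chrom, iv.start, iv.end)
        if observed != call.ref_allele:
            raise ReferenceInconsistencyError(
                f"reference at {iv.chrom}:{iv.start} is {observed!r}, "
                f"call says {call.ref_allele!r}"
            )
    net = len(call.alt_allele) - len(call.ref_allele)
    if call.vtype is not VariantType.SNV:
        if net % 3 != 0:
            return ImpactCall(Impact.FRAMESHIFT, f"net length change {net:+d}")
        if net != 0:
            return ImpactCall(Impact.INFRAME_INDEL, f"net length change {net:+d}")
        return ImpactCall(Impact.CODING_SUBSTITUTION, "length-preserving")

    cds = _cds_sequence(gene, reference)
    ci = _cds_index(gene, iv.start)
    if ci is None:  # CDS overlap without containment cannot happen for SNVs
        return ImpactCall(Impact.NONCODING, "outside CDS")
    alt_base = call.alt_allele
    if gene.strand == "-":
        alt_base = str(Seq(alt_base).reverse_complement())
    codon_i, within = divmod(ci, 3)
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:  # trailing partial codon (CDS not multiple of 3)
        return ImpactCall(Impact.MISSENSE, "partial terminal codon")
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    aa_before = str(Seq(codon).translate())
    aa_after = str(Seq(mutated).translate())
    details = f"codon {codon_i + 1} {codon}>{mutated} p.{aa_before}>{aa_after}"
    if aa_after == aa_before:
        return ImpactCall(Impact.SYNONYMOUS, details)
    if aa_after == _STOP:
        return ImpactCall(Impact.NONSENSE, details)
    return ImpactCall(Impact.MISSENSE, details)


def restrict_to_panel(
    partition: TriagePartition,
    panel: GenePanel,
    gene_models: Iterable[GeneModel],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    flank_window: int = DEFAULT_FLANK_WINDOW,
) -> tuple[TriagePartition, dict[VariantKey, list[RegionAssignment]]]:
    """Keep only partition keys whose region assignment maps to a panel gene
    (within the upstream/flank windows).

    Returns the restricted partition plus the panel-gene region assignments
    per retained key.  Gene models missing for panel symbols are tolerated
    (a symbol with no model simply cannot retain variants).
    """
    if len(panel) == 0:
        raise ValueError(f"panel {panel.name!r} is empty")
    panel_models = [g for g in gene_models if g.gene_symbol in panel]
    kept: dict[VariantKey, list[RegionAssignment]] = {}

    def keep(key: VariantKey, call: VariantCall) -> bool:
        ras = assign_regions(call, panel_models, upstream_window, flank_window)
        if ras:
            kept[key] = ras
            return True
        return False

    shared = {k: v for k, v in partition.shared.items() if keep(k, v[0])}
    tumor_private = {
        k: c for k, c in partition.tumor_private.items() if keep(k, c)
    }
    node_private = {k: c for k, c in partition.node_private.items() if keep(k, c)}
    restricted = TriagePartition(
        shared=shared,
        tumor_private=tumor_private,
        node_private=node_private,
        known_in_dbsnp={
            k: v for k, v in partition.known_in_dbsnp.items() if k in kept
        },
        cosmic_ids={k: v for k, v in partition.cosmic_ids.items() if k in kept},
        low_confidence=partition.low_confidence & set(kept),
    )
    return restricted, kept


def gene_set_enrichment(
    query_genes: set[str],
    background_genes: set[str],
    term_map: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation test per term.

    For each term, the upper-tail probability of drawing at least the
    observed overlap when ``|query|`` genes are sampled without replacement
    from the background, of which ``|term ∩ background|`` carry the term.
    Benjamini–Hochberg adjusted values accompany the raw p-values.
    """
    if not query_genes <= background_genes:
        extra = sorted(query_genes - background_genes)[:5]
        raise ValueError(f"query genes not in background, e.g. {extra}")
    M, N = len(background_genes), len(query_genes)
    rows = []
    for term, genes in term_map.items():
        term_bg = genes & background_genes
        n = len(term_bg)
        k = len(term_bg & query_genes)
        p = float(hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append({"term": term, "overlap": k, "term_size": n, "p_raw": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_raw"])
    if not df.empty:
        df["p_bh"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    else:
        df["p_bh"] = []
    return df.sort_values("p_raw", kind="stable").reset_index(drop=True)
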
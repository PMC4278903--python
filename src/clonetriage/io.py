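"""Readers and writers for every file format the pipeline touches.

Formats
-------
* **VCF 4.x** — read via :mod:`cyvcf2`; 1-based anchored records are
  converted to the internal 0-based half-open dialect with anchor bases
  trimmed, so a VCF indel and the same indel in tab-separated form produce
  identical variant keys.  Multi-allelic records are split into biallelic
  calls; non-PASS records are kept but marked ``no_call``.
* **CG-style TSV** — a tab-separated dialect with columns
  ``chromosome  start  end  type  reference  variant  depth  alt_reads
  [catalog_id]``; ``-`` denotes an empty allele; coordinates already
  0-based half-open (insertions have start == end).
* **Gene models** — GFF3 (gene/mRNA/CDS/five_prime_UTR/three_prime_UTR
  features) or an 8-column TSV (see :func:`read_gene_model_tsv`).
* **Catalogs** — variant-keyed TSV snapshots standing in for dbSNP / COSMIC.
* **Panels** — one gene symbol per line (e.g. the CIN25 list).

Chromosome names are normalized by stripping a leading ``chr`` prefix by
default (configurable), so ``chr17`` and ``17`` match.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from cyvcf2 import VCF

from .variants import (
    CallStatus,
    GenomicInterval,
    SampleRole,
    SampleVariantSet,
    VariantCall,
    VariantKey,
    VariantType,
    classify_variant_type,
    _trim_shared,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "CatalogSnapshot",
    "GenePanel",
    "read_vcf",
    "write_vcf",
    "read_cg_tsv",
    "write_cg_tsv",
    "read_gene_model",
    "read_gene_model_tsv",
    "read_gene_model_gff3",
    "write_gene_model_gff3",
    "read_catalog",
    "write_catalog",
    "read_panel",
    "write_panel",
    "normalize_chrom",
]

_TYPE_LABELS = {
    VariantType.SNV: "SNV",
    VariantType.INS: "Insertion",
    VariantType.DEL: "Deletion",
    VariantType.SUB: "Substitution",
}
_LABEL_TYPES = {v.lower(): k for k, v in _TYPE_LABELS.items()}
_LABEL_TYPES.update({t.value: t for t in VariantType})

CG_COLUMNS = [
    "chromosome",
    "start",
    "end",
    "type",
    "reference",
    "variant",
    "depth",
    "alt_reads",
    "catalog_id",
]


def normalize_chrom(name: str, strip_chr: bool = True) -> str:
    """Canonical chromosome label (``chr17`` → ``17`` by default)."""
    if strip_chr and name.lower().startswith("chr"):
        return name[3:]
    return name


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """Strand-aware gene geometry: TSS, CDS, UTRs and span.

    Intervals are genomic (0-based half-open) and stored sorted by start;
    ``cds_intervals`` in *transcription* order means reverse genomic order
    on the minus strand — accessors below handle that.
    """

    gene_symbol: str
    chrom: str
    strand: str
    gene_span: GenomicInterval
    cds_intervals: list[GenomicInterval] = field(default_factory=list)
    utr5_intervals: list[GenomicInterval] = field(default_factory=list)
    utr3_intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for name in ("cds_intervals", "utr5_intervals", "utr3_intervals"):
            ivs = sorted(getattr(self, name), key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping {name} in {self.gene_symbol}")
            setattr(self, name, ivs)
        total = sum(len(iv) for iv in self.cds_intervals)
        if self.cds_intervals and total % 3 != 0:
            warnings.warn(
                f"{self.gene_symbol}: CDS length {total} not a multiple of 3",
                stacklevel=2,
            )

    @property
    def tss(self) -> int:
        """Transcription start site: span start on +, span end − 1 on −."""
        if self.strand == "+":
            return self.gene_span.start
        return self.gene_span.end - 1

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_intervals)

    @property
    def exons(self) -> list[GenomicInterval]:
        """Merged UTR+CDS intervals in genomic order."""
        ivs = sorted(
            self.utr5_intervals + self.cds_intervals + self.utr3_intervals,
            key=lambda iv: iv.start,
        )
        merged: list[GenomicInterval] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, max(merged[-1].end, iv.end)
                )
            else:
                merged.append(iv)
        return merged

    @property
    def introns(self) -> list[GenomicInterval]:
        ex = self.exons
        return [
            GenomicInterval(self.chrom, a.end, b.start)
            for a, b in zip(ex, ex[1:])
            if b.start > a.end
        ]

    def cds_in_transcription_order(self) -> list[GenomicInterval]:
        return self.cds_intervals if self.strand == "+" else self.cds_intervals[::-1]


def _fmt_ivs(ivs: list[GenomicInterval]) -> str:
    return ",".join(f"{iv.start}-{iv.end}" for iv in ivs) or "."


def _parse_ivs(chrom: str, text: str) -> list[GenomicInterval]:
    if not text or text == ".":
        return []
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


GENE_TSV_COLUMNS = [
    "gene_symbol",
    "chromosome",
    "strand",
    "span_start",
    "span_end",
    "cds_intervals",
    "utr5_intervals",
    "utr3_intervals",
]


def read_gene_model_tsv(path: str | Path, strip_chr: bool = True) -> list[GeneModel]:
    """Read the 8-column gene TSV.

    Columns: gene_symbol, chromosome, strand, span_start, span_end,
    cds_intervals, utr5_intervals, utr3_intervals.  Interval lists are
    comma-separated ``start-end`` pairs (0-based half-open), ``.`` if empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(GENE_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene TSV {path} missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        chrom = normalize_chrom(row.chromosome, strip_chr)
        genes.append(
            GeneModel(
                gene_symbol=row.gene_symbol,
                chrom=chrom,
                strand=row.strand,
                gene_span=GenomicInterval(chrom, int(row.span_start), int(row.span_end)),
                cds_intervals=_parse_ivs(chrom, row.cds_intervals),
                utr5_intervals=_parse_ivs(chrom, row.utr5_intervals),
                utr3_intervals=_parse_ivs(chrom, row.utr3_intervals),
            )
        )
    return genes


def write_gene_model_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_symbol": g.gene_symbol,
            "chromosome": g.chrom,
            "strand": g.strand,
            "span_start": g.gene_span.start,
            "span_end": g.gene_span.end,
            "cds_intervals": _fmt_ivs(g.cds_intervals),
            "utr5_intervals": _fmt_ivs(g.utr5_intervals),
            "utr3_intervals": _fmt_ivs(g.utr3_intervals),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


_GFF_UTR5 = {"five_prime_utr", "5'utr", "five_prime_UTR".lower()}
_GFF_UTR3 = {"three_prime_utr", "3'utr"}


def read_gene_model_gff3(path: str | Path, strip_chr: bool = True) -> list[GeneModel]:
    """Parse gene/CDS/UTR features from a GFF3 file (1-based inclusive on
    disk, converted to 0-based half-open)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            chrom = normalize_chrom(seqid, strip_chr)
            iv = GenomicInterval(chrom, int(start) - 1, int(end))
            ftype_l = ftype.lower()
            if ftype_l == "gene":
                symbol = attr.get("Name") or attr.get("gene_name") or attr.get("ID")
                genes.setdefault(
                    symbol, {"chrom": chrom, "strand": strand, "span": iv,
                             "cds": [], "utr5": [], "utr3": []}
                )
                genes[symbol].update({"span": iv, "strand": strand})
            elif ftype_l in ("cds",) or ftype_l in _GFF_UTR5 or ftype_l in _GFF_UTR3:
                symbol = (
                    attr.get("gene_name")
                    or attr.get("gene")
                    or (attr.get("Parent") or "").split(":")[-1]
                )
                rec = genes.setdefault(
                    symbol, {"chrom": chrom, "strand": strand, "span": None,
                             "cds": [], "utr5": [], "utr3": []}
                )
                bucket = "cds" if ftype_l == "cds" else (
                    "utr5" if ftype_l in _GFF_UTR5 else "utr3"
                )
                rec[bucket].append(iv)
    out = []
    for symbol, rec in genes.items():
        span = rec["span"]
        if span is None:
            ivs = rec["cds"] + rec["utr5"] + rec["utr3"]
            span = GenomicInterval(
                rec["chrom"], min(i.start for i in ivs), max(i.end for i in ivs)
            )
        out.append(
            GeneModel(
                gene_symbol=symbol,
                chrom=rec["chrom"],
                strand=rec["strand"],
                gene_span=span,
                cds_intervals=rec["cds"],
                utr5_intervals=rec["utr5"],
                utr3_intervals=rec["utr3"],
            )
        )
    return out


def write_gene_model_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid = f"gene:{g.gene_symbol}"
            fh.write(
                "\t".join(
                    [g.chrom, "clonetriage", "gene", str(g.gene_span.start + 1),
                     str(g.gene_span.end), ".", g.strand, ".",
                     f"ID={gid};Name={g.gene_symbol}"]
                )
                + "\n"
            )
            for ftype, ivs in (
                ("CDS", g.cds_intervals),
                ("five_prime_UTR", g.utr5_intervals),
                ("three_prime_UTR", g.utr3_intervals),
            ):
                for iv in ivs:
                    fh.write(
                        "\t".join(
                            [g.chrom, "clonetriage", ftype, str(iv.start + 1),
                             str(iv.end), ".", g.strand,
                             "0" if ftype == "CDS" else ".",
                             f"Parent={gid};gene_name={g.gene_symbol}"]
                        )
                        + "\n"
                    )


def read_gene_model(path: str | Path, strip_chr: bool = True) -> list[GeneModel]:
    """Dispatch on extension: ``.gff3``/``.gff`` → GFF3, else the gene TSV."""
    p = Path(path)
    if p.suffix.lower() in (".gff3", ".gff"):
        return read_gene_model_gff3(p, strip_chr)
    return read_gene_model_tsv(p, strip_chr)


# ---------------------------------------------------------------------------
# catalogs and panels


@dataclass
class CatalogSnapshot:
    """A pinned variant catalog (dbSNP-like or COSMIC-like): key → ID."""

    name: str
    entries: dict[VariantKey, str] = field(default_factory=dict)

    def lookup(self, key: VariantKey) -> Optional[str]:
        return self.entries.get(key)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GenePanel:
    """A named gene list, e.g. the CIN25 chromosomal-instability signature."""

    name: str
    gene_symbols: set[str]

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            warnings.warn(f"panel {self.name!r} is empty", stacklevel=2)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.gene_symbols

    def __len__(self) -> int:
        return len(self.gene_symbols)


CATALOG_COLUMNS = ["chromosome", "start", "end", "reference", "variant", "id"]


def read_catalog(path: str | Path, name: str, strip_chr: bool = True) -> CatalogSnapshot:
    """Read a variant-keyed catalog TSV (columns chromosome, start, end,
    reference, variant, id).  Keys are canonicalized by allele trimming;
    duplicates collapse keeping the first ID with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        warnings.warn(f"catalog {path} is empty", stacklevel=2)
        return CatalogSnapshot(name=name)
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog {path} missing columns: {sorted(missing)}")
    entries: dict[VariantKey, str] = {}
    for row in df.itertuples(index=False):
        ref = "" if row.reference == "-" else row.reference
        alt = "" if row.variant == "-" else row.variant
        start, ref, alt = _trim_shared(int(row.start), ref, alt)
        key = VariantKey(
            normalize_chrom(row.chromosome, strip_chr), start, start + len(ref), ref, alt
        )
        if key in entries:
            warnings.warn(
                f"catalog {name}: duplicate key {key}, keeping first ID", stacklevel=2
            )
            continue
        entries[key] = row.id
    return CatalogSnapshot(name=name, entries=entries)


def write_catalog(snapshot: CatalogSnapshot, path: str | Path) -> None:
    rows = [
        {
            "chromosome": k.chrom,
            "start": k.start,
            "end": k.end,
            "reference": k.ref or "-",
            "variant": k.alt or "-",
            "id": cid,
        }
        for k, cid in snapshot.entries.items()
    ]
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path, name: str) -> GenePanel:
    symbols = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                symbols.add(sym)
    return GenePanel(name=name, gene_symbols=symbols)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(panel.gene_symbols):
            fh.write(sym + "\n")


# ---------------------------------------------------------------------------
# CG-style TSV


def read_cg_tsv(
    path: str | Path, sample_role: SampleRole | str, sample_id: Optional[str] = None,
    strip_chr: bool = True,
) -> SampleVariantSet:
    """Read the tab-separated variant dialect into a sample call set.

    The declared ``type`` column must agree with the type implied by the
    alleles; a disagreement raises a validation error naming the row.
    """
    role = SampleRole(sample_role)
    sid = sample_id or Path(path).stem
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        return SampleVariantSet(sid, role)
    required = set(CG_COLUMNS) - {"catalog_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path} missing columns: {sorted(missing)}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ref = "" if row.reference == "-" else row.reference
        alt = "" if row.variant == "-" else row.variant
        declared = _LABEL_TYPES.get(row.type.lower())
        if declared is None:
            raise ValueError(f"{path} row {i}: unknown variant type {row.type!r}")
        actual = classify_variant_type(ref, alt)
        if actual is not declared:
            raise ValueError(
                f"{path} row {i}: declared type {row.type!r} disagrees with alleles "
                f"{row.reference!r}>{row.variant!r} (implies {actual.value})"
            )
        chrom = normalize_chrom(row.chromosome, strip_chr)
        ids = set()
        if "catalog_id" in df.columns and row.catalog_id and row.catalog_id != ".":
            ids = {row.catalog_id}
        calls.append(
            VariantCall(
                interval=GenomicInterval(chrom, int(row.start), int(row.end)),
                vtype=actual,
                ref_allele=ref,
                alt_allele=alt,
                position_read_depth=int(row.depth),
                alt_read_count=int(row.alt_reads),
                catalog_ids=ids,
                normalized=True,
            )
        )
    return SampleVariantSet(sid, role, calls)


def write_cg_tsv(sample: SampleVariantSet, path: str | Path) -> None:
    rows = [
        {
            "chromosome": c.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "type": _TYPE_LABELS[c.vtype],
            "reference": c.ref_allele or "-",
            "variant": c.alt_allele or "-",
            "depth": c.position_read_depth,
            "alt_reads": c.alt_read_count,
            "catalog_id": ";".join(sorted(c.catalog_ids)) or ".",
        }
        for c in sample
    ]
    pd.DataFrame(rows, columns=CG_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str | Path,
    sample_role: SampleRole | str,
    sample_id: Optional[str] = None,
    depth_tag: str = "DP",
    allele_depth_tag: str = "AD",
    strip_chr: bool = True,
) -> SampleVariantSet:
    """Read a VCF into a normalized sample call set.

    1-based anchored records become 0-based half-open calls with shared
    prefix/suffix bases trimmed (so ``pos 100 ref A alt AT`` is the
    insertion of ``T`` at the zero-length anchor after base 100).  The input
    is assumed left-aligned, as VCF convention requires.  Multi-allelic
    records are split; non-PASS records are marked ``no_call``.  Depth and
    allele depth come from the per-sample FORMAT fields (falling back to
    INFO ``DP``); if absent, depth is recorded as 0 with a warning so depth
    filters exclude the call.
    """
    role = SampleRole(sample_role)
    sid = sample_id or Path(path).stem
    vcf = VCF(str(path))
    calls = []
    missing_depth_warned = False
    for rec in vcf:
        status = CallStatus.CALLED
        if rec.FILTER is not None:  # cyvcf2: None means PASS/'.'
            status = CallStatus.NO_CALL
        depth = 0
        ad = None
        try:
            fmt_dp = rec.format(depth_tag)
            if fmt_dp is not None:
                depth = int(fmt_dp[0][0])
        except (KeyError, TypeError):
            pass
        if depth <= 0:
            info_dp = rec.INFO.get(depth_tag)
            if info_dp is not None:
                depth = int(info_dp)
        try:
            fmt_ad = rec.format(allele_depth_tag)
            if fmt_ad is not None:
                ad = [int(x) for x in fmt_ad[0]]
        except (KeyError, TypeError):
            ad = None
        if depth <= 0 and not missing_depth_warned:
            warnings.warn(
                f"{path}: no usable {depth_tag} field; depth recorded as 0",
                stacklevel=2,
            )
            missing_depth_warned = True
            depth = 0
        for alt_index, alt in enumerate(rec.ALT):
            if alt in (".", "<NON_REF>") or "<" in alt:
                continue
            start, ref_a, alt_a = _trim_shared(rec.POS - 1, rec.REF, alt)
            alt_reads = 0
            if ad is not None and len(ad) > alt_index + 1:
                alt_reads = max(0, ad[alt_index + 1])
            alt_reads = min(alt_reads, depth)
            calls.append(
                VariantCall(
                    interval=GenomicInterval(
                        normalize_chrom(rec.CHROM, strip_chr), start, start + len(ref_a)
                    ),
                    vtype=classify_variant_type(ref_a, alt_a),
                    ref_allele=ref_a,
                    alt_allele=alt_a,
                    position_read_depth=max(depth, 0),
                    alt_read_count=alt_reads,
                    call_status=status,
                    catalog_ids=set(rec.ID.split(";")) if rec.ID else set(),
                    normalized=True,
                )
            )
    return SampleVariantSet(sid, role, calls)


_VCF_HEADER = """##fileformat=VCFv4.2
##source=clonetriage
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def write_vcf(
    sample: SampleVariantSet,
    path: str | Path,
    reference_base: Optional[dict[str, str] | "ReferenceLookup"] = None,
) -> None:
    """Write calls as VCF 4.2.

    Empty-allele indels need a 1-based anchor base; ``reference_base`` maps
    each call to the reference base preceding it (any object with a
    ``base(chrom, pos)`` method or a chrom → sequence dict).  Without it the
    anchor is written as ``N``.
    """

    def anchor(chrom: str, pos: int) -> str:
        if reference_base is None:
            return "N"
        if hasattr(reference_base, "base"):
            return reference_base.base(chrom, pos)
        return reference_base[chrom][pos]

    contigs = sorted({c.chrom for c in sample})
    records = []
    for c in sorted(sample, key=lambda c: (c.interval.chrom, c.interval.start)):
        iv = c.interval
        if c.ref_allele and c.alt_allele:
            pos1 = iv.start + 1
            ref, alt = c.ref_allele, c.alt_allele
        else:  # indel: prepend the base before the event
            a = anchor(iv.chrom, iv.start - 1)
            pos1 = iv.start  # 1-based position of the anchor base
            ref = a + c.ref_allele
            alt = a + c.alt_allele
        filt = "PASS" if c.call_status is CallStatus.CALLED else "lowq"
        ref_reads = max(c.position_read_depth - c.alt_read_count, 0)
        records.append(
            "\t".join(
                [
                    iv.chrom,
                    str(pos1),
                    ";".join(sorted(c.catalog_ids)) or ".",
                    ref,
                    alt,
                    ".",
                    filt,
                    f"DP={c.position_read_depth}",
                    "GT:DP:AD",
                    f"0/1:{c.position_read_depth}:{ref_reads},{c.alt_read_count}",
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample.sample_id
            + "\n"
        )
        fh.write("\n".join(records) + ("\n" if records else ""))
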
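"""Synthetic matched normal/tumor/node trios with known clonal structure.

The generator emulates the data shape of a matched-trio whole-genome
study: germline heterozygous variants called in all three samples,
truncal somatic variants present in both tumor and lymph node (the
founding clone's mutations, carried into the metastasis), and
sample-private somatic variants belonging to subclones that branched
after divergence.  Evidence is read-count based: per variant and sample,
depth is drawn from a negative-binomial (Poisson when the dispersion is
zero) and alt reads from a binomial at the expected variant allele
fraction

    expected VAF = purity × clone fraction × 0.5        (heterozygous)

with germline VAF 0.5 everywhere.  A deliberately simple caller stands
in for a production pipeline: a somatic call is emitted iff the alt read
count reaches ``caller_min_alt_reads``, which reproduces the masking of
low-fraction subclones at finite depth.  Everything — toy genome, gene
models, variants, catalogs — is reproducible from the architecture's
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotate import DictReference
from .clonality import ClonalityReport
from .io import (
    CatalogSnapshot,
    GeneModel,
    GenePanel,
    write_catalog,
    write_cg_tsv,
    write_gene_model_gff3,
    write_panel,
    write_vcf,
)
from .variants import (
    CallStatus,
    GenomicInterval,
    ReferenceWindow,
    SampleRole,
    SampleVariantSet,
    VariantCall,
    VariantKey,
    classify_variant_type,
    normalize_variant,
)

__all__ = [
    "ClonalArchitecture",
    "TruthTable",
    "SimulatedTrio",
    "RecoveryResult",
    "simulate_trio",
    "evaluate_recovery",
]

ORIGINS = ("germline", "truncal", "tumor_private", "node_private")


@dataclass
class ClonalArchitecture:
    """Ground-truth description of the simulated trio.

    Defaults describe the study conditions the pipeline targets: ~100×
    depth with modest overdispersion, 90% neoplastic purity in tumor and
    node, variant-type mix dominated by SNVs (84.1 / 7 / 6.9 / 2% for
    SNV / insertion / deletion / substitution), germline variants mostly
    present in the known-variant catalog, and private subclones at cell
    fractions ≥ 0.2 so their expected VAFs sit near or below 13%.
    Problem sizes are desk-scale: hundreds of variants rather than the
    millions of a real genome, which leaves every rate estimable while
    keeping a full trio simulation under a second.
    """

    n_germline_variants: int = 300
    n_truncal: int = 80
    n_tumor_private: int = 60
    n_node_private: int = 60
    tumor_subclone_fractions: tuple[float, ...] = (0.6, 0.3)
    node_subclone_fractions: tuple[float, ...] = (0.6, 0.3)
    purity_tumor: float = 0.9
    purity_node: float = 0.9
    mean_depth: float = 100.0
    depth_dispersion: float = 0.02  # var = mean·(1 + dispersion·mean); 0 → Poisson
    type_probabilities: tuple[float, float, float, float] = (0.841, 0.07, 0.069, 0.02)
    known_fraction: float = 0.95
    cosmic_fraction: float = 0.10
    caller_min_alt_reads: int = 3
    seed: int = 0
    n_genes: int = 40
    panel_size: int = 25

    def __post_init__(self) -> None:
        for fr in (*self.tumor_subclone_fractions, *self.node_subclone_fractions):
            if not 0 < fr <= 1:
                raise ValueError(f"subclone fraction {fr} outside (0,1]")
        for p in (self.purity_tumor, self.purity_node):
            if not 0 < p <= 1:
                raise ValueError(f"purity {p} outside (0,1]")
        if abs(sum(self.type_probabilities) - 1.0) > 1e-6:
            raise ValueError("type_probabilities must sum to 1")
        if not 0 <= self.known_fraction <= 1:
            raise ValueError("known_fraction outside [0,1]")


@dataclass
class TruthRecord:
    origin: str
    clone_fraction: float
    expected_vaf: dict[str, float]  # per sample role


@dataclass
class TruthTable:
    """Per-variant ground truth: origin class, assigned clone fraction and
    the expected VAF in each sample."""

    records: dict[VariantKey, TruthRecord] = field(default_factory=dict)

    def origin(self, key: VariantKey) -> Optional[str]:
        rec = self.records.get(key)
        return rec.origin if rec else None

    def keys_of(self, origin: str) -> set[VariantKey]:
        return {k for k, r in self.records.items() if r.origin == origin}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chromosome": k.chrom,
                "start": k.start,
                "end": k.end,
                "reference": k.ref or "-",
                "variant": k.alt or "-",
                "origin": r.origin,
                "clone_fraction": r.clone_fraction,
                "vaf_normal": r.expected_vaf.get("normal", 0.0),
                "vaf_tumor": r.expected_vaf.get("tumor", 0.0),
                "vaf_node": r.expected_vaf.get("node", 0.0),
            }
            for k, r in self.records.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class SimulatedTrio:
    architecture: ClonalArchitecture
    normal: SampleVariantSet
    tumor: SampleVariantSet
    node: SampleVariantSet
    truth: TruthTable
    dbsnp: CatalogSnapshot
    cosmic: CatalogSnapshot
    gene_models: list[GeneModel]
    panel: GenePanel
    reference: DictReference

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the trio as VCF + tab-separated mirrors, truth table,
        catalogs, gene models (GFF3) and panel list."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, sample in (
            ("normal", self.normal), ("tumor", self.tumor), ("node", self.node)
        ):
            paths[f"{name}_vcf"] = out / f"{name}.vcf"
            write_vcf(sample, paths[f"{name}_vcf"], self.reference)
            paths[f"{name}_tsv"] = out / f"{name}.cg.tsv"
            write_cg_tsv(sample, paths[f"{name}_tsv"])
        paths["truth"] = out / "truth.tsv"
        self.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
        paths["dbsnp"] = out / "dbsnp.tsv"
        write_catalog(self.dbsnp, paths["dbsnp"])
        paths["cosmic"] = out / "cosmic.tsv"
        write_catalog(self.cosmic, paths["cosmic"])
        paths["genes"] = out / "genes.gff3"
        write_gene_model_gff3(self.gene_models, paths["genes"])
        paths["panel"] = out / "panel.txt"
        write_panel(self.panel, paths["panel"])
        return paths


# ---------------------------------------------------------------------------
# toy genome

_BASES = np.array(list("ACGT"))

# per-gene geometry (bp): 5'UTR, CDS exon, intron, CDS exon, 3'UTR
_UTR5, _CDS1, _INTRON, _CDS2, _UTR3 = 200, 300, 1000, 300, 300
_SPAN = _UTR5 + _CDS1 + _INTRON + _CDS2 + _UTR3
_FLANK = 2000  # promoter/flank head-room simulated around each gene
_GAP = 6000  # intergenic spacing beyond the flanks


def _build_genome(
    rng: np.random.Generator, n_genes: int
) -> tuple[DictReference, list[GeneModel], np.ndarray, str]:
    """One toy chromosome with ``n_genes`` alternating-strand genes and a
    random reference sequence; returns candidate variant positions too."""
    chrom = "1"
    slot = _SPAN + 2 * _FLANK + _GAP
    length = n_genes * slot + _GAP
    seq = "".join(rng.choice(_BASES, size=length))
    genes = []
    candidates = []
    for i in range(n_genes):
        g0 = _GAP + i * slot + _FLANK
        span = GenomicInterval(chrom, g0, g0 + _SPAN)
        strand = "+" if i % 2 == 0 else "-"
        # genomic-order blocks; biological role flips with strand
        b_utr_low = GenomicInterval(chrom, g0, g0 + _UTR5)
        b_cds1 = GenomicInterval(chrom, g0 + _UTR5, g0 + _UTR5 + _CDS1)
        b_cds2_start = g0 + _UTR5 + _CDS1 + _INTRON
        b_cds2 = GenomicInterval(chrom, b_cds2_start, b_cds2_start + _CDS2)
        b_utr_high = GenomicInterval(chrom, b_cds2_start + _CDS2, g0 + _SPAN)
        genes.append(
            GeneModel(
                gene_symbol=f"GENE{i:04d}",
                chrom=chrom,
                strand=strand,
                gene_span=span,
                cds_intervals=[b_cds1, b_cds2],
                utr5_intervals=[b_utr_low if strand == "+" else b_utr_high],
                utr3_intervals=[b_utr_high if strand == "+" else b_utr_low],
            )
        )
        candidates.append(np.arange(g0 - _FLANK, g0 + _SPAN + _FLANK, 8))
    return DictReference({chrom: seq}), genes, np.concatenate(candidates), chrom


def _draw_depths(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _draw_alleles(
    rng: np.random.Generator, ref: DictReference, chrom: str, pos: int, vtype: str
) -> tuple[str, str]:
    base = ref.fetch(chrom, pos, pos + 1)
    if vtype == "snv":
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        return base, alt
    if vtype == "ins":
        k = int(rng.integers(1, 4))
        return "", "".join(rng.choice(_BASES, size=k))
    if vtype == "del":
        k = int(rng.integers(1, 4))
        return ref.fetch(chrom, pos, pos + k), ""
    # sub: replace 2 bases with a different 2-base sequence
    refseq = ref.fetch(chrom, pos, pos + 2)
    while True:
        alt = "".join(rng.choice(_BASES, size=2))
        # avoid degenerating into an SNV or reference call after trimming
        if alt[0] != refseq[0] and alt[1] != refseq[1]:
            return refseq, alt


def simulate_trio(arch: ClonalArchitecture) -> SimulatedTrio:
    """Generate the matched trio plus truth, catalogs and gene models.

    Variant positions are drawn without collision over the toy genome;
    every emitted call is normalized, so downstream set algebra sees
    canonical keys.  Raises if the requested variant count exceeds the
    genome's candidate-position capacity.
    """
    rng = np.random.default_rng(arch.seed)
    reference, genes, candidates, chrom = _build_genome(rng, arch.n_genes)
    n_total = (
        arch.n_germline_variants
        + arch.n_truncal
        + arch.n_tumor_private
        + arch.n_node_private
    )
    if n_total > len(candidates):
        raise ValueError(
            f"{n_total} variants requested but toy genome has only "
            f"{len(candidates)} candidate positions; raise n_genes"
        )

    positions = rng.choice(candidates, size=n_total, replace=False)
    vtypes = rng.choice(
        ["snv", "ins", "del", "sub"], size=n_total, p=arch.type_probabilities
    )
    origins = (
        ["germline"] * arch.n_germline_variants
        + ["truncal"] * arch.n_truncal
        + ["tumor_private"] * arch.n_tumor_private
        + ["node_private"] * arch.n_node_private
    )

    truth = TruthTable()
    proto_calls: dict[VariantKey, tuple[VariantCall, str]] = {}
    for pos, vt, origin in zip(positions, vtypes, origins):
        pos = int(pos)
        ref_a, alt_a = _draw_alleles(rng, reference, chrom, pos, vt)
        call = VariantCall(
            interval=GenomicInterval(chrom, pos, pos + len(ref_a)),
            vtype=classify_variant_type(ref_a, alt_a),
            ref_allele=ref_a,
            alt_allele=alt_a,
        )
        win_lo = max(0, pos - 60)
        window = ReferenceWindow(chrom, win_lo, reference.fetch(chrom, win_lo, pos + 10))
        norm = normalize_variant(call, window)
        key = norm.key
        if key in proto_calls:  # left-alignment collision in a repeat: rare
            continue
        if origin == "germline":
            fraction = 1.0
            vaf = {"normal": 0.5, "tumor": 0.5, "node": 0.5}
        elif origin == "truncal":
            fraction = 1.0
            vaf = {
                "normal": 0.0,
                "tumor": arch.purity_tumor * 0.5,
                "node": arch.purity_node * 0.5,
            }
        elif origin == "tumor_private":
            fraction = float(rng.choice(arch.tumor_subclone_fractions))
            vaf = {"normal": 0.0, "tumor": arch.purity_tumor * fraction * 0.5, "node": 0.0}
        else:
            fraction = float(rng.choice(arch.node_subclone_fractions))
            vaf = {"normal": 0.0, "tumor": 0.0, "node": arch.purity_node * fraction * 0.5}
        proto_calls[key] = (norm, origin)
        truth.records[key] = TruthRecord(origin, fraction, vaf)

    samples = {
        "normal": SampleVariantSet("sim_normal", SampleRole.NORMAL),
        "tumor": SampleVariantSet("sim_tumor", SampleRole.TUMOR),
        "node": SampleVariantSet("sim_node", SampleRole.NODE),
    }
    keys = list(proto_calls)
    for sample_name, sset in samples.items():
        depths = _draw_depths(
            rng, arch.mean_depth, arch.depth_dispersion, len(keys)
        )
        for key, depth in zip(keys, depths):
            call, origin = proto_calls[key]
            vaf = truth.records[key].expected_vaf[sample_name]
            depth = int(depth)
            if vaf <= 0.0:
                continue
            alt_reads = int(rng.binomial(depth, vaf)) if depth > 0 else 0
            if origin != "germline" and alt_reads < arch.caller_min_alt_reads:
                continue  # the caller misses weakly supported somatic variants
            sset.add(
                VariantCall(
                    interval=GenomicInterval(key.chrom, key.start, key.end),
                    vtype=call.vtype,
                    ref_allele=key.ref,
                    alt_allele=key.alt,
                    position_read_depth=depth,
                    alt_read_count=min(alt_reads, depth),
                    call_status=CallStatus.CALLED,
                    normalized=True,
                )
            )

    germline_keys = truth.keys_of("germline")
    known = [k for k in germline_keys if rng.random() < arch.known_fraction]
    dbsnp = CatalogSnapshot(
        "synthetic_dbSNP",
        {k: f"rs9{i:07d}" for i, k in enumerate(sorted(known))},
    )
    somatic_keys = sorted(set(keys) - germline_keys)
    cosmic_keys = [k for k in somatic_keys if rng.random() < arch.cosmic_fraction]
    cosmic = CatalogSnapshot(
        "synthetic_COSMIC",
        {k: f"COSM9{i:06d}" for i, k in enumerate(cosmic_keys)},
    )
    panel_genes = rng.choice(
        [g.gene_symbol for g in genes],
        size=min(arch.panel_size, len(genes)),
        replace=False,
    )
    panel = GenePanel("synthetic_CIN25", set(map(str, panel_genes)))
    return SimulatedTrio(
        architecture=arch,
        normal=samples["normal"],
        tumor=samples["tumor"],
        node=samples["node"],
        truth=truth,
        dbsnp=dbsnp,
        cosmic=cosmic,
        gene_models=genes,
        panel=panel,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# recovery harness


@dataclass
class RecoveryResult:
    confusion: pd.DataFrame  # truth origin × predicted label (incl. "missed")
    recall: dict[str, float]
    precision: dict[str, float]
    accuracy: float
    germline_leakage: int

    def __str__(self) -> str:
        lines = [f"accuracy={self.accuracy:.4f} germline_leakage={self.germline_leakage}"]
        for cls in sorted(self.recall):
            lines.append(
                f"  {cls}: recall={self.recall[cls]:.4f} "
                f"precision={self.precision.get(cls, float('nan')):.4f}"
            )
        return "\n".join(lines)


def evaluate_recovery(report: ClonalityReport, truth: TruthTable) -> RecoveryResult:
    """Score pipeline clonality labels against simulator truth.

    Somatic truth keys missing from the report count as ``missed`` (they
    depress recall); germline leakage counts truth-germline keys that
    survived germline subtraction into the report.
    """
    somatic_classes = ("truncal", "tumor_private", "node_private")
    unknown = set(report.labels) - set(truth.records)
    if unknown:
        raise ValueError(
            f"{len(unknown)} labeled keys absent from truth (key-space mismatch)"
        )
    cm: dict[str, dict[str, int]] = {
        c: {p: 0 for p in (*somatic_classes, "missed")} for c in somatic_classes
    }
    correct = total = 0
    for cls in somatic_classes:
        for k in truth.keys_of(cls):
            pred = report.labels.get(k, "missed")
            cm[cls][pred] += 1
            total += 1
            if pred == cls:
                correct += 1
    confusion = pd.DataFrame(cm).T  # rows = truth, cols = predicted
    recall = {
        c: (cm[c][c] / sum(cm[c].values())) if sum(cm[c].values()) else float("nan")
        for c in somatic_classes
    }
    precision = {}
    for c in somatic_classes:
        predicted_c = sum(cm[t][c] for t in somatic_classes)
        precision[c] = cm[c][c] / predicted_c if predicted_c else float("nan")
    leakage = sum(1 for k in truth.keys_of("germline") if k in report.labels)
    return RecoveryResult(
        confusion=confusion,
        recall=recall,
        precision=precision,
        accuracy=correct / total if total else float("nan"),
        germline_leakage=leakage,
    )
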
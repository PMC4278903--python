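"""Variant-allele-frequency summaries and clonality reasoning.

Frequencies are percentages: 100 × alt reads / position read depth,
reported to two decimals.  A shared somatic variant is *truncal* —
present in the founding clone and carried from tumor to node — while a
sample-private variant marks a subclone that branched after divergence.
When one gene carries two or more variants in the same sample at very
different frequencies, a single clone cannot comfortably explain both,
so the gene is flagged as evidence of multiple coexisting clones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .triage import TriagePartition
from .variants import SampleVariantSet, VariantCall, VariantKey, VariantType

__all__ = [
    "UNDEFINED_FREQUENCY",
    "TypeProportionProfile",
    "ClonalityReport",
    "MultiCloneFlag",
    "variant_frequency",
    "type_proportions",
    "lowest_frequency_by_type",
    "clonality_summary",
    "DEFAULT_DISCORDANCE_THRESHOLD",
    "HIGH_FREQUENCY_NOTE_THRESHOLD",
]

UNDEFINED_FREQUENCY = float("nan")
DEFAULT_DISCORDANCE_THRESHOLD = 30.0  # percentage points
HIGH_FREQUENCY_NOTE_THRESHOLD = 80.0  # % — suggests homozygosity/amplification

_TYPES = [VariantType.SNV, VariantType.INS, VariantType.DEL, VariantType.SUB]


def variant_frequency(alt_read_count: int, position_read_depth: int) -> float:
    """Variant allele frequency as a percentage, 2-decimal precision.

    Depth 0 yields NaN (undefined), which every summary here excludes.
    """
    if position_read_depth <= 0:
        return UNDEFINED_FREQUENCY
    if alt_read_count > position_read_depth:
        raise ValueError(
            f"alt reads {alt_read_count} exceed depth {position_read_depth}"
        )
    return round(100.0 * alt_read_count / position_read_depth, 2)


def call_frequency(call: VariantCall) -> float:
    return variant_frequency(call.alt_read_count, call.position_read_depth)


@dataclass(frozen=True)
class TypeProportionProfile:
    """Percentage of calls per variant type; sums to 100 up to rounding."""

    snv: float
    ins: float
    dele: float
    sub: float

    def as_dict(self) -> dict[str, float]:
        return {"snv": self.snv, "ins": self.ins, "del": self.dele, "sub": self.sub}


def type_proportions(sample: SampleVariantSet) -> Optional[TypeProportionProfile]:
    """Per-type share of a sample's calls, as percentages.

    Returns ``None`` for an empty set (no profile is defined).
    """
    total = len(sample)
    if total == 0:
        return None
    counts = {t: 0 for t in _TYPES}
    for c in sample:
        counts[c.vtype] += 1
    pct = {t: round(100.0 * n / total, 2) for t, n in counts.items()}
    return TypeProportionProfile(
        snv=pct[VariantType.SNV],
        ins=pct[VariantType.INS],
        dele=pct[VariantType.DEL],
        sub=pct[VariantType.SUB],
    )


def lowest_frequency_by_type(sample: SampleVariantSet) -> dict[str, Optional[float]]:
    """Minimum observed VAF per variant type; ``None`` where a type is
    absent (or only depth-0 calls exist)."""
    mins: dict[str, Optional[float]] = {t.value: None for t in _TYPES}
    for c in sample:
        f = call_frequency(c)
        if math.isnan(f):
            continue
        cur = mins[c.vtype.value]
        if cur is None or f < cur:
            mins[c.vtype.value] = f
    return mins


@dataclass(frozen=True)
class MultiCloneFlag:
    """Evidence of ≥2 clones: one gene, one sample, discordant VAFs."""

    gene_symbol: str
    sample: str  # "tumor" | "node"
    max_frequency: float
    min_frequency: float

    @property
    def spread(self) -> float:
        return round(self.max_frequency - self.min_frequency, 2)


@dataclass
class ClonalityReport:
    """Per-key clonal labels plus gene-level multi-clone evidence."""

    labels: dict[VariantKey, str] = field(default_factory=dict)
    tumor_frequency: dict[VariantKey, float] = field(default_factory=dict)
    node_frequency: dict[VariantKey, float] = field(default_factory=dict)
    multi_clone_flags: list[MultiCloneFlag] = field(default_factory=list)
    lowest_frequency: dict[str, dict[str, Optional[float]]] = field(
        default_factory=dict
    )
    notes: dict[VariantKey, str] = field(default_factory=dict)

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.labels.values():
            out[v] = out.get(v, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, label in self.labels.items():
            rows.append(
                {
                    "chromosome": k.chrom,
                    "start": k.start,
                    "end": k.end,
                    "reference": k.ref or "-",
                    "variant": k.alt or "-",
                    "label": label,
                    "tumor_frequency": self.tumor_frequency.get(k),
                    "node_frequency": self.node_frequency.get(k),
                    "note": self.notes.get(k, ""),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chromosome", "start", "end", "reference", "variant",
                "label", "tumor_frequency", "node_frequency", "note",
            ],
        )


def clonality_summary(
    partition: TriagePartition,
    gene_map: Optional[Mapping[VariantKey, str]] = None,
    freq_discordance_threshold: float = DEFAULT_DISCORDANCE_THRESHOLD,
    tumor_sample: Optional[SampleVariantSet] = None,
    node_sample: Optional[SampleVariantSet] = None,
) -> ClonalityReport:
    """Label each somatic key truncal / tumor-private / node-private and
    flag genes whose same-sample variants have discordant frequencies.

    Parameters
    ----------
    partition
        The tumor/node triage partition (frequencies are taken from the
        calls it holds).
    gene_map
        Variant key → gene symbol; required for multi-clone flags (keys
        without a gene are skipped there).
    freq_discordance_threshold
        Percentage-point spread beyond which two same-gene, same-sample
        variants are deemed incompatible with a single clone.  Default 30.
    tumor_sample, node_sample
        Optional full sample sets used only for the lowest-frequency-per-type
        table; when omitted the table is built from partition calls.
    """
    report = ClonalityReport()
    for k, (tc, nc) in partition.shared.items():
        report.labels[k] = "truncal"
        report.tumor_frequency[k] = call_frequency(tc)
        report.node_frequency[k] = call_frequency(nc)
    for k, c in partition.tumor_private.items():
        report.labels[k] = "tumor_private"
        report.tumor_frequency[k] = call_frequency(c)
    for k, c in partition.node_private.items():
        report.labels[k] = "node_private"
        report.node_frequency[k] = call_frequency(c)

    # high-VAF free-text note: compatible with homozygosity or amplification,
    # which this pipeline deliberately does not call
    for k in report.labels:
        freqs = [
            f
            for f in (report.tumor_frequency.get(k), report.node_frequency.get(k))
            if f is not None and not math.isnan(f)
        ]
        if freqs and max(freqs) > HIGH_FREQUENCY_NOTE_THRESHOLD:
            report.notes[k] = (
                "high frequency (>80%): consistent with homozygosity or "
                "amplification at this locus"
            )

    if gene_map:
        per_gene_sample: dict[tuple[str, str], list[float]] = {}
        for k, gene in gene_map.items():
            if k not in report.labels:
                continue
            for sample_name, freqs in (
                ("tumor", report.tumor_frequency),
                ("node", report.node_frequency),
            ):
                f = freqs.get(k)
                if f is not None and not math.isnan(f):
                    per_gene_sample.setdefault((gene, sample_name), []).append(f)
        for (gene, sample_name), fs in sorted(per_gene_sample.items()):
            if len(fs) >= 2 and max(fs) - min(fs) > freq_discordance_threshold:
                report.multi_clone_flags.append(
                    MultiCloneFlag(gene, sample_name, max(fs), min(fs))
                )

    def _mins_from_calls(calls) -> dict[str, Optional[float]]:
        mins: dict[str, Optional[float]] = {t.value: None for t in _TYPES}
        for c in calls:
            f = call_frequency(c)
            if math.isnan(f):
                continue
            cur = mins[c.vtype.value]
            if cur is None or f < cur:
                mins[c.vtype.value] = f
        return mins

    if tumor_sample is not None:
        report.lowest_frequency["tumor"] = lowest_frequency_by_type(tumor_sample)
    else:
        report.lowest_frequency["tumor"] = _mins_from_calls(
            [v[0] for v in partition.shared.values()]
            + list(partition.tumor_private.values())
        )
    if node_sample is not None:
        report.lowest_frequency["node"] = lowest_frequency_by_type(node_sample)
    else:
        report.lowest_frequency["node"] = _mins_from_calls(
            [v[1] for v in partition.shared.values()]
            + list(partition.node_private.values())
        )
    return report
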
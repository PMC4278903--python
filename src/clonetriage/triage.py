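"""Somatic triage: germline subtraction, tumor/node partition, depth
filtering, and known/novel judgment against pinned catalogs.

The partition is pure key-set algebra over normalized calls: ``shared`` is
the intersection of the germline-subtracted tumor and node sets,
``tumor_private`` and ``node_private`` the respective differences.  A
variant "unique" to one sample where the other sample has a *no-call* (as
opposed to a confident reference call) is demoted to low-confidence and
reported separately — absence of evidence is not evidence of absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

from .io import CatalogSnapshot
from .variants import (
    CallStatus,
    ContractViolationError,
    SampleRole,
    SampleVariantSet,
    VariantCall,
    VariantKey,
    VariantType,
)

__all__ = [
    "TriagePartition",
    "subtract_normal",
    "compare_tumor_node",
    "filter_min_depth",
    "annotate_known",
    "annotate_cosmic",
    "count_known_novel",
    "cosmic_report",
]

LOW_CONFIDENCE_SOMATIC = "low_confidence_somatic"


@dataclass
class TriagePartition:
    """Shared / tumor-private / node-private decomposition.

    Each bucket maps a variant key to the supporting :class:`VariantCall`
    evidence (both samples for shared keys).  ``known_in_dbsnp`` and
    ``cosmic_ids`` are populated by :func:`annotate_known` /
    :func:`annotate_cosmic`; ``low_confidence`` holds keys whose privacy
    rests on a no-call rather than a confident reference call in the other
    sample.
    """

    shared: dict[VariantKey, tuple[VariantCall, VariantCall]] = field(
        default_factory=dict
    )
    tumor_private: dict[VariantKey, VariantCall] = field(default_factory=dict)
    node_private: dict[VariantKey, VariantCall] = field(default_factory=dict)
    known_in_dbsnp: dict[VariantKey, bool] = field(default_factory=dict)
    cosmic_ids: dict[VariantKey, str] = field(default_factory=dict)
    low_confidence: set[VariantKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        s, t, n = set(self.shared), set(self.tumor_private), set(self.node_private)
        if s & t or s & n or t & n:
            raise ValueError("partition buckets must be pairwise disjoint")

    @property
    def all_keys(self) -> set[VariantKey]:
        return set(self.shared) | set(self.tumor_private) | set(self.node_private)

    def tumor_call(self, key: VariantKey) -> Optional[VariantCall]:
        if key in self.shared:
            return self.shared[key][0]
        return self.tumor_private.get(key)

    def node_call(self, key: VariantKey) -> Optional[VariantCall]:
        if key in self.shared:
            return self.shared[key][1]
        return self.node_private.get(key)

    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "tumor_private": len(self.tumor_private),
            "node_private": len(self.node_private),
        }


def subtract_normal(
    sample: SampleVariantSet, normal: SampleVariantSet
) -> SampleVariantSet:
    """Remove from ``sample`` every variant confidently called in the
    matched normal, isolating candidate somatic events.

    Keys that coincide with a *no-call* in the normal (rather than a
    confident call) survive but are tagged ``low_confidence_somatic`` in
    their ``catalog_ids`` — the normal provides no evidence either way.
    """
    if normal.role is not SampleRole.NORMAL:
        raise ContractViolationError(
            f"subtract_normal needs a normal sample, got role={normal.role.value}"
        )
    normal_called = normal.called_keys()
    normal_nocall = normal.keys() - normal_called
    out = SampleVariantSet(sample.sample_id, sample.role)
    for call in sample:
        k = call.key
        if k in normal_called:
            continue
        if k in normal_nocall:
            call = replace(
                call, catalog_ids=set(call.catalog_ids) | {LOW_CONFIDENCE_SOMATIC}
            )
        out.add(call)
    return out


def compare_tumor_node(
    tumor_somatic: SampleVariantSet, node_somatic: SampleVariantSet
) -> TriagePartition:
    """Partition germline-subtracted tumor and node calls into shared,
    tumor-private and node-private sets by exact variant key."""
    tkeys, nkeys = tumor_somatic.keys(), node_somatic.keys()
    shared = {
        k: (tumor_somatic.get(k), node_somatic.get(k)) for k in tkeys & nkeys
    }
    # privacy resting on the other sample's no-call is weaker evidence
    t_nocall = tkeys - tumor_somatic.called_keys()
    n_nocall = nkeys - node_somatic.called_keys()
    low_conf = set()
    tumor_private = {}
    for k in tkeys - nkeys:
        tumor_private[k] = tumor_somatic.get(k)
    node_private = {}
    for k in nkeys - tkeys:
        node_private[k] = node_somatic.get(k)
    for k, c in list(tumor_private.items()):
        if LOW_CONFIDENCE_SOMATIC in c.catalog_ids:
            low_conf.add(k)
    for k, c in list(node_private.items()):
        if LOW_CONFIDENCE_SOMATIC in c.catalog_ids:
            low_conf.add(k)
    low_conf |= (t_nocall | n_nocall) & (set(tumor_private) | set(node_private))
    return TriagePartition(
        shared=shared,
        tumor_private=tumor_private,
        node_private=node_private,
        low_confidence=low_conf,
    )


def filter_min_depth(obj, min_depth: int, require: str = "both"):
    """Retain only calls with position read depth ≥ ``min_depth``.

    Works on a :class:`SampleVariantSet` or a :class:`TriagePartition`.
    For shared keys in a partition, ``require`` chooses whether the
    threshold must hold in ``"both"`` samples (default) or ``"either"``.
    """
    if min_depth < 0:
        raise ValueError(f"min_depth must be ≥ 0, got {min_depth}")
    if require not in ("both", "either"):
        raise ValueError("require must be 'both' or 'either'")
    if isinstance(obj, SampleVariantSet):
        return obj.filter(lambda c: c.position_read_depth >= min_depth)
    if isinstance(obj, TriagePartition):
        def deep(c: VariantCall) -> bool:
            return c.position_read_depth >= min_depth

        if require == "both":
            shared = {k: v for k, v in obj.shared.items() if deep(v[0]) and deep(v[1])}
        else:
            shared = {k: v for k, v in obj.shared.items() if deep(v[0]) or deep(v[1])}
        return TriagePartition(
            shared=shared,
            tumor_private={k: c for k, c in obj.tumor_private.items() if deep(c)},
            node_private={k: c for k, c in obj.node_private.items() if deep(c)},
            known_in_dbsnp=dict(obj.known_in_dbsnp),
            cosmic_ids=dict(obj.cosmic_ids),
            low_confidence=set(obj.low_confidence),
        )
    raise TypeError(f"cannot depth-filter {type(obj).__name__}")


def annotate_known(
    partition: TriagePartition, dbsnp: CatalogSnapshot
) -> TriagePartition:
    """Flag every partition key known/novel by catalog membership."""
    for k in partition.all_keys:
        partition.known_in_dbsnp[k] = k in dbsnp
    return partition


def annotate_cosmic(
    partition: TriagePartition, cosmic: CatalogSnapshot
) -> TriagePartition:
    """Attach COSMIC-style IDs to partition keys present in the catalog."""
    for k in partition.all_keys:
        cid = cosmic.lookup(k)
        if cid is not None:
            partition.cosmic_ids[k] = cid
    return partition


_GRID_TYPES = [VariantType.SNV, VariantType.INS, VariantType.DEL, VariantType.SUB]
_TYPE_ROW = {
    VariantType.SNV: "SNVs",
    VariantType.INS: "Insertions",
    VariantType.DEL: "Deletions",
    VariantType.SUB: "Substitutions",
}


def count_known_novel(partition: TriagePartition) -> pd.DataFrame:
    """Known/novel count grid by variant type.

    Rows are (variant type × {Total calls, dbSNP, Not in dbSNP}); columns
    are the tumor and node somatic sets and the sample-unique subsets.
    ``Total calls == dbSNP + Not in dbSNP`` holds in every cell group by
    construction.
    """
    columns = {
        "tumor": set(partition.shared) | set(partition.tumor_private),
        "node": set(partition.shared) | set(partition.node_private),
        "unique_tumor": set(partition.tumor_private),
        "unique_node": set(partition.node_private),
    }

    def vtype_of(k: VariantKey) -> VariantType:
        call = partition.tumor_call(k) or partition.node_call(k)
        return call.vtype

    rows = []
    index = []
    for vt in _GRID_TYPES:
        by_col = {
            name: [k for k in keys if vtype_of(k) is vt]
            for name, keys in columns.items()
        }
        for stat in ("total", "known", "novel"):
            index.append((_TYPE_ROW[vt], stat))
            row = {}
            for name, keys in by_col.items():
                if stat == "total":
                    row[name] = len(keys)
                elif stat == "known":
                    row[name] = sum(
                        bool(partition.known_in_dbsnp.get(k, False)) for k in keys
                    )
                else:
                    row[name] = sum(
                        not partition.known_in_dbsnp.get(k, False) for k in keys
                    )
            rows.append(row)
    df = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["variant_type", "count"])
    )
    return df[["tumor", "node", "unique_tumor", "unique_node"]]


def cosmic_report(partition: TriagePartition) -> pd.DataFrame:
    """Catalog-hit report: one row per partition key carrying a COSMIC-style
    ID, with Tumor?/Node? membership columns."""
    from .io import _TYPE_LABELS  # shared label mapping

    rows = []
    for k in sorted(partition.cosmic_ids):
        call = partition.tumor_call(k) or partition.node_call(k)
        rows.append(
            {
                "chromosome": k.chrom,
                "start": k.start,
                "end": k.end,
                "type": _TYPE_LABELS[call.vtype],
                "reference": k.ref or "-",
                "variant": k.alt or "-",
                "cosmic_id": partition.cosmic_ids[k],
                "gene": call.gene_hint or ".",
                "tumor": "Yes" if partition.tumor_call(k) is not None else "No",
                "node": "Yes" if partition.node_call(k) is not None else "No",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start", "end", "type", "reference", "variant",
            "cosmic_id", "gene", "tumor", "node",
        ],
    )
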
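"""End-to-end orchestration: read → normalize → quality filter → gene/flank
restriction → germline subtraction → tumor/node partition → depth filter →
catalog annotation → region/impact annotation → panel restriction →
clonality statistics → optional gene-set enrichment.

The in-memory entry point is :func:`run_trio`; :func:`run_full_pipeline`
wraps it with file reading, report writing and a run log, and is what the
command-line interface calls.  Counts at every stage are recorded so a
reader can audit exactly where calls were removed; through the filtering
stages they are monotone non-increasing by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    DEFAULT_FLANK_WINDOW,
    DEFAULT_UPSTREAM_WINDOW,
    assign_regions,
    gene_set_enrichment,
    restrict_to_panel,
)
from .clonality import (
    DEFAULT_DISCORDANCE_THRESHOLD,
    ClonalityReport,
    clonality_summary,
    type_proportions,
)
from .io import (
    CatalogSnapshot,
    GeneModel,
    GenePanel,
    read_catalog,
    read_cg_tsv,
    read_gene_model,
    read_panel,
    read_vcf,
)
from .triage import (
    TriagePartition,
    annotate_cosmic,
    annotate_known,
    compare_tumor_node,
    cosmic_report,
    count_known_novel,
    filter_min_depth,
    subtract_normal,
)
from .variants import SampleVariantSet, VariantKey

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_trio", "run_full_pipeline"]

DEFAULT_MIN_DEPTH = 100  # position read depth floor for the truncal-focused pass


@dataclass
class RunConfig:
    """Paths and thresholds for a file-based pipeline run."""

    tumor: str
    node: str
    normal: str
    gene_model: str
    dbsnp: Optional[str] = None
    cosmic: Optional[str] = None
    panel: Optional[str] = None
    term_map: Optional[str] = None
    out_dir: str = "clonetriage_out"
    min_depth: int = DEFAULT_MIN_DEPTH
    depth_require: str = "both"
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW
    flank_window: int = DEFAULT_FLANK_WINDOW
    freq_discordance_threshold: float = DEFAULT_DISCORDANCE_THRESHOLD
    enrichment_p_threshold: float = 1e-4
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("min_depth", "upstream_window", "flank_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.freq_discordance_threshold < 0:
            raise ValueError("freq_discordance_threshold must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("tumor", "node", "normal", "gene_model", "dbsnp", "cosmic",
                     "panel", "term_map"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


@dataclass
class PipelineResult:
    stage_counts: dict[str, int]
    partition: TriagePartition
    gene_map: dict[VariantKey, str]
    clonality: ClonalityReport
    known_novel_grid: pd.DataFrame
    cosmic_table: pd.DataFrame
    type_proportions: dict[str, Optional[dict[str, float]]]
    panel_partition: Optional[TriagePartition] = None
    panel_clonality: Optional[ClonalityReport] = None
    enrichment: Optional[pd.DataFrame] = None

    def summary(self) -> dict:
        out = {
            "stage_counts": self.stage_counts,
            "partition": self.partition.counts(),
            "clonality_labels": self.clonality.label_counts(),
            "n_cosmic_hits": len(self.partition.cosmic_ids),
            "n_multi_clone_flags": len(self.clonality.multi_clone_flags),
            "type_proportions": self.type_proportions,
            "lowest_frequency": self.clonality.lowest_frequency,
        }
        if self.panel_partition is not None:
            out["panel_partition"] = self.panel_partition.counts()
        return out


def _read_calls(path: str, role: str) -> SampleVariantSet:
    if str(path).endswith((".tsv", ".cg.tsv", ".txt")):
        return read_cg_tsv(path, role)
    return read_vcf(path, role)


def _gene_filter(
    sample: SampleVariantSet,
    genes: list[GeneModel],
    upstream_window: int,
    flank_window: int,
) -> tuple[SampleVariantSet, dict[VariantKey, str]]:
    """Keep calls in genes or their flanking windows; returns the surviving
    set plus each key's first gene assignment (annotation against every
    overlapping gene is used for the keep decision)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    gene_map: dict[VariantKey, str] = {}
    kept = []
    for call in sample:
        ras = assign_regions(
            call, by_chrom.get(call.chrom, ()), upstream_window, flank_window
        )
        if ras:
            gene_map[call.key] = ras[0].gene_symbol
            kept.append(call)
    return SampleVariantSet(sample.sample_id, sample.role, kept), gene_map


def run_trio(
    normal: SampleVariantSet,
    tumor: SampleVariantSet,
    node: SampleVariantSet,
    gene_models: list[GeneModel],
    dbsnp: Optional[CatalogSnapshot] = None,
    cosmic: Optional[CatalogSnapshot] = None,
    panel: Optional[GenePanel] = None,
    term_map: Optional[Mapping[str, set[str]]] = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    depth_require: str = "both",
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    flank_window: int = DEFAULT_FLANK_WINDOW,
    freq_discordance_threshold: float = DEFAULT_DISCORDANCE_THRESHOLD,
) -> PipelineResult:
    """The full analysis on in-memory objects.

    Enrichment (when a term map is supplied) asks which annotated terms are
    over-represented among genes carrying node-private variants, against
    the background of all modeled genes.
    """
    counts: dict[str, int] = {}
    counts["input_tumor"] = len(tumor)
    counts["input_node"] = len(node)
    counts["input_normal"] = len(normal)

    # quality: keep confidently called records only
    tumor_q = tumor.filter(lambda c: c.call_status.value == "called")
    node_q = node.filter(lambda c: c.call_status.value == "called")
    counts["qc_tumor"] = len(tumor_q)
    counts["qc_node"] = len(node_q)

    # genes and flanking regions only
    tumor_g, gm_t = _gene_filter(tumor_q, gene_models, upstream_window, flank_window)
    node_g, gm_n = _gene_filter(node_q, gene_models, upstream_window, flank_window)
    gene_map = {**gm_t, **gm_n}
    counts["gene_region_tumor"] = len(tumor_g)
    counts["gene_region_node"] = len(node_g)

    tumor_somatic = subtract_normal(tumor_g, normal)
    node_somatic = subtract_normal(node_g, normal)
    counts["somatic_tumor"] = len(tumor_somatic)
    counts["somatic_node"] = len(node_somatic)

    partition = compare_tumor_node(tumor_somatic, node_somatic)
    counts["partition_shared"] = len(partition.shared)
    counts["partition_tumor_private"] = len(partition.tumor_private)
    counts["partition_node_private"] = len(partition.node_private)

    partition = filter_min_depth(partition, min_depth, require=depth_require)
    counts["depth_filtered_total"] = len(partition.all_keys)

    if dbsnp is not None:
        annotate_known(partition, dbsnp)
    if cosmic is not None:
        annotate_cosmic(partition, cosmic)
    grid = count_known_novel(partition)
    cosmic_df = cosmic_report(partition)

    props = {
        "tumor": (p.as_dict() if (p := type_proportions(tumor_somatic)) else None),
        "node": (p.as_dict() if (p := type_proportions(node_somatic)) else None),
        "unique_node": None,
    }
    node_unique = SampleVariantSet(
        "unique_node", "node", partition.node_private.values()
    )
    if len(node_unique):
        props["unique_node"] = type_proportions(node_unique).as_dict()

    clonality = clonality_summary(
        partition,
        gene_map=gene_map,
        freq_discordance_threshold=freq_discordance_threshold,
        tumor_sample=tumor_somatic,
        node_sample=node_somatic,
    )

    panel_partition = panel_clonality = None
    if panel is not None:
        panel_partition, panel_assignments = restrict_to_panel(
            partition, panel, gene_models, upstream_window, flank_window
        )
        panel_gene_map = {
            k: ras[0].gene_symbol for k, ras in panel_assignments.items()
        }
        panel_clonality = clonality_summary(
            panel_partition,
            gene_map=panel_gene_map,
            freq_discordance_threshold=freq_discordance_threshold,
        )

    enrichment = None
    if term_map:
        background = {g.gene_symbol for g in gene_models}
        query = {
            gene_map[k] for k in partition.node_private if k in gene_map
        } & background
        if query:
            enrichment = gene_set_enrichment(query, background, dict(term_map))

    result = PipelineResult(
        stage_counts=counts,
        partition=partition,
        gene_map=gene_map,
        clonality=clonality,
        known_novel_grid=grid,
        cosmic_table=cosmic_df,
        type_proportions=props,
        panel_partition=panel_partition,
        panel_clonality=panel_clonality,
        enrichment=enrichment,
    )
    return result


def _write_reports(result: PipelineResult, config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.clonality.to_frame().to_csv(out / "clonality.tsv", sep="\t", index=False)
    result.known_novel_grid.to_csv(out / "known_novel_grid.tsv", sep="\t")
    result.cosmic_table.to_csv(out / "cosmic_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"sample": s, **(p or {})}
            for s, p in result.type_proportions.items()
        ]
    ).to_csv(out / "type_proportions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"sample": s, **{k: v for k, v in mins.items()}}
            for s, mins in result.clonality.lowest_frequency.items()
        ]
    ).to_csv(out / "lowest_frequency.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene": f.gene_symbol,
                "sample": f.sample,
                "max_frequency": f.max_frequency,
                "min_frequency": f.min_frequency,
                "spread": f.spread,
            }
            for f in result.clonality.multi_clone_flags
        ],
        columns=["gene", "sample", "max_frequency", "min_frequency", "spread"],
    ).to_csv(out / "multi_clone_flags.tsv", sep="\t", index=False)
    if result.panel_clonality is not None:
        result.panel_clonality.to_frame().to_csv(
            out / "panel_clonality.tsv", sep="\t", index=False
        )
    if result.enrichment is not None:
        result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"clonetriage {__version__}\n")
        for k, v in vars(config).items():
            fh.write(f"config.{k} = {v}\n")
        for k, v in result.stage_counts.items():
            fh.write(f"count.{k} = {v}\n")
    return out


def _read_term_map(path: str) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"term map {path} needs two columns (term_id, gene_symbol)")
    term_col, gene_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(getattr(row, term_col), set()).add(getattr(row, gene_col))
    return out


def run_full_pipeline(config: RunConfig) -> PipelineResult:
    """File-based run: read inputs per the config, execute :func:`run_trio`
    and write the report bundle (tables, summary JSON, run log)."""
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    normal = _read_calls(config.normal, "normal")
    tumor = _read_calls(config.tumor, "tumor")
    node = _read_calls(config.node, "node")
    genes = read_gene_model(config.gene_model)
    dbsnp = read_catalog(config.dbsnp, "dbSNP") if config.dbsnp else None
    cosmic = read_catalog(config.cosmic, "COSMIC") if config.cosmic else None
    panel = read_panel(config.panel, "panel") if config.panel else None
    term_map = _read_term_map(config.term_map) if config.term_map else None
    result = run_trio(
        normal,
        tumor,
        node,
        genes,
        dbsnp=dbsnp,
        cosmic=cosmic,
        panel=panel,
        term_map=term_map,
        min_depth=config.min_depth,
        depth_require=config.depth_require,
        upstream_window=config.upstream_window,
        flank_window=config.flank_window,
        freq_discordance_threshold=config.freq_discordance_threshold,
    )
    _write_reports(result, config)
    return result
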
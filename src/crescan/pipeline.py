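"""End-to-end orchestration: sequence mode and percent-table (classify) mode.

Sequence mode runs genome -> promoters -> scan -> presence matrix ->
representation tiers -> comparison -> category summary and writes every
intermediate artifact. Percent-table mode reclassifies a precomputed
percent table (e.g. a published table) without any sequences. Output
tables are byte-stable across reruns; timestamps live only in the run log.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from fractions import Fraction
from pathlib import Path

from crescan.annotation import annotate_results, annotated_to_table, summarize_categories
from crescan.catalog import load_catalog
from crescan.genome_io import (
    attach_labels,
    extract_promoter,
    read_fasta,
    read_gene_annotations,
    read_gene_labels,
    write_promoters_fasta,
)
from crescan.representation import (
    RepresentationThresholds,
    Tier,
    classify_percent_table,
    compare_gene_sets,
    compute_representation,
    read_percent_table,
    results_to_table,
)
from crescan.scanner import (
    build_presence_matrix,
    occurrences_to_bed,
    occurrences_to_table,
    scan_promoters,
)

logger = logging.getLogger(__name__)

_version = "0.1.0"


@dataclass
class PipelineConfig:
    """All pipeline knobs; exactly one of sequence-mode inputs or percent_table."""

    genome: Path | None = None
    annotation: Path | None = None
    annotation_format: str = "gff3"
    labels: Path | None = None
    catalog: Path | None = None
    percent_table: Path | None = None
    promoter_length: int = 3000
    anchor: str = "tss"
    strands: str = "both"
    min_occurrences: int = 1
    over: float = 0.75
    moderate_low: float = 0.50
    drop_truncated: bool = False
    outdir: Path = Path("crescan_out")

    def __post_init__(self) -> None:
        sequence_mode = self.genome is not None
        table_mode = self.percent_table is not None
        if sequence_mode == table_mode:
            raise ValueError(
                "supply either sequence-mode inputs (genome/annotation/labels/catalog) "
                "or a percent table, not both"
            )
        if sequence_mode and not (self.annotation and self.labels and self.catalog):
            raise ValueError(
                "sequence mode needs genome, annotation, labels and catalog paths"
            )
        for name in ("genome", "annotation", "labels", "catalog", "percent_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @property
    def thresholds(self) -> RepresentationThresholds:
        return RepresentationThresholds(
            Fraction(str(self.over)), Fraction(str(self.moderate_low))
        )


def _write_comparisons(results, outdir: Path) -> dict:
    up = [r for r in results if r.gene_set == "up"]
    down = [r for r in results if r.gene_set == "down"]
    tier_counts = {
        s: {t.value: sum(1 for r in rs if r.tier == t) for t in Tier}
        for s, rs in (("up", up), ("down", down))
    }
    comparisons = {}
    lines = ["tier\tcommon\tup_only\tdown_only"]
    for tier in Tier:
        cmp_result = compare_gene_sets(up, down, tier)
        comparisons[tier.value] = {
            "common": list(cmp_result.common),
            "up_only": list(cmp_result.up_only),
            "down_only": list(cmp_result.down_only),
        }
        lines.append(
            f"{tier.value}\t{','.join(cmp_result.common)}\t"
            f"{','.join(cmp_result.up_only)}\t{','.join(cmp_result.down_only)}"
        )
    (outdir / "comparison.tsv").write_text("\n".join(lines) + "\n")
    summary = {"tier_counts": tier_counts, "comparison": comparisons}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured analysis; write the report bundle; return the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"crescan {_version}",
        f"started {datetime.now(timezone.utc).isoformat()}",
        f"config: {config}",
    ]
    thresholds = config.thresholds

    if config.percent_table is not None:
        table = read_percent_table(config.percent_table)
        results, _counts = classify_percent_table(table, thresholds)
        results_to_table(results).to_csv(outdir / "classified.tsv", sep="\t", index=False)
        summary = _write_comparisons(results, outdir)
        summary["mode"] = "percent_table"
    else:
        genome = read_fasta(config.genome)
        genes = read_gene_annotations(
            config.annotation, config.annotation_format, config.anchor
        )
        labels = read_gene_labels(config.labels)
        genes = attach_labels(genes, labels)
        labeled = [g for g in genes if g.label in ("up", "down")]
        if not labeled:
            raise ValueError("no annotated genes carry an up/down label")
        catalog = load_catalog(config.catalog)
        promoters = [
            extract_promoter(genome, g, config.promoter_length) for g in labeled
        ]
        if config.drop_truncated:
            kept = [p for p in promoters if not p.truncated]
            log_lines.append(
                f"dropped {len(promoters) - len(kept)} truncated promoters"
            )
            promoters = kept
        write_promoters_fasta(promoters, outdir / "promoters.fasta")
        occurrences = scan_promoters(promoters, catalog, config.strands)
        (outdir / "occurrences.bed").write_text(occurrences_to_bed(occurrences))
        occurrences_to_table(occurrences).to_csv(
            outdir / "occurrences.tsv", sep="\t", index=False
        )
        matrix = build_presence_matrix(
            promoters, catalog, config.strands, config.min_occurrences, occurrences
        )
        matrix.to_tsv(outdir / "presence_matrix.tsv")
        kept_ids = {p.gene_id for p in promoters}
        gene_sets = {
            s: [g.gene_id for g in labeled if g.label == s and g.gene_id in kept_ids]
            for s in ("up", "down")
        }
        gene_sets = {s: ids for s, ids in gene_sets.items() if ids}
        results = compute_representation(matrix, gene_sets, thresholds)
        results_to_table(results).to_csv(outdir / "classified.tsv", sep="\t", index=False)
        annotated = annotate_results(results, catalog)
        annotated_to_table(annotated).to_csv(
            outdir / "annotated.tsv", sep="\t", index=False
        )
        categories = {
            tier.value: summarize_categories(annotated, tier) for tier in Tier
        }
        (outdir / "category_summary.json").write_text(
            json.dumps(categories, indent=2, sort_keys=True) + "\n"
        )
        summary = _write_comparisons(results, outdir)
        summary["mode"] = "sequence"
        summary["n_promoters"] = len(promoters)
        summary["categories"] = categories
        log_lines.append(
            f"{len(promoters)} promoters scanned against {len(catalog)} CRE groups; "
            f"{len(occurrences)} occurrences"
        )

    log_lines.append(f"finished {datetime.now(timezone.utc).isoformat()}")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    logger.info("pipeline complete; outputs in %s", outdir)
    return summary
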
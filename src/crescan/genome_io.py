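"""Genome sequence and gene-annotation input, and strand-aware promoter extraction.

Coordinates are 0-based half-open internally. GFF3 (1-based inclusive) is
converted on read; human-readable report headers print 1-based inclusive.
The promoter window is the ``length`` bases immediately upstream of the
anchor (TSS by default), excluding the anchor base itself, read 5'->3'
toward the gene, i.e. reverse-complemented for minus-strand genes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_STRANDS = frozenset({"+", "-"})
_VALID_LABELS = frozenset({"up", "down", "none"})
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's location plus its regulation label.

    ``tss`` is the 0-based coordinate of the transcription start base on the
    forward strand of ``chrom`` (the 5'-most transcribed base of the gene).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    label: str = "none"

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id!r}: tss must be >= 0, got {self.tss}")
        if self.label not in _VALID_LABELS:
            raise ValueError(
                f"gene {self.gene_id!r}: label must be one of {sorted(_VALID_LABELS)}, "
                f"got {self.label!r}"
            )


@dataclass(frozen=True)
class PromoterSequence:
    """An extracted promoter window.

    ``sequence`` reads 5'->3' toward the TSS (reverse-complemented for minus
    strand genes). ``start``/``end`` delimit the forward-strand window on
    ``chrom`` (0-based half-open). ``truncated`` is set when the window was
    clipped at a chromosome boundary.
    """

    gene_id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    truncated: bool
    requested_length: int

    def __post_init__(self) -> None:
        if len(self.sequence) > self.requested_length:
            raise ValueError("promoter longer than requested window")
        if self.truncated != (len(self.sequence) < self.requested_length):
            raise ValueError("truncated flag inconsistent with sequence length")

    @property
    def window(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def header(self) -> str:
        """FASTA header with the window printed 1-based inclusive."""
        return (
            f"{self.gene_id} window={self.chrom}:{self.start + 1}-{self.end}"
            f"({self.strand}) truncated={int(self.truncated)}"
        )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly wrapped) multi-record FASTA into {id: sequence}.

    Sequences are uppercased; characters outside {A,C,G,T,N} are replaced by
    N with a warning. Duplicate record ids and empty files are format errors.
    """
    path = Path(path)
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FormatError(f"{path}: duplicate FASTA record id {record.id!r}")
        seq = str(record.seq).upper().replace(" ", "").replace("\t", "")
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            logger.warning(
                "%s: record %s contains %d non-ACGTN characters; mapped to N",
                path, record.id, n_bad,
            )
            seq = _NON_ACGTN.sub("N", seq)
        genome[record.id] = seq
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def _gff3_gene_models(path: Path, anchor: str) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in _VALID_STRANDS:
            raise FormatError(
                f"{path}: gene {feat.id!r} has unknown strand {feat.strand!r}"
            )
        start0, end0 = feat.start - 1, feat.end  # to 0-based half-open
        if anchor == "cds_start":
            cds = list(db.children(feat, featuretype="CDS"))
            if cds:
                start0 = min(c.start for c in cds) - 1
                end0 = max(c.end for c in cds)
        tss = start0 if feat.strand == "+" else end0 - 1
        genes.append(GeneModel(feat.id, feat.seqid, feat.strand, tss))
    return genes


def _bed6_gene_models(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(
                    f"{path}:{lineno}: BED6 requires 6 columns, got {len(cols)}"
                )
            chrom, start, end, name, _score, strand = cols[:6]
            if strand not in _VALID_STRANDS:
                raise FormatError(
                    f"{path}:{lineno}: unknown strand {strand!r} for {name!r}"
                )
            start0, end0 = int(start), int(end)
            tss = start0 if strand == "+" else end0 - 1
            genes.append(GeneModel(name, chrom, strand, tss))
    return genes


def read_gene_annotations(
    path: str | Path, format: str = "gff3", anchor: str = "tss"
) -> list[GeneModel]:
    """Read gene models from GFF3 (features of type ``gene``) or BED6.

    ``anchor`` selects the promoter anchor coordinate: ``tss`` (annotated
    transcription start, the default) or ``cds_start`` (5'-most CDS base,
    GFF3 only; falls back to the gene 5' end when no CDS is annotated).
    """
    path = Path(path)
    if anchor not in {"tss", "cds_start"}:
        raise ValueError(f"anchor must be 'tss' or 'cds_start', got {anchor!r}")
    if format == "gff3":
        genes = _gff3_gene_models(path, anchor)
    elif format == "bed":
        genes = _bed6_gene_models(path)
    else:
        raise ValueError(f"format must be 'gff3' or 'bed', got {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def read_gene_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV ``gene_id<TAB>label`` with label in {up, down}."""
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            gene_id, label = cols[0].strip(), cols[1].strip().lower()
            if gene_id == "gene_id" and label == "label":
                continue  # optional header
            if label not in {"up", "down"}:
                raise FormatError(f"{path}:{lineno}: label must be up/down, got {label!r}")
            if gene_id in labels:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            labels[gene_id] = label
    if not labels:
        raise FormatError(f"{path}: no gene labels found")
    return labels


def attach_labels(genes: list[GeneModel], labels: dict[str, str]) -> list[GeneModel]:
    """Return gene models with labels attached; genes absent from ``labels`` keep 'none'."""
    return [
        GeneModel(g.gene_id, g.chrom, g.strand, g.tss, labels.get(g.gene_id, "none"))
        for g in genes
    ]


def extract_promoter(
    genome: dict[str, str], gene: GeneModel, length: int = 3000
) -> PromoterSequence:
    """Extract the ``length``-bp window immediately upstream of the gene anchor.

    For a plus-strand gene the forward-strand window is [tss-length, tss);
    for a minus-strand gene it is [tss+1, tss+1+length), returned
    reverse-complemented so the string reads 5'->3' toward the TSS. The TSS
    base itself is excluded. Windows are clipped at chromosome bounds and
    flagged ``truncated``.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not in genome")
    chrom_seq = genome[gene.chrom]
    if gene.tss >= len(chrom_seq):
        raise ValueError(
            f"gene {gene.gene_id!r}: tss {gene.tss} beyond chromosome "
            f"{gene.chrom!r} length {len(chrom_seq)}"
        )
    if gene.strand == "+":
        start, end = max(0, gene.tss - length), gene.tss
        seq = chrom_seq[start:end]
    else:
        start, end = gene.tss + 1, min(len(chrom_seq), gene.tss + 1 + length)
        seq = str(Seq(chrom_seq[start:end]).reverse_complement())
    truncated = len(seq) < length
    if not seq:
        logger.warning(
            "gene %s: promoter window is empty (anchor at chromosome edge)",
            gene.gene_id,
        )
    return PromoterSequence(
        gene_id=gene.gene_id, sequence=seq, chrom=gene.chrom,
        start=start, end=end, strand=gene.strand,
        truncated=truncated, requested_length=length,
    )


def write_promoters_fasta(promoters: list[PromoterSequence], path: str | Path) -> None:
    """Write promoters as FASTA with window metadata in the headers."""
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.header()}\n")
            for i in range(0, len(p.sequence), 80):
                fh.write(p.sequence[i : i + 80] + "\n")
            if not p.sequence:
                fh.write("\n")
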
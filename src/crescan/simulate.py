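"""Synthetic promoter datasets with motifs planted at known probabilities.

Emulates the two-set differential-expression design the pipeline consumes:
two labeled gene sets
(61 up-regulated and 54 down-regulated genes by default) with 3-kb
promoters, i.i.d. background base composition, and each CRE planted
independently per gene with a set-specific Bernoulli probability at a
uniform random offset. One synthetic chromosome per gene keeps promoter
windows disjoint; strands alternate so both extraction branches are
exercised.

The truth table records post-hoc re-scan ground truth — what is actually
present in each promoter after all planting (and background) — not planting
intent, so recovery checks against the scanner are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from crescan.catalog import MotifDefinition, parse_iupac
from crescan.genome_io import GeneModel
from crescan.scanner import scan_sequence

_GENE_BODY = 200  # bases of transcribed sequence per synthetic gene
_UPSTREAM_PAD = 100  # extra bases beyond the promoter window

DEFAULT_SEED = 20230131


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-set promoter dataset."""

    n_up: int = 61
    n_down: int = 54
    promoter_length: int = 3000
    composition: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    plant_probs: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("gene counts must be >= 0")
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be >= 1")
        if set(self.composition) != set("ACGT"):
            raise ValueError("composition must assign probabilities to exactly A,C,G,T")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1, got {total}")
        if any(p < 0 for p in self.composition.values()):
            raise ValueError("composition probabilities must be >= 0")
        for cre_id, (p_up, p_down) in self.plant_probs.items():
            if not (0 <= p_up <= 1 and 0 <= p_down <= 1):
                raise ValueError(f"{cre_id}: planting probabilities must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its ground-truth table."""

    genome: dict[str, str]
    genes: list[GeneModel]
    labels: dict[str, str]
    promoters: dict[str, str]  # gene_id -> promoter string (5'->3' toward TSS)
    truth: pd.DataFrame  # gene_id, cre_id, planted, positions

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome FASTA, gene GFF3, label TSV and truth TSV (byte-stable)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "annotation": outdir / "genes.gff3",
            "labels": outdir / "labels.tsv",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(paths["annotation"], "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                chrom_len = len(self.genome[g.chrom])
                if g.strand == "+":
                    start, end = g.tss + 1, chrom_len  # 1-based inclusive
                else:
                    start, end = 1, g.tss + 1
                fh.write(
                    f"{g.chrom}\tcrescan\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}\n"
                )
        with open(paths["labels"], "w") as fh:
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{self.labels[g.gene_id]}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_background(
    length: int, composition: dict[str, float], rng: np.random.Generator
) -> str:
    """An i.i.d. nucleotide string drawn from ``composition``."""
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    if length == 0:
        return ""
    bases = sorted(composition)
    probs = np.array([composition[b] for b in bases], dtype=float)
    probs = probs / probs.sum()
    return "".join(rng.choice(bases, size=length, p=probs))


def sample_instance(pattern: str, rng: np.random.Generator) -> str:
    """A concrete sequence drawn uniformly from an IUPAC pattern's allowed sets."""
    return "".join(rng.choice(sorted(allowed)) for allowed in parse_iupac(pattern))


def plant_motif(
    sequence: str, variant_pattern: str, position: int, rng: np.random.Generator
) -> str:
    """Overwrite ``sequence`` at ``position`` with a concrete instance of the pattern."""
    instance = sample_instance(variant_pattern, rng)
    if position < 0 or position + len(instance) > len(sequence):
        raise ValueError(
            f"position {position} + pattern length {len(instance)} exceeds "
            f"sequence length {len(sequence)}"
        )
    return sequence[:position] + instance + sequence[position + len(instance) :]


def generate_dataset(
    spec: SyntheticSpec,
    catalog: list[MotifDefinition],
    outdir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate a reproducible synthetic genome + annotation + labels + truth.

    Per gene and per CRE in ``spec.plant_probs``, a Bernoulli draw at that
    gene set's probability decides whether one variant instance (variant
    chosen uniformly) is planted at a uniform random promoter offset.
    Later plants may overwrite earlier ones; the truth table is produced by
    re-scanning the final promoter, so it records what is actually present.
    """
    by_id = {m.cre_id: m for m in catalog}
    for cre_id in spec.plant_probs:
        if cre_id not in by_id:
            raise KeyError(f"plant_probs names unknown cre_id {cre_id!r}")
        if by_id[cre_id].max_variant_length > spec.promoter_length:
            raise ValueError(
                f"{cre_id}: longest variant exceeds promoter_length {spec.promoter_length}"
            )
    rng = np.random.default_rng(spec.seed)
    L = spec.promoter_length
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    labels: dict[str, str] = {}
    promoters: dict[str, str] = {}
    truth_rows: list[dict] = []

    gene_plan = [("up", i) for i in range(spec.n_up)] + [
        ("down", i) for i in range(spec.n_down)
    ]
    for idx, (label, _set_idx) in enumerate(gene_plan):
        gene_id = f"synth_{label}_{_set_idx + 1:03d}"
        chrom = f"chr_{gene_id}"
        strand = "+" if idx % 2 == 0 else "-"
        promoter = generate_background(L, spec.composition, rng)
        for cre_id in sorted(spec.plant_probs):
            p_up, p_down = spec.plant_probs[cre_id]
            p = p_up if label == "up" else p_down
            if rng.random() < p:
                motif = by_id[cre_id]
                variant = motif.variants[int(rng.integers(len(motif.variants)))]
                offset = int(rng.integers(0, L - len(variant) + 1))
                promoter = plant_motif(promoter, variant, offset, rng)
        pad = generate_background(_UPSTREAM_PAD, spec.composition, rng)
        body = generate_background(_GENE_BODY, spec.composition, rng)
        if strand == "+":
            # layout: [pad][promoter][gene body]; TSS right after the promoter
            genome[chrom] = pad + promoter + body
            tss = _UPSTREAM_PAD + L
        else:
            # layout: [gene body][revcomp(promoter)][pad]; TSS at body's last base
            genome[chrom] = body + str(Seq(promoter).reverse_complement()) + pad
            tss = _GENE_BODY - 1
        genes.append(GeneModel(gene_id, chrom, strand, tss, label))
        labels[gene_id] = label
        promoters[gene_id] = promoter
        # ground truth = what the scanner actually finds in the final promoter
        for cre_id in sorted(spec.plant_probs):
            hits = scan_sequence(promoter, by_id[cre_id], gene_id)
            positions = sorted({h.start for h in hits})
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "cre_id": cre_id,
                    "planted": bool(positions),
                    "positions": ",".join(map(str, positions)),
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "cre_id", "planted", "positions"]
    )
    dataset = SyntheticDataset(
        genome=genome, genes=genes, labels=labels, promoters=promoters, truth=truth
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset
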
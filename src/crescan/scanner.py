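"""Both-strand IUPAC motif scanning and the gene x CRE presence matrix.

Every window of each variant's length is tested against the pattern on the
plus strand and against the reverse-complemented pattern on the minus
strand. A sequence N is conservative: it satisfies a pattern position only
when that position allows the full {A,C,G,T} set (i.e. the pattern says N),
so a match is never claimed that the sequence cannot guarantee.

The headline statistic is presence/absence per CRE group — a gene carries a
group if any variant matches anywhere on either strand — but the full
occurrence list is kept for reporting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from crescan.catalog import MotifDefinition, parse_iupac, reverse_complement_pattern
from crescan.genome_io import PromoterSequence


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif hit, in 0-based half-open promoter-relative coordinates.

    ``strand`` is relative to the promoter string; for a minus-strand hit
    the reverse complement of ``matched`` satisfies ``variant``.
    """

    gene_id: str
    cre_id: str
    variant: str
    start: int
    end: int
    strand: str
    matched: str


def _pattern_to_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC pattern to an overlap-reporting regex over {A,C,G,T,N}."""
    parts = []
    for allowed in parse_iupac(pattern):
        chars = "".join(sorted(allowed))
        if len(allowed) == 4:
            chars += "N"
        parts.append(chars if len(chars) == 1 else f"[{chars}]")
    return re.compile(f"(?=({''.join(parts)}))")


def scan_sequence(
    sequence: str,
    motif: MotifDefinition,
    gene_id: str = "",
    strands: str = "both",
) -> list[MotifOccurrence]:
    """Find every occurrence of any variant of ``motif`` in ``sequence``.

    Occurrences are sorted by (start, strand, variant). With ``strands``
    set to ``"forward"`` only plus-strand hits are reported. A minus-strand
    hit at [s, e) means the reverse complement of sequence[s:e] satisfies
    the variant; self-reverse-complementary patterns therefore yield
    mirrored hits on both strands at the same span.
    """
    if strands not in {"both", "forward"}:
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    sequence = sequence.upper()
    hits: list[MotifOccurrence] = []
    for variant in motif.variants:
        for strand, pattern in (("+", variant), ("-", reverse_complement_pattern(variant))):
            if strand == "-" and strands == "forward":
                continue
            for m in _pattern_to_regex(pattern).finditer(sequence):
                s = m.start()
                hits.append(
                    MotifOccurrence(
                        gene_id=gene_id, cre_id=motif.cre_id, variant=variant,
                        start=s, end=s + len(variant), strand=strand,
                        matched=m.group(1),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand, h.variant))
    return hits


def scan_promoters(
    promoters: list[PromoterSequence],
    catalog: list[MotifDefinition],
    strands: str = "both",
) -> list[MotifOccurrence]:
    """Scan every promoter against every catalog motif."""
    occurrences: list[MotifOccurrence] = []
    for p in promoters:
        for motif in catalog:
            occurrences.extend(scan_sequence(p.sequence, motif, p.gene_id, strands))
    return occurrences


@dataclass
class PresenceMatrix:
    """Boolean gene x CRE-group table: does the promoter carry >=1 occurrence?"""

    table: pd.DataFrame  # bool, index = gene ids, columns = cre ids

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def cres(self) -> list[str]:
        return list(self.table.columns)

    def __getitem__(self, key: tuple[str, str]) -> bool:
        gene_id, cre_id = key
        return bool(self.table.at[gene_id, cre_id])

    def to_tsv(self, path) -> None:
        self.table.astype(int).to_csv(path, sep="\t", index_label="gene_id")


def build_presence_matrix(
    promoters: list[PromoterSequence],
    catalog: list[MotifDefinition],
    strands: str = "both",
    min_occurrences: int = 1,
    occurrences: list[MotifOccurrence] | None = None,
) -> PresenceMatrix:
    """Reduce motif occurrences to a gene x CRE presence matrix.

    A gene is "present" for a CRE when its promoter holds at least
    ``min_occurrences`` distinct (start, end) spans matching any variant;
    mirrored plus/minus hits of a palindromic pattern at the same span count
    once. Pass a precomputed ``occurrences`` list to avoid rescanning.
    """
    gene_ids = [p.gene_id for p in promoters]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids among promoters: {dupes}")
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    if occurrences is None:
        occurrences = scan_promoters(promoters, catalog, strands)
    cre_ids = [m.cre_id for m in catalog]
    spans: dict[tuple[str, str], set[tuple[int, int]]] = {}
    for occ in occurrences:
        spans.setdefault((occ.gene_id, occ.cre_id), set()).add((occ.start, occ.end))
    table = pd.DataFrame(
        [
            [len(spans.get((g, c), ())) >= min_occurrences for c in cre_ids]
            for g in gene_ids
        ],
        index=pd.Index(gene_ids, name="gene_id"),
        columns=cre_ids,
        dtype=bool,
    )
    return PresenceMatrix(table)


def occurrences_to_bed(occurrences: list[MotifOccurrence]) -> str:
    """Render occurrences as BED6 lines in promoter-relative coordinates."""
    lines = [
        f"{o.gene_id}\t{o.start}\t{o.end}\t{o.cre_id}:{o.variant}\t0\t{o.strand}"
        for o in occurrences
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def occurrences_to_table(occurrences: list[MotifOccurrence]) -> pd.DataFrame:
    """Long-format occurrence table (one row per hit)."""
    return pd.DataFrame(
        [
            {
                "gene_id": o.gene_id, "cre_id": o.cre_id, "variant": o.variant,
                "start": o.start, "end": o.end, "strand": o.strand,
                "matched": o.matched,
            }
            for o in occurrences
        ],
        columns=["gene_id", "cre_id", "variant", "start", "end", "strand", "matched"],
    )
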
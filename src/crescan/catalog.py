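"""CRE motif catalog: IUPAC degenerate consensus patterns grouped into CRE families.

A CRE group (e.g. the W box or the MYB-binding site) may comprise several
consensus variants; a promoter "carries" the group if any variant matches on
either strand. Patterns use the 15 IUPAC nucleotide codes; no position
weight matrices are involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: The 15 IUPAC nucleotide codes and the concrete bases each allows.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

STANDARD_TAGS = frozenset({"growth", "stress", "light"})


def parse_iupac(pattern: str) -> tuple[frozenset[str], ...]:
    """Map a degenerate consensus to per-position allowed-base sets.

    Case-insensitive. Raises ValueError naming the (1-based) position of the
    first character outside the IUPAC alphabet.
    """
    if not pattern:
        raise ValueError("empty IUPAC pattern")
    sets = []
    for i, ch in enumerate(pattern.upper()):
        try:
            sets.append(IUPAC_CODES[ch])
        except KeyError:
            raise ValueError(
                f"invalid IUPAC character {ch!r} at position {i + 1} in {pattern!r}"
            ) from None
    return tuple(sets)


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse-complement a degenerate consensus (R<->Y, K<->M, W/S/N fixed)."""
    parse_iupac(pattern)  # validate first so errors name the pattern position
    return str(Seq(pattern.upper()).reverse_complement())


@dataclass(frozen=True)
class MotifDefinition:
    """A named CRE group: one or more IUPAC variants plus TF/category annotation."""

    cre_id: str
    display_name: str
    variants: tuple[str, ...]
    tfs: tuple[str, ...] = ()
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cre_id:
            raise ValueError("cre_id must be nonempty")
        if not self.variants:
            raise ValueError(f"{self.cre_id}: at least one variant required")
        deduped = tuple(dict.fromkeys(v.upper() for v in self.variants))
        for v in deduped:
            parse_iupac(v)
        object.__setattr__(self, "variants", deduped)
        object.__setattr__(self, "tags", frozenset(self.tags))

    @property
    def max_variant_length(self) -> int:
        return max(len(v) for v in self.variants)


def _split(cell: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in cell.split(",") if s.strip())


def load_catalog(path: str | Path) -> list[MotifDefinition]:
    """Load a motif catalog TSV.

    Columns: cre_id, display_name, variants (comma-separated IUPAC),
    tfs (comma-separated), tags (comma-separated). Duplicate cre_ids and
    unparsable variants are errors; variants shorter than 4 bases get a
    warning (high background hit rate).
    """
    path = Path(path)
    catalog: list[MotifDefinition] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "cre_id":
                continue  # header
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(cols)}")
            cre_id, display_name, variants = cols[0], cols[1], _split(cols[2])
            tfs = _split(cols[3]) if len(cols) > 3 else ()
            tags = _split(cols[4]) if len(cols) > 4 else ()
            if cre_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate cre_id {cre_id!r}")
            seen.add(cre_id)
            try:
                motif = MotifDefinition(cre_id, display_name, variants, tfs, frozenset(tags))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            for v in motif.variants:
                if len(v) < 4:
                    logger.warning(
                        "%s:%d: variant %r of %s is shorter than 4 bases "
                        "(expect a high background hit rate)",
                        path, lineno, v, cre_id,
                    )
            catalog.append(motif)
    if not catalog:
        raise ValueError(f"{path}: no catalog rows found")
    return catalog


def write_meme(catalog: list[MotifDefinition], path: str | Path) -> None:
    """Export the catalog in minimal MEME motif format.

    Each consensus variant becomes one motif whose position frequency matrix
    puts equal weight on every base its IUPAC code allows.
    """
    order = "ACGT"
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for motif in catalog:
            for vi, variant in enumerate(motif.variants, 1):
                sets = parse_iupac(variant)
                name = motif.cre_id if len(motif.variants) == 1 else f"{motif.cre_id}.{vi}"
                fh.write(f"MOTIF {name} {variant}\n")
                fh.write(
                    f"letter-probability matrix: alength= 4 w= {len(sets)} "
                    f"nsites= 1 E= 0\n"
                )
                for allowed in sets:
                    p = 1.0 / len(allowed)
                    fh.write(
                        " ".join(f"{p:.6f}" if b in allowed else "0.000000" for b in order)
                        + "\n"
                    )
                fh.write("\n")
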
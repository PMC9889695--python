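"""Join classified CREs to their interacting TFs and functional categories.

Categories follow the growth / stress / light vocabulary plus free-form
hormone tags (ABA, JA, SA, CK, GA, BR, auxin, ...). A CRE may belong to
several categories at once, so category counts are multi-membership counts,
not a partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from crescan.catalog import MotifDefinition
from crescan.representation import RepresentationResult, Tier


@dataclass(frozen=True)
class AnnotatedResult:
    """A representation result plus the catalog's TF and category annotation."""

    result: RepresentationResult
    tfs: tuple[str, ...]
    tags: frozenset[str]

    @property
    def cre_id(self) -> str:
        return self.result.cre_id

    @property
    def gene_set(self) -> str:
        return self.result.gene_set

    @property
    def tier(self) -> Tier | None:
        return self.result.tier


def annotate_results(
    results: list[RepresentationResult], catalog: list[MotifDefinition]
) -> list[AnnotatedResult]:
    """Attach each result's TFs and tags from its catalog entry, preserving order."""
    by_id = {m.cre_id: m for m in catalog}
    annotated = []
    for r in results:
        motif = by_id.get(r.cre_id)
        if motif is None:
            raise KeyError(f"cre_id {r.cre_id!r} not in catalog")
        annotated.append(AnnotatedResult(result=r, tfs=motif.tfs, tags=motif.tags))
    return annotated


def summarize_categories(
    annotated: list[AnnotatedResult], tier: Tier
) -> dict[str, dict[str, int]]:
    """Count CREs per category tag per gene set at the given tier.

    A CRE carrying k tags contributes to all k tag counts.
    """
    counts: dict[str, dict[str, int]] = {}
    for a in annotated:
        if a.tier != tier:
            continue
        per_set = counts.setdefault(a.gene_set, {})
        for tag in sorted(a.tags):
            per_set[tag] = per_set.get(tag, 0) + 1
    return counts


def annotated_to_table(annotated: list[AnnotatedResult]) -> pd.DataFrame:
    """Wide summary table: one row per (CRE, gene set) with G/S/L flags."""
    rows = []
    for a in annotated:
        rows.append(
            {
                "cre_id": a.cre_id,
                "gene_set": a.gene_set,
                "tfs": ",".join(a.tfs),
                "G": int("growth" in a.tags),
                "S": int("stress" in a.tags),
                "L": int("light" in a.tags),
                "other_tags": ",".join(sorted(a.tags - {"growth", "stress", "light"})),
                "percent": round(a.result.percent),
                "tier": a.tier.value if a.tier else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cre_id", "gene_set", "tfs", "G", "S", "L", "other_tags", "percent", "tier"],
    )
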
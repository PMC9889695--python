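"""Percent-of-genes statistic per CRE per gene set, and representation tiers.

A CRE's representation in a gene set is the fraction of the set whose
promoters carry the CRE. Tiers partition [0, 1] on the exact fraction:
over-represented on [0.75, 1], moderately over-represented on [0.50, 0.75),
under-represented on [0, 0.50). Classification always uses the exact
rational fraction, never the rounded display percent, so a 74.5% CRE cannot
flip tiers through rounding. No significance testing is attached: the
scheme is a threshold classification, not a hypothesis test.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Real
from pathlib import Path

import pandas as pd

from crescan.scanner import PresenceMatrix


class Tier(str, enum.Enum):
    OVER = "overrepresented"
    MODERATE = "moderately_overrepresented"
    UNDER = "underrepresented"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class RepresentationThresholds:
    """Tier cut points as fractions: >=over is over-represented, [moderate_low, over) moderate."""

    over: Fraction = Fraction(3, 4)
    moderate_low: Fraction = Fraction(1, 2)

    def __post_init__(self) -> None:
        over = Fraction(self.over)
        moderate_low = Fraction(self.moderate_low)
        if not (0 < moderate_low < over <= 1):
            raise ValueError(
                f"need 0 < moderate_low < over <= 1, got "
                f"moderate_low={moderate_low}, over={over}"
            )
        object.__setattr__(self, "over", over)
        object.__setattr__(self, "moderate_low", moderate_low)


@dataclass(frozen=True)
class RepresentationResult:
    """One CRE's representation within one gene set."""

    cre_id: str
    gene_set: str
    n_present: int
    n_total: int
    fraction: Fraction
    percent: float
    tier: Tier | None = None

    def with_tier(self, thresholds: RepresentationThresholds) -> "RepresentationResult":
        return RepresentationResult(
            self.cre_id, self.gene_set, self.n_present, self.n_total,
            self.fraction, self.percent,
            classify_representation(self.fraction, thresholds),
        )


@dataclass(frozen=True)
class ComparisonResult:
    """CREs at a given tier in both, only the up, or only the down gene set."""

    tier: Tier
    common: tuple[str, ...]
    up_only: tuple[str, ...]
    down_only: tuple[str, ...]


def classify_representation(
    fraction: Real | Fraction, thresholds: RepresentationThresholds | None = None
) -> Tier:
    """Assign the representation tier for an exact presence fraction in [0, 1]."""
    thresholds = thresholds or RepresentationThresholds()
    if isinstance(fraction, float) and not math.isfinite(fraction):
        raise ValueError(f"fraction must be finite, got {fraction}")
    frac = Fraction(fraction)
    if not (0 <= frac <= 1):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if frac >= thresholds.over:
        return Tier.OVER
    if frac >= thresholds.moderate_low:
        return Tier.MODERATE
    return Tier.UNDER


def percent_with_cre(
    matrix: PresenceMatrix, gene_set: list[str], cre_id: str, set_name: str = ""
) -> RepresentationResult:
    """Fraction/percent of ``gene_set`` whose promoter carries ``cre_id``.

    The denominator is the full gene set; the fraction is kept as an exact
    rational. The returned result has no tier (classify separately).
    """
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    if cre_id not in matrix.table.columns:
        raise KeyError(f"unknown cre_id {cre_id!r}")
    missing = [g for g in gene_set if g not in matrix.table.index]
    if missing:
        raise KeyError(f"genes not in presence matrix: {missing}")
    n_total = len(gene_set)
    n_present = int(matrix.table.loc[gene_set, cre_id].sum())
    fraction = Fraction(n_present, n_total)
    return RepresentationResult(
        cre_id=cre_id, gene_set=set_name, n_present=n_present, n_total=n_total,
        fraction=fraction, percent=float(100 * fraction),
    )


def compute_representation(
    matrix: PresenceMatrix,
    gene_sets: dict[str, list[str]],
    thresholds: RepresentationThresholds | None = None,
) -> list[RepresentationResult]:
    """Classified representation of every CRE in every named gene set."""
    thresholds = thresholds or RepresentationThresholds()
    return [
        percent_with_cre(matrix, genes, cre_id, set_name).with_tier(thresholds)
        for set_name, genes in gene_sets.items()
        for cre_id in matrix.cres
    ]


def read_percent_table(path: str | Path) -> pd.DataFrame:
    """Read a ``cre_id<TAB>percent_up<TAB>percent_down`` table (blank = absent)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["cre_id", "percent_up", "percent_down"], header=None,
        dtype={"cre_id": str}, skip_blank_lines=True,
    )
    if len(df) and df.iloc[0]["cre_id"] == "cre_id":
        df = df.iloc[1:].reset_index(drop=True)
    for col in ("percent_up", "percent_down"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def classify_percent_table(
    table: pd.DataFrame, thresholds: RepresentationThresholds | None = None
) -> tuple[list[RepresentationResult], dict[str, dict[Tier, int]]]:
    """Classify a precomputed percent table (reanalysis without sequences).

    ``table`` columns: cre_id, percent_up, percent_down; NaN means the CRE
    is absent from that gene set's listing and is excluded from that set's
    tier counts. Returns the classified rows and per-set tier counts.
    """
    thresholds = thresholds or RepresentationThresholds()
    results: list[RepresentationResult] = []
    counts: dict[str, dict[Tier, int]] = {
        "up": {t: 0 for t in Tier}, "down": {t: 0 for t in Tier},
    }
    for row in table.itertuples(index=False):
        for set_name, pct in (("up", row.percent_up), ("down", row.percent_down)):
            if pd.isna(pct):
                continue
            if not (0 <= pct <= 100):
                raise ValueError(
                    f"cre {row.cre_id!r}, set {set_name!r}: percent {pct} outside [0, 100]"
                )
            fraction = Fraction(str(pct)) / 100
            tier = classify_representation(fraction, thresholds)
            counts[set_name][tier] += 1
            results.append(
                RepresentationResult(
                    cre_id=row.cre_id, gene_set=set_name, n_present=-1, n_total=-1,
                    fraction=fraction, percent=float(pct), tier=tier,
                )
            )
    return results, counts


def compare_gene_sets(
    up_results: list[RepresentationResult],
    down_results: list[RepresentationResult],
    tier: Tier,
) -> ComparisonResult:
    """CREs at ``tier`` common to both sets, or private to one."""
    up = {r.cre_id for r in up_results if r.tier == tier}
    down = {r.cre_id for r in down_results if r.tier == tier}
    return ComparisonResult(
        tier=tier,
        common=tuple(sorted(up & down)),
        up_only=tuple(sorted(up - down)),
        down_only=tuple(sorted(down - up)),
    )


def results_to_table(results: list[RepresentationResult]) -> pd.DataFrame:
    """Long-format result table; percents rounded for display only."""
    return pd.DataFrame(
        [
            {
                "cre_id": r.cre_id, "gene_set": r.gene_set,
                "n_present": r.n_present, "n_total": r.n_total,
                "percent": round(r.percent),
                "tier": r.tier.value if r.tier else "",
            }
            for r in results
        ],
        columns=["cre_id", "gene_set", "n_present", "n_total", "percent", "tier"],
    )
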
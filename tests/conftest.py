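"""Shared fixtures and the independent naive motif-matching oracle.

The oracle deliberately re-derives IUPAC semantics from its own lookup
tables and matches window-by-window, position-by-position, so scanner tests
compare two independent routes to the same answer.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")

from crescan.catalog import MotifDefinition
from crescan.resources import example_catalog_path
from crescan.catalog import load_catalog

# Independent IUPAC tables (not imported from the package under test).
ORACLE_IUPAC: dict[str, set[str]] = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_window_match(window: str, pattern: str) -> bool:
    """Does a concrete {A,C,G,T,N} window satisfy an IUPAC pattern?

    A window N counts as a match only where the pattern allows all four bases.
    """
    for ch, p in zip(window.upper(), pattern.upper()):
        allowed = ORACLE_IUPAC[p]
        if ch == "N":
            if allowed != {"A", "C", "G", "T"}:
                return False
        elif ch not in allowed:
            return False
    return True


def oracle_scan(sequence: str, pattern: str, strands: str = "both") -> set[tuple[int, str]]:
    """All (start, strand) hits of one pattern by exhaustive window testing."""
    seq = sequence.upper()
    k = len(pattern)
    hits: set[tuple[int, str]] = set()
    for s in range(len(seq) - k + 1):
        window = seq[s : s + k]
        if oracle_window_match(window, pattern):
            hits.add((s, "+"))
        if strands == "both":
            rc_window = "".join(_COMPLEMENT[c] for c in reversed(window))
            if oracle_window_match(rc_window, pattern):
                hits.add((s, "-"))
    return hits


def random_iupac_pattern(rng: np.random.Generator, max_len: int = 8) -> str:
    codes = list(ORACLE_IUPAC)
    length = int(rng.integers(1, max_len + 1))
    return "".join(rng.choice(codes) for _ in range(length))


def random_sequence(rng: np.random.Generator, max_len: int = 50, with_n: bool = True) -> str:
    alphabet = list("ACGTN") if with_n else list("ACGT")
    length = int(rng.integers(0, max_len + 1))
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture(scope="session")
def example_catalog():
    return load_catalog(example_catalog_path())


@pytest.fixture
def wbox() -> MotifDefinition:
    return MotifDefinition("W_BOX", "W box", ("TTGACC", "TTGACT"), ("WRKY",),
                           frozenset({"stress", "SA"}))


@pytest.fixture
def ebox() -> MotifDefinition:
    return MotifDefinition("E_BOX", "E box", ("CANNTG",), ("bHLH112",),
                           frozenset({"stress"}))
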
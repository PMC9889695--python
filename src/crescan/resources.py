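"""Paths to the packaged data fixtures."""

from __future__ import annotations

from importlib.resources import as_file, files
from pathlib import Path

_DATA = files("crescan") / "data"


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    with as_file(_DATA / name) as p:
        return Path(p)


def table1_overrepresented_path() -> Path:
    """Percent table for the over-represented tier listing (published columns)."""
    return data_path("table1_overrepresented.tsv")


def table2_moderately_overrepresented_path() -> Path:
    """Percent table for the moderately over-represented tier listing."""
    return data_path("table2_moderately_overrepresented.tsv")


def example_catalog_path() -> Path:
    """Example CRE catalog fixture (illustrative consensus sequences)."""
    return data_path("example_catalog.tsv")


def synthetic_gene_labels_path() -> Path:
    """Synthetic stand-in gene-label list at a realistic scale (61 up, 54 down)."""
    return data_path("synthetic_gene_labels.tsv")
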
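"""Paths to the small fixture files bundled with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def guide_genes_path() -> Path:
    """The eight photoperiodic flowering-time guide genes (symbol, MSU id).

    OsGI, Ghd7, Hd1, Ehd1, RFT1, Hd3a, OsMADS14 and OsMADS15 - the
    OsGI-Hd1-Hd3a and Ghd7-Ehd1-Hd3a/RFT1 pathway members plus the two
    downstream MADS-box genes.
    """
    return Path(str(resources.files("guidecoex").joinpath("data/guide_genes.tsv")))


def tf_families_path() -> Path:
    """A small synthetic stand-in TF-family table for demos and tests.

    This is NOT a PlantTFDB export: it is a hand-assembled illustrative
    table (gene id -> family) whose one scientifically load-bearing row is
    LOC_Os09g12750 -> G2-like (the OsPHL3 locus). For a real analysis,
    supply a genome-wide family annotation in the same two-column format.
    """
    return Path(str(resources.files("guidecoex").joinpath("data/synthetic_tf_families.tsv")))
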
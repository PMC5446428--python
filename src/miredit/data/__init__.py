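"""Packaged reference data.

* ``mir411.fa`` / ``mir411_matures.tsv`` — the hsa-mir-411 hairpin precursor
  (chr14, miR-379/miR-656 cluster) with its 5p/3p mature arms. The 5p seed
  carries a well-characterised A-to-I editing site at precursor position 20
  (mature position 5) whose edit converts an A-C mismatch into an I(G)-C pair
  and strongly stabilises the hairpin.
* ``gbm_hypoediting_table.tsv`` — curated summary of 22 A-to-I editing events
  significantly hypoedited in glioblastoma multiforme (GBM) relative to
  frontal cortex (FC) and corpus callosum (CC): per-group presence counts and
  median editing levels, seed membership, precursor position, and 7-mer seed
  target counts before/after editing with their overlap. "-" marks medians
  not computable from too few expressed samples; ``novel`` marks events first
  reported in that GBM screen; NA target columns are non-seed events (no
  target redirection to score).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..refset import ReferenceSet, load_reference


def _path(name: str):
    return resources.files(__package__) / name


def load_mir411_reference() -> ReferenceSet:
    """The hsa-mir-411 precursor with both mature arms."""
    with resources.as_file(_path("mir411.fa")) as fasta, resources.as_file(
        _path("mir411_matures.tsv")
    ) as matures:
        return load_reference(fasta, matures)


def load_gbm_hypoediting_table() -> pd.DataFrame:
    """The GBM hypoediting event summary (one row per event)."""
    with resources.as_file(_path("gbm_hypoediting_table.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype={"mirna": str})
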
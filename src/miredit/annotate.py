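"""Sequence-context annotation of editing sites.

Covers seed membership (mature positions 2-8; seed-relative positions 1-7),
the +/-10 nt window around the edited base with its immediate-neighbor UAG
context (5' uracil, 3' guanine around an edited adenosine — the context most
permissive for ADAR), position frequency matrices for logo rendering, and
sliding trinucleotide counts over the precursor set.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Optional

import pandas as pd

from .editcall import EditingSite
from .refset import ReferenceSet

DEFAULT_FLANK = 10


@dataclasses.dataclass(frozen=True)
class MotifContext:
    precursor_id: str
    position: int
    window: str                 # up to 2*flank+1 bases, truncated at ends
    center_offset: int          # index of the edited base within window
    flank: int
    five_prime: Optional[str]   # immediate 5' neighbor (None at precursor end)
    three_prime: Optional[str]
    uag_flag: bool

    def base_at(self, offset: int) -> Optional[str]:
        """Base at window offset (-flank..+flank); None where truncated."""
        idx = self.center_offset + offset
        if 0 <= idx < len(self.window):
            return self.window[idx]
        return None


def annotate_seed(site: EditingSite, refset: ReferenceSet) -> EditingSite:
    """Set in_seed/seed_pos from the mature coordinates.

    Seed = mature positions 2-8; seed-relative position = mature_pos - 1
    (so seed positions run 1-7). Pure function of mature_pos.
    """
    in_seed = 2 <= site.mature_pos <= 8
    return dataclasses.replace(
        site,
        in_seed=in_seed,
        seed_pos=site.mature_pos - 1 if in_seed else None,
    )


def motif_window(
    refset: ReferenceSet,
    precursor_id: str,
    position: int,
    flank: int = DEFAULT_FLANK,
) -> MotifContext:
    """Window of +/-flank bases around a precursor position, truncated (never
    padded) at the precursor ends."""
    rec = refset[precursor_id]
    seq = rec.sequence
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} outside precursor {precursor_id}")
    lo = max(1, position - flank)
    hi = min(len(seq), position + flank)
    window = seq[lo - 1 : hi]
    five = seq[position - 2] if position >= 2 else None
    three = seq[position] if position < len(seq) else None
    center = seq[position - 1]
    uag = center == "A" and five == "U" and three == "G"
    return MotifContext(
        precursor_id=precursor_id,
        position=position,
        window=window,
        center_offset=position - lo,
        flank=flank,
        five_prime=five,
        three_prime=three,
        uag_flag=uag,
    )


def build_pfm(contexts: Iterable[MotifContext], flank: int = DEFAULT_FLANK) -> pd.DataFrame:
    """Position frequency matrix over window offsets -flank..+flank.

    Rows A/C/G/U, one column per offset; truncated windows contribute only at
    offsets where they are defined, so column totals equal the number of
    windows covering that offset.
    """
    offsets = list(range(-flank, flank + 1))
    counts = {base: {o: 0 for o in offsets} for base in "ACGU"}
    for ctx in contexts:
        for o in offsets:
            base = ctx.base_at(o)
            if base is not None:
                counts[base][o] += 1
    return pd.DataFrame(
        {o: [counts[b][o] for b in "ACGU"] for o in offsets}, index=list("ACGU")
    )


def trinucleotide_counts(refset: ReferenceSet) -> pd.Series:
    """Overlapping 3-mer counts (step 1) over every precursor sequence."""
    kmers = ["".join(p) for p in itertools.product("ACGU", repeat=3)]
    counts = dict.fromkeys(kmers, 0)
    for rec in refset:
        seq = rec.sequence
        for i in range(len(seq) - 2):
            counts[seq[i : i + 3]] += 1
    return pd.Series(counts, name="count")


def annotate_sites(
    sites: Iterable[EditingSite],
    refset: ReferenceSet,
    flank: int = DEFAULT_FLANK,
) -> tuple[list[EditingSite], list[MotifContext]]:
    """Seed-annotate every site and collect its motif window."""
    annotated, contexts = [], []
    for site in sites:
        annotated.append(annotate_seed(site, refset))
        contexts.append(motif_window(refset, site.precursor_id, site.position, flank))
    return annotated, contexts
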
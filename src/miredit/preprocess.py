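"""3' adapter trimming and read-length filtering.

Small RNA inserts (15-28 nt after trimming) are shorter than the sequencing
read, so the 3' adapter is expected at the read's 3' end. Trimming removes the
read suffix at the leftmost position where a prefix of the adapter (at least
``min_overlap`` bases, zero mismatches) matches. Reads with no adapter match
are kept and flagged: they may be adapter-free full-length inserts, and
dropping them would bias against 28-nt matures.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

DEFAULT_MIN_LEN = 15
DEFAULT_MAX_LEN = 28
DEFAULT_MIN_OVERLAP = 8
# Illumina TruSeq small RNA 3' adapter prefix
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclasses.dataclass
class Read:
    read_id: str
    bases: str
    qualities: str

    def __len__(self) -> int:
        return len(self.bases)


@dataclasses.dataclass
class ReadBatch:
    """Reads plus provenance: where they came from and what was dropped."""

    reads: list[Read]
    source: str = ""
    dropped: dict[str, int] = dataclasses.field(default_factory=dict)
    untrimmed: int = 0

    def __len__(self) -> int:
        return len(self.reads)

    def total_seen(self) -> int:
        return len(self.reads) + sum(self.dropped.values())


def trim_adapter(read: Read, adapter: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> tuple[Read, bool]:
    """Remove the 3' adapter from one read.

    Returns ``(trimmed_read, found)``. ``found`` is False when no adapter
    prefix of >= min_overlap bases matches a read suffix; the read is then
    returned unchanged.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    bases = read.bases
    n = len(bases)
    for i in range(0, n - min_overlap + 1):
        k = min(len(adapter), n - i)
        if bases[i : i + k] == adapter[:k]:
            return Read(read.read_id, bases[:i], read.qualities[:i]), True
    return read, False


def length_filter(
    batch: ReadBatch,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> ReadBatch:
    """Keep reads with length in [min_len, max_len] inclusive; count the rest."""
    kept, too_short, too_long = [], 0, 0
    for read in batch.reads:
        if len(read) < min_len:
            too_short += 1
        elif len(read) > max_len:
            too_long += 1
        else:
            kept.append(read)
    dropped = dict(batch.dropped)
    dropped["too_short"] = dropped.get("too_short", 0) + too_short
    dropped["too_long"] = dropped.get("too_long", 0) + too_long
    return ReadBatch(kept, source=batch.source, dropped=dropped, untrimmed=batch.untrimmed)


def read_fastq(path: str | Path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield Read(rec.id, str(rec.seq), quals)


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{read.qualities}\n")
            n += 1
    return n


def preprocess_fastq(
    fastq: str | Path,
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> ReadBatch:
    """Trim and length-filter a FASTQ file in one pass."""
    trimmed, untrimmed = [], 0
    for read in read_fastq(fastq):
        out, found = trim_adapter(read, adapter, min_overlap)
        if not found:
            untrimmed += 1
        trimmed.append(out)
    batch = ReadBatch(trimmed, source=str(fastq), untrimmed=untrimmed)
    return length_filter(batch, min_len, max_len)
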
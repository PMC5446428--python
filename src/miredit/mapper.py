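"""Ungapped 1-mismatch alignment of small RNA reads to the precursor set.

Reads are placed at every offset of every precursor and scored by Hamming
distance; only the best stratum (fewest mismatches, up to ``max_mismatch``) is
kept. Reads whose best stratum holds more than one placement are discarded —
a deliberate, conservative policy that prevents cross-mapping between
paralogous precursors, the classic artifact in miRNA editing detection.

The scan is exact and exhaustive (the reference is a few kilobases of
hairpins, not a genome), vectorised with a sliding-window view over the
concatenated precursor sequences.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import Read, ReadBatch
from .refset import ReferenceSet

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_CODE_TO_BASE = "ACGU"
_SENTINEL = 255

PILEUP_COLUMNS = ["precursor_id", "position", "ref_base", "A", "C", "G", "U", "depth"]


def encode(seq: str) -> np.ndarray:
    return np.array([_BASE_TO_CODE.get(b, _SENTINEL) for b in seq.upper()], dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    precursor_id: str
    offset: int  # 1-based start on the precursor
    read_bases: str
    mismatches: tuple[tuple[int, str, str], ...]  # (precursor_pos, ref, read)

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatches)

    @property
    def read_length(self) -> int:
        return len(self.read_bases)

    @property
    def end(self) -> int:
        """1-based inclusive end on the precursor."""
        return self.offset + self.read_length - 1


class PrecursorIndex:
    """Concatenated, encoded precursor sequences with per-length window views."""

    def __init__(self, refset: ReferenceSet):
        parts, self.bounds = [], []  # bounds: (precursor_id, concat_start)
        pos = 0
        pad = np.full(28, _SENTINEL, dtype=np.uint8)
        for rec in refset:
            self.bounds.append((rec.precursor_id, pos, len(rec.sequence)))
            parts.append(encode(rec.sequence))
            parts.append(pad)
            pos += len(rec.sequence) + len(pad)
        self.concat = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        self._windows: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def windows(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        """(window matrix, boolean validity mask) for a given read length."""
        if length not in self._windows:
            if len(self.concat) < length:
                w = np.empty((0, length), dtype=np.uint8)
                valid = np.empty(0, dtype=bool)
            else:
                w = np.lib.stride_tricks.sliding_window_view(self.concat, length)
                valid = ~(w == _SENTINEL).any(axis=1)
            self._windows[length] = (w, valid)
        return self._windows[length]

    def locate(self, concat_offset: int) -> tuple[str, int]:
        """Map a concatenated 0-based offset to (precursor_id, 1-based offset)."""
        for pid, start, length in self.bounds:
            if start <= concat_offset < start + length:
                return pid, concat_offset - start + 1
        raise ValueError(f"offset {concat_offset} not inside any precursor")


def _get_index(refset: ReferenceSet) -> PrecursorIndex:
    if refset._index_cache is None:
        refset._index_cache = PrecursorIndex(refset)
    return refset._index_cache


def align_read(
    read: Read, refset: ReferenceSet, max_mismatch: int = 1
) -> list[AlignmentHit]:
    """All best-stratum ungapped placements of one read (empty = unmapped)."""
    index = _get_index(refset)
    seq = read.bases.upper().replace("T", "U")
    enc = encode(seq)
    windows, valid = index.windows(len(enc))
    if windows.shape[0] == 0:
        return []
    mm = (windows != enc).sum(axis=1)
    mm = np.where(valid, mm, len(enc) + 1)
    best = int(mm.min())
    if best > max_mismatch:
        return []
    hits = []
    for concat_offset in np.flatnonzero(mm == best):
        pid, offset = index.locate(int(concat_offset))
        ref_seq = refset[pid].sequence[offset - 1 : offset - 1 + len(seq)]
        mismatches = tuple(
            (offset + i, rb, qb)
            for i, (rb, qb) in enumerate(zip(ref_seq, seq))
            if rb != qb
        )
        hits.append(AlignmentHit(read.read_id, pid, offset, seq, mismatches))
    return hits


def resolve_ambiguity(hits: Sequence[AlignmentHit]) -> Optional[AlignmentHit]:
    """Keep the unique best-stratum hit; equally good multi-mappers are dropped."""
    if not hits:
        return None
    best = min(h.n_mismatch for h in hits)
    stratum = [h for h in hits if h.n_mismatch == best]
    return stratum[0] if len(stratum) == 1 else None


@dataclasses.dataclass
class MappingResult:
    hits: list[AlignmentHit]
    weights: list[int]  # multiplicity of each hit (collapsed duplicate reads)
    n_unmapped: int = 0
    n_ambiguous: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.weights)


def map_batch(
    batch: ReadBatch, refset: ReferenceSet, max_mismatch: int = 1
) -> MappingResult:
    """Align a whole batch, collapsing identical sequences for speed."""
    unique: Counter[str] = Counter(r.bases.upper().replace("T", "U") for r in batch.reads)
    rep_id = {}
    for r in batch.reads:
        rep_id.setdefault(r.bases.upper().replace("T", "U"), r.read_id)
    result = MappingResult([], [])
    for seq, count in unique.items():
        hits = align_read(Read(rep_id[seq], seq, "I" * len(seq)), refset, max_mismatch)
        if not hits:
            result.n_unmapped += count
            continue
        chosen = resolve_ambiguity(hits)
        if chosen is None:
            result.n_ambiguous += count
        else:
            result.hits.append(chosen)
            result.weights.append(count)
    return result


def build_pileup(
    hits: Iterable[AlignmentHit],
    refset: ReferenceSet,
    weights: Optional[Iterable[int]] = None,
) -> pd.DataFrame:
    """Per-position base counts from assigned reads.

    Returns a DataFrame with columns precursor_id, position (1-based),
    ref_base, A, C, G, U, depth; positions with zero coverage are absent.
    """
    counts: dict[str, np.ndarray] = {}
    hits = list(hits)
    w = list(weights) if weights is not None else [1] * len(hits)
    for hit, weight in zip(hits, w):
        arr = counts.get(hit.precursor_id)
        if arr is None:
            arr = np.zeros((4, len(refset[hit.precursor_id].sequence)), dtype=np.int64)
            counts[hit.precursor_id] = arr
        codes = encode(hit.read_bases)
        positions = np.arange(hit.offset - 1, hit.offset - 1 + len(codes))
        np.add.at(arr, (codes, positions), weight)
    rows = []
    for pid in sorted(counts):
        arr = counts[pid]
        seq = refset[pid].sequence
        covered = np.flatnonzero(arr.sum(axis=0) > 0)
        for j in covered:
            a, c, g, u = (int(x) for x in arr[:, j])
            rows.append((pid, int(j) + 1, seq[j], a, c, g, u, a + c + g + u))
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


def mature_read_counts(
    hits: Iterable[AlignmentHit],
    refset: ReferenceSet,
    weights: Optional[Iterable[int]] = None,
) -> dict[tuple[str, str], int]:
    """Reads overlapping each mature interval: the expression count used for
    the >=10-read expression threshold. Keys are (precursor_id, mature_id)."""
    hits = list(hits)
    w = list(weights) if weights is not None else [1] * len(hits)
    out: dict[tuple[str, str], int] = {}
    for rec, m in refset.matures():
        out[(rec.precursor_id, m.mature_id)] = 0
    for hit, weight in zip(hits, w):
        for m in refset[hit.precursor_id].matures:
            if hit.offset <= m.end and hit.end >= m.start:
                out[(hit.precursor_id, m.mature_id)] += weight
    return out


def write_sam(
    hits: Iterable[AlignmentHit],
    refset: ReferenceSet,
    path: str | Path,
    weights: Optional[Iterable[int]] = None,
) -> None:
    """Minimal SAM output of assignments (1-based POS, NM tag)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": p.precursor_id, "LN": len(p.sequence)} for p in refset
        ],
    }
    tid = {p.precursor_id: i for i, p in enumerate(refset)}
    hits = list(hits)
    w = list(weights) if weights is not None else [1] * len(hits)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for hit, weight in zip(hits, w):
            a = pysam.AlignedSegment(out.header)
            a.query_name = hit.read_id
            a.query_sequence = hit.read_bases.replace("U", "T")
            a.reference_id = tid[hit.precursor_id]
            a.reference_start = hit.offset - 1
            a.mapping_quality = 255
            a.cigarstring = f"{hit.read_length}M"
            a.set_tag("NM", hit.n_mismatch)
            a.set_tag("XW", weight)
            out.write(a)
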
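"""Precursor reference handling.

The reference set ties together three small text inputs:

* a FASTA of pre-miRNA hairpin sequences (sense orientation, RNA alphabet;
  DNA input is transliterated T->U on load),
* a TSV of mature-arm coordinates (precursor_id, mature_id, arm, start, end;
  1-based inclusive, miRBase convention),
* an optional TSV of cluster memberships (precursor_id, cluster_id), e.g. the
  chr14 miR-379/miR-656 cluster (C14MC).

All downstream coordinates are 1-based positions on the sense precursor, so an
A-to-I event is always observed as reference A with G in the reads.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
SEED_START, SEED_END = 2, 8  # mature positions (1-based) of the seed region


class ReferenceError(ValueError):
    """Raised when a reference input violates an invariant."""


@dataclasses.dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA arm located on its precursor (1-based inclusive)."""

    mature_id: str
    arm: str  # "5p" or "3p"
    start: int
    end: int

    def __post_init__(self) -> None:
        length = self.end - self.start + 1
        if not 15 <= length <= 28:
            raise ReferenceError(
                f"mature {self.mature_id}: length {length} outside [15, 28]"
            )
        if self.arm not in ("5p", "3p"):
            raise ReferenceError(f"mature {self.mature_id}: arm must be 5p or 3p")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def seed_interval(self) -> tuple[int, int]:
        """Precursor positions of mature positions 2-8 (the seed)."""
        return self.start + SEED_START - 1, self.start + SEED_END - 1


@dataclasses.dataclass(frozen=True)
class PrecursorRecord:
    precursor_id: str
    sequence: str
    matures: tuple[MatureAnnotation, ...]
    chromosome: str = "."
    cluster_id: Optional[str] = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not 40 <= n <= 200:
            raise ReferenceError(
                f"precursor {self.precursor_id}: length {n} outside [40, 200]"
            )
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ReferenceError(
                f"precursor {self.precursor_id}: illegal characters {sorted(bad)}"
            )
        spans = []
        for m in self.matures:
            if m.start < 1 or m.end > n:
                raise ReferenceError(
                    f"precursor {self.precursor_id}: mature {m.mature_id} "
                    f"interval [{m.start}, {m.end}] outside [1, {n}]"
                )
            spans.append((m.start, m.end, m.mature_id))
        spans.sort()
        for (s1, e1, id1), (s2, e2, id2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ReferenceError(
                    f"precursor {self.precursor_id}: matures {id1} and {id2} overlap"
                )

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequence[position - 1]

    def mature_sequence(self, mature: MatureAnnotation) -> str:
        return self.sequence[mature.start - 1 : mature.end]


class ReferenceSet:
    """Validated collection of precursors, keyed by precursor id."""

    def __init__(self, precursors: Iterable[PrecursorRecord]):
        self.precursors: dict[str, PrecursorRecord] = {}
        for rec in precursors:
            if rec.precursor_id in self.precursors:
                raise ReferenceError(f"duplicate precursor id {rec.precursor_id}")
            self.precursors[rec.precursor_id] = rec
        self._index_cache = None  # lazy alignment index (see mapper)

    def __len__(self) -> int:
        return len(self.precursors)

    def __iter__(self):
        return iter(self.precursors.values())

    def __getitem__(self, precursor_id: str) -> PrecursorRecord:
        try:
            return self.precursors[precursor_id]
        except KeyError:
            raise ReferenceError(f"unknown precursor id {precursor_id}") from None

    def matures(self) -> Iterable[tuple[PrecursorRecord, MatureAnnotation]]:
        for rec in self:
            for m in rec.matures:
                yield rec, m

    def cluster_members(self, cluster_id: str) -> set[str]:
        return {p.precursor_id for p in self if p.cluster_id == cluster_id}


def _normalize_sequence(raw: str, name: str) -> str:
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ReferenceError(f"precursor {name}: illegal characters {sorted(bad)}")
    return seq


def load_reference(
    precursor_fasta: str | Path,
    mature_table: str | Path,
    cluster_table: str | Path | None = None,
) -> ReferenceSet:
    """Load precursors + mature coordinates (+ optional clusters) into a ReferenceSet.

    The mature table is a TSV with columns precursor_id, mature_id, arm, start,
    end; the cluster table has columns precursor_id, cluster_id.
    """
    sequences: dict[str, str] = {}
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(precursor_fasta), "fasta"):
        if rec.id in sequences:
            raise ReferenceError(f"duplicate precursor id {rec.id}")
        sequences[rec.id] = _normalize_sequence(str(rec.seq), rec.id)
        # optional "chrom=..." token in the description
        for token in rec.description.split():
            if token.startswith("chrom="):
                chroms[rec.id] = token.split("=", 1)[1]

    matures: dict[str, list[MatureAnnotation]] = {pid: [] for pid in sequences}
    mtab = pd.read_csv(mature_table, sep="\t", comment="#", dtype=str)
    required = {"precursor_id", "mature_id", "arm", "start", "end"}
    missing = required - set(mtab.columns)
    if missing:
        raise ReferenceError(f"mature table missing columns {sorted(missing)}")
    for row in mtab.itertuples(index=False):
        if row.precursor_id not in sequences:
            raise ReferenceError(
                f"mature {row.mature_id} names unknown precursor {row.precursor_id}"
            )
        matures[row.precursor_id].append(
            MatureAnnotation(row.mature_id, row.arm, int(row.start), int(row.end))
        )

    clusters: dict[str, str] = {}
    if cluster_table is not None:
        ctab = pd.read_csv(cluster_table, sep="\t", comment="#", dtype=str)
        clusters = dict(zip(ctab["precursor_id"], ctab["cluster_id"]))

    records = [
        PrecursorRecord(
            precursor_id=pid,
            sequence=seq,
            matures=tuple(sorted(matures[pid], key=lambda m: m.start)),
            chromosome=chroms.get(pid, "."),
            cluster_id=clusters.get(pid),
        )
        for pid, seq in sequences.items()
    ]
    return ReferenceSet(records)


def write_reference(
    refset: ReferenceSet,
    precursor_fasta: str | Path,
    mature_table: str | Path,
    cluster_table: str | Path | None = None,
) -> None:
    """Inverse of :func:`load_reference` (round-trip safe)."""
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=p.precursor_id,
            description=f"chrom={p.chromosome}" if p.chromosome != "." else "",
        )
        for p in refset
    ]
    SeqIO.write(records, str(precursor_fasta), "fasta")
    rows = [
        {
            "precursor_id": p.precursor_id,
            "mature_id": m.mature_id,
            "arm": m.arm,
            "start": m.start,
            "end": m.end,
        }
        for p, m in refset.matures()
    ]
    pd.DataFrame(rows).to_csv(mature_table, sep="\t", index=False)
    if cluster_table is not None:
        crows = [
            {"precursor_id": p.precursor_id, "cluster_id": p.cluster_id}
            for p in refset
            if p.cluster_id is not None
        ]
        pd.DataFrame(crows, columns=["precursor_id", "cluster_id"]).to_csv(
            cluster_table, sep="\t", index=False
        )


def to_mature_position(
    precursor_id: str, precursor_pos: int, refset: ReferenceSet
) -> Optional[tuple[str, int]]:
    """Map a precursor position into the mature arm containing it.

    Returns ``(mature_id, mature_pos)`` with mature_pos 1-based from the mature
    5' end, or None for positions in the loop / outside every arm.
    """
    rec = refset[precursor_id]
    if not 1 <= precursor_pos <= len(rec.sequence):
        raise ReferenceError(
            f"position {precursor_pos} outside precursor {precursor_id}"
        )
    for m in rec.matures:
        if m.start <= precursor_pos <= m.end:
            return m.mature_id, precursor_pos - m.start + 1
    return None


# ---------------------------------------------------------------------------
# Known DNA-level variants (dbSNP-style and matched exome VCFs)
# ---------------------------------------------------------------------------


class VariantTable:
    """Union of DNA-level variants keyed by (chrom, pos, ref, alt).

    ``chrom`` is a precursor id for precursor-space VCFs (the simulator's
    output); genome-space VCFs can be lifted with
    :func:`variants_to_precursor_coords`.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, int, str, str], set[str]] = {}

    def add(self, chrom: str, pos: int, ref: str, alt: str, source: str) -> None:
        if ref == alt:
            raise ReferenceError(f"variant {chrom}:{pos} has ref == alt ({ref})")
        if pos < 1:
            raise ReferenceError(f"variant {chrom}:{pos} has non-positive position")
        self._entries.setdefault((chrom, pos, ref.upper(), alt.upper()), set()).add(
            source
        )

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        chrom, pos, ref, alt = key
        return (chrom, pos, ref.upper(), alt.upper()) in self._entries

    def sources(self, chrom: str, pos: int, ref: str, alt: str) -> set[str]:
        return self._entries.get((chrom, pos, ref.upper(), alt.upper()), set())

    def items(self):
        return self._entries.items()


def load_variants(
    vcf_paths: Iterable[str | Path],
    sources: Optional[Iterable[str]] = None,
) -> VariantTable:
    """Read one or more VCF 4.x files into a single variant table.

    Multi-allelic records are split into one entry per ALT. Source labels
    default to the file stem (e.g. ``dbsnp``, ``exome``).
    """
    import pysam

    table = VariantTable()
    paths = [Path(p) for p in vcf_paths]
    labels = list(sources) if sources is not None else [p.stem for p in paths]
    if len(labels) != len(paths):
        raise ReferenceError("one source label required per VCF path")
    for path, label in zip(paths, labels):
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    table.add(rec.chrom, rec.pos, rec.ref, alt, label)
    return table


def variants_to_precursor_coords(
    table: VariantTable, locations: Mapping[str, tuple[str, int, str]]
) -> VariantTable:
    """Lift genome-space variants onto precursor coordinates.

    ``locations`` maps precursor_id -> (chromosome, genomic start of precursor
    position 1, strand "+"/"-"). Alleles are complemented on the minus strand
    so they read off the sense precursor. DNA alleles are transliterated to RNA.
    """
    comp = str.maketrans("ACGTU", "TGCAA")
    lifted = VariantTable()
    for (chrom, gpos, ref, alt), srcs in table.items():
        for pid, (pchrom, gstart, strand) in locations.items():
            if pchrom != chrom:
                continue
            if strand == "+":
                ppos = gpos - gstart + 1
                pref, palt = ref, alt
            else:
                ppos = gstart - gpos + 1
                pref = ref.translate(comp)[::-1]
                palt = alt.translate(comp)[::-1]
            ref_rna = pref.replace("T", "U")
            alt_rna = palt.replace("T", "U")
            if ppos >= 1:
                for src in srcs:
                    lifted.add(pid, ppos, ref_rna, alt_rna, src)
    return lifted
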
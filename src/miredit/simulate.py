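"""Synthetic small RNA-seq cohorts with planted editing truth.

The generator emulates the statistical structure the caller assumes:

* per-miRNA read depth drawn log-uniformly over [10, 10^4] (the dynamic range
  of expressed miRNAs in small RNA-seq),
* per-site editing fractions planted per sample group, spanning the sub-1% to
  ~31% range observed for real A-to-I events,
* uniform per-base sequencing error (default 0.1%),
* reads that are full-length mature sequences carrying a 3' sequencing
  adapter, truncated to the 50-base instrument read length,
* homozygous germline SNPs (every read carries the alternate allele) written
  to a matched VCF for the DNA-level filter,
* a group-level hypoediting factor multiplying tumor-group fractions.

Everything is deterministic given (seed, sample_id).
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .mapper import PILEUP_COLUMNS
from .preprocess import TRUSEQ_SMALL_RNA_ADAPTER
from .refset import MatureAnnotation, PrecursorRecord, ReferenceSet

READ_LENGTH = 50  # instrument read length; insert + adapter is truncated to this
_BASES = "ACGU"


@dataclasses.dataclass(frozen=True)
class PlantedSite:
    precursor_id: str
    position: int              # 1-based on the precursor
    edit_type: str             # "A>G" or "C>U"
    fractions: dict            # group label -> editing fraction in [0, 1]

    @property
    def ref_base(self) -> str:
        return self.edit_type[0]

    @property
    def alt_base(self) -> str:
        return self.edit_type[-1]


@dataclasses.dataclass(frozen=True)
class PlantedSNP:
    precursor_id: str
    position: int
    ref: str
    alt: str
    genotype: str = "hom"      # homozygous: all reads carry the alternate


@dataclasses.dataclass
class SimConfig:
    seed: int
    samples: list              # (sample_id, group) pairs
    depth_range: tuple = (10, 10_000)   # log-uniform expected read count per mature
    error_rate: float = 0.001
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    planted_sites: list = dataclasses.field(default_factory=list)
    planted_snps: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        for site in self.planted_sites:
            for group, f in site.fractions.items():
                if not 0 <= f <= 1:
                    raise ValueError(
                        f"fraction {f} for {site.precursor_id}:{site.position} "
                        f"({group}) outside [0, 1]"
                    )
        ids = [s for s, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")

    def group_of(self, sample_id: str) -> str:
        for sid, group in self.samples:
            if sid == sample_id:
                return group
        raise KeyError(sample_id)


@dataclasses.dataclass
class TruthSite:
    sample_id: str
    precursor_id: str
    position: int
    mature_id: str
    true_fraction: float
    depth: int
    k_edited: int

    @property
    def below_detection(self) -> bool:
        return self.true_fraction == 0.0


@dataclasses.dataclass
class SimTruth:
    """Planted truth: the acceptance oracle for every downstream stage."""

    depths: dict = dataclasses.field(default_factory=dict)  # (sample, precursor, mature) -> reads
    sites: list = dataclasses.field(default_factory=list)   # TruthSite records
    snps: list = dataclasses.field(default_factory=list)    # PlantedSNP records

    def merge(self, other: "SimTruth") -> None:
        self.depths.update(other.depths)
        self.sites.extend(other.sites)
        for snp in other.snps:
            if snp not in self.snps:
                self.snps.append(snp)

    def total_reads(self, sample_id: str) -> int:
        return sum(
            d for (sid, _, _), d in self.depths.items() if sid == sample_id
        )

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": t.sample_id,
                    "precursor": t.precursor_id,
                    "position": t.position,
                    "mature": t.mature_id,
                    "true_fraction": t.true_fraction,
                    "depth": t.depth,
                    "k_edited": t.k_edited,
                    "below_detection": t.below_detection,
                }
                for t in self.sites
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.sites_frame().to_csv(path, sep="\t", index=False)


def _sample_rng(config: SimConfig, sample_id: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed % (2**31), zlib.crc32(sample_id.encode()) % (2**31)]
    )


def _validate_planting(refset: ReferenceSet, config: SimConfig) -> None:
    for site in config.planted_sites:
        rec = refset[site.precursor_id]
        if rec.base(site.position) != site.ref_base:
            raise ValueError(
                f"planted site {site.precursor_id}:{site.position} ref "
                f"{site.ref_base} does not match reference {rec.base(site.position)}"
            )
        if not any(m.start <= site.position <= m.end for m in rec.matures):
            raise ValueError(
                f"planted site {site.precursor_id}:{site.position} lies outside "
                "every mature arm (edited reads would be unobservable)"
            )
    for snp in config.planted_snps:
        rec = refset[snp.precursor_id]
        if rec.base(snp.position) != snp.ref:
            raise ValueError(
                f"planted SNP {snp.precursor_id}:{snp.position} ref {snp.ref} "
                f"does not match reference {rec.base(snp.position)}"
            )


def simulate_sample(
    refset: ReferenceSet,
    config: SimConfig,
    sample_id: str,
    out_dir: str | Path,
) -> tuple[Path, SimTruth]:
    """Write one sample's FASTQ; return its path and the per-sample truth."""
    _validate_planting(refset, config)
    rng = _sample_rng(config, sample_id)
    group = config.group_of(sample_id)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fastq = out_dir / f"{sample_id}.fastq"
    truth = SimTruth(snps=list(config.planted_snps))

    lo, hi = config.depth_range
    with open(fastq, "w") as fh:
        for rec, mature in refset.matures():
            depth = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            truth.depths[(sample_id, rec.precursor_id, mature.mature_id)] = depth
            base_seq = list(rec.mature_sequence(mature))
            # homozygous SNPs: substituted deterministically in every read
            for snp in config.planted_snps:
                if (
                    snp.precursor_id == rec.precursor_id
                    and mature.start <= snp.position <= mature.end
                ):
                    base_seq[snp.position - mature.start] = snp.alt
            base_seq = "".join(base_seq)
            length = len(base_seq)

            # per-read modifications: planted edits, then sequencing errors
            mods: dict[int, dict[int, str]] = {}
            for site in config.planted_sites:
                if site.precursor_id != rec.precursor_id:
                    continue
                if not mature.start <= site.position <= mature.end:
                    continue
                fraction = site.fractions.get(group, 0.0)
                offset = site.position - mature.start
                edited = np.flatnonzero(rng.random(depth) < fraction)
                for i in edited:
                    mods.setdefault(int(i), {})[offset] = site.alt_base
                truth.sites.append(
                    TruthSite(
                        sample_id=sample_id,
                        precursor_id=rec.precursor_id,
                        position=site.position,
                        mature_id=mature.mature_id,
                        true_fraction=fraction,
                        depth=depth,
                        k_edited=len(edited),
                    )
                )
            if config.error_rate > 0:
                n_err = rng.binomial(depth * length, config.error_rate)
                if n_err:
                    flat = rng.choice(depth * length, size=n_err, replace=False)
                    for idx in flat:
                        i, offset = int(idx) // length, int(idx) % length
                        current = mods.get(i, {}).get(offset, base_seq[offset])
                        alternatives = [b for b in _BASES if b != current]
                        mods.setdefault(i, {})[offset] = alternatives[
                            rng.integers(3)
                        ]

            for i in range(depth):
                if i in mods:
                    seq = list(base_seq)
                    for offset, base in mods[i].items():
                        seq[offset] = base
                    seq = "".join(seq)
                else:
                    seq = base_seq
                insert = (seq + config.adapter)[:READ_LENGTH]
                fh.write(
                    f"@{sample_id}:{mature.mature_id}:{i}\n{insert}\n+\n"
                    f"{'I' * len(insert)}\n"
                )
    return fastq, truth


def write_snp_vcf(
    snps: Sequence[PlantedSNP], refset: ReferenceSet, path: str | Path,
    source: str = "exome",
) -> Path:
    """Write planted SNPs as a precursor-space VCF 4.2 via pysam."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##source=miredit-simulate-{source}")
    for rec in refset:
        header.contigs.add(rec.precursor_id, length=len(rec.sequence))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for snp in sorted(snps, key=lambda s: (s.precursor_id, s.position)):
            vrec = out.new_record(
                contig=snp.precursor_id,
                start=snp.position - 1,
                stop=snp.position,
                alleles=(snp.ref.replace("U", "T"), snp.alt.replace("U", "T")),
            )
            out.write(vrec)
    return Path(path)


def simulate_cohort(
    refset: ReferenceSet, config: SimConfig, out_dir: str | Path
) -> tuple[list[Path], SimTruth, Path]:
    """Simulate every sample in the config; also write the SNP VCF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = SimTruth()
    fastqs = []
    for sample_id, _ in config.samples:
        fastq, sample_truth = simulate_sample(refset, config, sample_id, out_dir)
        fastqs.append(fastq)
        truth.merge(sample_truth)
    vcf = write_snp_vcf(config.planted_snps, refset, out_dir / "planted_snps.vcf")
    return fastqs, truth, vcf


def apply_hypoediting(
    sites: Iterable[PlantedSite],
    control_fractions: dict,
    tumor_groups: Sequence[str],
    factor: float,
) -> list[PlantedSite]:
    """Derive per-group fractions from control fractions and a hypoediting factor.

    ``control_fractions`` maps group label -> 1.0-scale multiplier (usually 1.0
    for every control group); tumor groups get ``factor`` times the site's
    reference fraction.
    """
    out = []
    for site in sites:
        base = max(site.fractions.values())
        fractions = {g: base * m for g, m in control_fractions.items()}
        for g in tumor_groups:
            fractions[g] = base * factor
        out.append(
            PlantedSite(site.precursor_id, site.position, site.edit_type, fractions)
        )
    return out


# ---------------------------------------------------------------------------
# Random references and pileup-level simulation (caller calibration)
# ---------------------------------------------------------------------------


def random_reference(
    n_precursors: int,
    rng: np.random.Generator,
    precursor_len: int = 60,
    mature_start: int = 16,
    mature_len: int = 22,
) -> ReferenceSet:
    """Random-sequence reference with one 5p mature per precursor."""
    records = []
    for i in range(n_precursors):
        seq = "".join(rng.choice(list(_BASES), size=precursor_len))
        pid = f"sim-mir-{i:03d}"
        records.append(
            PrecursorRecord(
                precursor_id=pid,
                sequence=seq,
                matures=(
                    MatureAnnotation(
                        f"{pid}-5p", "5p", mature_start, mature_start + mature_len - 1
                    ),
                ),
            )
        )
    return ReferenceSet(records)


def simulate_pileups(
    refset: ReferenceSet,
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
    planted: Optional[dict] = None,
) -> tuple[pd.DataFrame, dict]:
    """Direct pileup-count simulation over every mature position.

    ``planted`` maps (precursor_id, position) -> (alt_base, fraction). The
    caller's operating characteristics (FWER, sensitivity, level bias) depend
    only on the count table, so this path supports large replicate counts
    without generating reads. Errors on edited reads are neglected
    (an O(error_rate * fraction) effect).
    """
    planted = planted or {}
    rows = []
    mature_counts = {}
    for rec, mature in refset.matures():
        mature_counts[(rec.precursor_id, mature.mature_id)] = depth
        positions = np.arange(mature.start, mature.end + 1)
        length = len(positions)
        err = rng.multinomial(depth, [error_rate / 3] * 3 + [1 - error_rate], size=length)
        for j, pos in enumerate(positions):
            ref = rec.base(int(pos))
            counts = dict.fromkeys(_BASES, 0)
            alts = [b for b in _BASES if b != ref]
            key = (rec.precursor_id, int(pos))
            k_edit = 0
            if key in planted:
                alt, fraction = planted[key]
                k_edit = int(rng.binomial(depth, fraction))
                counts[alt] += k_edit
                err_counts = rng.multinomial(
                    depth - k_edit, [error_rate / 3] * 3 + [1 - error_rate]
                )[:3]
            else:
                err_counts = err[j, :3]
            for a, b in zip(alts, err_counts):
                counts[a] += int(b)
            counts[ref] = depth - sum(counts.values())
            rows.append(
                (
                    rec.precursor_id,
                    int(pos),
                    ref,
                    counts["A"],
                    counts["C"],
                    counts["G"],
                    counts["U"],
                    depth,
                )
            )
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS), mature_counts


DEFAULT_COHORT_FRACTIONS = (
    0.30, 0.25, 0.21, 0.17, 0.14, 0.11, 0.09, 0.07, 0.06, 0.05,
)


def hypoediting_cohort(
    seed: int,
    n_control: int = 6,
    n_tumor: int = 5,
    n_precursors: int = 30,
    fractions: Sequence[float] = DEFAULT_COHORT_FRACTIONS,
    hypoediting_factor: float = 0.2,
    depth: int = 1000,
    n_snps: int = 2,
    error_rate: float = 0.001,
) -> tuple[ReferenceSet, "SimConfig"]:
    """Standard two-group study design: planted A>G sites in control samples
    with a constant hypoediting factor applied to the tumor group.

    Sites are planted at seed-region adenosines with control fractions
    spanning 5-30% (the consistently detectable range that a >=3-sample
    presence screen selects for); germline A>G SNPs are planted on separate,
    unedited precursors to exercise the DNA-level filter. Depth is fixed so
    that group comparisons measure the statistics, not coverage dropout.
    """
    rng = np.random.default_rng(seed % (2**31))
    refset = random_reference(n_precursors, rng)
    sites: list[PlantedSite] = []
    edited_precursors: set[str] = set()
    for rec in refset:
        if len(sites) >= len(fractions):
            break
        m = rec.matures[0]
        # adenosines at mature positions 2-8 (the seed)
        apos = [p for p in range(m.start + 1, m.start + 8) if rec.base(p) == "A"]
        if not apos:
            continue
        f = fractions[len(sites)]
        sites.append(
            PlantedSite(
                rec.precursor_id,
                int(rng.choice(apos)),
                "A>G",
                {"control": f, "tumor": f * hypoediting_factor},
            )
        )
        edited_precursors.add(rec.precursor_id)
    snps: list[PlantedSNP] = []
    for rec in reversed(list(refset)):
        if len(snps) >= n_snps:
            break
        if rec.precursor_id in edited_precursors:
            continue
        m = rec.matures[0]
        apos = [p for p in range(m.start, m.end + 1) if rec.base(p) == "A"]
        if apos:
            snps.append(PlantedSNP(rec.precursor_id, apos[0], "A", "G"))
    samples = [(f"control{i}", "control") for i in range(n_control)] + [
        (f"tumor{i}", "tumor") for i in range(n_tumor)
    ]
    config = SimConfig(
        seed=seed % (2**31),
        samples=samples,
        depth_range=(depth, depth),
        error_rate=error_rate,
        planted_sites=sites,
        planted_snps=snps,
    )
    return refset, config
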
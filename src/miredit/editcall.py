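"""Binomial error-model calling of miRNA editing sites.

Every non-reference base observed at a position inside an expressed mature
miRNA is tested against the sequencing-error null: with per-base error rate
epsilon spread uniformly over the three alternatives, the count k of a
specific alternative base among n covering reads is Binomial(n, epsilon/3)
under "no editing". The one-sided tail P(X >= k) is Bonferroni-corrected over
every covered (position x alternative base) hypothesis inside an expressed
mature, and sites with corrected p below alpha survive.

A mature miRNA counts as expressed when at least ``min_depth`` assigned reads
overlap its interval (default 10); only positions inside expressed matures are
tested, and the same denominator defines the sample-level percentage editing:

    percent editing(type) = 100 * edited matures(type) / expressed matures
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .refset import ReferenceSet, VariantTable

EDIT_TYPES = {("A", "G"): "A-to-I", ("C", "U"): "C-to-U"}


@dataclasses.dataclass
class CallerConfig:
    error_rate: float = 0.001  # per-base substitution probability
    alpha: float = 0.05        # family-wise level after Bonferroni
    min_depth: int = 10        # reads on a mature for it to count as expressed

    def __post_init__(self) -> None:
        if not 0 < self.error_rate < 0.05:
            raise ValueError("error_rate must be in (0, 0.05)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")

    @property
    def per_substitution_rate(self) -> float:
        """Error rate toward one specific alternative base (uniform spectrum)."""
        return self.error_rate / 3.0


@dataclasses.dataclass
class EditingSite:
    sample_id: str
    precursor_id: str
    position: int          # 1-based on the precursor
    mature_id: str
    mature_pos: int        # 1-based from the mature 5' end
    ref_base: str
    obs_base: str
    edit_type: str         # "A-to-I", "C-to-U" or "other"
    alt_count: int
    depth: int
    p_raw: float
    p_adj: float
    in_seed: bool = False
    seed_pos: Optional[int] = None   # 1-7, mature_pos - 1, when in seed
    dna_variant: bool = False
    variant_sources: tuple[str, ...] = ()

    @property
    def editing_level(self) -> float:
        """Percent of covering reads carrying the edited base."""
        return 100.0 * self.alt_count / self.depth


def binomial_tail(k: int | np.ndarray, n: int | np.ndarray, p: float) -> np.ndarray:
    """One-sided upper tail P(X >= k), X ~ Binomial(n, p)."""
    return sps.binom.sf(np.asarray(k) - 1, n, p)


def classify(ref: str, obs: str) -> str:
    return EDIT_TYPES.get((ref, obs), "other")


def call_sites(
    pileups: pd.DataFrame,
    refset: ReferenceSet,
    config: CallerConfig,
    mature_counts: Optional[Mapping[tuple[str, str], int]] = None,
    sample_id: str = "",
) -> list[EditingSite]:
    """Call editing sites from a pileup table for one sample.

    ``mature_counts`` maps (precursor_id, mature_id) to the number of assigned
    reads overlapping that mature (from :func:`miredit.mapper.mature_read_counts`).
    When absent, the maximum pileup depth inside the mature interval is used as
    a stand-in, which is exact for full-length mature reads.
    """
    if pileups.empty:
        return []

    expressed = _expressed_matures(pileups, refset, config, mature_counts)
    if not expressed:
        return []

    # restrict pileup rows to positions inside expressed matures
    keep_rows = []
    mature_of_row = []
    for row in pileups.itertuples(index=False):
        rec = refset[row.precursor_id]
        if rec.base(row.position) != row.ref_base:
            raise ValueError(
                f"pileup/reference mismatch at {row.precursor_id}:{row.position}"
            )
        for m in rec.matures:
            if (row.precursor_id, m.mature_id) in expressed and m.start <= row.position <= m.end:
                keep_rows.append(row)
                mature_of_row.append(m)
                break

    # Bonferroni family: every (covered position x alternative base) inside an
    # expressed mature, whether or not a mismatch was observed. Conditioning
    # the family on k >= 1 would shrink the correction by exactly the factor
    # that inflates the family-wise error above alpha.
    n_tests = 3 * len(keep_rows)
    tests = []  # (row, mature, obs_base, k, n); k = 0 rows can never be called
    for row, m in zip(keep_rows, mature_of_row):
        for obs in "ACGU":
            if obs == row.ref_base:
                continue
            k = getattr(row, obs)
            if k >= 1:
                tests.append((row, m, obs, k, row.depth))
    if not tests:
        return []

    ks = np.array([t[3] for t in tests])
    ns = np.array([t[4] for t in tests])
    p_raw = binomial_tail(ks, ns, config.per_substitution_rate)
    p_adj = np.minimum(1.0, p_raw * n_tests)

    sites = []
    for (row, m, obs, k, n), praw, padj in zip(tests, p_raw, p_adj):
        if padj >= config.alpha:
            continue
        mature_pos = row.position - m.start + 1
        in_seed = 2 <= mature_pos <= 8
        sites.append(
            EditingSite(
                sample_id=sample_id,
                precursor_id=row.precursor_id,
                position=row.position,
                mature_id=m.mature_id,
                mature_pos=mature_pos,
                ref_base=row.ref_base,
                obs_base=obs,
                edit_type=classify(row.ref_base, obs),
                alt_count=int(k),
                depth=int(n),
                p_raw=float(praw),
                p_adj=float(padj),
                in_seed=in_seed,
                seed_pos=mature_pos - 1 if in_seed else None,
            )
        )
    sites.sort(key=lambda s: (s.precursor_id, s.position, s.obs_base))
    return sites


def _expressed_matures(
    pileups: pd.DataFrame,
    refset: ReferenceSet,
    config: CallerConfig,
    mature_counts: Optional[Mapping[tuple[str, str], int]],
) -> set[tuple[str, str]]:
    if mature_counts is not None:
        return {key for key, n in mature_counts.items() if n >= config.min_depth}
    expressed = set()
    by_prec = {pid: grp for pid, grp in pileups.groupby("precursor_id")}
    for rec, m in refset.matures():
        grp = by_prec.get(rec.precursor_id)
        if grp is None:
            continue
        inside = grp[(grp["position"] >= m.start) & (grp["position"] <= m.end)]
        if not inside.empty and inside["depth"].max() >= config.min_depth:
            expressed.add((rec.precursor_id, m.mature_id))
    return expressed


def estimate_error_rate(pileups: pd.DataFrame, floor: float = 1e-5) -> float:
    """Self-calibrated per-base error rate from non-canonical mismatches.

    Canonical editing channels (A->G and C->U) are excluded; the remaining
    mismatch counts are divided by the number of error channels they represent
    (2 of 3 for A and C reference positions, 3 of 3 for G and U), giving an
    unbiased estimate of the full per-base rate without per-base qualities.
    """
    if pileups.empty:
        return floor
    counted = 0.0
    channel_weighted_depth = 0.0
    for row in pileups.itertuples(index=False):
        alts = {b: getattr(row, b) for b in "ACGU" if b != row.ref_base}
        if row.ref_base == "A":
            alts.pop("G", None)
            n_channels = 2
        elif row.ref_base == "C":
            alts.pop("U", None)
            n_channels = 2
        else:
            n_channels = 3
        counted += sum(alts.values())
        channel_weighted_depth += row.depth * n_channels / 3.0
    if channel_weighted_depth == 0:
        return floor
    return max(floor, counted / channel_weighted_depth)


def filter_dna_variants(
    sites: Iterable[EditingSite],
    variants: VariantTable,
    refset: ReferenceSet,
) -> tuple[list[EditingSite], list[EditingSite]]:
    """Split sites into (kept, removed-as-DNA-variant), allele-aware.

    A site is removed only when a variant entry matches its precursor,
    position, reference base AND observed base — a germline variant at the
    same position with a different alternate allele does not veto the site.
    """
    kept, removed = [], []
    for site in sites:
        sources = variants.sources(
            site.precursor_id, site.position, site.ref_base, site.obs_base
        )
        if sources:
            site = dataclasses.replace(
                site, dna_variant=True, variant_sources=tuple(sorted(sources))
            )
            removed.append(site)
        else:
            kept.append(site)
    return kept, removed


@dataclasses.dataclass
class SampleProfile:
    sample_id: str
    group: str
    expressed: int                      # matures with >= min_depth reads
    edited_by_type: dict[str, int]      # matures with >=1 surviving site, per type
    expressed_matures: set[tuple[str, str]] = dataclasses.field(default_factory=set)

    def percent_editing(self, edit_type: str) -> Optional[float]:
        """100 * edited / expressed; None when nothing is expressed."""
        if self.expressed == 0:
            return None
        return 100.0 * self.edited_by_type.get(edit_type, 0) / self.expressed


def summarize_sample(
    sites: Iterable[EditingSite],
    pileups: pd.DataFrame,
    refset: ReferenceSet,
    config: CallerConfig,
    mature_counts: Optional[Mapping[tuple[str, str], int]] = None,
    sample_id: str = "",
    group: str = "",
) -> SampleProfile:
    """Sample-level percentage-editing summary (miRNA-level numerator:
    a mature with several surviving sites still counts once)."""
    expressed = _expressed_matures(pileups, refset, config, mature_counts)
    edited: dict[str, set[tuple[str, str]]] = {}
    for site in sites:
        edited.setdefault(site.edit_type, set()).add(
            (site.precursor_id, site.mature_id)
        )
    return SampleProfile(
        sample_id=sample_id,
        group=group,
        expressed=len(expressed),
        edited_by_type={t: len(ms) for t, ms in edited.items()},
        expressed_matures=expressed,
    )


def sites_to_frame(sites: Iterable[EditingSite]) -> pd.DataFrame:
    rows = [
        {
            "sample": s.sample_id,
            "precursor": s.precursor_id,
            "position": s.position,
            "mature": s.mature_id,
            "mature_pos": s.mature_pos,
            "type": s.edit_type,
            "ref": s.ref_base,
            "obs": s.obs_base,
            "k": s.alt_count,
            "n": s.depth,
            "level_pct": round(s.editing_level, 4),
            "p_raw": s.p_raw,
            "p_adj": s.p_adj,
            "in_seed": s.in_seed,
            "seed_pos": s.seed_pos if s.seed_pos is not None else "",
            "dna_variant": s.dna_variant,
            "variant_sources": ",".join(s.variant_sources),
        }
        for s in sites
    ]
    return pd.DataFrame(rows)
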
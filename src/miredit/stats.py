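"""Cohort-level statistics over called editing sites.

Covers the enrichment, group-comparison and target-redirection analyses:

* two-proportion z test (pooled, Yates continuity correction by default) for
  seed-enrichment contrasts such as A-to-I vs C-to-U seed fractions,
* hypergeometric upper-tail enrichment of edited miRNAs inside a named
  cluster (e.g. C14MC) against the expressed miRnome,
* per-event presence/median summaries across samples mirroring a
  presence-in-samples / median-editing table,
* two-tailed Wilcoxon rank-sum differential editing (hypoediting screen),
  exact when both groups are small and tie-free,
* 7-mer seed matching against 3'UTR sets and the before/after-editing target
  overlap percentage.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .editcall import EditingSite, SampleProfile

EXACT_MAX_N = 8  # exact rank-sum enumeration when both groups are <= this and tie-free


# ---------------------------------------------------------------------------
# Proportion and enrichment tests
# ---------------------------------------------------------------------------


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> tuple[float, float]:
    """Pooled two-proportion z test, two-sided, Yates-corrected by default.

    Returns ``(z, p)``. The continuity correction subtracts
    (1/n1 + 1/n2)/2 from the absolute difference (clamped at zero), which is
    the classical correction matching a chi-square test with Yates correction.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    diff = p1 - p2
    if continuity:
        correction = 0.5 * (1 / n1 + 1 / n2)
        z = math.copysign(max(0.0, abs(diff) - correction), diff) / se
    else:
        z = diff / se
    p = 2 * sps.norm.sf(abs(z))
    return z, float(min(1.0, p))


def cluster_enrichment(
    edited_ids: set, cluster_ids: set, expressed_ids: set
) -> float:
    """Hypergeometric upper-tail p for edited miRNAs inside a cluster.

    Null: the |edited| edited miRNAs are a uniform draw from the |expressed|
    expressed miRNAs; observed = |edited inside cluster|.
    """
    if not cluster_ids:
        raise ValueError("cluster is empty")
    if not cluster_ids <= expressed_ids:
        raise ValueError("cluster must be a subset of the expressed set")
    edited = edited_ids & expressed_ids
    observed = len(edited & cluster_ids)
    m, n_edit, n_clu = len(expressed_ids), len(edited), len(cluster_ids)
    # P(X >= observed), X ~ Hypergeom(M=m, n=n_edit, N=n_clu)
    return float(sps.hypergeom.sf(observed - 1, m, n_edit, n_clu))


def group_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Routine two-sample two-tailed t test (unequal variance)."""
    t, p = sps.ttest_ind(list(a), list(b), equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Event summaries across samples
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class EventKey:
    mature_id: str
    mature_pos: int
    edit_type: str


@dataclasses.dataclass
class EventSummary:
    key: EventKey
    precursor_id: str
    position: int
    in_seed: bool
    presence: dict          # group -> samples where the site survived calling
    expressed: dict         # group -> samples where the mature was expressed
    medians: dict           # group -> median level % or None (too few expressed)
    levels: dict            # group -> list of levels over expressed samples
    below_detection: dict   # group -> True when presence == 0 in that group

    def presence_string(self, groups: Sequence[str]) -> str:
        return "/".join(str(self.presence.get(g, 0)) for g in groups)


@dataclasses.dataclass
class SampleCalls:
    """One sample's surviving sites plus its expressed-mature universe."""

    sample_id: str
    group: str
    sites: list
    expressed_matures: set  # (precursor_id, mature_id) pairs

    @classmethod
    def from_profile(
        cls, profile: SampleProfile, sites: Iterable[EditingSite]
    ) -> "SampleCalls":
        return cls(
            sample_id=profile.sample_id,
            group=profile.group,
            sites=list(sites),
            expressed_matures=set(profile.expressed_matures),
        )


def summarize_events(
    samples: Sequence[SampleCalls],
    groups: Sequence[str],
    min_samples_for_median: int = 3,
) -> list[EventSummary]:
    """Presence counts and per-group medians for every event seen anywhere.

    A sample contributes level 0 for an event whose mature it expresses but
    where no site survived (expressed-but-uncalled); samples not expressing
    the mature contribute nothing. The median is reported as None when fewer
    than ``min_samples_for_median`` samples in the group expressed the mature.
    """
    events: dict[EventKey, dict] = {}
    for sc in samples:
        for site in sc.sites:
            key = EventKey(site.mature_id, site.mature_pos, site.edit_type)
            info = events.setdefault(
                key,
                {
                    "precursor_id": site.precursor_id,
                    "position": site.position,
                    "in_seed": site.in_seed,
                },
            )
            info.setdefault("levels", {}).setdefault(sc.sample_id, site.editing_level)

    mature_of = {
        key: info["precursor_id"] for key, info in events.items()
    }
    summaries = []
    for key, info in sorted(
        events.items(), key=lambda kv: (kv[0].mature_id, kv[0].mature_pos, kv[0].edit_type)
    ):
        presence: dict[str, int] = {g: 0 for g in groups}
        expressed: dict[str, int] = {g: 0 for g in groups}
        levels: dict[str, list[float]] = {g: [] for g in groups}
        for sc in samples:
            if sc.group not in presence:
                continue
            mature_key = (mature_of[key], key.mature_id)
            if mature_key not in sc.expressed_matures:
                continue
            expressed[sc.group] += 1
            level = info["levels"].get(sc.sample_id)
            if level is not None:
                presence[sc.group] += 1
                levels[sc.group].append(level)
            else:
                levels[sc.group].append(0.0)
        medians = {
            g: (float(np.median(levels[g])) if expressed[g] >= min_samples_for_median else None)
            for g in groups
        }
        summaries.append(
            EventSummary(
                key=key,
                precursor_id=info["precursor_id"],
                position=info["position"],
                in_seed=info["in_seed"],
                presence=presence,
                expressed=expressed,
                medians=medians,
                levels=levels,
                below_detection={g: presence[g] == 0 for g in groups},
            )
        )
    return summaries


def select_consistent_events(
    summaries: Iterable[EventSummary],
    min_presence: int = 3,
    groups: Sequence[str] = (),
) -> list[EventSummary]:
    """Events called in at least ``min_presence`` samples of EACH named group."""
    return [
        s
        for s in summaries
        if all(s.presence.get(g, 0) >= min_presence for g in groups)
    ]


# ---------------------------------------------------------------------------
# Differential editing (hypoediting screen)
# ---------------------------------------------------------------------------


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed two-sample Wilcoxon rank-sum p-value.

    When both groups have <= 8 values the exact permutation null of the
    rank-sum statistic is enumerated over all group assignments (midranks make
    this correct under ties, where the classical tie-free tables are not);
    larger designs use the normal approximation with tie and continuity
    corrections. For tie-free small samples the enumeration reproduces the
    classical exact two-sided p.
    """
    x, y = list(x), list(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    n1, n2 = len(x), len(y)
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        import itertools

        ranks = sps.rankdata(x + y)
        mu = n1 * n2 / 2.0
        offset = n1 * (n1 + 1) / 2.0
        obs = float(ranks[:n1].sum()) - offset
        extreme = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = sum(ranks[i] for i in idx) - offset
            total += 1
            if abs(u - mu) >= abs(obs - mu) - 1e-9:
                extreme += 1
        return extreme / total
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


@dataclasses.dataclass
class DifferentialEditingRecord:
    key: EventKey
    levels_by_group: dict
    p_value: Optional[float]
    direction: Optional[str]   # "hypo" / "hyper" in the test group
    significant: bool
    untestable: bool = False
    reason: str = ""


def differential_editing(
    summary: EventSummary,
    test_group: str,
    control_groups: Sequence[str],
    alpha: float = 0.05,
) -> DifferentialEditingRecord:
    """Wilcoxon screen of one event: pooled controls vs the test group.

    Levels come from expressed samples (expressed-but-uncalled = 0). Events
    with fewer than 2 expressed samples in either side are flagged untestable,
    never silently dropped.
    """
    control = [lv for g in control_groups for lv in summary.levels.get(g, [])]
    test = list(summary.levels.get(test_group, []))
    key = summary.key
    levels = {g: summary.levels.get(g, []) for g in (*control_groups, test_group)}
    if len(control) < 2 or len(test) < 2:
        return DifferentialEditingRecord(
            key, levels, None, None, False, untestable=True,
            reason="fewer than 2 expressed samples in a group",
        )
    p = rank_sum_test(control, test)
    med_c, med_t = float(np.median(control)), float(np.median(test))
    if med_t < med_c:
        direction = "hypo"
    elif med_t > med_c:
        direction = "hyper"
    else:
        direction = None
    return DifferentialEditingRecord(
        key, levels, p, direction, significant=p < alpha
    )


def differential_screen(
    summaries: Iterable[EventSummary],
    test_group: str,
    control_groups: Sequence[str],
    alpha: float = 0.05,
    min_presence: int = 3,
) -> list[DifferentialEditingRecord]:
    """Select consistently edited control events, then test each against the
    test group."""
    selected = select_consistent_events(
        summaries, min_presence=min_presence, groups=control_groups
    )
    return [
        differential_editing(s, test_group, control_groups, alpha) for s in selected
    ]


# ---------------------------------------------------------------------------
# Seed target scanning and overlap
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGU", "TGCA")


def seed_match_7mer(mature_seq: str, edit: Optional[tuple[int, str]] = None) -> str:
    """DNA 7-mer a 3'UTR must contain to match this miRNA's seed.

    The seed is mature positions 2-8 (optionally with the edited base
    substituted at ``edit = (mature_pos, alt_base)``); the UTR site is its
    reverse complement in DNA alphabet.
    """
    seq = mature_seq.upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError("mature sequence shorter than 8 nt")
    if edit is not None:
        pos, alt = edit
        if not 1 <= pos <= len(seq):
            raise ValueError("edit position outside mature")
        seq = seq[: pos - 1] + alt + seq[pos:]
    seed = seq[1:8]
    return seed.translate(_RC)[::-1]


def seed_targets(
    mature_seq: str,
    utrs: str | Path | Mapping[str, str],
    edit: Optional[tuple[int, str]] = None,
) -> set[str]:
    """IDs of 3'UTRs containing at least one exact seed-match 7-mer."""
    if isinstance(utrs, (str, Path)):
        from Bio import SeqIO

        utr_map = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(utrs), "fasta")
        }
    else:
        utr_map = {k: v.upper() for k, v in utrs.items()}
    site = seed_match_7mer(mature_seq, edit)
    return {
        utr_id
        for utr_id, seq in utr_map.items()
        if site in seq.replace("U", "T")
    }


def target_overlap(before: set, after: set) -> Optional[float]:
    """100 * |before & after| / |before|, to 2 decimals; None when |before|=0."""
    if not before:
        return None
    return round(100.0 * len(before & after) / len(before), 2)


def overlap_percent(n_before: int, n_overlap: int) -> Optional[float]:
    """Overlap percentage from counts (same definition as target_overlap)."""
    if n_before < 1:
        return None
    return round(100.0 * n_overlap / n_before, 2)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def events_to_frame(
    summaries: Sequence[EventSummary], groups: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "mature": s.key.mature_id,
            "mature_pos": s.key.mature_pos,
            "type": s.key.edit_type,
            "precursor": s.precursor_id,
            "position": s.position,
            "in_seed": s.in_seed,
        }
        for g in groups:
            row[f"presence_{g}"] = s.presence.get(g, 0)
            row[f"expressed_{g}"] = s.expressed.get(g, 0)
            med = s.medians.get(g)
            row[f"median_{g}"] = round(med, 2) if med is not None else "-"
        rows.append(row)
    return pd.DataFrame(rows)


def differential_to_frame(
    records: Sequence[DifferentialEditingRecord],
) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "mature": r.key.mature_id,
                "mature_pos": r.key.mature_pos,
                "type": r.key.edit_type,
                "p_value": r.p_value if r.p_value is not None else "",
                "direction": r.direction or "",
                "significant": r.significant,
                "untestable": r.untestable,
            }
        )
    return pd.DataFrame(rows)
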
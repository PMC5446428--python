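import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import rankdata

from miredit.stats import (
    EventKey,
    SampleCalls,
    cluster_enrichment,
    differential_editing,
    differential_screen,
    rank_sum_test,
    seed_match_7mer,
    seed_targets,
    select_consistent_events,
    summarize_events,
    target_overlap,
    two_proportion_test,
)


# ---------------------------------------------------------------------------
# two-proportion test
# ---------------------------------------------------------------------------


def test_two_proportion_seed_enrichment_contrast():
    """44/60 vs 10/56 (A-to-I vs C-to-U seed fractions) gives p ~ 6.66e-9
    with the continuity-corrected pooled z test."""
    z, p = two_proportion_test(44, 60, 10, 56)
    assert 6.5e-9 <= p <= 6.8e-9
    assert z > 0


def test_two_proportion_symmetry_and_edges():
    z1, p1 = two_proportion_test(44, 60, 10, 56)
    z2, p2 = two_proportion_test(10, 56, 44, 60)
    assert p1 == pytest.approx(p2)
    assert z1 == pytest.approx(-z2)
    # identical proportions: corrected z clamps to 0, p = 1
    assert two_proportion_test(10, 20, 10, 20) == (0.0, 1.0)
    z, p = two_proportion_test(50, 50, 0, 50)
    assert z > 0 and p < 1e-20
    with pytest.raises(ValueError):
        two_proportion_test(1, 0, 1, 2)


# ---------------------------------------------------------------------------
# cluster enrichment
# ---------------------------------------------------------------------------


def hypergeom_tail(observed, m, n_edit, n_clu):
    total = comb(m, n_edit)
    return float(
        sum(
            Fraction(comb(n_clu, x) * comb(m - n_clu, n_edit - x), total)
            for x in range(observed, min(n_clu, n_edit) + 1)
        )
    )


def test_cluster_enrichment_vs_enumeration():
    expressed = {f"m{i}" for i in range(40)}
    cluster = {f"m{i}" for i in range(8)}
    edited = {f"m{i}" for i in range(6)}  # all edited fall in the cluster
    p = cluster_enrichment(edited, cluster, expressed)
    assert p == pytest.approx(hypergeom_tail(6, 40, 6, 8), rel=1e-9)
    assert p < 1e-5


def test_cluster_enrichment_null_and_edges():
    expressed = {f"m{i}" for i in range(100)}
    cluster = {f"m{i}" for i in range(20)}
    # edited fraction identical inside and outside the cluster
    edited = {f"m{i}" for i in range(0, 100, 5)}
    assert cluster_enrichment(edited, cluster, expressed) >= 0.5
    # no edited miRNA inside the cluster: observed 0 => upper tail is 1
    outside = {f"m{i}" for i in range(50, 60)}
    assert cluster_enrichment(outside, cluster, expressed) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cluster_enrichment(edited, set(), expressed)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------


def enum_rank_sum_p(x, y):
    """Full enumeration oracle: two-sided p from the permutation distribution
    of the rank-sum statistic."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = rankdata(pooled)
    mu = n1 * len(y) / 2

    def ustat(idx):
        return sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2

    obs = ustat(range(n1))
    num = den = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        den += 1
        if abs(ustat(idx) - mu) >= abs(obs - mu) - 1e-9:
            num += 1
    return num / den


def test_rank_sum_complete_separation_exact():
    assert rank_sum_test([3, 4, 5, 6], [0, 0, 0, 0]) == pytest.approx(2 / 70)


def test_rank_sum_identical_groups():
    assert rank_sum_test([5, 5, 5], [5, 5, 5]) == pytest.approx(1.0)


def test_rank_sum_exact_agrees_with_enumeration(rng):
    """Exact branch equals both the hand-rolled enumeration and scipy's
    independent exact implementation for tie-free group sizes <= 6."""
    from scipy.stats import mannwhitneyu

    for trial in range(40):
        n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        vals = rng.permutation(50)[: n1 + n2].tolist()
        x, y = vals[:n1], vals[n1:]
        p = rank_sum_test(x, y)
        assert p == pytest.approx(enum_rank_sum_p(x, y), abs=1e-12)
        scipy_p = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(float(scipy_p), abs=1e-12)


def test_rank_sum_requires_two_per_group():
    with pytest.raises(ValueError):
        rank_sum_test([1], [2, 3])


# ---------------------------------------------------------------------------
# event summaries and the differential screen
# ---------------------------------------------------------------------------


def _sample(sample_id, group, level, expressed=True, mature="mirX-5p"):
    from miredit.editcall import EditingSite

    sites = []
    if level is not None:
        k = int(round(level * 10))  # depth 1000
        sites = [
            EditingSite(
                sample_id=sample_id, precursor_id="mirX", position=20,
                mature_id=mature, mature_pos=5, ref_base="A", obs_base="G",
                edit_type="A-to-I", alt_count=k, depth=1000,
                p_raw=1e-12, p_adj=1e-9, in_seed=True, seed_pos=4,
            )
        ]
    return SampleCalls(
        sample_id=sample_id,
        group=group,
        sites=sites,
        expressed_matures={("mirX", mature)} if expressed else set(),
    )


def test_summarize_events_presence_and_median():
    levels = [25, 27, 28, 28, 30, 31]
    samples = [_sample(f"fc{i}", "FC", lv) for i, lv in enumerate(levels)]
    summaries = summarize_events(samples, ["FC"])
    assert len(summaries) == 1
    s = summaries[0]
    assert s.presence["FC"] == 6
    assert s.medians["FC"] == pytest.approx(28.0)
    assert not s.below_detection["FC"]


def test_summarize_events_expressed_but_uncalled_contributes_zero():
    samples = [
        _sample("a", "FC", 10.0),
        _sample("b", "FC", None),          # expressed, no call -> level 0
        _sample("c", "FC", 20.0),
    ]
    s = summarize_events(samples, ["FC"])[0]
    assert s.presence["FC"] == 2
    assert s.expressed["FC"] == 3
    assert s.medians["FC"] == pytest.approx(10.0)


def test_summarize_events_median_policy_and_below_detection():
    samples = [
        _sample("a", "FC", 10.0),
        _sample("b", "FC", None, expressed=False),
        _sample("g0", "GBM", None),
        _sample("g1", "GBM", None),
        _sample("g2", "GBM", None),
    ]
    s = summarize_events(samples, ["FC", "GBM"], min_samples_for_median=2)[0]
    assert s.medians["FC"] is None      # only 1 expressed FC sample
    assert s.presence["GBM"] == 0
    assert s.below_detection["GBM"]
    assert s.medians["GBM"] == pytest.approx(0.0)


def test_select_consistent_events_threshold():
    samples = (
        [_sample(f"fc{i}", "FC", 10.0) for i in range(3)]
        + [_sample(f"cc{i}", "CC", 10.0) for i in range(2)]
        + [_sample("cc9", "CC", None)]
    )
    summaries = summarize_events(samples, ["FC", "CC"])
    assert select_consistent_events(summaries, 3, ["FC", "CC"]) == []
    assert len(select_consistent_events(summaries, 2, ["FC", "CC"])) == 1
    assert select_consistent_events([], 3, ["FC"]) == []
    assert len(select_consistent_events(summaries, 1, ["FC", "CC"])) == 1


def test_differential_editing_directions_and_untestable():
    samples = (
        [_sample(f"fc{i}", "FC", lv) for i, lv in enumerate([3, 4, 5, 6])]
        + [_sample(f"g{i}", "GBM", None) for i in range(4)]
    )
    s = summarize_events(samples, ["FC", "GBM"])[0]
    record = differential_editing(s, "GBM", ["FC"])
    assert record.p_value == pytest.approx(2 / 70)
    assert record.direction == "hypo"
    assert record.significant

    lonely = summarize_events(
        [_sample("fc0", "FC", 5.0), _sample("g0", "GBM", 1.0)], ["FC", "GBM"]
    )[0]
    rec2 = differential_editing(lonely, "GBM", ["FC"])
    assert rec2.untestable and rec2.p_value is None


def test_differential_power_hypoediting(rng):
    """6 controls at 28% vs 5 tumor samples at 5.6% (factor 0.2), levels from
    binomial sampling at depth 1000: significant hypoediting in >= 90% of 100
    replicates."""
    hits = 0
    for _ in range(100):
        control = 100 * rng.binomial(1000, 0.28, size=6) / 1000
        tumor = 100 * rng.binomial(1000, 0.056, size=5) / 1000
        p = rank_sum_test(control.tolist(), tumor.tolist())
        if p < 0.05 and np.median(tumor) < np.median(control):
            hits += 1
    assert hits >= 90


# ---------------------------------------------------------------------------
# seed targets
# ---------------------------------------------------------------------------


def brute_scan(site, utrs):
    return {k for k, v in utrs.items() if site in v}


def test_seed_match_7mer_and_edit():
    mature = "UAGUAGACCGUAUAGCGUACG"
    site = seed_match_7mer(mature)
    # seed AGUAGAC -> UTR site reverse complement in DNA
    assert site == "GTCTACT"
    edited = seed_match_7mer(mature, edit=(5, "G"))
    assert edited == "GTCCACT"
    assert site != edited
    with pytest.raises(ValueError):
        seed_match_7mer("ACGUACG")


def test_seed_targets_membership(rng, tmp_path):
    mature = "UAGUAGACCGUAUAGCGUACG"
    site = seed_match_7mer(mature)
    utrs = {
        "hit": "AAAA" + site + "CCCC",
        "double_hit": site + "TT" + site,
        "miss": "A" * 30,
    }
    assert seed_targets(mature, utrs) == {"hit", "double_hit"}
    # brute-force substring scan oracle on random UTRs
    random_utrs = {
        f"u{i}": "".join(rng.choice(list("ACGT"), size=200)) for i in range(50)
    }
    assert seed_targets(mature, random_utrs) == brute_scan(site, random_utrs)
    # FASTA path behaves identically
    fasta = tmp_path / "utrs.fa"
    fasta.write_text("".join(f">{k}\n{v}\n" for k, v in utrs.items()))
    assert seed_targets(mature, fasta) == {"hit", "double_hit"}


def test_target_overlap_definition():
    before = {f"t{i}" for i in range(146)}
    after = {f"t{i}" for i in range(135, 135 + 197)}  # overlap of 11
    assert target_overlap(before, after) == 7.53
    assert target_overlap({"a"}, {"b"}) == 0.0
    assert target_overlap({"a", "b"}, {"a", "b"}) == 100.0
    assert target_overlap(set(), {"a"}) is None
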
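import dataclasses
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from miredit.editcall import (
    CallerConfig,
    EditingSite,
    binomial_tail,
    call_sites,
    estimate_error_rate,
    filter_dna_variants,
    summarize_sample,
)
from miredit.refset import VariantTable
from miredit.simulate import random_reference, simulate_pileups


def exact_tail(k, n, p):
    """Exact rational binomial upper tail, summed term by term."""
    pf = Fraction(p).limit_denominator(10**12)
    return float(sum(comb(n, j) * pf**j * (1 - pf) ** (n - j) for j in range(k, n + 1)))


@pytest.mark.parametrize(
    "k,n,p",
    [(5, 50, 0.001 / 3), (1, 10, 0.01), (3, 1000, 0.000333), (0, 40, 0.005)],
)
def test_binomial_tail_matches_enumeration(k, n, p):
    assert binomial_tail(k, n, p) == pytest.approx(exact_tail(k, n, p), rel=1e-9)


def test_tail_monotonicity():
    ks = np.arange(1, 20)
    tails = binomial_tail(ks, 100, 0.001)
    assert np.all(np.diff(tails) < 0)  # strictly decreasing in k
    eps = np.array([0.0005, 0.001, 0.002, 0.004])
    by_eps = [float(binomial_tail(3, 100, e / 3)) for e in eps]
    assert by_eps == sorted(by_eps)  # increasing in the error rate


def _single_site_refset_and_pileup(rng, depth, fraction, n_precursors=10):
    refset = random_reference(n_precursors, rng)
    rec = next(iter(refset))
    m = rec.matures[0]
    pos = next(p for p in range(m.start, m.end + 1) if rec.base(p) == "A")
    pile, counts = simulate_pileups(
        refset, depth, 0.001, rng, planted={(rec.precursor_id, pos): ("G", fraction)}
    )
    return refset, pile, counts, (rec.precursor_id, pos)


def test_zero_mismatch_never_called(rng):
    refset = random_reference(3, rng)
    pile, counts = simulate_pileups(refset, 1000, 0.0, rng)
    assert call_sites(pile, refset, CallerConfig(), counts) == []


def test_planted_site_called_with_level(rng):
    refset, pile, counts, key = _single_site_refset_and_pileup(rng, 1000, 0.10)
    sites = call_sites(pile, refset, CallerConfig(), counts, sample_id="s")
    match = [s for s in sites if (s.precursor_id, s.position) == key]
    assert len(match) == 1
    site = match[0]
    assert site.edit_type == "A-to-I"
    assert 7.0 <= site.editing_level <= 13.0
    assert site.p_adj < 0.05
    assert site.p_adj >= site.p_raw


def test_expression_threshold_gates_testing(rng):
    refset, pile, counts, key = _single_site_refset_and_pileup(rng, 1000, 0.10)
    starved = {k: 5 for k in counts}  # below min_depth: nothing is expressed
    assert call_sites(pile, refset, CallerConfig(), starved) == []


def test_fwer_on_error_only_simulation(rng):
    """Family-wise false-call rate stays at the Bonferroni level on pure-noise
    pileups (no planted edits): 200 matures, depth 100, 200 replicates."""
    refset = random_reference(200, rng)
    config = CallerConfig(error_rate=0.001)
    n_reps, false_reps = 200, 0
    for _ in range(n_reps):
        pile, counts = simulate_pileups(refset, 100, config.error_rate, rng)
        if call_sites(pile, refset, config, counts):
            false_reps += 1
    rate = false_reps / n_reps
    bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_reps)
    assert rate <= bound


def test_recovery_sensitivity_and_level_bias(rng):
    """Planted fractions {1,5,10,30}% at depth 150: fractions >= 5% recovered
    with sensitivity >= 0.9 and levels unbiased within 2 points (100 reps)."""
    fractions = [0.01, 0.05, 0.10, 0.30]
    refset = random_reference(12, rng)
    recs = list(refset)[:4]
    planted = {}
    for rec, f in zip(recs, fractions):
        m = rec.matures[0]
        pos = next(p for p in range(m.start, m.end + 1) if rec.base(p) == "A")
        planted[(rec.precursor_id, pos)] = ("G", f)
    frac_of = {key: f for key, (_, f) in planted.items()}
    called = {key: 0 for key in planted}
    levels = {key: [] for key in planted}
    n_reps = 100
    for _ in range(n_reps):
        pile, counts = simulate_pileups(refset, 150, 0.001, rng, planted=planted)
        sites = call_sites(pile, refset, CallerConfig(), counts)
        for s in sites:
            key = (s.precursor_id, s.position)
            if key in planted and s.obs_base == "G":
                called[key] += 1
                levels[key].append(s.editing_level)
    for key, f in frac_of.items():
        if f >= 0.05:
            assert called[key] / n_reps >= 0.9
            assert abs(np.mean(levels[key]) - 100 * f) <= 2.0


def _site(**kw):
    base = dict(
        sample_id="s", precursor_id="p", position=20, mature_id="m",
        mature_pos=5, ref_base="A", obs_base="G", edit_type="A-to-I",
        alt_count=10, depth=100, p_raw=1e-9, p_adj=1e-7,
    )
    base.update(kw)
    return EditingSite(**base)


def test_filter_dna_variants_allele_aware(toy_refset):
    variants = VariantTable()
    variants.add("p", 20, "A", "G", "exome")
    variants.add("p", 30, "A", "C", "dbsnp")
    sites = [
        _site(),                                # matches exome variant
        _site(position=30, obs_base="G"),       # same pos, different alt: kept
        _site(position=40),                     # no variant: kept
    ]
    kept, removed = filter_dna_variants(sites, variants, toy_refset)
    assert [s.position for s in removed] == [20]
    assert removed[0].variant_sources == ("exome",)
    assert [s.position for s in kept] == [30, 40]


def test_summarize_sample_mirna_level_numerator(rng):
    refset = random_reference(40, rng)
    pile, counts = simulate_pileups(refset, 50, 0.001, rng)
    recs = list(refset)[:3]
    sites = []
    for rec in recs:
        sites.append(_site(precursor_id=rec.precursor_id, mature_id=rec.matures[0].mature_id))
    # a second site on the same mature must not double-count
    sites.append(
        _site(
            precursor_id=recs[0].precursor_id,
            mature_id=recs[0].matures[0].mature_id,
            position=21,
        )
    )
    profile = summarize_sample(sites, pile, refset, CallerConfig(), counts)
    assert profile.expressed == 40
    assert profile.edited_by_type["A-to-I"] == 3
    assert profile.percent_editing("A-to-I") == pytest.approx(7.5)
    assert profile.percent_editing("C-to-U") == pytest.approx(0.0)


def test_summarize_sample_zero_expressed(rng):
    refset = random_reference(2, rng)
    pile, counts = simulate_pileups(refset, 5, 0.001, rng)  # below min_depth
    profile = summarize_sample([], pile, refset, CallerConfig(), counts)
    assert profile.expressed == 0
    assert profile.percent_editing("A-to-I") is None


def test_estimate_error_rate_recovers_truth(rng):
    refset = random_reference(100, rng)
    true_eps = 0.002
    pile, _ = simulate_pileups(refset, 500, true_eps, rng)
    est = estimate_error_rate(pile)
    assert 0.5 * true_eps < est < 1.5 * true_eps


def test_caller_config_validation():
    with pytest.raises(ValueError):
        CallerConfig(error_rate=0.2)
    with pytest.raises(ValueError):
        CallerConfig(alpha=0)
    with pytest.raises(ValueError):
        CallerConfig(min_depth=0)


def test_pileup_reference_mismatch_rejected(rng):
    refset, pile, counts, _ = _single_site_refset_and_pileup(rng, 100, 0.0)
    pile.loc[0, "ref_base"] = "C" if pile.loc[0, "ref_base"] != "C" else "G"
    with pytest.raises(ValueError, match="mismatch"):
        call_sites(pile, refset, CallerConfig(), counts)
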
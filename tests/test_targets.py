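"""Seed / walk predictors against brute-force scanning oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircnv.models import BindingSite, InteractionPair, MiRNA
from mircnv.targets import (collapse_families, intersect_predictions,
                            mirna_family, predict_all, predict_seed_sites,
                            predict_walk_sites, revcomp)

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

rna = st.text(alphabet="ACGU", min_size=7, max_size=200)
mirna_seq = st.text(alphabet="ACGU", min_size=18, max_size=25)


# ---------------------------------------------------------------- oracles

def brute_seed(seq: str, utr: str) -> list[tuple[int, str]]:
    """Position-by-position substring scan for canonical seed sites."""
    m8 = revcomp(seq[1:8])
    a1 = revcomp(seq[1:7]) + "A"
    eights = {o for o in range(len(utr)) if utr[o:o + 8] == m8 + "A"}
    sites = [(o, "8mer") for o in eights]
    sites += [(o, "7mer-m8") for o in range(len(utr))
              if utr[o:o + 7] == m8 and o not in eights]
    sites += [(o, "7mer-A1") for o in range(len(utr))
              if utr[o:o + 7] == a1 and o - 1 not in eights]
    return sorted(sites)


def brute_walk(seq: str, utr: str, min_len: int = 7) -> list[tuple[int, int]]:
    """Character-wise antiparallel pairing scan for 5'-end runs."""
    best: dict[int, int] = {}
    for a in (0, 1):
        max_k = len(seq) - a
        for r in range(min_len, len(utr) + 1):   # exclusive right edge
            k = 0
            while k < max_k and r - 1 - k >= 0 and (seq[a + k], utr[r - 1 - k]) in _PAIRS:
                k += 1
            if k >= min_len and best.get(r - k, 0) < k:
                best[r - k] = k
    return sorted(best.items())


# ---------------------------------------------------------------- family

def test_family_key_is_positions_2_to_8():
    assert mirna_family(LET7A) == "GAGGUAG"
    assert mirna_family("AAAAAAAA") == "AAAAAAA"


def test_family_key_ignores_position_1():
    assert mirna_family("A" + LET7A[1:]) == mirna_family(LET7A)


def test_family_key_requires_8_nt():
    with pytest.raises(ValueError):
        mirna_family("ACGUACG")


# ---------------------------------------------------------------- seed sites

def test_8mer_site_with_suppressed_nested_7mers():
    sites = predict_seed_sites(LET7A, "AAACUACCUCAAA")
    assert [(s.utr_offset, s.site_type) for s in sites] == [(3, "8mer")]


def test_7mer_m8_when_trailing_base_not_a():
    sites = predict_seed_sites(LET7A, "CUACCUCG")
    assert [(s.utr_offset, s.site_type) for s in sites] == [(0, "7mer-m8")]


def test_no_match_in_homopolymer_utr():
    assert predict_seed_sites(LET7A, "G" * 50) == []


def test_bad_utr_character_named_by_offset():
    with pytest.raises(ValueError, match="offset 4"):
        predict_seed_sites(LET7A, "ACGUNACGU")


@settings(max_examples=300, derandomize=True)
@given(mirna_seq, rna)
def test_seed_sites_match_bruteforce(seq, utr):
    got = [(s.utr_offset, s.site_type) for s in predict_seed_sites(seq, utr)]
    assert sorted(got) == brute_seed(seq, utr)


# ---------------------------------------------------------------- walk sites

def test_full_length_complement_is_walk_8():
    sites = predict_walk_sites("UGAGGUAG", "CUACCUCA")
    assert [(s.utr_offset, s.site_type) for s in sites] == [(0, "walk-8")]


def test_seed_anchored_run_is_walk_7():
    sites = predict_walk_sites("UGAGGUAG", "CUACCUC")
    assert [(s.utr_offset, s.site_type) for s in sites] == [(0, "walk-7")]


def test_min_len_threshold_excludes_short_runs():
    assert predict_walk_sites("UGAGGUAG", "CUACCUC", min_len=8) == []


@settings(max_examples=300, derandomize=True)
@given(mirna_seq, rna)
def test_walk_sites_match_bruteforce(seq, utr):
    got = [(s.utr_offset, s.length) for s in predict_walk_sites(seq, utr)]
    assert got == brute_walk(seq, utr)


@settings(max_examples=200, derandomize=True)
@given(mirna_seq, rna)
def test_8mer_implies_walk_run_at_same_locus(seq, utr):
    """Canonical seed sites are a subset of walk sites with k >= 7."""
    walk = {s.utr_offset: s.length for s in predict_walk_sites(seq, utr)}
    for s in predict_seed_sites(seq, utr):
        if s.site_type in ("8mer", "7mer-m8"):
            assert any(o <= s.utr_offset and o + k >= s.utr_offset + 7
                       for o, k in walk.items())


def test_background_7mer_match_rate_matches_theory():
    """Mean 7mer-m8 pattern count on random UTRs tracks (L-6)/4^7."""
    rng = np.random.default_rng(7)
    length, trials = 100, 10_000
    bases = np.array(list("ACGU"))
    total = 0
    for _ in range(trials):
        seq = "".join(rng.choice(bases, size=22))
        utr = "".join(rng.choice(bases, size=length))
        total += sum(1 for s in predict_seed_sites(seq, utr)
                     if s.site_type in ("7mer-m8", "8mer"))
    expected = trials * (length - 6) * 4 ** -7
    assert abs(total - expected) <= 3 * np.sqrt(expected)


# ---------------------------------------------------------------- intersection

def _pair(m, g, sp="human", by=("seed",), sites=((0, "7mer-m8", 7),)):
    return InteractionPair(m, g, sp, [BindingSite(*s) for s in sites],
                           frozenset(by))


def test_intersection_keeps_only_shared_pairs():
    walk = [_pair("m1", "g1", by=("walk",), sites=((0, "walk-7", 7),))]
    seed = [_pair("m1", "g1"), _pair("m1", "g2")]
    out = intersect_predictions(walk, seed)
    assert [p.key for p in out] == [("m1", "g1", "human")]
    assert out[0].predicted_by == {"walk", "seed"}
    assert {(s.utr_offset, s.site_type) for s in out[0].sites} == {
        (0, "walk-7"), (0, "7mer-m8")}


def test_disjoint_predictions_intersect_to_empty():
    assert intersect_predictions([_pair("m1", "g1", by=("walk",))],
                                 [_pair("m2", "g2")]) == []


def test_species_mismatch_rejected():
    with pytest.raises(ValueError, match="species mismatch"):
        intersect_predictions([_pair("m1", "g1", "mouse", by=("walk",))],
                              [_pair("m1", "g1", "human")])


def test_intersection_matches_bruteforce_on_random_tables():
    rng = np.random.default_rng(3)
    def random_pairs(n, by):
        return [_pair(f"m{rng.integers(40)}", f"g{rng.integers(40)}", by=by)
                for _ in range(n)]
    walk = random_pairs(1000, ("walk",))
    seed = random_pairs(1000, ("seed",))
    got = {p.key for p in intersect_predictions(walk, seed)}
    expect = {s.key for s in seed for w in walk if s.key == w.key}
    assert got == expect


# ---------------------------------------------------------------- predict_all

def test_planted_sites_fully_recovered_through_intersection(small_cohort):
    """Every truth-recorded planted 8mer survives both predictors."""
    pair_keys = {}
    for sp in small_cohort.config.species:
        genes = [g for g in small_cohort.genes[sp] if g.utr_seq]
        pairs, _ = predict_all(small_cohort.mirnas, genes)
        for p in pairs:
            pair_keys[(p.mirna_id, p.gene_id, sp)] = p
    planted = small_cohort.truth["planted_sites"]
    assert planted, "fixture cohort should plant sites"
    for rec in planted:
        p = pair_keys[(rec["mirna_id"], rec["gene_id"], rec["species"])]
        assert any(s.utr_offset == rec["offset"] and s.site_type == "8mer"
                   for s in p.sites)


def test_zero_mirnas_predict_nothing(small_cohort):
    genes = [g for g in small_cohort.genes["human"] if g.utr_seq][:5]
    assert predict_all([], genes) == ([], [])


def test_family_collapse_merges_shared_seed():
    m_a = MiRNA("m_a", "A" + "GAGGUAG" + "UUUUUUUUUUUUUU")
    m_b = MiRNA("m_b", "C" + "GAGGUAG" + "AAAAAAAAAAAAAA")
    pairs = [_pair("m_a", "g1"), _pair("m_b", "g1")]
    fams = collapse_families(pairs, [m_a, m_b])
    assert [p.key for p in fams] == [("GAGGUAG", "g1", "human")]


def test_family_pairs_never_exceed_mirna_pairs(small_cohort):
    genes = [g for g in small_cohort.genes["human"] if g.utr_seq]
    pairs, fams = predict_all(small_cohort.mirnas, genes)
    assert len(fams) <= len(pairs)
    per_gene_pairs = {}
    per_gene_fams = {}
    for p in pairs:
        per_gene_pairs[p.gene_id] = per_gene_pairs.get(p.gene_id, 0) + 1
    for f in fams:
        per_gene_fams[f.gene_id] = per_gene_fams.get(f.gene_id, 0) + 1
    for g, n in per_gene_fams.items():
        assert n <= per_gene_pairs[g]
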
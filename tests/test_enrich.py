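"""Fisher/BH oracles, pathway enrichment, class counts and binding-site ORA."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircnv.enrich import (bh_adjust, binding_site_ora, classify_genes,
                           fisher_exact_greater, heatmap_matrix,
                           ora_across_sets, pathway_enrichment)
from mircnv.io import GeneSetCollection
from mircnv.models import BindingSite, GeneRecord, InteractionPair


# ---------------------------------------------------------------- oracles

def enum_fisher_greater(a, b, c, d):
    """Exact hypergeometric upper tail by integer enumeration."""
    n_total, k_set, n_draw = a + b + c + d, a + c, a + b
    denom = comb(n_total, n_draw)
    hi = min(k_set, n_draw)
    return sum(comb(k_set, x) * comb(n_total - k_set, n_draw - x)
               for x in range(a, hi + 1)) / denom


def stepup_bh(ps):
    """Independently coded BH step-up with cumulative-min monotonicity."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, ps[i] * m / rank)
        adj[i] = prev
    return adj


# ---------------------------------------------------------------- fisher

def test_fisher_tail_is_one_when_a_at_support_minimum():
    assert fisher_exact_greater(0, 5, 3, 7) == pytest.approx(1.0)


def test_fisher_exact_small_table_by_hand():
    # Hypergeom(N=8, K=4, n=4): P(X>=3) = (16 + 1)/70
    assert fisher_exact_greater(3, 1, 1, 3) == pytest.approx(17 / 70, abs=1e-12)


def test_fisher_rejects_negative_or_empty():
    with pytest.raises(ValueError):
        fisher_exact_greater(-1, 1, 1, 1)
    with pytest.raises(ValueError):
        fisher_exact_greater(0, 0, 0, 0)


@settings(max_examples=300, derandomize=True)
@given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                 st.integers(0, 12), st.integers(0, 12)).filter(lambda t: sum(t) > 0))
def test_fisher_matches_enumeration(table):
    assert fisher_exact_greater(*table) == pytest.approx(
        enum_fisher_greater(*table), abs=1e-12)


# ---------------------------------------------------------------- BH

def test_bh_single_value_unchanged():
    assert bh_adjust([0.037]) == [0.037]


def test_bh_stepup_by_hand():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_bh_matches_independent_stepup_on_random_vectors():
    rng = np.random.default_rng(1)
    for _ in range(200):
        ps = rng.random(int(rng.integers(1, 40))).tolist()
        assert bh_adjust(ps) == pytest.approx(stepup_bh(ps), abs=1e-12)


def test_bh_preserves_rank_monotonicity():
    rng = np.random.default_rng(2)
    ps = rng.random(25).tolist()
    adj = bh_adjust(ps)
    order = sorted(range(25), key=lambda i: ps[i])
    assert all(adj[order[i]] <= adj[order[i + 1]] for i in range(24))


# ---------------------------------------------------------------- pathways

def _collection(sets):
    return GeneSetCollection("pathways", sets=sets)


def test_saturated_list_cannot_be_enriched():
    bg = [f"g{i}" for i in range(20)]
    coll = _collection({"s1": bg[:5], "s2": bg[5:12]})
    results, n_sig = pathway_enrichment(bg, bg, coll)
    assert n_sig == 0
    assert all(r.p_raw == pytest.approx(1.0) for r in results)
    assert all(r.a == len(coll.sets[r.set_id]) for r in results)


def test_gene_list_outside_background_rejected():
    with pytest.raises(ValueError, match="not background"):
        pathway_enrichment(["gX"], ["g1"], _collection({"s": ["g1"]}))
    with pytest.raises(ValueError, match="empty background"):
        pathway_enrichment([], [], _collection({"s": ["g1"]}))


def test_enrichment_on_hand_built_table():
    bg = [f"g{i}" for i in range(10)]
    coll = _collection({"s1": bg[:4], "s2": bg[4:6]})
    results, _ = pathway_enrichment(bg[:4] + bg[8:9], bg, coll)
    by_id = {r.set_id: r for r in results}
    assert (by_id["s1"].a, by_id["s1"].b, by_id["s1"].c, by_id["s1"].d) == (4, 1, 0, 5)
    assert by_id["s1"].p_raw == pytest.approx(enum_fisher_greater(4, 1, 0, 5))
    assert all(r.p_adj >= r.p_raw for r in results)


def test_planted_pathways_recovered_at_default_scale():
    """One default cohort: the planted pathways come out BH-significant."""
    from mircnv.evaluation import replicate_metrics
    from mircnv.synthetic import SyntheticConfig
    rep = replicate_metrics(SyntheticConfig(rng_seed=42))
    assert rep["planted"], "default config should plant pathways"
    assert rep["planted"] <= rep["significant"]


# ---------------------------------------------------------------- heatmap

def _res(set_id, p_adj, sig=True):
    from mircnv.enrich import EnrichmentResult
    return EnrichmentResult(set_id, 1, 1, 1, 1, p_adj, p_adj, sig)


def test_single_species_sets_are_all_specific():
    mat, specific = heatmap_matrix({"human": [_res("s1", 0.01)]})
    assert list(mat.columns) == ["human"]
    assert specific["human"] == ["s1"]


def test_identical_species_results_have_no_specific_sets():
    results = {sp: [_res("s1", 0.01)] for sp in ("human", "mouse")}
    _, specific = heatmap_matrix(results)
    assert specific == {"human": [], "mouse": []}


def test_human_only_significant_set_reported_specific():
    results = {"human": [_res("sX", 0.001)], "mouse": [_res("sX", 0.5, sig=False)]}
    mat, specific = heatmap_matrix(results, mode="neglog10")
    assert specific["human"] == ["sX"]
    assert mat.loc["sX", "human"] == pytest.approx(3.0)
    assert mat.loc["sX", "mouse"] == 0.0


# ---------------------------------------------------------------- classes

def _atlas_records(statuses):
    return [GeneRecord(f"g{i}", "human", "c", i * 10, i * 10 + 5,
                       cnv_status=s) for i, s in enumerate(statuses)]


def test_class_counts_split_by_status():
    atlas = {"human": _atlas_records(["CNV", "CNV", "nonCNV"])}
    coll = GeneSetCollection("classes", sets={"k1": ["g0", "g1", "g2"]})
    df = classify_genes(atlas, coll)
    assert df.loc[0, ["n_cnv", "n_noncnv"]].tolist() == [2, 1]


def test_class_with_no_atlas_overlap_counts_zero():
    atlas = {"human": _atlas_records(["CNV"])}
    coll = GeneSetCollection("classes", sets={"k1": ["zz1", "zz2"]})
    df = classify_genes(atlas, coll)
    assert df.loc[0, ["n_cnv", "n_noncnv"]].tolist() == [0, 0]


# ---------------------------------------------------------------- ORA

def _density_pairs(rng, genes, lam):
    pairs = []
    for g in genes:
        n = int(rng.poisson(lam))
        if n:
            pairs.append(InteractionPair(
                "m1", g, "human", [BindingSite(i, "7mer-m8", 7) for i in range(n)],
                frozenset({"walk", "seed"})))
    return pairs


def test_ora_null_pvalues_are_uniform():
    """Same density law in both groups: KS vs U(0,1) passes at 0.01."""
    from scipy import stats as sps
    rng = np.random.default_rng(21)
    genes = [f"g{i}" for i in range(100)]
    ps = []
    for _ in range(500):
        utr_lengths = {g: int(rng.integers(100, 500)) for g in genes}
        pairs = _density_pairs(rng, genes, 4.0)
        members = list(rng.choice(genes, size=50, replace=False))
        nonmembers = [g for g in genes if g not in set(members)]
        ps.append(binding_site_ora(pairs, members, nonmembers, utr_lengths))
    _, ks_p = sps.kstest(ps, "uniform")
    assert ks_p > 0.01


def test_ora_detects_planted_density_excess():
    """3x member site rate: p <= 0.05 in >= 90% of 100 replicates."""
    rng = np.random.default_rng(22)
    hits = 0
    for _ in range(100):
        members = [f"m{i}" for i in range(50)]
        nonmembers = [f"n{i}" for i in range(50)]
        utr_lengths = {g: int(rng.integers(150, 400))
                       for g in members + nonmembers}
        pairs = _density_pairs(rng, members, 6.0) \
            + _density_pairs(rng, nonmembers, 2.0)
        hits += binding_site_ora(pairs, members, nonmembers, utr_lengths) <= 0.05
    assert hits >= 90


def test_ora_degenerate_inputs_yield_nan():
    utr_lengths = {f"g{i}": 100 for i in range(10)}
    genes = sorted(utr_lengths)
    assert math.isnan(binding_site_ora([], genes[:5], genes[5:], utr_lengths))
    assert math.isnan(binding_site_ora([], genes[:1], genes[1:],
                                       {"g0": 100, "g1": 100}))
    with pytest.raises(ValueError):
        binding_site_ora([], [], genes, utr_lengths)


def test_ora_fisher_variant_and_bh_across_sets():
    rng = np.random.default_rng(23)
    genes = [f"g{i}" for i in range(60)]
    utr_lengths = {g: 200 for g in genes}
    pairs = _density_pairs(rng, genes[:20], 8.0) + _density_pairs(rng, genes[20:], 2.0)
    coll = GeneSetCollection("pathways", sets={"hot": genes[:20],
                                               "cold": genes[40:]})
    df = ora_across_sets(pairs, coll, genes, utr_lengths, method="fisher")
    hot_p = df.set_index("set_id").loc["hot", "p_raw"]
    cold_p = df.set_index("set_id").loc["cold", "p_raw"]
    assert hot_p < cold_p
    assert (df["p_adj"] >= df["p_raw"]).all()
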
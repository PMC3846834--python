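"""Generator behaviour: determinism, planted-site accounting, round-trips."""

import dataclasses
import filecmp
import math

import pytest

from mircnv.models import CNV, NONCNV, GeneRecord, MiRNA
from mircnv.synthetic import (MANIFEST_FILES, SyntheticCohort, SyntheticConfig,
                              generate_cohort, read_cohort, write_cohort)

from conftest import small_config


def zero_rate_config(seed: int = 5) -> SyntheticConfig:
    cfg = small_config(seed)
    return dataclasses.replace(
        cfg,
        planted_site_rate={(sp, st): 0.0 for sp in cfg.species
                           for st in (CNV, NONCNV)},
        prolific_mirna_fraction=0.0,
    )


def test_zero_rate_plants_nothing():
    cohort = generate_cohort(zero_rate_config())
    assert cohort.truth["planted_sites"] == []


def test_same_seed_gives_byte_identical_files(tmp_path):
    for d in ("a", "b"):
        write_cohort(generate_cohort(small_config(17)), tmp_path / d)
    for name in MANIFEST_FILES.values():
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                           shallow=False), name


def test_different_seeds_differ(tmp_path):
    a = generate_cohort(small_config(1))
    b = generate_cohort(small_config(2))
    assert a.truth != b.truth


def test_planted_site_total_follows_poisson_sum():
    """Sum of per-gene Poisson(2) counts over the CNV stratum."""
    cfg = SyntheticConfig(
        n_species=1, n_homology_groups=3000, n_mirnas=20,
        utr_length_mean=200.0, utr_length_sd=30.0,
        planted_site_rate={("human", CNV): 2.0, ("human", NONCNV): 0.0},
        prolific_mirna_fraction=0.0, planted_enriched_pathways=[],
        rng_seed=23,
    )
    cohort = generate_cohort(cfg)
    n_cnv = cohort.truth["atlas_counts"]["human"][0]
    total = len(cohort.truth["planted_sites"])
    expected = 2.0 * n_cnv
    assert abs(total - expected) <= 3 * math.sqrt(expected)


def test_planted_sites_literally_present(small_cohort):
    by_key = {(g.species, g.gene_id): g
              for genes in small_cohort.genes.values() for g in genes}
    mirnas = {m.mirna_id: m for m in small_cohort.mirnas}
    for rec in small_cohort.truth["planted_sites"]:
        g = by_key[(rec["species"], rec["gene_id"])]
        m = mirnas[rec["mirna_id"]]
        site = g.utr_seq[rec["offset"]:rec["offset"] + 8]
        assert site[-1] == "A"
        assert site[:7] == m.mature_seq[1:8].translate(
            str.maketrans("ACGU", "UGCA"))[::-1]


def test_structural_invariants(small_cohort):
    for grp in small_cohort.homology:
        assert "human" in grp.members
    for sp, genes in small_cohort.genes.items():
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 >= e1, f"overlapping genes in {sp}"


def test_roundtrip_equals_original(tmp_path, small_cohort):
    write_cohort(small_cohort, tmp_path)
    back = read_cohort(tmp_path)
    assert back.config == small_cohort.config
    assert back.genes == small_cohort.genes
    assert back.homology == small_cohort.homology
    assert back.mirnas == small_cohort.mirnas
    assert back.pathways.sets == small_cohort.pathways.sets
    assert back.gene_classes.sets == small_cohort.gene_classes.sets
    assert back.truth == small_cohort.truth


def test_empty_cohort_writes_wellformed_files(tmp_path):
    cohort = SyntheticCohort(config=small_config())
    paths = write_cohort(cohort, tmp_path)
    for path in paths.values():
        assert path.exists()
    back = read_cohort(tmp_path)
    assert back.genes == {}
    assert back.mirnas == []


def test_single_gene_single_mirna_bed_line_count(tmp_path):
    cohort = SyntheticCohort(config=small_config())
    cohort.genes["human"] = [GeneRecord("g0", "human", "human_chr1", 100, 600,
                                        cnv_status=NONCNV, utr_seq="ACGU" * 20)]
    cohort.mirnas = [MiRNA("syn-miR-001", "ACGUACGUACGUACGUACGUA",
                           placements={"human": ("human_chr1", 150, 230, "+")})]
    paths = write_cohort(cohort, tmp_path)
    n_lines = sum(1 for _ in open(paths["genes"])) \
        + sum(1 for _ in open(paths["mirna_loci"]))
    assert n_lines == 2


def test_infeasible_site_density_rejected():
    cfg = small_config()
    bad = dataclasses.replace(
        cfg, utr_length_mean=40.0,
        planted_site_rate={(sp, st): 10.0 for sp in cfg.species
                           for st in (CNV, NONCNV)})
    with pytest.raises(ValueError, match="do not fit"):
        generate_cohort(bad)


def test_invalid_fraction_rejected():
    with pytest.raises(ValueError, match="hot_gene_fraction"):
        generate_cohort(dataclasses.replace(small_config(),
                                            hot_gene_fraction=1.5))
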
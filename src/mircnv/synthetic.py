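"""Self-contained multi-species synthetic cohort with planted effects.

The generator emulates the data regime of the real analysis — homologous
gene groups across species, per-species CNV region assignment, random 3'UTR
sequences with exact canonical 8mer seed sites planted at configurable
rates, a miRNA catalogue with families, intragenic/intergenic miRNA loci
with a configurable CNV-host bias, and pathway / curated-class gene sets —
while keeping every planted effect on record in a ``truth`` structure so
downstream stages can be tested without external downloads.

Planted structure, in brief:

* per-gene planted 8mer sites follow a Poisson law with a per
  (species, CNV-status) rate; rate-planted sites are drawn from the
  *non-prolific* miRNA pool;
* a designated "prolific" miRNA subset receives extra sites concentrated in
  a "hot" pool of human CNV genes, which drives those miRNAs above the
  overall target mean and makes hot genes the core of the above-mean gene
  list;
* a planted pathway with arm ``above`` draws an excess fraction of its
  members from the hot pool (arm ``below`` draws from the complement),
  which is what makes it recoverable by the enrichment stage;
* intragenic miRNA placement honours a per-species CNV-host bias.

All randomness flows through one seeded PCG64 generator; a fixed seed gives
byte-identical serialized cohorts.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .models import CNV, NONCNV, SPECIES, GeneRecord, HomologyGroup, MiRNA
from .targets import revcomp

log = logging.getLogger(__name__)

SITE_LEN = 8           # planted sites are canonical 8mers
_BASES = np.frombuffer(b"ACGU", dtype=np.uint8)

#: CNV gene fractions per species, matching the relative magnitudes of the
#: homolog-distribution table of the original eight-species study.
DEFAULT_CNV_FRACTION = {
    "human": 0.566,
    "chimpanzee": 0.560,
    "macaque": 0.469,
    "mouse": 0.568,
    "rat": 0.565,
    "chicken": 0.577,
    "dog": 0.565,
    "cow": 0.560,
}

#: fraction of intragenic miRNAs placed inside CNV genes. Human carries a
#: strong planted bias; chimpanzee, macaque and rat are set to their CNV
#: gene fraction (i.e. no bias, "similar" densities), mirroring the
#: qualitative cross-species pattern the host scan is meant to recover.
DEFAULT_HOST_BIAS = {
    "human": 0.80,
    "chimpanzee": 0.560,
    "macaque": 0.469,
    "mouse": 0.70,
    "rat": 0.565,
    "chicken": 0.70,
    "dog": 0.70,
    "cow": 0.70,
}


def default_planted_site_rate(species: tuple[str, ...]) -> dict[tuple[str, str], float]:
    """Default per-(species, status) planted-site rates.

    Human CNV genes carry an elevated rate; every other cell shares a low
    background rate, so the human-CNV excess is the only planted density
    signal.
    """
    rates = {}
    for sp in species:
        for status in (CNV, NONCNV):
            rates[(sp, status)] = 0.8 if (sp == "human" and status == CNV) else 0.2
    return rates


@dataclass
class SyntheticConfig:
    """Tunable knobs of the synthetic cohort; defaults define the study
    conditions exercised by the test-bench."""

    n_species: int = 8
    n_homology_groups: int = 360
    homolog_presence: float = 0.9
    cnv_fraction_per_species: dict[str, float] = field(default_factory=dict)
    n_mirnas: int = 50
    mirna_length_range: tuple[int, int] = (21, 25)
    family_reuse_prob: float = 0.1
    utr_length_mean: float = 300.0
    utr_length_sd: float = 60.0
    planted_site_rate: dict[tuple[str, str], float] = field(default_factory=dict)
    hot_gene_fraction: float = 0.25
    prolific_mirna_fraction: float = 0.2
    prolific_site_prob: float = 0.5
    n_pathways: int = 12
    pathway_size_range: tuple[int, int] = (10, 16)
    planted_enriched_pathways: list[tuple[str, str, float]] | None = None
    n_gene_classes: int = 6
    class_size_range: tuple[int, int] = (15, 30)
    intragenic_mirna_fraction: float = 0.7
    host_mirna_cnv_bias: dict[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_HOST_BIAS))
    gene_length: int = 5000
    gene_gap: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_enriched_pathways is None:
            self.planted_enriched_pathways = [
                ("PW01", "above", 1.0),
                ("PW02", "above", 1.0),
                ("PW03", "above", 1.0),
            ]
        sp = self.species
        if not self.cnv_fraction_per_species:
            self.cnv_fraction_per_species = {
                s: DEFAULT_CNV_FRACTION.get(s, 0.5) for s in sp
            }
        if not self.planted_site_rate:
            self.planted_site_rate = default_planted_site_rate(sp)

    @property
    def species(self) -> tuple[str, ...]:
        return SPECIES[: self.n_species]

    def host_bias(self, species: str) -> float:
        if isinstance(self.host_mirna_cnv_bias, Mapping):
            return self.host_mirna_cnv_bias.get(species, 0.5)
        return float(self.host_mirna_cnv_bias)

    def validate(self) -> None:
        counts = {
            "n_species": self.n_species,
            "n_homology_groups": self.n_homology_groups,
            "n_mirnas": self.n_mirnas,
            "n_pathways": self.n_pathways,
            "n_gene_classes": self.n_gene_classes,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_species > len(SPECIES):
            raise ValueError(f"n_species cannot exceed {len(SPECIES)}")
        fracs = {
            "homolog_presence": self.homolog_presence,
            "family_reuse_prob": self.family_reuse_prob,
            "hot_gene_fraction": self.hot_gene_fraction,
            "prolific_mirna_fraction": self.prolific_mirna_fraction,
            "prolific_site_prob": self.prolific_site_prob,
            "intragenic_mirna_fraction": self.intragenic_mirna_fraction,
            **{f"cnv_fraction[{s}]": f
               for s, f in self.cnv_fraction_per_species.items()},
            **{f"host_bias[{s}]": self.host_bias(s) for s in self.species},
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.utr_length_mean < 30:
            raise ValueError("utr_length_mean must be >= 30 nt")
        for key, rate in self.planted_site_rate.items():
            if rate < 0:
                raise ValueError(f"planted_site_rate{key} must be >= 0")
        n_prolific = round(self.prolific_mirna_fraction * self.n_mirnas)
        max_expected = (max(self.planted_site_rate.values(), default=0.0)
                        + self.prolific_site_prob * n_prolific)
        if SITE_LEN * max_expected > self.utr_length_mean:
            raise ValueError(
                "expected planted sites do not fit without overlap: "
                f"{SITE_LEN} nt x {max_expected:.1f} expected sites exceeds "
                f"the {self.utr_length_mean:.0f} nt mean UTR"
            )

    # -- JSON round-trip (tuple keys flattened) --------------------------
    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["planted_site_rate"] = {
            f"{sp}:{status}": r for (sp, status), r in self.planted_site_rate.items()
        }
        d["mirna_length_range"] = list(self.mirna_length_range)
        d["pathway_size_range"] = list(self.pathway_size_range)
        d["class_size_range"] = list(self.class_size_range)
        d["planted_enriched_pathways"] = [
            list(t) for t in self.planted_enriched_pathways
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        d["planted_site_rate"] = {
            tuple(k.split(":")): v for k, v in d.get("planted_site_rate", {}).items()
        }
        for key in ("mirna_length_range", "pathway_size_range", "class_size_range"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("planted_enriched_pathways") is not None:
            d["planted_enriched_pathways"] = [
                tuple(t) for t in d["planted_enriched_pathways"]
            ]
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A generated cohort plus the complete record of its planted effects."""

    config: SyntheticConfig
    genes: dict[str, list[GeneRecord]] = field(default_factory=dict)
    homology: list[HomologyGroup] = field(default_factory=list)
    cnv_regions: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    mirnas: list[MiRNA] = field(default_factory=list)
    pathways: mio.GeneSetCollection = field(
        default_factory=lambda: mio.GeneSetCollection("pathways"))
    gene_classes: mio.GeneSetCollection = field(
        default_factory=lambda: mio.GeneSetCollection("classes"))
    truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        for grp in self.homology:
            grp.validate()
            if len(grp.members) != len(set(grp.members)):
                raise AssertionError("homology group with >1 gene per species")
        for sp, genes in self.genes.items():
            spans = sorted((g.start, g.end) for g in genes)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise AssertionError(f"overlapping gene intervals in {sp}")
        by_key = {(g.species, g.gene_id): g
                  for genes in self.genes.values() for g in genes}
        for rec in self.truth.get("planted_sites", []):
            g = by_key[(rec["species"], rec["gene_id"])]
            site = _site_sequence(self._mirna_by_id(rec["mirna_id"]))
            o = rec["offset"]
            if g.utr_seq[o:o + SITE_LEN] != site:
                raise AssertionError(
                    f"planted site missing from UTR: {rec}")

    def _mirna_by_id(self, mirna_id: str) -> MiRNA:
        for m in self.mirnas:
            if m.mirna_id == mirna_id:
                return m
        raise KeyError(mirna_id)


def _site_sequence(mirna: MiRNA) -> str:
    """The exact canonical 8mer match of a miRNA's seed."""
    return revcomp(mirna.mature_seq[1:8]) + "A"


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _place_sites(rng: np.random.Generator, length: int,
                 n_sites: int) -> list[int]:
    """Non-overlapping site offsets, uniform over feasible placements."""
    if n_sites == 0:
        return []
    slack = length - SITE_LEN * n_sites
    draws = np.sort(rng.integers(0, slack + 1, size=n_sites))
    return [int(d + SITE_LEN * i) for i, d in enumerate(draws)]


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full cohort; deterministic for a fixed ``rng_seed``."""
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.rng_seed))
    species = config.species
    cohort = SyntheticCohort(config=config)
    truth: dict = {
        "planted_sites": [], "enriched_pathways": [], "prolific_mirnas": [],
        "hot_genes": [], "cnv_host_mirnas": {}, "intragenic_mirnas": {},
        "atlas_counts": {},
    }

    # ---- homology groups and per-species gene scaffolds ----------------
    gene_ids = [f"g{i:04d}" for i in range(config.n_homology_groups)]
    for i, gid in enumerate(gene_ids):
        members = {"human": gid}
        for sp in species[1:]:
            if rng.random() < config.homolog_presence:
                members[sp] = gid
        cohort.homology.append(HomologyGroup(group_id=f"HG{i:04d}", members=members))

    step = config.gene_length + config.gene_gap
    for sp in species:
        chrom = f"{sp}_chr1"
        present = [grp.members[sp] for grp in cohort.homology if sp in grp.members]
        frac = config.cnv_fraction_per_species.get(sp, 0.5)
        is_cnv = rng.random(len(present)) < frac
        genes, regions = [], []
        for j, gid in enumerate(present):
            start = 1000 + j * step
            end = start + config.gene_length
            status = CNV if is_cnv[j] else NONCNV
            genes.append(GeneRecord(gene_id=gid, species=sp, chrom=chrom,
                                    start=start, end=end, strand="+",
                                    cnv_status=status))
            if status == CNV:
                regions.append((chrom, start - 100, end + 100))
        cohort.genes[sp] = genes
        cohort.cnv_regions[sp] = regions
        n_cnv = int(is_cnv.sum())
        truth["atlas_counts"][sp] = [n_cnv, len(present) - n_cnv]

    # ---- miRNA catalogue with families ---------------------------------
    for i in range(config.n_mirnas):
        length = int(rng.integers(config.mirna_length_range[0],
                                  config.mirna_length_range[1] + 1))
        seq = _random_rna(rng, length)
        if i > 0 and rng.random() < config.family_reuse_prob:
            donor = cohort.mirnas[int(rng.integers(0, i))]
            seq = seq[0] + donor.family_key + seq[8:]
        cohort.mirnas.append(MiRNA(mirna_id=f"syn-miR-{i + 1:03d}", mature_seq=seq))

    n_prolific = round(config.prolific_mirna_fraction * config.n_mirnas)
    prolific_idx = sorted(
        int(i) for i in rng.choice(config.n_mirnas, size=n_prolific, replace=False)
    ) if n_prolific else []
    prolific = [cohort.mirnas[i] for i in prolific_idx]
    nonprolific = [m for i, m in enumerate(cohort.mirnas) if i not in set(prolific_idx)]
    truth["prolific_mirnas"] = [m.mirna_id for m in prolific]

    # ---- hot genes and gene-set collections ----------------------------
    human_cnv = [g.gene_id for g in cohort.genes["human"] if g.cnv_status == CNV]
    n_hot = round(config.hot_gene_fraction * len(human_cnv))
    hot = sorted(
        str(g) for g in rng.choice(human_cnv, size=n_hot, replace=False)
    ) if n_hot else []
    hot_set = set(hot)
    truth["hot_genes"] = hot

    hot_pool = list(hot)
    cold_pool = [g for g in human_cnv if g not in hot_set]
    rng.shuffle(hot_pool)
    rng.shuffle(cold_pool)

    def draw(pool: list[str], n: int, what: str) -> list[str]:
        if len(pool) < n:
            raise ValueError(
                f"gene pool exhausted while drawing {what}; increase "
                "n_homology_groups or reduce pathway sizes"
            )
        out, pool[:] = pool[:n], pool[n:]
        return out

    lo, hi = config.pathway_size_range
    planted_ids = set()
    for pid, arm, excess in config.planted_enriched_pathways:
        if arm not in ("above", "below"):
            raise ValueError(f"planted pathway {pid}: arm must be above|below")
        size = int(rng.integers(lo, hi + 1))
        n_excess = round(excess * size)
        src = hot_pool if arm == "above" else cold_pool
        other = cold_pool if arm == "above" else hot_pool
        members = draw(src, n_excess, f"planted pathway {pid}")
        members += draw(other, size - n_excess, f"planted pathway {pid}")
        cohort.pathways.sets[pid] = sorted(members)
        cohort.pathways.descriptions[pid] = f"planted:{arm}:{excess}"
        planted_ids.add(pid)
        truth["enriched_pathways"].append(
            {"pathway_id": pid, "arm": arm, "excess": excess})
    remaining = cold_pool + hot_pool
    rng.shuffle(remaining)
    k = 1
    while len(cohort.pathways.sets) < config.n_pathways:
        while f"PW{k:02d}" in planted_ids or f"PW{k:02d}" in cohort.pathways.sets:
            k += 1
        size = int(rng.integers(lo, hi + 1))
        members = draw(remaining, size, "background pathways")
        cohort.pathways.sets[f"PW{k:02d}"] = sorted(members)
        cohort.pathways.descriptions[f"PW{k:02d}"] = "background"

    all_human = [g.gene_id for g in cohort.genes["human"]]
    clo, chi = config.class_size_range
    class_names = ["cell_differentiation", "cytokines_growth_factors",
                   "homeodomain", "oncogene", "kinases",
                   "transcription_factors", "translocated_cancer",
                   "tumor_suppressor"]
    for i in range(config.n_gene_classes):
        size = int(rng.integers(clo, min(chi, len(all_human)) + 1))
        members = sorted(
            str(g) for g in rng.choice(all_human, size=size, replace=False))
        name = class_names[i] if i < len(class_names) else f"class_{i + 1:02d}"
        cohort.gene_classes.sets[name] = members
        cohort.gene_classes.descriptions[name] = "curated-class stand-in"

    # ---- UTR sequences with planted 8mer sites -------------------------
    site_donors = nonprolific if nonprolific else cohort.mirnas
    for sp in species:
        for g in cohort.genes[sp]:
            length = max(60, int(round(rng.normal(config.utr_length_mean,
                                                  config.utr_length_sd))))
            rate = config.planted_site_rate.get((sp, g.cnv_status), 0.0)
            chosen: list[MiRNA] = []
            n_rate = int(rng.poisson(rate)) if rate > 0 else 0
            for _ in range(n_rate):
                chosen.append(site_donors[int(rng.integers(0, len(site_donors)))])
            if sp == "human" and g.gene_id in hot_set:
                for m in prolific:
                    if rng.random() < config.prolific_site_prob:
                        chosen.append(m)
            cap = length // SITE_LEN
            if len(chosen) > cap:
                log.warning("gene %s (%s): %d planted sites truncated to %d",
                            g.gene_id, sp, len(chosen), cap)
                chosen = chosen[:cap]
            seq = _random_rna(rng, length)
            offsets = _place_sites(rng, length, len(chosen))
            for m, o in zip(chosen, offsets):
                site = _site_sequence(m)
                seq = seq[:o] + site + seq[o + SITE_LEN:]
                truth["planted_sites"].append(
                    {"species": sp, "gene_id": g.gene_id,
                     "mirna_id": m.mirna_id, "offset": o})
            g.utr_seq = seq

    # ---- miRNA genomic placement ----------------------------------------
    mirna_width = 80
    for sp in species:
        genes = cohort.genes[sp]
        cnv_genes = [g for g in genes if g.cnv_status == CNV]
        noncnv_genes = [g for g in genes if g.cnv_status == NONCNV]
        last_end = max((g.end for g in genes), default=1000)
        bias = config.host_bias(sp)
        intragenic, cnv_hosted = [], []
        for i, m in enumerate(cohort.mirnas):
            if rng.random() < config.intragenic_mirna_fraction:
                want_cnv = rng.random() < bias
                pool = cnv_genes if want_cnv else noncnv_genes
                if not pool:
                    pool = noncnv_genes if want_cnv else cnv_genes
                if not pool:
                    m.placements[sp] = None
                    continue
                host = pool[int(rng.integers(0, len(pool)))]
                offset = int(rng.integers(0, config.gene_length - mirna_width))
                start = host.start + offset
                m.placements[sp] = (host.chrom, start, start + mirna_width, "+")
                intragenic.append(m.mirna_id)
                if host.cnv_status == CNV:
                    cnv_hosted.append(m.mirna_id)
            else:
                start = last_end + 10_000 + i * 500
                m.placements[sp] = (f"{sp}_chr1", start, start + mirna_width, "+")
        truth["intragenic_mirnas"][sp] = intragenic
        truth["cnv_host_mirnas"][sp] = cnv_hosted

    cohort.truth = truth
    cohort.pathways.validate()
    cohort.gene_classes.validate()
    cohort.validate()
    return cohort


# ---------------------------------------------------------------- serialization

MANIFEST_FILES = {
    "utrs": "utrs.fasta",
    "mirnas": "mirnas.fasta",
    "genes": "genes.bed",
    "mirna_loci": "mirna_loci.bed",
    "cnv_regions": "cnv_regions.bed",
    "homology": "homology.tsv",
    "pathways": "pathways.gmt",
    "classes": "classes.gmt",
    "truth": "truth.json",
    "config": "config.json",
}


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a cohort to flat files; returns the file manifest.

    UTR FASTA ids are ``gene_id|species``; chromosome names encode the
    species (``<species>_chr1``), so a single BED file carries all species.
    Output ordering is fully sorted, making equal cohorts byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in MANIFEST_FILES.items()}

    utrs = sorted(
        (f"{g.gene_id}|{sp}", g.utr_seq)
        for sp, genes in cohort.genes.items() for g in genes if g.utr_seq
    )
    mio.write_fasta(utrs, paths["utrs"])
    mio.write_fasta([(m.mirna_id, m.mature_seq) for m in cohort.mirnas],
                    paths["mirnas"])

    gene_rows = sorted(
        (g.chrom, g.start, g.end, g.gene_id, 0, g.strand)
        for genes in cohort.genes.values() for g in genes
    )
    mio.write_bed6(pd.DataFrame(gene_rows, columns=mio.BED6_COLUMNS),
                   paths["genes"])

    loci_rows = sorted(
        (chrom, start, end, m.mirna_id, 0, strand)
        for m in cohort.mirnas
        for chrom, start, end, strand in
        (pl for pl in m.placements.values() if pl is not None)
    )
    mio.write_bed6(pd.DataFrame(loci_rows, columns=mio.BED6_COLUMNS),
                   paths["mirna_loci"])

    region_rows = sorted(
        (chrom, start, end, f"cnvr_{i:05d}", 0, ".")
        for regions in cohort.cnv_regions.values()
        for i, (chrom, start, end) in enumerate(regions)
    )
    mio.write_bed6(pd.DataFrame(region_rows, columns=mio.BED6_COLUMNS),
                   paths["cnv_regions"])

    mio.write_homology_tsv(cohort.homology, paths["homology"])
    mio.write_gmt(cohort.pathways, paths["pathways"])
    mio.write_gmt(cohort.gene_classes, paths["classes"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=1, sort_keys=True))
    paths["config"].write_text(
        json.dumps(cohort.config.to_dict(), indent=1, sort_keys=True))
    return paths


def _species_of_chrom(chrom: str) -> str:
    return chrom.rsplit("_chr", 1)[0]


def read_cohort(in_dir: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    d = Path(in_dir)
    paths = {k: d / v for k, v in MANIFEST_FILES.items()}
    config = SyntheticConfig.from_dict(json.loads(paths["config"].read_text()))
    cohort = SyntheticCohort(config=config)
    cohort.truth = json.loads(paths["truth"].read_text())

    utrs = mio.read_fasta(paths["utrs"])
    genes_bed = mio.read_bed6(paths["genes"])
    regions_bed = mio.read_bed6(paths["cnv_regions"])

    for r in regions_bed.itertuples(index=False):
        sp = _species_of_chrom(r.chrom)
        cohort.cnv_regions.setdefault(sp, []).append((r.chrom, r.start, r.end))

    from .atlas import assign_cnv_status   # deferred: avoids import cycle

    for r in genes_bed.itertuples(index=False):
        sp = _species_of_chrom(r.chrom)
        rec = GeneRecord(gene_id=r.name, species=sp, chrom=r.chrom,
                         start=r.start, end=r.end, strand=r.strand,
                         utr_seq=utrs.get(f"{r.name}|{sp}"))
        cohort.genes.setdefault(sp, []).append(rec)
    for sp, genes in cohort.genes.items():
        assign_cnv_status(genes, cohort.cnv_regions.get(sp, []))
        genes.sort(key=lambda g: g.start)

    mirna_seqs = mio.read_fasta(paths["mirnas"])
    mirnas = {mid: MiRNA(mirna_id=mid, mature_seq=seq)
              for mid, seq in mirna_seqs.items()}
    for r in mio.read_bed6(paths["mirna_loci"]).itertuples(index=False):
        sp = _species_of_chrom(r.chrom)
        mirnas[r.name].placements[sp] = (r.chrom, r.start, r.end, r.strand)
    cohort.mirnas = [mirnas[mid] for mid in sorted(mirnas)]

    cohort.homology = mio.read_homology_tsv(paths["homology"])
    cohort.pathways = mio.read_gmt(paths["pathways"], "pathways")
    cohort.gene_classes = mio.read_gmt(paths["classes"], "classes")
    return cohort
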
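"""Replicate experiments over synthetic cohorts.

These drive the package's statistical self-checks: recovery of planted
pathway enrichment (sensitivity and empirical FDR through the real
predict -> partition -> enrichment path), the cross-species density
ordering, the planted host-miRNA CNV bias, and the no-effect null rate of
the enrichment stage. Child seeds are derived from one master seed via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .enrich import pathway_enrichment
from .models import CNV
from .scan import host_bias_summary, scan_hosts
from .stats import overall_mean, partition_genes
from .synthetic import SyntheticCohort, SyntheticConfig, generate_cohort
from .targets import predict_all

log = logging.getLogger(__name__)


def child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2^31) from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def _cnv_pairs(cohort: SyntheticCohort, species: str):
    genes = [g for g in cohort.genes[species]
             if g.cnv_status == CNV and g.utr_seq]
    pairs, _ = predict_all(cohort.mirnas, genes)
    return pairs, len(genes)


def replicate_metrics(config: SyntheticConfig, alpha: float = 0.05) -> dict:
    """Run one cohort through the analysis and score it against its truth.

    Returns per-replicate observations: per-species interaction densities,
    significant/planted pathway sets for the human above-mean list, and the
    human host-bias label.
    """
    cohort = generate_cohort(config)
    densities: dict[str, float] = {}
    human_pairs = None
    for sp in config.species:
        pairs, n_cnv = _cnv_pairs(cohort, sp)
        densities[sp] = len(pairs) / n_cnv if n_cnv else 0.0
        if sp == "human":
            human_pairs = pairs

    mean = overall_mean(len(human_pairs), config.n_mirnas)
    part = partition_genes(human_pairs, mean, species="human", level="mirna",
                           n_units=config.n_mirnas)
    annotated = set().union(*cohort.pathways.sets.values()) \
        if cohort.pathways.sets else set()
    universe = sorted(
        {g.gene_id for g in cohort.genes["human"] if g.cnv_status == CNV}
        & annotated)
    significant: set[str] = set()
    if universe:
        gene_list = sorted(set(part.above_genes) & set(universe))
        results, _ = pathway_enrichment(gene_list, universe, cohort.pathways,
                                        alpha=alpha)
        significant = {r.set_id for r in results if r.significant}
    planted = {rec["pathway_id"] for rec in cohort.truth["enriched_pathways"]
               if rec["arm"] == "above"}

    human_genes = cohort.genes["human"]
    rows = [(m.mirna_id, *m.placements["human"]) for m in cohort.mirnas
            if m.placements.get("human") is not None]
    res = scan_hosts(rows, human_genes, species="human")
    label = host_bias_summary({"human": res}).loc[0, "label"]

    return {
        "densities": densities,
        "significant": significant,
        "planted": planted,
        "host_label": str(label),
    }


def planted_recovery_experiment(n_reps: int = 100, seed: int = 0,
                                config: SyntheticConfig | None = None,
                                alpha: float = 0.05) -> dict:
    """Planted-effect recovery over seeded replicates of the default cohort.

    Reports planted-pathway sensitivity (mean per-replicate recall),
    empirical FDR (pooled false discoveries / pooled discoveries), the
    fraction of replicates where the human CNV density is strictly the
    greatest, and the fraction labelled cnv-biased by the host scan.
    """
    base = config or SyntheticConfig()
    tp = fp = found = 0
    recalls = []
    density_top = 0
    host_biased = 0
    for s in child_seeds(seed, n_reps):
        rep = replicate_metrics(dataclasses.replace(base, rng_seed=s),
                                alpha=alpha)
        hits = rep["significant"] & rep["planted"]
        tp += len(hits)
        fp += len(rep["significant"] - rep["planted"])
        found += len(rep["significant"])
        if rep["planted"]:
            recalls.append(len(hits) / len(rep["planted"]))
        dens = rep["densities"]
        if all(dens["human"] > v for sp, v in dens.items() if sp != "human"):
            density_top += 1
        if rep["host_label"] == "cnv-biased":
            host_biased += 1
    return {
        "n_reps": n_reps,
        "sensitivity": float(np.mean(recalls)) if recalls else float("nan"),
        "empirical_fdr": fp / found if found else 0.0,
        "density_top_fraction": density_top / n_reps,
        "host_bias_fraction": host_biased / n_reps,
    }


def null_config() -> SyntheticConfig:
    """Human-only cohort with no planted effects of any kind."""
    cfg = SyntheticConfig(
        n_species=1,
        planted_site_rate={("human", "CNV"): 0.25, ("human", "nonCNV"): 0.25},
        prolific_mirna_fraction=0.0,
        planted_enriched_pathways=[],
    )
    return cfg


def null_enrichment_experiment(n_reps: int = 200, seed: int = 1,
                               alpha: float = 0.05) -> dict:
    """No-effect control: how often does the enrichment stage fire at all?

    Runs the full predict -> partition -> enrichment path on cohorts with a
    flat planted-site rate and no planted pathways, and reports the
    fraction of replicates with >= 1 significant pathway in either the
    above- or below-mean gene list.
    """
    base = null_config()
    any_sig = 0
    for s in child_seeds(seed, n_reps):
        cohort = generate_cohort(dataclasses.replace(base, rng_seed=s))
        pairs, _ = _cnv_pairs(cohort, "human")
        mean = overall_mean(len(pairs), base.n_mirnas)
        part = partition_genes(pairs, mean, species="human", level="mirna",
                               n_units=base.n_mirnas)
        annotated = set().union(*cohort.pathways.sets.values())
        universe = sorted(
            {g.gene_id for g in cohort.genes["human"] if g.cnv_status == CNV}
            & annotated)
        hit = False
        for genes in (part.above_genes, part.below_genes):
            gene_list = sorted(set(genes) & set(universe))
            _, n_sig = pathway_enrichment(gene_list, universe,
                                          cohort.pathways, alpha=alpha)
            if n_sig:
                hit = True
        any_sig += hit
    return {"n_reps": n_reps, "null_significant_fraction": any_sig / n_reps}
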
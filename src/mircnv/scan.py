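"""Host-gene scanning: which miRNAs reside inside CNV / non-CNV genes.

A miRNA is *hosted* by a gene when its genomic interval is fully contained
within the gene span on the same chromosome (strand-agnostic by default);
an any-overlap mode is available. Counts are tallied per CNV stratum, with
each miRNA counted at most once per stratum even when it sits inside
several genes of that stratum.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .models import CNV, NONCNV, GeneRecord

log = logging.getLogger(__name__)

#: density ratios within [1/SIMILAR_BAND, SIMILAR_BAND] are called "similar"
SIMILAR_BAND = 1.2


@dataclass
class HostScanResult:
    """Per-stratum hosted-miRNA counts for one species."""

    species: str
    n_mirnas_in_cnv: int
    n_cnv_genes: int
    n_mirnas_in_noncnv: int
    n_noncnv_genes: int
    assignments: dict[str, list[str]] = field(default_factory=dict)


def scan_hosts(mirna_intervals: Sequence[tuple[str, str, int, int, str]],
               genes: Sequence[GeneRecord],
               species: str = "",
               containment: bool = True,
               require_strand: bool = False) -> HostScanResult:
    """Scan miRNA loci against gene spans of one species.

    ``mirna_intervals`` rows are (mirna_id, chrom, start, end, strand);
    intergenic miRNAs are simply never assigned. With ``containment`` the
    miRNA must lie fully inside the gene span; otherwise any-base overlap
    suffices. Chromosomes present on one side only produce a warning, not
    an error.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    gene_chroms = set(trees)
    mirna_chroms = {row[1] for row in mirna_intervals}
    for c in sorted(mirna_chroms - gene_chroms):
        log.warning("miRNA chromosome %s absent from gene table", c)

    assignments: dict[str, list[str]] = {}
    hosted_cnv: set[str] = set()
    hosted_noncnv: set[str] = set()
    for mirna_id, chrom, start, end, strand in mirna_intervals:
        tree = trees.get(chrom)
        if tree is None:
            continue
        hosts = []
        for iv in tree.overlap(start, end):
            g: GeneRecord = iv.data
            if containment and not (g.start <= start and end <= g.end):
                continue
            if require_strand and g.strand != strand:
                continue
            hosts.append(g)
        if not hosts:
            continue
        assignments[mirna_id] = sorted(g.gene_id for g in hosts)
        strata = {g.cnv_status for g in hosts}
        if CNV in strata:
            hosted_cnv.add(mirna_id)
        if NONCNV in strata:
            hosted_noncnv.add(mirna_id)

    n_cnv_genes = sum(1 for g in genes if g.cnv_status == CNV)
    return HostScanResult(
        species=species or (genes[0].species if genes else ""),
        n_mirnas_in_cnv=len(hosted_cnv),
        n_cnv_genes=n_cnv_genes,
        n_mirnas_in_noncnv=len(hosted_noncnv),
        n_noncnv_genes=len(genes) - n_cnv_genes,
        assignments=assignments,
    )


def host_bias_summary(results: Mapping[str, HostScanResult],
                      similar_band: float = SIMILAR_BAND) -> pd.DataFrame:
    """Per-species hosted-miRNA densities, their ratio and a sign label.

    Density is hosted miRNAs per gene within each stratum; the ratio is
    CNV density over non-CNV density. Ratios inside
    [1/similar_band, similar_band] are labelled "similar", larger ones
    "cnv-biased", smaller ones "noncnv-biased". Zero denominators give NA
    cells and an "undefined" label.
    """
    if not results:
        raise ValueError("at least one species result required")
    rows = []
    for sp in sorted(results):
        r = results[sp]
        d_cnv = r.n_mirnas_in_cnv / r.n_cnv_genes if r.n_cnv_genes else float("nan")
        d_non = (r.n_mirnas_in_noncnv / r.n_noncnv_genes
                 if r.n_noncnv_genes else float("nan"))
        if d_cnv != d_cnv or d_non != d_non or d_non == 0:
            ratio, label = float("nan"), "undefined"
        else:
            ratio = d_cnv / d_non
            if 1 / similar_band <= ratio <= similar_band:
                label = "similar"
            elif ratio > similar_band:
                label = "cnv-biased"
            else:
                label = "noncnv-biased"
        rows.append((sp, r.n_mirnas_in_cnv, r.n_cnv_genes,
                     r.n_mirnas_in_noncnv, r.n_noncnv_genes,
                     d_cnv, d_non, ratio, label))
    return pd.DataFrame(rows, columns=[
        "species", "mirnas_cnv", "genes_cnv", "mirnas_noncnv", "genes_noncnv",
        "density_cnv", "density_noncnv", "ratio", "label",
    ])
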
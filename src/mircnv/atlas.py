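"""Cross-species atlas of homologous CNV and non-CNV genes.

A gene's CNV status is decided against its *own* species' catalogue of
copy-number-variable regions: any-base overlap (>= 1 bp, strand-agnostic)
makes it CNV. The atlas retains, for each non-human species, exactly the
genes with a human homolog, and summarises per-species CNV / non-CNV counts
in the layout of the classic homolog-distribution table.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .models import CNV, NONCNV, GeneRecord, HomologyGroup

log = logging.getLogger(__name__)


@dataclass
class AtlasSummary:
    """Per-species (n_cnv, n_noncnv) counts of retained homologous genes."""

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sp, n_cnv, n_non, n_cnv + n_non)
            for sp, (n_cnv, n_non) in self.counts.items()
        ]
        return pd.DataFrame(rows, columns=["species", "n_cnv", "n_noncnv", "n_total"])


def assign_cnv_status(genes: Sequence[GeneRecord],
                      cnv_regions: Iterable[tuple[str, int, int]]) -> list[GeneRecord]:
    """Label each gene CNV iff it overlaps >= 1 region by >= 1 base.

    Intervals are 0-based half-open, so a gene [100,200) and a region
    [200,300) do not overlap. Strand is ignored. Returns the same records,
    mutated in place, for chaining; the operation is idempotent.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in cnv_regions:
        if start >= end:
            raise ValueError(f"malformed CNV region {chrom}:{start}-{end}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    for g in genes:
        if g.start >= g.end:
            raise ValueError(
                f"malformed gene interval for {g.gene_id} "
                f"({g.chrom}:{g.start}-{g.end})"
            )
        tree = trees.get(g.chrom)
        g.cnv_status = CNV if tree is not None and tree.overlaps(g.start, g.end) else NONCNV
    return list(genes)


def build_atlas(
    human_genes: Sequence[GeneRecord],
    homology: Sequence[HomologyGroup],
    other_species_genes: Mapping[str, Sequence[GeneRecord]],
    inherit_human_status: bool = False,
) -> tuple[dict[str, list[GeneRecord]], AtlasSummary]:
    """Map human genes through homology groups into a per-species atlas.

    Every retained non-human gene has a human homolog; its classification is
    its own species' ``cnv_status`` (already assigned), unless
    ``inherit_human_status`` forces the human homolog's status onto it.
    Species named by the homology table but lacking a gene table are a hard
    error; genes named by homology but absent from a species' table are
    dropped with a logged count; duplicate gene ids within a species keep
    the first occurrence.
    """
    for g in human_genes:
        if g.cnv_status is None:
            raise ValueError(f"human gene {g.gene_id} lacks cnv_status")

    species_in_homology = sorted(
        {sp for grp in homology for sp in grp.members} - {"human"}
    )
    missing = [sp for sp in species_in_homology if sp not in other_species_genes]
    if missing:
        raise ValueError(
            f"species in homology table without a gene table: {missing}"
        )

    def index_genes(genes: Sequence[GeneRecord], species: str) -> dict[str, GeneRecord]:
        idx: dict[str, GeneRecord] = {}
        dupes = 0
        for g in genes:
            if g.gene_id in idx:
                dupes += 1
                continue
            idx[g.gene_id] = g
        if dupes:
            log.warning("%s: %d duplicate gene ids, first occurrence kept",
                        species, dupes)
        return idx

    human_idx = index_genes(human_genes, "human")
    human_groups = [g for g in homology if "human" in g.members]

    atlas: dict[str, list[GeneRecord]] = {}
    retained_human = {
        grp.members["human"]: human_idx[grp.members["human"]]
        for grp in human_groups
        if grp.members["human"] in human_idx
    }
    atlas["human"] = sorted(retained_human.values(), key=lambda g: g.gene_id)

    for sp in species_in_homology:
        sp_idx = index_genes(other_species_genes[sp], sp)
        kept: dict[str, GeneRecord] = {}
        dropped = 0
        for grp in human_groups:
            gid = grp.members.get(sp)
            if gid is None:
                continue
            rec = sp_idx.get(gid)
            if rec is None:
                dropped += 1
                continue
            if inherit_human_status:
                human_rec = human_idx.get(grp.members["human"])
                if human_rec is not None:
                    rec.cnv_status = human_rec.cnv_status
            if rec.cnv_status is None:
                raise ValueError(f"{sp} gene {gid} lacks cnv_status")
            kept.setdefault(gid, rec)
        if dropped:
            log.info("%s: %d homologous genes without coordinates dropped",
                     sp, dropped)
        atlas[sp] = sorted(kept.values(), key=lambda g: g.gene_id)

    summary = AtlasSummary()
    for sp, genes in atlas.items():
        n_cnv = sum(1 for g in genes if g.cnv_status == CNV)
        summary.counts[sp] = (n_cnv, len(genes) - n_cnv)
    return atlas, summary
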
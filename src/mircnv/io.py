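"""Readers and writers for the flat-file formats the pipeline exchanges.

Formats: FASTA (3'UTRs, mature miRNAs), BED6 (gene / miRNA / CNV-region
coordinates), a three-column homology TSV, GMT gene-set collections, and the
per-site interaction TSV that lets externally produced prediction tables
replace the built-in predictors.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import BindingSite, GeneRecord, HomologyGroup, InteractionPair

log = logging.getLogger(__name__)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
PAIR_COLUMNS = [
    "mirna_id",
    "gene_id",
    "species",
    "utr_offset",
    "site_type",
    "length",
    "predicted_by",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path, *, rna: bool = True) -> dict[str, str]:
    """Read FASTA into {id: sequence}, upper-cased.

    With ``rna=True`` any T is transliterated to U (logged once per file),
    matching the convention that UTRs are handled as sense-strand RNA.
    """
    seqs: dict[str, str] = {}
    saw_t = False
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if rna and "T" in s:
            saw_t = True
            s = s.replace("T", "U")
        seqs[rec.id] = s
    if saw_t:
        log.info("%s: DNA-style sequences transliterated T->U", path)
    return seqs


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- BED6

def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file (0-based half-open) into a DataFrame."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS,
                         dtype={"chrom": str, "name": str, "strand": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED6_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def genes_to_bed(genes: Iterable[GeneRecord]) -> pd.DataFrame:
    rows = [(g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in genes]
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def bed_to_genes(df: pd.DataFrame, species: str) -> list[GeneRecord]:
    return [
        GeneRecord(gene_id=r.name, species=species, chrom=r.chrom,
                   start=int(r.start), end=int(r.end), strand=r.strand)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------- homology TSV

def read_homology_tsv(path: str | Path) -> list[HomologyGroup]:
    """Read the (group_id, species, gene_id) table into homology groups."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"group_id", "species", "gene_id"}
    if not expected <= set(df.columns):
        raise ValueError(
            f"homology table {path}: expected columns {sorted(expected)}, "
            f"found {list(df.columns)}"
        )
    groups: dict[str, HomologyGroup] = {}
    for r in df.itertuples(index=False):
        grp = groups.setdefault(r.group_id, HomologyGroup(group_id=r.group_id))
        grp.members[r.species] = r.gene_id
    return [groups[k] for k in sorted(groups)]


def write_homology_tsv(groups: Iterable[HomologyGroup], path: str | Path) -> None:
    rows = [
        (g.group_id, sp, gid)
        for g in sorted(groups, key=lambda g: g.group_id)
        for sp, gid in sorted(g.members.items())
    ]
    pd.DataFrame(rows, columns=["group_id", "species", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- GMT

@dataclass
class GeneSetCollection:
    """A named collection of gene sets (GMT semantics)."""

    name: str
    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def validate(self) -> None:
        for sid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {sid} in {self.name} is empty")
            if len(genes) != len(set(genes)):
                raise ValueError(f"gene set {sid} in {self.name} has duplicate ids")


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    coll = GeneSetCollection(name=name or Path(path).stem)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: GMT line with <3 fields: {line[:80]!r}")
            sid, desc, genes = parts[0], parts[1], parts[2:]
            coll.sets[sid] = [g for g in genes if g]
            coll.descriptions[sid] = desc
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(coll.sets):
            desc = coll.descriptions.get(sid, "na")
            fh.write("\t".join([sid, desc, *coll.sets[sid]]) + "\n")


# ---------------------------------------------------------------- pairs TSV

def pairs_to_frame(pairs: Iterable[InteractionPair]) -> pd.DataFrame:
    """One row per binding site; the pair key repeats across its sites."""
    rows = []
    for p in sorted(pairs, key=lambda p: p.key):
        tag = ",".join(sorted(p.predicted_by))
        for s in p.sites:
            rows.append((p.mirna_id, p.gene_id, p.species,
                         s.utr_offset, s.site_type, s.length, tag))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def frame_to_pairs(df: pd.DataFrame) -> list[InteractionPair]:
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"interaction table lacks columns: {sorted(missing)}")
    out: dict[tuple[str, str, str], InteractionPair] = {}
    for r in df.itertuples(index=False):
        key = (r.mirna_id, r.gene_id, r.species)
        pair = out.get(key)
        if pair is None:
            pair = InteractionPair(
                mirna_id=r.mirna_id, gene_id=r.gene_id, species=r.species,
                predicted_by=frozenset(str(r.predicted_by).split(",")),
            )
            out[key] = pair
        pair.sites.append(
            BindingSite(int(r.utr_offset), str(r.site_type), int(r.length))
        )
    return [out[k] for k in sorted(out)]


def read_pairs_tsv(path: str | Path) -> list[InteractionPair]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str,
                                                "species": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    return frame_to_pairs(df)


def write_pairs_tsv(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
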
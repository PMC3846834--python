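"""Core domain records shared by every pipeline stage.

Coordinates are 0-based half-open throughout (BED convention). Sequences are
RNA, 5'->3', over the alphabet {A, C, G, U}; DNA input is transliterated on
read. A gene is *CNV* when its genomic span overlaps at least one catalogued
copy-number-variable region of its own species, *nonCNV* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CNV = "CNV"
NONCNV = "nonCNV"

RNA_ALPHABET = frozenset("ACGU")

#: canonical species keys, human first (the reference lineage of the analysis)
SPECIES = (
    "human",
    "chimpanzee",
    "macaque",
    "mouse",
    "rat",
    "chicken",
    "dog",
    "cow",
)


@dataclass
class GeneRecord:
    """One gene in one species: coordinates, CNV status and its 3'UTR."""

    gene_id: str
    species: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    cnv_status: str | None = None
    utr_seq: str | None = None

    def validate(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id} ({self.species}): start {self.start} "
                f">= end {self.end}"
            )
        if self.utr_seq is not None and not set(self.utr_seq) <= RNA_ALPHABET:
            bad = sorted(set(self.utr_seq) - RNA_ALPHABET)
            raise ValueError(f"gene {self.gene_id}: non-ACGU characters {bad} in UTR")

    @property
    def interval(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class HomologyGroup:
    """Cross-species mapping of one gene, keyed by its human member.

    ``members`` maps a species key to at most one gene id; a group used in
    the atlas always names a human member.
    """

    group_id: str
    members: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if "human" not in self.members:
            raise ValueError(f"homology group {self.group_id} lacks a human member")


@dataclass
class MiRNA:
    """A mature miRNA with optional per-species genomic placements.

    ``family_key`` is the 7-nt seed (mature positions 2-8); miRNAs sharing
    it are one family. ``placements`` maps species -> (chrom, start, end,
    strand) for intragenic/intergenic loci, or None when the miRNA has no
    locus in that species.
    """

    mirna_id: str
    mature_seq: str
    placements: dict[str, tuple[str, int, int, str] | None] = field(default_factory=dict)

    @property
    def family_key(self) -> str:
        return self.mature_seq[1:8]

    def validate(self) -> None:
        if not 18 <= len(self.mature_seq) <= 30:
            raise ValueError(
                f"{self.mirna_id}: mature sequence length {len(self.mature_seq)} "
                "outside 18-30 nt"
            )
        if not set(self.mature_seq) <= RNA_ALPHABET:
            raise ValueError(f"{self.mirna_id}: mature sequence is not ACGU RNA")


@dataclass(frozen=True)
class BindingSite:
    """One predicted site inside a UTR.

    ``site_type`` is one of the canonical seed classes (``8mer``,
    ``7mer-m8``, ``7mer-A1``) or ``walk-k`` for a k-nt 5'-complementarity
    run.
    """

    utr_offset: int
    site_type: str
    length: int


@dataclass
class InteractionPair:
    """One (miRNA, gene) prediction with its sites and provenance."""

    mirna_id: str
    gene_id: str
    species: str
    sites: list[BindingSite] = field(default_factory=list)
    predicted_by: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mirna_id, self.gene_id, self.species)
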
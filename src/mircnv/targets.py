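"""miRNA binding-site prediction in 3'UTRs with two independent algorithms.

Two deterministic predictors are run over every (miRNA, UTR) combination and
their outputs are intersected at the (miRNA, gene) pair level, the standard
strategy for suppressing false-positive target calls:

* a canonical *seed* predictor reporting 8mer, 7mer-m8 and 7mer-A1 sites
  (perfect Watson-Crick complement of the miRNA seed, with or without an A
  opposite miRNA position 1), and
* a *walk* predictor reporting, for each UTR locus, the longest consecutive
  Watson-Crick complementary run of the miRNA 5' end (anchored at mature
  position 1 or 2), reported when the run reaches ``min_len`` nucleotides.

G:U wobble pairs are not allowed in either predictor. Pairs surviving the
intersection carry the union of both predictors' sites.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence

from .models import BindingSite, GeneRecord, InteractionPair, MiRNA, RNA_ALPHABET

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _comp(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (A:U, G:C)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_utr(utr: str) -> None:
    if not set(utr) <= RNA_ALPHABET:
        for i, ch in enumerate(utr):
            if ch not in RNA_ALPHABET:
                raise ValueError(f"non-ACGU character {ch!r} in UTR at offset {i}")


def mirna_family(mature_seq: str) -> str:
    """Family key of a mature miRNA: its seed, nucleotides 2-8 (1-based).

    miRNAs sharing the key form one family; position 1 never contributes.
    """
    if len(mature_seq) < 8:
        raise ValueError(
            f"mature sequence of length {len(mature_seq)} < 8 nt has no seed"
        )
    return mature_seq[1:8]


def _find_all(pattern: str, text: str) -> list[int]:
    """All (possibly overlapping) start offsets of pattern in text."""
    hits = []
    i = text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits


def predict_seed_sites(mirna: MiRNA | str, utr: str) -> list[BindingSite]:
    """Canonical seed-match sites of one miRNA in one UTR.

    Site definitions (on the sense-strand UTR, 5'->3'):

    * ``8mer``    : reverse complement of seed positions 2-8, followed by A
    * ``7mer-m8`` : reverse complement of seed positions 2-8
    * ``7mer-A1`` : reverse complement of positions 2-7, followed by A

    When an 8mer occurs, the two 7mers nested at the same locus are
    suppressed (longest type wins). Sites are returned sorted by offset.
    """
    seq = mirna.mature_seq if isinstance(mirna, MiRNA) else mirna
    if len(seq) < 8:
        raise ValueError("miRNA shorter than 8 nt has no seed")
    if len(utr) < 7:
        raise ValueError("UTR shorter than 7 nt cannot carry a seed site")
    _check_utr(utr)

    m8 = revcomp(seq[1:8])          # 7 nt
    mer8 = m8 + "A"                  # 8 nt
    a1 = revcomp(seq[1:7]) + "A"     # 7 nt

    eight_offsets = set(_find_all(mer8, utr))
    sites = [BindingSite(o, "8mer", 8) for o in eight_offsets]
    sites += [
        BindingSite(o, "7mer-m8", 7)
        for o in _find_all(m8, utr)
        if o not in eight_offsets
    ]
    # a 7mer-A1 at offset o is nested in an 8mer starting one base earlier
    sites += [
        BindingSite(o, "7mer-A1", 7)
        for o in _find_all(a1, utr)
        if o - 1 not in eight_offsets
    ]
    return sorted(sites, key=lambda s: (s.utr_offset, s.site_type))


def predict_walk_sites(mirna: MiRNA | str, utr: str,
                       min_len: int = 7) -> list[BindingSite]:
    """Longest 5'-end complementarity runs of one miRNA in one UTR.

    For each UTR locus the maximal k is found such that miRNA positions
    1..k (or 2..k+1; both anchor modes are scanned) pair antiparallel and
    Watson-Crick with the UTR. A ``walk-k`` site is emitted when
    k >= ``min_len``; when both anchors produce a run at the same offset
    only the maximal k is reported.
    """
    seq = mirna.mature_seq if isinstance(mirna, MiRNA) else mirna
    if min_len < 5:
        raise ValueError("min_len below 5 is not meaningful")
    _check_utr(utr)

    best: dict[int, int] = {}   # utr offset -> max run length
    for anchor in (0, 1):
        max_k = len(seq) - anchor
        if max_k < min_len:
            continue
        core = revcomp(seq[anchor:anchor + min_len])
        for o in _find_all(core, utr):
            # extending the run prepends complements of further miRNA bases
            k, left = min_len, o
            while k < max_k and left > 0 and utr[left - 1] == _comp(seq[anchor + k]):
                left -= 1
                k += 1
            if best.get(left, 0) < k:
                best[left] = k
    return [
        BindingSite(o, f"walk-{k}", k) for o, k in sorted(best.items())
    ]


def _dedup_sites(sites: Iterable[BindingSite]) -> list[BindingSite]:
    seen = {}
    for s in sites:
        seen.setdefault((s.utr_offset, s.site_type), s)
    return [seen[k] for k in sorted(seen)]


def intersect_predictions(walk_pairs: Sequence[InteractionPair],
                          seed_pairs: Sequence[InteractionPair],
                          check_species: bool = True) -> list[InteractionPair]:
    """Keep exactly the (miRNA, gene, species) pairs found by both predictors.

    Retained pairs carry the union of their sites from both sides,
    deduplicated on (offset, site type), with provenance {walk, seed}.
    ``check_species`` rejects input lists whose species sets differ, the
    usual sign of mismatched prediction tables.
    """
    if check_species and walk_pairs and seed_pairs:
        sp_w = {p.species for p in walk_pairs}
        sp_s = {p.species for p in seed_pairs}
        if sp_w != sp_s:
            raise ValueError(
                f"species mismatch between prediction lists: {sorted(sp_w)} "
                f"vs {sorted(sp_s)}"
            )
    walk_by_key = {p.key: p for p in walk_pairs}
    out = []
    for sp in seed_pairs:
        wp = walk_by_key.get(sp.key)
        if wp is None:
            continue
        out.append(InteractionPair(
            mirna_id=sp.mirna_id, gene_id=sp.gene_id, species=sp.species,
            sites=_dedup_sites([*wp.sites, *sp.sites]),
            predicted_by=frozenset({"walk", "seed"}),
        ))
    return sorted(out, key=lambda p: p.key)


def collapse_families(pairs: Sequence[InteractionPair],
                      mirnas: Sequence[MiRNA]) -> list[InteractionPair]:
    """Collapse miRNA-level pairs to family level.

    A family targets a gene iff at least one member does; the family pair
    carries the deduplicated union of member sites and uses the 7-nt seed
    as its identifier.
    """
    fam_of = {m.mirna_id: m.family_key for m in mirnas}
    grouped: dict[tuple[str, str, str], list[InteractionPair]] = defaultdict(list)
    for p in pairs:
        fam = fam_of.get(p.mirna_id)
        if fam is None:
            raise KeyError(f"pair references unknown miRNA {p.mirna_id}")
        grouped[(fam, p.gene_id, p.species)].append(p)
    out = []
    for (fam, gene, species), members in grouped.items():
        out.append(InteractionPair(
            mirna_id=fam, gene_id=gene, species=species,
            sites=_dedup_sites(s for m in members for s in m.sites),
            predicted_by=frozenset().union(*(m.predicted_by for m in members)),
        ))
    return sorted(out, key=lambda p: p.key)


def predict_all(mirnas: Sequence[MiRNA], genes: Sequence[GeneRecord],
                min_len: int = 7) -> tuple[list[InteractionPair], list[InteractionPair]]:
    """Run both predictors over every (miRNA, gene) combination and intersect.

    Only genes with a UTR are scanned. Returns (miRNA-level pairs,
    family-level pairs). The walk scan is evaluated only where the seed
    scan found at least one site: the intersection is a subset of the seed
    side, so the result is identical and the quadratic scan stays cheap.
    """
    seed_pairs: list[InteractionPair] = []
    walk_pairs: list[InteractionPair] = []
    scanned = [g for g in genes if g.utr_seq]
    for m in mirnas:
        for g in scanned:
            s_sites = predict_seed_sites(m.mature_seq, g.utr_seq)
            if not s_sites:
                continue
            seed_pairs.append(InteractionPair(
                m.mirna_id, g.gene_id, g.species, s_sites, frozenset({"seed"})))
            w_sites = predict_walk_sites(m.mature_seq, g.utr_seq, min_len=min_len)
            if w_sites:
                walk_pairs.append(InteractionPair(
                    m.mirna_id, g.gene_id, g.species, w_sites, frozenset({"walk"})))
    pairs = intersect_predictions(walk_pairs, seed_pairs, check_species=False)
    families = collapse_families(pairs, mirnas)
    return pairs, families
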
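"""Interaction densities, overall means, the above/below-mean partition and
the 3'UTR-length control.

The central quantity is the *overall mean*: total intersected (miRNA, gene)
interactions divided by the number of miRNAs (or families) considered. Each
unit whose target count exceeds the overall mean is classed "above", the
rest (ties included) "below"; the above/below *gene* lists are the unions of
the targets of the corresponding units and may overlap — a gene can be
targeted by both kinds of unit.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats as sps

from .models import CNV, GeneRecord, InteractionPair

log = logging.getLogger(__name__)


@dataclass
class PartitionResult:
    """Above/below-mean partition of targeting units and their gene lists."""

    species: str
    level: str                      # "mirna" or "family"
    n_units: int                    # denominator of the overall mean
    total_pairs: int
    overall_mean: float
    above_units: list[str] = field(default_factory=list)
    below_units: list[str] = field(default_factory=list)
    above_genes: list[str] = field(default_factory=list)
    below_genes: list[str] = field(default_factory=list)
    target_counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.above_units) & set(self.below_units):
            raise AssertionError("a unit appears in both partition classes")
        with_targets = {u for u, c in self.target_counts.items() if c >= 1}
        if set(self.above_units) | set(self.below_units) != with_targets:
            raise AssertionError("partition does not cover all units with targets")


def per_gene_density(pairs: Sequence[InteractionPair] | int, n_genes: int) -> float:
    """Interactions per gene: total pair count / ``n_genes``."""
    if n_genes == 0:
        raise ZeroDivisionError("n_genes must be >= 1")
    n_pairs = pairs if isinstance(pairs, int) else len(pairs)
    return n_pairs / n_genes


def overall_mean(pairs: Sequence[InteractionPair] | int, n_units: int) -> float:
    """Mean targets per unit: total pair count / ``n_units``.

    Reported at full precision; round to 2 decimals for display.
    """
    if n_units == 0:
        raise ZeroDivisionError("n_units must be >= 1")
    n_pairs = pairs if isinstance(pairs, int) else len(pairs)
    return n_pairs / n_units


def partition_genes(pairs: Sequence[InteractionPair], mean: float,
                    species: str = "", level: str = "mirna",
                    n_units: int | None = None,
                    tie_rule: str = "below") -> PartitionResult:
    """Split targeting units at the overall-mean cut-off.

    A unit is "above" when its distinct-gene target count is strictly
    greater than ``mean`` (with ``tie_rule="inclusive"``, greater or equal);
    everything else with >= 1 target is "below". ``pairs`` is expected to
    already be at the requested level (family-level pairs use the family key
    as ``mirna_id``).
    """
    if mean < 0:
        raise ValueError("overall mean must be >= 0")
    if tie_rule not in ("below", "inclusive"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    targets: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        targets[p.mirna_id].add(p.gene_id)
    counts = {u: len(gs) for u, gs in targets.items()}

    def is_above(c: int) -> bool:
        return c > mean if tie_rule == "below" else c >= mean

    above = sorted(u for u, c in counts.items() if is_above(c))
    below = sorted(u for u, c in counts.items() if not is_above(c))
    above_genes = sorted(set().union(*(targets[u] for u in above)) if above else set())
    below_genes = sorted(set().union(*(targets[u] for u in below)) if below else set())
    res = PartitionResult(
        species=species, level=level,
        n_units=n_units if n_units is not None else len(counts),
        total_pairs=len(pairs), overall_mean=mean,
        above_units=above, below_units=below,
        above_genes=above_genes, below_genes=below_genes,
        target_counts=counts,
    )
    res.validate()
    return res


def partition_to_frame(res: PartitionResult) -> pd.DataFrame:
    rows = [
        (u, res.level, res.target_counts[u], cls)
        for cls, units in (("above", res.above_units), ("below", res.below_units))
        for u in units
    ]
    rows.sort()
    return pd.DataFrame(rows, columns=["unit_id", "level", "target_count", "class"])


def utr_length_comparison(atlas: Mapping[str, Sequence[GeneRecord]],
                          ) -> tuple[pd.DataFrame, float]:
    """Compare normalized CNV-gene 3'UTR lengths across species.

    Each species' CNV-gene UTR lengths are divided by that species'
    all-gene mean UTR length (so a uniformly longer-UTR genome is not
    flagged); a Kruskal-Wallis omnibus test across species is reported.
    Species without UTRs are excluded with a warning; with fewer than two
    usable species, or degenerate data, the p-value is NaN.
    """
    rows = []
    groups = []
    for sp in sorted(atlas):
        lengths = [len(g.utr_seq) for g in atlas[sp] if g.utr_seq]
        cnv_lengths = [len(g.utr_seq) for g in atlas[sp]
                       if g.utr_seq and g.cnv_status == CNV]
        if not lengths or not cnv_lengths:
            log.warning("species %s has no usable UTRs; excluded from control", sp)
            continue
        sp_mean = sum(lengths) / len(lengths)
        normed = [x / sp_mean for x in cnv_lengths]
        rows.append((sp, len(cnv_lengths), sp_mean,
                     sum(normed) / len(normed)))
        groups.append(normed)
    df = pd.DataFrame(rows, columns=["species", "n_cnv_utrs",
                                     "mean_utr_length", "normalized_cnv_mean"])
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        return df, float("nan")
    flat = [x for g in groups for x in g]
    if all(x == flat[0] for x in flat):      # zero variance everywhere
        return df, float("nan")
    _, p = sps.kruskal(*groups)
    return df, float(p)
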
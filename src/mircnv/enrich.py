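"""Gene-set enrichment, curated-class counting and binding-site
overrepresentation analysis.

Pathway enrichment is a one-sided Fisher's exact test (enrichment
alternative) per gene set, with Benjamini-Hochberg correction across the
sets tested and a 5% significance level on the adjusted values. The
binding-site ORA compares per-gene site densities (site count / UTR length)
between the members and non-members of a set with a one-sided rank-sum
test; a Fisher test on median-thresholded densities is available as a
variant.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .models import CNV, GeneRecord, InteractionPair

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One gene set's 2x2 table, raw and BH-adjusted p-value."""

    set_id: str
    a: int      # in list and in set
    b: int      # in list, not in set
    c: int      # not in list, in set
    d: int      # neither
    p_raw: float
    p_adj: float = float("nan")
    significant: bool = False


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher's exact p-value for enrichment: P(X >= a).

    X is hypergeometric with the table's margins fixed: population
    N = a+b+c+d, K = a+c successes, n = a+b draws.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 counts must be non-negative")
    n_total = a + b + c + d
    if n_total < 1:
        raise ValueError("empty 2x2 table")
    return float(sps.hypergeom.sf(a - 1, n_total, a + c, a + b))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


def pathway_enrichment(gene_list: Sequence[str], background: Sequence[str],
                       collection: GeneSetCollection,
                       alpha: float = 0.05) -> tuple[list[EnrichmentResult], int]:
    """Fisher + BH enrichment of ``gene_list`` against each set.

    ``background`` is the gene universe; the list must be a subset of it.
    Only sets intersecting the background are tested. Returns the per-set
    results (sorted by set id; BH across exactly the tested sets) and the
    number of significant sets at ``alpha`` on adjusted values.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    lst = set(gene_list)
    stray = lst - bg
    if stray:
        raise ValueError(
            f"{len(stray)} genes in list but not background, e.g. "
            f"{sorted(stray)[:5]}"
        )
    results = []
    for sid in sorted(collection.sets):
        members = set(collection.sets[sid]) & bg
        if not members:
            continue
        a = len(lst & members)
        b = len(lst) - a
        c = len(members) - a
        d = len(bg) - a - b - c
        results.append(EnrichmentResult(sid, a, b, c, d,
                                        fisher_exact_greater(a, b, c, d)))
    if results:
        adj = bh_adjust([r.p_raw for r in results])
        for r, pa in zip(results, adj):
            r.p_adj = pa
            r.significant = pa <= alpha
    return results, sum(r.significant for r in results)


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [(r.set_id, r.a, r.b, r.c, r.d, r.p_raw, r.p_adj, r.significant)
            for r in results]
    return pd.DataFrame(rows, columns=["set_id", "a", "b", "c", "d",
                                       "p_raw", "p_adj", "significant"])


def heatmap_matrix(results_by_species: Mapping[str, Sequence[EnrichmentResult]],
                   mode: str = "binary",
                   ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Set x species significance matrix plus the species-specific report.

    Rows are the union of sets significant anywhere; values are 0/1
    indicators (``mode="binary"``) or -log10 adjusted p for significant
    cells (``mode="neglog10"``). A set is *specific* to a species when it
    is significant there and in no other species.
    """
    if not results_by_species:
        raise ValueError("at least one species required")
    sig: dict[str, dict[str, float]] = defaultdict(dict)
    for sp, results in results_by_species.items():
        for r in results:
            if r.significant:
                sig[r.set_id][sp] = r.p_adj
    species = sorted(results_by_species)
    set_ids = sorted(sig)
    mat = pd.DataFrame(0.0, index=set_ids, columns=species)
    for sid, by_sp in sig.items():
        for sp, p_adj in by_sp.items():
            if mode == "binary":
                mat.loc[sid, sp] = 1.0
            elif mode == "neglog10":
                mat.loc[sid, sp] = -math.log10(max(p_adj, 1e-300))
            else:
                raise ValueError(f"unknown mode {mode!r}")
    specific = {
        sp: sorted(sid for sid in set_ids
                   if set(sig[sid]) == {sp})
        for sp in species
    }
    return mat, specific


def classify_genes(atlas: Mapping[str, Sequence[GeneRecord]],
                   classes: GeneSetCollection) -> pd.DataFrame:
    """Per species and curated class, count CNV and non-CNV atlas genes.

    Multi-class genes count once per class. Class genes absent from the
    atlas are skipped (the count is an intersection); a class with an empty
    intersection yields (0, 0) with a warning.
    """
    rows = []
    for sp in sorted(atlas):
        status = {g.gene_id: g.cnv_status for g in atlas[sp]}
        for cid in sorted(classes.sets):
            hit = [status[g] for g in classes.sets[cid] if g in status]
            if not hit:
                log.warning("class %s has no genes in the %s atlas", cid, sp)
            n_cnv = sum(1 for s in hit if s == CNV)
            rows.append((sp, cid, n_cnv, len(hit) - n_cnv))
    return pd.DataFrame(rows, columns=["species", "class_id", "n_cnv", "n_noncnv"])


def site_density(pairs: Sequence[InteractionPair],
                 utr_lengths: Mapping[str, int]) -> dict[str, float]:
    """Per-gene binding-site density: total site count / UTR length.

    Genes present in ``utr_lengths`` but in no pair have density 0.
    """
    counts: dict[str, int] = defaultdict(int)
    for p in pairs:
        counts[p.gene_id] += len(p.sites)
    return {g: counts.get(g, 0) / utr_lengths[g] for g in utr_lengths}


def binding_site_ora(pairs: Sequence[InteractionPair],
                     member_genes: Sequence[str],
                     nonmember_genes: Sequence[str],
                     utr_lengths: Mapping[str, int],
                     method: str = "ranksum") -> float:
    """Overrepresentation of binding sites inside one gene set.

    Compares per-gene site densities between members and non-members,
    one-sided (members greater). ``method="ranksum"`` uses Mann-Whitney U;
    ``method="fisher"`` thresholds densities at the pooled median and runs
    the one-sided Fisher test. Groups with < 2 genes, or zero variance
    overall, yield NaN with a warning rather than an error.
    """
    if not member_genes or not nonmember_genes:
        raise ValueError("both gene groups must be non-empty")
    dens = site_density(pairs, utr_lengths)
    x = [dens[g] for g in member_genes if g in dens]
    y = [dens[g] for g in nonmember_genes if g in dens]
    if len(x) < 2 or len(y) < 2:
        log.warning("ORA group with < 2 usable genes; returning NaN")
        return float("nan")
    if len(set(x) | set(y)) == 1:
        log.warning("ORA densities are constant; returning NaN")
        return float("nan")
    if method == "ranksum":
        _, p = sps.mannwhitneyu(x, y, alternative="greater")
        return float(p)
    if method == "fisher":
        med = float(np.median(x + y))
        a = sum(1 for v in x if v > med)
        b = len(x) - a
        c = sum(1 for v in y if v > med)
        d = len(y) - c
        return fisher_exact_greater(a, b, c, d)
    raise ValueError(f"unknown ORA method {method!r}")


def ora_across_sets(pairs: Sequence[InteractionPair],
                    collection: GeneSetCollection,
                    universe: Sequence[str],
                    utr_lengths: Mapping[str, int],
                    method: str = "ranksum",
                    alpha: float = 0.05) -> pd.DataFrame:
    """Run the binding-site ORA for every set, with BH across sets."""
    uni = sorted(set(universe))
    rows = []
    for sid in sorted(collection.sets):
        members = sorted(set(collection.sets[sid]) & set(uni))
        nonmembers = sorted(set(uni) - set(members))
        if not members or not nonmembers:
            rows.append((sid, len(members), float("nan")))
            continue
        p = binding_site_ora(pairs, members, nonmembers, utr_lengths,
                             method=method)
        rows.append((sid, len(members), p))
    df = pd.DataFrame(rows, columns=["set_id", "n_members", "p_raw"])
    ok = df["p_raw"].notna()
    df["p_adj"] = float("nan")
    if ok.any():
        df.loc[ok, "p_adj"] = bh_adjust(df.loc[ok, "p_raw"].tolist())
    df["significant"] = df["p_adj"] <= alpha
    return df
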
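# mircnv

Cross-species analysis of microRNA regulation of genes in copy-number-variable
(CNV) regions.

Genes inside CNV regions are dosage-variable, and one long-standing hypothesis
in regulatory genomics is that miRNAs buffer that variability: CNV genes are
targeted by more miRNAs and carry more binding sites than non-CNV genes, and
this coupling is strongest in the human lineage. `mircnv` implements the full
comparative pipeline needed to interrogate that hypothesis across several
genomes (human plus up to seven other vertebrates), for computational
biologists who want the analysis as tested, reusable, seed-reproducible code
rather than a chain of one-off scripts:

1. **Homolog atlas** — map human CNV/non-CNV genes through a HomoloGene-style
   table; each species' genes are classified against its *own* CNV regions
   (any-base overlap, 0-based half-open BED coordinates).
2. **Dual-predictor target scan** — two independent, deterministic miRNA
   target predictors over every (miRNA, 3'UTR) combination: a canonical seed
   matcher (8mer, 7mer-m8, 7mer-A1 — perfect Watson–Crick complement of
   miRNA positions 2–8, with or without an A opposite position 1) and a
   5'-complementarity walk (longest consecutive paired run anchored at mature
   position 1 or 2, reported at length ≥ 7). Only pairs found by **both**
   algorithms are kept, the standard false-positive screen.
3. **Interaction statistics** — per-gene interaction densities, the overall
   mean μ = (total pairs)/(number of miRNAs), and the partition of targeting
   units into *above-mean* and *below-mean* classes (count > μ is above; ties
   below) with their target-gene lists, at miRNA and seed-family level.
4. **Enrichment** — one-sided Fisher's exact test per gene set
   (P(X ≥ a) under the hypergeometric law with fixed margins), Benjamini–
   Hochberg correction, α = 0.05 on adjusted values; a set × species
   significance matrix with a species-specific-pathway report; curated-class
   CNV/non-CNV counts; and a binding-site overrepresentation analysis
   comparing per-gene site densities (sites / UTR length) between set members
   and non-members with a one-sided rank-sum test.
5. **Host-gene scan** — which miRNA loci are contained inside CNV vs non-CNV
   gene spans, with per-stratum densities and a cnv-biased / similar /
   noncnv-biased call (ratio band 1.2×).

A first-class **synthetic cohort generator** emulates the whole data regime —
homology groups, per-species CNV assignment, random UTRs with exact planted
8mer sites, miRNA families, biased intragenic miRNA placement, planted
enriched pathways — and records every planted effect in a machine-readable
truth file, so the entire pipeline is testable end-to-end without any
database downloads. Real data in standard formats (FASTA, BED6, TSV, GMT)
drops into the same interfaces, and externally produced prediction tables
can replace the built-in predictors via the per-site interaction TSV.

## Worked example

The headline human statistic of the analysis is the overall mean number of
CNV-gene targets per miRNA. With the published human inputs — 436,972
intersected miRNA–target interactions across 820 miRNAs:

```python
>>> from mircnv.stats import overall_mean
>>> round(overall_mean(436_972, 820), 2)
532.89
```

End-to-end on a synthetic eight-species cohort (one command, ~2 s):

```bash
mircnv run -o demo --seed 9
mircnv report -w demo
```

prints, among other tables,

```
== means.tsv ==          (human rows)
species  level  total_pairs  n_units  overall_mean  mean_2dp
  human  mirna          658       50     13.160000     13.16
  human family          543       44     12.340909     12.34

== density.tsv ==
species     n_pairs  n_cnv_genes  density
human           658          191  3.445026    <- strict maximum
chimpanzee      204          173  1.179191
mouse           245          182  1.346154
...
```

The human CNV stratum shows the highest interactions-per-gene density — the
planted analogue of the cross-species pattern the pipeline is built to
detect. The pathway heat map (`heatmap.tsv`) marks the three planted
pathways significant in human and in no other species, and
`species_specific.tsv` lists them as human-specific; `host_scan.tsv` labels
the human genome `cnv-biased` (density ratio 3.54 in this run) because the
generator placed 80% of intragenic miRNAs inside CNV genes.

Every stage is also available as a subcommand (`generate`, `atlas`,
`predict`, `partition`, `enrich`, `scan`, `report`) over a shared working
directory, and as plain library functions.

## Layout

```
src/mircnv/
  models.py      shared domain records (genes, homology groups, miRNAs, pairs)
  io.py          FASTA / BED6 / homology TSV / GMT / interaction-TSV readers+writers
  synthetic.py   cohort generator with planted effects and truth record
  atlas.py       CNV-status assignment and homolog atlas
  targets.py     seed + walk predictors, intersection, family collapse
  stats.py       densities, overall means, above/below partition, UTR control
  enrich.py      Fisher/BH enrichment, heat map, class counts, binding-site ORA
  scan.py        host-gene containment scan and bias summary
  evaluation.py  replicate experiments (planted recovery, null control)
  pipeline.py    stage orchestration, manifest, reproducibility
  cli.py         `mircnv` command-line interface
```

See `docs/methods.md` for the statistical model, generator design and
numerical conventions.
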
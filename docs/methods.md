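# Methods

## The analysis model

The pipeline asks whether genes residing in copy-number-variable (CNV)
regions receive more miRNA-mediated regulation than non-CNV genes, and
whether that coupling differs between species. Its observable unit is the
*interaction pair*: one (miRNA, gene) combination predicted as a target
relationship, carrying one or more binding sites in the gene's 3'UTR.

**CNV status.** A gene is CNV iff its genomic span overlaps a catalogued CNV
region of its own species by at least one base. Coordinates are 0-based
half-open throughout, so abutting intervals do not overlap. Overlap is
strand-agnostic (CNV catalogues are region memberships, not stranded
features). A fallback that copies the human homolog's status onto other
species exists behind a flag but is off by default, since per-species CNV
catalogues are the norm.

**Target prediction.** Two deterministic predictors scan every (miRNA, UTR)
combination; only pairs reported by both are retained. The *seed* predictor
reports canonical site types on the sense-strand UTR: `8mer` (reverse
complement of mature positions 2–8 followed by A), `7mer-m8` (the same
7-mer without the A), `7mer-A1` (reverse complement of positions 2–7
followed by A); when an 8mer occurs, the two 7mers nested at the same locus
are suppressed. The *walk* predictor reports, per UTR locus, the longest
consecutive Watson–Crick complementary run of the miRNA 5' end, anchored at
mature position 1 or 2 (maximal run length per locus, reported when
k ≥ `min_len`, default 7 — the conventional minimum for 5'-dominant sites).
G:U wobble is disallowed in both predictors; this keeps the predictors
consistent with canonical seed-site definitions and makes them exactly
checkable against brute-force scans. Because every 8mer/7mer-m8 contains a
7-nt anchor-2 run, canonical sites are a subset of walk sites, so the
intersection never loses a planted canonical site. The intersection is at
pair level, not site level (site coordinate systems of heterogeneous
predictors are not commensurable); retained pairs carry the deduplicated
union of both predictors' sites. DNA input is transliterated T→U on read.
The widely used web resources that motivate the two-predictor design are
consumed products, not redistributable algorithms; the two scanners here
are documented, deterministic stand-ins, and externally produced prediction
tables can be injected through the per-site interaction TSV instead.

**Families.** A miRNA family is the set of miRNAs sharing mature positions
2–8 (the seed). A family targets a gene iff at least one member does, so
family-level pair counts never exceed miRNA-level counts.

**Partition.** For each species the overall mean is
μ = total pairs / number of units, where units are all catalogued miRNAs
(or families), not only those with targets — mirroring the convention of
dividing by the full miRNA catalogue. A unit is *above* the cut-off when
its distinct-gene target count strictly exceeds μ; ties go below (an
inclusive tie rule is available). The above/below *gene* lists are unions
of the corresponding units' targets and may overlap, deliberately: a gene
can be targeted by both kinds of unit, and enrichment is reported for both
lists. The cut-off itself is the overall mean; no further threshold is
applied.

**Enrichment.** One-sided Fisher's exact test per gene set:
p = P(X ≥ a) for X hypergeometric with the 2×2 margins fixed
(implemented via `scipy.stats.hypergeom.sf`; verified in the tests against
exhaustive integer enumeration of every table with total ≤ 40).
Benjamini–Hochberg step-up across exactly the sets tested
(`statsmodels.multipletests`, cross-checked against an independently coded
step-up), significance at α = 0.05 on adjusted values. The default
universe is the species' CNV genes appearing in at least one pathway
("annotated"); an all-CNV-genes universe is available. Sidedness, α and
universe are explicit configuration, since gene-set analyses are sensitive
to all three.

**Binding-site overrepresentation (ORA).** Per-gene site density = total
predicted sites / UTR length. For each set, densities of member vs
non-member CNV genes are compared with a one-sided Mann–Whitney U test
(members greater), BH across sets; a variant thresholds densities at the
pooled median and applies the one-sided Fisher test. Groups with fewer
than two usable genes, or zero variance, return NaN rather than failing.
The rank-sum density comparison is this package's documented choice of ORA
mechanics; both variants are provided because the choice is genuinely open.

**Host scan.** A miRNA is hosted by a gene when its locus is fully
contained in the gene span on the same chromosome; containment (rather
than any overlap) is the default reading of "within a gene", with an
any-overlap mode behind a flag. Strand is ignored by default (many miRNAs
are antisense to their hosts). A miRNA inside genes of both strata counts
once in each stratum. Per-stratum density is hosted miRNAs per gene;
the CNV/non-CNV density ratio is labelled *similar* inside
[1/1.2, 1.2] — a deliberately simple band that reproduces the qualitative
three-way classification (cnv-biased / similar / noncnv-biased) — and the
band is configurable.

**UTR-length control.** Cross-species density comparisons could be
confounded by UTR length. Each species' CNV-gene UTR lengths are divided
by that species' all-gene mean length, and a Kruskal–Wallis omnibus test is
run across species on the normalized values. Mean-scaling is the
normalization; it is configurable in the sense that the unnormalized
lengths are retained in the output.

## The synthetic cohort generator

The generator produces the full input regime with known ground truth. What
it emulates: homologous gene groups over up to eight species (human always
present; other species carry a group with probability 0.9); per-species CNV
assignment with fractions matched to the relative magnitudes of real
homolog-distribution tables (≈ 0.47–0.58); one 3'UTR per gene,
i.i.d.-uniform over {A,C,G,U}; mature miRNAs of 21–25 nt with 10% seed
reuse (families); intragenic miRNA loci (70% of miRNAs) placed inside CNV
hosts with a per-species bias; pathway and curated-class GMTs over human
gene ids, with homologs sharing one symbol across species.

Planted effects, all recorded in `truth.json`:

* **Sites.** Per-gene planted site counts are Poisson with a
  per-(species, CNV-status) rate — default 0.8 for human-CNV, 0.2
  elsewhere — and each planted site is the exact canonical 8mer of a
  chosen miRNA's seed, inserted verbatim at non-overlapping uniform
  offsets. Configurations whose expected site footprint exceeds the mean
  UTR length are rejected.
* **Above-mean structure.** A designated *prolific* subset of miRNAs (20%)
  receives extra sites concentrated in a *hot* pool of human CNV genes
  (25% of them, each prolific miRNA hitting each hot gene with
  probability 0.5). This drives prolific miRNAs above the overall mean and
  makes hot genes the core of the above-mean gene list. Rate-planted
  background sites are drawn from the non-prolific pool so that they do
  not blur this separation.
* **Enriched pathways.** A planted pathway with arm `above` draws a
  configured fraction (default 1.0) of its members from the hot pool, and
  is therefore overrepresented in the above-mean list that the *real*
  partition computes. Arm `below` draws from the non-hot pool; it is
  supported but has little power at default scale, because the below list
  is a union over many units and covers most of the universe — the default
  configuration therefore plants above-armed pathways only. Pathways are
  sampled without replacement from the human CNV gene pool, so planted and
  background sets are disjoint and truth is unambiguous.
* **Host bias.** Human intragenic miRNAs land in CNV genes with
  probability 0.8; chimpanzee, macaque and rat are set to their CNV gene
  fraction (no bias, so their densities come out "similar"); the remaining
  species use 0.7 — reproducing the qualitative cross-species host-bias
  pattern as a planted truth.

All randomness flows through one `numpy.random.Generator(PCG64(seed))` in a
fixed draw order, and all serialization is sorted, so one seed gives
byte-identical output files across runs.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic nucleotide composition and
dinucleotide structure, conservation, UTR secondary structure and site
accessibility, SNPs/indels, transcript isoforms (one UTR per gene),
paralog ambiguity in homology groups, and overlap structure between real
pathways. The planted-recovery results certify the pipeline's mechanics
and calibration, not biological effect sizes.

## Default scales and runtime envelopes

Defaults were fixed once, by a design-phase power calculation plus pilot
runs, to make the planted effects unambiguous at a scale where hundreds of
replicates are cheap: 8 species × 360 homology groups, 50 miRNAs, 300 ± 60
nt UTRs, 12 pathways of 10–16 genes with 3 planted, 6 curated classes. At
these settings the background intersected-pair probability per (miRNA,
gene) is ≈ 0.03, the above-mean list covers roughly half of the annotated
universe, and a fully-hot planted pathway sits many orders of magnitude
below the BH threshold. Replicate experiments in `evaluation.py` use 100
cohorts (planted recovery; full 8-species prediction per replicate) and
200 human-only cohorts (null control). The published-scale totals
(≈ 1,900 miRNAs × ≈ 10,000 genes) are not simulated; the per-miRNA/per-gene
statistics are scale-free, which is why the small cohort is informative.

## Numerical and engineering choices

* `predict_all` evaluates the walk predictor only where the seed scan found
  at least one site; the intersection is a subset of the seed side, so the
  result is provably identical and the quadratic scan stays fast.
* Walk runs are found by locating the 7-nt anchor core with string search
  and extending leftward (the reverse complement of a longer 5' prefix
  prepends bases); maximal k per locus wins, and both anchors collapse to
  one site per offset.
* Fisher p-values come from `hypergeom.sf(a-1, N, a+c, a+b)` — exact to
  ~1e-12 against integer enumeration; BH keeps input order and enforces
  monotonicity via the cumulative minimum from the largest rank.
* Degenerate inputs prefer NaN-with-warning over exceptions where a real
  dataset could plausibly produce them (empty strata, constant densities,
  single-UTR species); malformed records (start ≥ end, non-ACGU UTRs) are
  hard errors naming the offender.
* Tie-break conventions: partition ties go below; equal-k walk anchors
  collapse; duplicate gene ids keep the first occurrence with a warning.
* Stage contracts are TSVs with documented columns; the run manifest
  records the config echo, seed, library versions and SHA-256 of every
  file, and two runs with one seed are byte-identical (asserted in tests).

## Known limitations

* The two predictors are canonical-site scanners; context scoring,
  conservation filtering, free-energy models and non-canonical sites are
  out of scope, so absolute pair counts are not comparable to published
  web-resource outputs (version- and algorithm-dependent in any case).
* The below-mean arm of planted pathway enrichment is statistically weak
  by construction at default scale (see above).
* The host scan is span-level; intron/exon-resolved host relationships and
  host/miRNA co-expression are not modelled.
* Family collapse uses the 7-nt seed key only; no cross-species family
  nomenclature reconciliation is attempted.
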
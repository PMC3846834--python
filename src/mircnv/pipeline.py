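"""End-to-end orchestration: generate/read -> atlas -> predict -> partition
-> enrichment/ORA/classes -> host scan, with a reproducible manifest.

Every stage consumes and produces flat TSV/FASTA/BED/GMT files inside one
working directory (``inputs/`` holds the raw cohort), so stages can be
re-run individually and externally produced prediction tables can replace
the built-in predictors. Re-running with an identical config and seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .atlas import AtlasSummary, assign_cnv_status, build_atlas
from .enrich import (classify_genes, enrichment_to_frame, heatmap_matrix,
                     ora_across_sets, pathway_enrichment)
from .models import CNV, GeneRecord, MiRNA
from .scan import host_bias_summary, scan_hosts
from .stats import (overall_mean, partition_genes, partition_to_frame,
                    per_gene_density, utr_length_comparison)
from .synthetic import (MANIFEST_FILES, SyntheticConfig, generate_cohort,
                        write_cohort)
from .targets import mirna_family, predict_all

log = logging.getLogger(__name__)

INPUT_KEYS = ("utrs", "mirnas", "genes", "mirna_loci", "cnv_regions",
              "homology", "pathways", "classes")


class ConfigError(ValueError):
    """Invalid pipeline configuration (bad value or missing input path)."""


@dataclass
class PipelineConfig:
    """Structured configuration of one pipeline run."""

    mode: str = "synthetic"                      # "synthetic" | "files"
    out_dir: str = "mircnv_run"
    rng_seed: int = 0
    input_paths: dict[str, str] = field(default_factory=dict)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    tie_rule: str = "below"                      # above/below tie handling
    universe: str = "annotated"                  # "annotated" | "all-cnv"
    alpha: float = 0.05
    ora_method: str = "ranksum"                  # "ranksum" | "fisher"
    scan_containment: bool = True
    scan_require_strand: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"mode must be synthetic|files, got {self.mode!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.mode == "files":
            missing = [k for k in INPUT_KEYS if k not in self.input_paths]
            if missing:
                raise ConfigError(f"files mode lacks input paths: {missing}")
            absent = [p for p in self.input_paths.values() if not Path(p).exists()]
            if absent:
                raise ConfigError(f"input paths do not exist: {absent}")
        try:
            self.synthetic.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn:
            cfg.synthetic = SyntheticConfig.from_dict(syn)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d


# ---------------------------------------------------------------- inputs

def prepare_inputs(cfg: PipelineConfig) -> Path:
    """Materialise the raw cohort files under ``out_dir/inputs``."""
    out = Path(cfg.out_dir)
    inp = out / "inputs"
    if cfg.mode == "synthetic":
        syn = dataclasses.replace(cfg.synthetic, rng_seed=cfg.rng_seed)
        cohort = generate_cohort(syn)
        write_cohort(cohort, inp)
    else:
        inp.mkdir(parents=True, exist_ok=True)
        for key in INPUT_KEYS:
            shutil.copyfile(cfg.input_paths[key], inp / MANIFEST_FILES[key])
    return inp


def _species_of_chrom(chrom: str) -> str:
    return chrom.rsplit("_chr", 1)[0] if "_chr" in chrom else chrom


def load_genes(inp: Path) -> tuple[dict[str, list[GeneRecord]],
                                   dict[str, list[tuple[str, int, int]]]]:
    utrs = mio.read_fasta(inp / MANIFEST_FILES["utrs"])
    genes: dict[str, list[GeneRecord]] = {}
    for r in mio.read_bed6(inp / MANIFEST_FILES["genes"]).itertuples(index=False):
        sp = _species_of_chrom(r.chrom)
        genes.setdefault(sp, []).append(GeneRecord(
            gene_id=r.name, species=sp, chrom=r.chrom, start=int(r.start),
            end=int(r.end), strand=r.strand,
            utr_seq=utrs.get(f"{r.name}|{sp}") or utrs.get(r.name)))
    regions: dict[str, list[tuple[str, int, int]]] = {}
    for r in mio.read_bed6(inp / MANIFEST_FILES["cnv_regions"]).itertuples(index=False):
        sp = _species_of_chrom(r.chrom)
        regions.setdefault(sp, []).append((r.chrom, int(r.start), int(r.end)))
    return genes, regions


def load_mirnas(inp: Path) -> list[MiRNA]:
    seqs = mio.read_fasta(inp / MANIFEST_FILES["mirnas"])
    mirnas = {mid: MiRNA(mirna_id=mid, mature_seq=seq)
              for mid, seq in seqs.items()}
    loci = inp / MANIFEST_FILES["mirna_loci"]
    if loci.exists():
        for r in mio.read_bed6(loci).itertuples(index=False):
            if r.name in mirnas:
                sp = _species_of_chrom(r.chrom)
                mirnas[r.name].placements[sp] = (r.chrom, int(r.start),
                                                 int(r.end), r.strand)
    return [mirnas[mid] for mid in sorted(mirnas)]


# ---------------------------------------------------------------- stages

def stage_atlas(workdir: Path) -> None:
    """CNV-status assignment and homology atlas; writes atlas + summary."""
    inp = workdir / "inputs"
    genes, regions = load_genes(inp)
    if "human" not in genes:
        raise ValueError("no human genes found in inputs")
    for sp in genes:
        assign_cnv_status(genes[sp], regions.get(sp, []))
    homology = mio.read_homology_tsv(inp / MANIFEST_FILES["homology"])
    others = {sp: g for sp, g in genes.items() if sp != "human"}
    atlas, summary = build_atlas(genes["human"], homology, others)

    rows = [
        (sp, g.gene_id, g.chrom, g.start, g.end, g.strand, g.cnv_status,
         len(g.utr_seq) if g.utr_seq else 0)
        for sp in sorted(atlas) for g in atlas[sp]
    ]
    pd.DataFrame(rows, columns=["species", "gene_id", "chrom", "start", "end",
                                "strand", "cnv_status", "utr_length"]
                 ).to_csv(workdir / "atlas.tsv", sep="\t", index=False)
    summary.to_frame().sort_values("species").to_csv(
        workdir / "atlas_summary.tsv", sep="\t", index=False)


def load_atlas(workdir: Path) -> dict[str, list[GeneRecord]]:
    path = workdir / "atlas.tsv"
    if not path.exists():
        raise FileNotFoundError("atlas.tsv missing; run the atlas stage first")
    utrs = mio.read_fasta(workdir / "inputs" / MANIFEST_FILES["utrs"])
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    atlas: dict[str, list[GeneRecord]] = {}
    for r in df.itertuples(index=False):
        atlas.setdefault(r.species, []).append(GeneRecord(
            gene_id=r.gene_id, species=r.species, chrom=r.chrom,
            start=int(r.start), end=int(r.end), strand=r.strand,
            cnv_status=r.cnv_status,
            utr_seq=utrs.get(f"{r.gene_id}|{r.species}") or utrs.get(r.gene_id)))
    return atlas


def stage_predict(workdir: Path, min_len: int = 7) -> None:
    """Dual-predictor scan of CNV-gene UTRs, intersected; writes pair TSVs."""
    atlas = load_atlas(workdir)
    mirnas = load_mirnas(workdir / "inputs")
    all_pairs, all_fams = [], []
    for sp in sorted(atlas):
        cnv_genes = [g for g in atlas[sp] if g.cnv_status == CNV and g.utr_seq]
        pairs, fams = predict_all(mirnas, cnv_genes, min_len=min_len)
        all_pairs.extend(pairs)
        all_fams.extend(fams)
    mio.write_pairs_tsv(all_pairs, workdir / "pairs.tsv")
    mio.write_pairs_tsv(all_fams, workdir / "family_pairs.tsv")


def stage_partition(workdir: Path, tie_rule: str = "below") -> None:
    """Overall means, above/below partition, densities, UTR-length control."""
    for name in ("pairs.tsv", "family_pairs.tsv"):
        if not (workdir / name).exists():
            raise FileNotFoundError(f"{name} missing; run the predict stage first")
    atlas = load_atlas(workdir)
    mirnas = load_mirnas(workdir / "inputs")
    n_mirnas = len(mirnas)
    n_families = len({mirna_family(m.mature_seq) for m in mirnas})

    pairs = mio.read_pairs_tsv(workdir / "pairs.tsv")
    fam_pairs = mio.read_pairs_tsv(workdir / "family_pairs.tsv")
    mean_rows, part_frames, list_rows, dens_rows = [], [], [], []
    for sp in sorted(atlas):
        n_cnv = sum(1 for g in atlas[sp] if g.cnv_status == CNV)
        for level, lvl_pairs, n_units in (("mirna", pairs, n_mirnas),
                                          ("family", fam_pairs, n_families)):
            sp_pairs = [p for p in lvl_pairs if p.species == sp]
            mean = overall_mean(len(sp_pairs), n_units)
            res = partition_genes(sp_pairs, mean, species=sp, level=level,
                                  n_units=n_units, tie_rule=tie_rule)
            mean_rows.append((sp, level, len(sp_pairs), n_units,
                              mean, round(mean, 2)))
            frame = partition_to_frame(res)
            frame.insert(0, "species", sp)
            part_frames.append(frame)
            list_rows += [(sp, level, "above", g) for g in res.above_genes]
            list_rows += [(sp, level, "below", g) for g in res.below_genes]
            if level == "mirna" and n_cnv:
                dens_rows.append((sp, len(sp_pairs), n_cnv,
                                  per_gene_density(len(sp_pairs), n_cnv)))

    pd.DataFrame(mean_rows, columns=["species", "level", "total_pairs",
                                     "n_units", "overall_mean", "mean_2dp"]
                 ).to_csv(workdir / "means.tsv", sep="\t", index=False)
    pd.concat(part_frames, ignore_index=True).to_csv(
        workdir / "partition.tsv", sep="\t", index=False)
    pd.DataFrame(list_rows, columns=["species", "level", "class", "gene_id"]
                 ).to_csv(workdir / "gene_lists.tsv", sep="\t", index=False)
    pd.DataFrame(dens_rows, columns=["species", "n_pairs", "n_cnv_genes",
                                     "density"]
                 ).to_csv(workdir / "density.tsv", sep="\t", index=False)

    ctrl, p = utr_length_comparison(atlas)
    ctrl["kruskal_p"] = p
    ctrl.to_csv(workdir / "utr_control.tsv", sep="\t", index=False)


def stage_enrich(workdir: Path, alpha: float = 0.05,
                 universe: str = "annotated",
                 ora_method: str = "ranksum") -> None:
    """Pathway enrichment, heat-map matrix, class counts and binding-site ORA."""
    for name in ("gene_lists.tsv", "partition.tsv"):
        if not (workdir / name).exists():
            raise FileNotFoundError(f"{name} missing; run the partition stage first")
    inp = workdir / "inputs"
    atlas = load_atlas(workdir)
    pathways = mio.read_gmt(inp / MANIFEST_FILES["pathways"], "pathways")
    classes = mio.read_gmt(inp / MANIFEST_FILES["classes"], "classes")
    lists = pd.read_csv(workdir / "gene_lists.tsv", sep="\t", dtype=str)
    annotated = set().union(*pathways.sets.values())

    enr_frames, summary_rows = [], []
    above_by_species = {}
    for sp in sorted(atlas):
        cnv_ids = {g.gene_id for g in atlas[sp] if g.cnv_status == CNV}
        bg = sorted(cnv_ids & annotated) if universe == "annotated" else sorted(cnv_ids)
        if not bg:
            log.warning("species %s has an empty enrichment universe", sp)
            continue
        for level in ("mirna", "family"):
            for arm in ("above", "below"):
                sel = lists[(lists.species == sp) & (lists.level == level)
                            & (lists["class"] == arm)]
                gene_list = sorted(set(sel.gene_id) & set(bg))
                results, n_sig = pathway_enrichment(gene_list, bg, pathways,
                                                    alpha=alpha)
                frame = enrichment_to_frame(results)
                frame.insert(0, "arm", arm)
                frame.insert(0, "level", level)
                frame.insert(0, "species", sp)
                enr_frames.append(frame)
                summary_rows.append((sp, level, arm, n_sig))
                if level == "mirna" and arm == "above":
                    above_by_species[sp] = results

    pd.concat(enr_frames, ignore_index=True).to_csv(
        workdir / "enrichment.tsv", sep="\t", index=False)
    pd.DataFrame(summary_rows, columns=["species", "level", "arm",
                                        "n_significant"]
                 ).to_csv(workdir / "enrichment_summary.tsv", sep="\t",
                          index=False)

    if above_by_species:
        mat, specific = heatmap_matrix(above_by_species)
        mat.to_csv(workdir / "heatmap.tsv", sep="\t", index_label="set_id")
        rows = [(sp, sid) for sp in sorted(specific) for sid in specific[sp]]
        pd.DataFrame(rows, columns=["species", "set_id"]).to_csv(
            workdir / "species_specific.tsv", sep="\t", index=False)

    classify_genes(atlas, classes).to_csv(
        workdir / "class_counts.tsv", sep="\t", index=False)

    # binding-site ORA on human CNV genes, above vs below miRNA strata
    if "human" in atlas:
        part = pd.read_csv(workdir / "partition.tsv", sep="\t", dtype=str)
        pairs = [p for p in mio.read_pairs_tsv(workdir / "pairs.tsv")
                 if p.species == "human"]
        fam_pairs = [p for p in mio.read_pairs_tsv(workdir / "family_pairs.tsv")
                     if p.species == "human"]
        utr_lengths = {g.gene_id: len(g.utr_seq) for g in atlas["human"]
                       if g.cnv_status == CNV and g.utr_seq}
        uni = sorted(utr_lengths)

        def arm_units(level: str, arm: str) -> set[str]:
            sel = part[(part.species == "human") & (part.level == level)
                       & (part["class"] == arm)]
            return set(sel.unit_id)

        frames = []
        for arm in ("above", "below"):
            units = arm_units("mirna", arm)
            sub = [p for p in pairs if p.mirna_id in units]
            df = ora_across_sets(sub, pathways, uni, utr_lengths,
                                 method=ora_method, alpha=alpha)
            df.insert(0, "stratum", f"mirna-{arm}")
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            workdir / "ora_pathways.tsv", sep="\t", index=False)

        frames = []
        for level, lvl_pairs in (("mirna", pairs), ("family", fam_pairs)):
            df = ora_across_sets(lvl_pairs, classes, uni, utr_lengths,
                                 method=ora_method, alpha=alpha)
            df.insert(0, "level", level)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            workdir / "ora_classes.tsv", sep="\t", index=False)


def stage_scan(workdir: Path, containment: bool = True,
               require_strand: bool = False) -> None:
    """Host-gene scan of miRNA loci per species; writes the distribution map."""
    atlas = load_atlas(workdir)
    mirnas = load_mirnas(workdir / "inputs")
    results = {}
    assign_rows = []
    for sp in sorted(atlas):
        rows = [(m.mirna_id, *m.placements[sp]) for m in mirnas
                if m.placements.get(sp) is not None]
        res = scan_hosts(rows, atlas[sp], species=sp, containment=containment,
                         require_strand=require_strand)
        results[sp] = res
        assign_rows += [(sp, mid, ",".join(hosts))
                        for mid, hosts in sorted(res.assignments.items())]
    host_bias_summary(results).to_csv(workdir / "host_scan.tsv", sep="\t",
                                      index=False)
    pd.DataFrame(assign_rows, columns=["species", "mirna_id", "host_genes"]
                 ).to_csv(workdir / "host_assignments.tsv", sep="\t",
                          index=False)


STAGE_OUTPUTS = {
    "atlas": ["atlas.tsv", "atlas_summary.tsv"],
    "predict": ["pairs.tsv", "family_pairs.tsv"],
    "partition": ["means.tsv", "partition.tsv", "gene_lists.tsv",
                  "density.tsv", "utr_control.tsv"],
    "enrich": ["enrichment.tsv", "enrichment_summary.tsv", "class_counts.tsv"],
    "scan": ["host_scan.tsv", "host_assignments.tsv"],
}


def stage_report(workdir: Path) -> str:
    """Aggregate stage summaries into a plain-text report."""
    missing = [f for files in STAGE_OUTPUTS.values() for f in files
               if not (workdir / f).exists()]
    if missing:
        raise FileNotFoundError(
            "report needs completed stages; missing outputs: "
            + ", ".join(sorted(missing)))
    parts = []
    for name in ("atlas_summary.tsv", "means.tsv", "density.tsv",
                 "enrichment_summary.tsv", "host_scan.tsv"):
        df = pd.read_csv(workdir / name, sep="\t")
        parts.append(f"== {name} ==\n{df.to_string(index=False)}\n")
    text = "\n".join(parts)
    (workdir / "report.txt").write_text(text)
    return text


# ---------------------------------------------------------------- manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(cfg: PipelineConfig, workdir: Path) -> Path:
    import numpy, scipy  # noqa: PLC0415

    files = {}
    for p in sorted(workdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(workdir))] = _sha256(p)
    manifest = {
        "config": cfg.to_dict(),
        "rng_seed": cfg.rng_seed,
        "versions": {"mircnv": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
        "files": files,
    }
    path = workdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dictionary."""
    cfg.validate()
    workdir = Path(cfg.out_dir)
    workdir.mkdir(parents=True, exist_ok=True)
    prepare_inputs(cfg)
    stage_atlas(workdir)
    stage_predict(workdir)
    stage_partition(workdir, tie_rule=cfg.tie_rule)
    stage_enrich(workdir, alpha=cfg.alpha, universe=cfg.universe,
                 ora_method=cfg.ora_method)
    stage_scan(workdir, containment=cfg.scan_containment,
               require_strand=cfg.scan_require_strand)
    stage_report(workdir)
    write_manifest(cfg, workdir)
    return json.loads((workdir / "manifest.json").read_text())
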
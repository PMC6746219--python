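"""End-to-end orchestration: clean reads -> alignments -> miRNA and siRNA
cluster expression -> MPV non-additivity calls -> target prediction for the
non-additive miRNAs -> GO enrichment, from a single declarative config.

Parent 1 libraries are aligned to subgenome A, parent 2 to subgenome C, and F2
libraries to the merged A+C reference; parent placements are lifted into
merged coordinates (prefix 'A_'/'C_') so that clusters called on the pooled
hits quantify every sample over the same intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import align as al
from . import clusters as cl
from . import diffexpr as dx
from . import enrichment as en
from . import mirna as mi
from . import preprocess as pp
from . import targets as tg
from ._seq import read_fasta

log = logging.getLogger("allosrna")

SCHEMA_VERSION = "allosrna-table-v1"

DEFAULT_PARAMS = {
    "adapter3": "TGGAATTCTCGGGTGCCAAGG",
    "adapter5": None,
    "min_overlap": 6,
    "min_len": 18,
    "max_len": 30,
    "max_mismatches": 2,
    "mirna_unique_only": False,
    "min_cluster_reads": 3,
    "min_distinct": None,
    "merge_dist": 200,
    "alpha": 0.05,
    "fdr_alpha": 0.05,
    "log2_offset": 0.25,
    "target_cutoff": 5.0,
    "go_alpha": 0.05,
}


@dataclass
class RunConfig:
    """Validated run description: sample sheet, references, stage parameters."""

    samples: pd.DataFrame        # columns: sample, genotype, replicate, fastq [, group]
    genome_a: Path
    genome_c: Path
    mature_mirnas: Path
    structural_rnas: Path
    transcripts: Path
    go_annotation: Path
    outdir: Path
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params = {**DEFAULT_PARAMS, **(self.params or {})}
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        s = self.samples
        required = {"sample", "genotype", "replicate", "fastq"}
        if not required <= set(s.columns):
            raise ValueError(f"sample sheet must have columns {sorted(required)}")
        if "group" not in s.columns:
            s = s.copy()
            s["group"] = s["genotype"]
            self.samples = s
        for parent in ("P1", "P2"):
            groups = s.loc[s["genotype"] == parent, "group"].unique()
            if len(groups) != 1:
                raise ValueError(f"design must contain exactly one {parent} sample "
                                 f"(found {len(groups)} groups)")
        if not (s["genotype"] == "F2").any():
            raise ValueError("design must contain at least one F2 sample")
        bad = set(s["genotype"]) - {"P1", "P2", "F2"}
        if bad:
            raise ValueError(f"unknown genotypes in sample sheet: {sorted(bad)}")
        for path_attr in ("genome_a", "genome_c", "mature_mirnas",
                          "structural_rnas", "transcripts", "go_annotation"):
            p = Path(getattr(self, path_attr))
            setattr(self, path_attr, p)
            if not p.exists():
                raise FileNotFoundError(f"{path_attr}: {p} does not exist")
        for fq in s["fastq"]:
            if not Path(fq).exists():
                raise FileNotFoundError(f"FASTQ not found: {fq}")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        samples = pd.DataFrame(raw["samples"])
        samples["fastq"] = [str(resolve(p)) for p in samples["fastq"]]
        return cls(samples=samples,
                   genome_a=resolve(raw["genome_a"]),
                   genome_c=resolve(raw["genome_c"]),
                   mature_mirnas=resolve(raw["mature_mirnas"]),
                   structural_rnas=resolve(raw["structural_rnas"]),
                   transcripts=resolve(raw["transcripts"]),
                   go_annotation=resolve(raw["go_annotation"]),
                   outdir=resolve(raw["outdir"]),
                   params=raw.get("params", {}))


@dataclass
class RunResult:
    config: RunConfig
    clean_stats: pd.DataFrame
    mapping_rates: pd.Series
    mirna_counts: pd.DataFrame
    conserved_support: pd.DataFrame
    clusters: list
    cluster_counts: pd.DataFrame
    mirna_results: dx.NonAdditivityResults
    sirna_results: dx.NonAdditivityResults
    target_hits: list
    enrichment: pd.DataFrame
    clean_totals: pd.Series
    sample_info: pd.DataFrame


def _write_table(df: pd.DataFrame, path: Path, name: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION} {name}\n")
        df.to_csv(fh, sep="\t", index=index)


def _lift_to_merged(hits: list[al.AlignmentHit], prefix: str) -> list[al.AlignmentHit]:
    return [al.AlignmentHit(h.read, f"{prefix}_{h.chrom}", h.start, h.end,
                            h.strand, h.unique) for h in hits]


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage; writes per-stage outputs under ``config.outdir``."""
    p = config.params
    out = config.outdir
    for sub in ("clean", "alignments", "mirna", "sirna", "diffexpr",
                "targets", "enrichment"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        return _run_all(config, out, p)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run_all(config: RunConfig, out: Path, p: dict) -> RunResult:
    for key, value in sorted(p.items()):
        log.info("parameter %s = %r", key, value)

    samples = config.samples.sort_values(["genotype", "group", "replicate"])
    sample_ids = list(samples["sample"])

    # ---- preprocess -----------------------------------------------------
    log.info("stage preprocess: %d libraries", len(sample_ids))
    structural = pp.StructuralFilter(read_fasta(config.structural_rnas),
                                     p["min_len"], p["max_len"])
    reads: dict[str, list[pp.SmallRNARead]] = {}
    read_counts: dict[str, dict[str, int]] = {}
    stats_rows = {}
    for _, row in samples.iterrows():
        collapsed, stats = pp.clean_library(
            pp.read_fastq_seqs(row["fastq"]), p["adapter3"], p["adapter5"],
            structural, p["min_len"], p["max_len"], p["min_overlap"])
        reads[row["sample"]] = collapsed
        read_counts[row["sample"]] = {r.sequence: r.count for r in collapsed}
        stats_rows[row["sample"]] = stats.as_row()
        pp.write_collapsed_fasta(out / "clean" / f"{row['sample']}_collapsed.fasta",
                                 collapsed)
    clean_stats = pd.DataFrame.from_dict(stats_rows, orient="index")
    clean_stats.index.name = "sample"
    clean_totals = clean_stats["clean"]
    _write_table(clean_stats, out / "clean" / "clean_stats.tsv", "clean_stats")

    # ---- alignment ------------------------------------------------------
    genome_a = al.Genome.from_fasta(config.genome_a, "A")
    genome_c = al.Genome.from_fasta(config.genome_c, "C")
    merged = al.Genome.merge(genome_a, genome_c)
    log.info("stage align: genomes A=%d nt, C=%d nt", len(genome_a), len(genome_c))
    index_a = al.ExactIndex(genome_a)
    index_c = al.ExactIndex(genome_c)
    index_m = al.ExactIndex(merged)

    merged_hits: dict[str, list[al.AlignmentHit]] = {}
    rates = {}
    for _, row in samples.iterrows():
        sid, genotype = row["sample"], row["genotype"]
        if genotype == "P1":
            hits, rate = al.align_reads(reads[sid], index_a)
            hits = _lift_to_merged(hits, "A")
        elif genotype == "P2":
            hits, rate = al.align_reads(reads[sid], index_c)
            hits = _lift_to_merged(hits, "C")
        else:
            hits, rate = al.align_reads(reads[sid], index_m)
        merged_hits[sid] = hits
        rates[sid] = rate
        al.hits_to_tsv(hits, out / "alignments" / f"{sid}_hits.tsv")
    mapping_rates = pd.Series(rates, name="mapping_rate")
    _write_table(mapping_rates.to_frame(), out / "alignments" / "mapping_rates.tsv",
                 "mapping_rates")

    # ---- miRNA quantification ------------------------------------------
    mature_ref = read_fasta(config.mature_mirnas)
    located = mi.locate_mirnas(mature_ref, index_m)
    with_locus = [m for m in located if m.loci]
    log.info("stage mirna: %d/%d reference matures located on the merged genome",
             len(with_locus), len(located))
    support_rows = []
    for sid in sample_ids:
        support = mi.identify_conserved(reads[sid], mature_ref, p["max_mismatches"])
        for name, count in sorted(support.items()):
            support_rows.append((sid, name, count))
    conserved_support = pd.DataFrame(support_rows,
                                     columns=["sample", "mirna", "read_count"])
    _write_table(conserved_support, out / "mirna" / "conserved_support.tsv",
                 "conserved_support", index=False)

    mirna_counts = pd.DataFrame(
        {sid: mi.count_mirna_reads(merged_hits[sid], with_locus, read_counts[sid],
                                   p["mirna_unique_only"])
         for sid in sample_ids}).fillna(0).astype(int)
    mirna_counts = mirna_counts.sort_index()
    mirna_rpm = mirna_counts / clean_totals[mirna_counts.columns] * 1e6
    _write_table(mirna_counts, out / "mirna" / "expression_raw.tsv", "mirna_raw")
    _write_table(mirna_rpm, out / "mirna" / "expression_rpm.tsv", "mirna_rpm")

    # ---- siRNA clusters -------------------------------------------------
    eligible: dict[str, list[al.AlignmentHit]] = {}
    pooled_intervals = []
    for sid in sample_ids:
        assigned = mi.mirna_assigned_reads(merged_hits[sid], with_locus)
        kept, _excluded = cl.select_sirna_hits(merged_hits[sid], assigned)
        eligible[sid] = kept
        pooled_intervals.extend((h.chrom, h.start, h.end, read_counts[sid][h.read])
                                for h in kept)
    clusters = cl.call_clusters(pooled_intervals, p["min_cluster_reads"],
                                p["merge_dist"])
    log.info("stage sirna: %d clusters from pooled hits of %d samples",
             len(clusters), len(sample_ids))
    cl.quantify_clusters(clusters, eligible, read_counts, clean_totals.to_dict())
    cl.clusters_to_bed(clusters, out / "sirna" / "clusters.bed")
    cluster_counts = pd.DataFrame(
        {sid: {c.cluster_id: c.counts.get(sid, 0) for c in clusters}
         for sid in sample_ids}).fillna(0).astype(int)
    cluster_counts = cluster_counts.sort_index()
    _write_table(cluster_counts, out / "sirna" / "expression_raw.tsv", "cluster_raw")

    # ---- differential expression vs MPV ---------------------------------
    info = samples.set_index("sample")[["genotype", "group", "replicate"]]
    mirna_model = dx.NonAdditivityModel(mirna_counts, info, clean_totals,
                                        method="ztest", log2_offset=p["log2_offset"])
    mirna_results = mirna_model.fit(p["alpha"], p["fdr_alpha"])
    _write_table(mirna_results.calls, out / "diffexpr" / "mirna_calls.tsv",
                 "mirna_calls", index=False)
    _write_table(mirna_results.category_counts(),
                 out / "diffexpr" / "mirna_category_counts.tsv", "mirna_categories")

    if len(cluster_counts):
        sirna_model = dx.NonAdditivityModel(cluster_counts, info, clean_totals,
                                            method="ttest", log2_offset=p["log2_offset"])
        sirna_results = sirna_model.fit(p["alpha"], p["fdr_alpha"])
    else:
        sirna_results = dx.NonAdditivityResults(
            mirna_model, mirna_results.calls.iloc[0:0], p["alpha"], p["fdr_alpha"])
    _write_table(sirna_results.calls, out / "diffexpr" / "sirna_calls.tsv",
                 "sirna_calls", index=False)
    _write_table(sirna_results.category_counts(),
                 out / "diffexpr" / "sirna_category_counts.tsv", "sirna_categories")
    # dominance split by subgenome (merged-genome chromosome prefix)
    subgenome = {c.cluster_id: c.chrom.split("_", 1)[0] for c in clusters}
    dom = sirna_results.calls[sirna_results.calls["tested"]].copy()
    if len(dom):
        dom["subgenome"] = dom["feature"].map(subgenome)
        dom_table = (dom.groupby(["sample", "subgenome", "dominance"]).size()
                     .unstack(fill_value=0)
                     .reindex(columns=list(dx.DOMINANCE), fill_value=0))
        dom_table.columns.name = None
    else:
        dom_table = pd.DataFrame(columns=list(dx.DOMINANCE))
    _write_table(dom_table, out / "diffexpr" / "sirna_dominance_by_subgenome.tsv",
                 "sirna_dominance")
    _write_table(sirna_results.log2fc_distribution(),
                 out / "diffexpr" / "sirna_log2fc_distribution.tsv",
                 "sirna_log2fc_distribution")

    # ---- targets of non-additive miRNAs ----------------------------------
    nonadd_mirnas = sorted(mirna_results.nonadditive()["feature"].unique())
    log.info("stage targets: %d non-additive miRNAs", len(nonadd_mirnas))
    transcripts = read_fasta(config.transcripts)
    target_hits = tg.predict_targets(
        {m: mature_ref[m] for m in nonadd_mirnas if m in mature_ref},
        transcripts, p["target_cutoff"])
    tg.hits_to_tsv(target_hits, out / "targets" / "target_hits.tsv")

    # ---- GO enrichment ---------------------------------------------------
    annotation = en.GOAnnotation.from_tsv(config.go_annotation)
    target_genes = sorted({h.transcript_id for h in target_hits})
    enrichment = en.enrich(target_genes, annotation, p["go_alpha"]) if target_genes \
        else en.enrich([], annotation, p["go_alpha"])
    _write_table(enrichment, out / "enrichment" / "go_enrichment.tsv",
                 "go_enrichment", index=False)

    with open(out / "summary.txt", "w") as fhs:
        fhs.write(mirna_results.summary() + "\n\n" + sirna_results.summary() + "\n")
    log.info("run complete: %d clusters, %d non-additive miRNAs, %d target hits, "
             "%d enriched GO terms", len(clusters), len(nonadd_mirnas),
             len(target_hits), int(enrichment["enriched"].sum()) if len(enrichment) else 0)

    return RunResult(config=config, clean_stats=clean_stats,
                     mapping_rates=mapping_rates, mirna_counts=mirna_counts,
                     conserved_support=conserved_support, clusters=clusters,
                     cluster_counts=cluster_counts, mirna_results=mirna_results,
                     sirna_results=sirna_results, target_hits=target_hits,
                     enrichment=enrichment, clean_totals=clean_totals,
                     sample_info=info)
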
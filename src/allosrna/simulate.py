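"""Synthetic small-RNA study generator.

Emulates the design of an allopolyploidy small-RNA experiment: two diploid
parents (subgenomes A and C), one F2 allotetraploid, three biological
replicates per genotype. The generator plants conserved miRNA loci (the same
mature 21-mer copied into both subgenomes, so both parents express it) and
subgenome-private siRNA loci, then draws sequencing libraries whose per-locus
read counts follow a gamma-Poisson (negative-binomial) law around each
genotype's true mean, conditioned on a fixed library depth.

Non-additive expression is planted directly: a configurable fraction of
features has an F2 mean displaced from the mid-parent value (MPV) by
``effect_log2fc`` in log2 units, with the direction (activated vs repressed)
chosen at random. The ground-truth table makes parameter-recovery tests
possible downstream.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp, write_fasta, write_fastq

GENOTYPES = ("P1", "P2", "F2")
_GENOTYPE_CODE = {"P1": 1, "P2": 2, "F2": 3}

# minimum separation between planted loci so that planted clusters can never
# merge by accident under the 200-nt merge rule
LOCUS_SPACING = 400

MATURE_LEN = 21


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator."""

    seed: int = 0
    n_chrom_a: int = 3
    n_chrom_c: int = 3
    chrom_len: int = 60_000
    n_mirna_loci: int = 50           # conserved miRNAs, planted once per subgenome
    n_sirna_loci: int = 150          # private siRNA loci per subgenome
    read_depth: int = 50_000         # reads per library (per replicate)
    frac_nonadditive: float = 0.1
    effect_log2fc: float = 2.0       # |log2(F2 / MPV)| for non-additive features
    dispersion: float = 0.0          # NB overdispersion; 0 = Poisson limit
    structural_frac: float = 0.05    # contaminant (rRNA/tRNA/...) read fraction
    n_replicates: int = 3
    mirna_mutation_frac: float = 0.05  # miRNA reads carrying 1-2 substitutions
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    base_mean_log_sd: float = 0.5    # lognormal spread of per-locus base means
    sirna_len_min: int = 100
    sirna_len_max: int = 500
    n_transcripts: int = 400
    n_targets_per_mirna: int = 3
    n_decoy_mirnas: int = 3
    n_go_terms: int = 15

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_nonadditive <= 1.0:
            raise ValueError("frac_nonadditive must be in [0, 1]")
        if self.chrom_len < 1000:
            raise ValueError("chrom_len must be >= 1000")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.structural_frac < 1.0:
            raise ValueError("structural_frac must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.sirna_len_min <= self.sirna_len_max:
            raise ValueError("sirna_len_min must be <= sirna_len_max")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)


def plan_features(cfg: SimConfig) -> pd.DataFrame:
    """True per-feature expression means and non-additivity categories.

    One row per *feature*: a conserved miRNA (expressed by both parents) or a
    subgenome-private siRNA locus. Coordinates are assigned later by
    :func:`make_genomes`; this table alone supports count-level simulation.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    rows = []
    for i in range(cfg.n_mirna_loci):
        rows.append(("miR%03d" % (i + 1), "mirna", "both"))
    for sub, tag in (("A", "sirA"), ("C", "sirC")):
        for i in range(cfg.n_sirna_loci):
            rows.append(("%s%03d" % (tag, i + 1), "sirna", sub))
    feats = pd.DataFrame(rows, columns=["feature_id", "kind", "subgenome"])
    n = len(feats)

    base = np.exp(rng.normal(0.0, cfg.base_mean_log_sd, size=(n, 2)))
    mean_p1 = np.where(feats["subgenome"] == "C", 0.0, base[:, 0])
    mean_p2 = np.where(feats["subgenome"] == "A", 0.0, base[:, 1])
    mpv = (mean_p1 + mean_p2) / 2.0

    nonadd = rng.random(n) < cfg.frac_nonadditive
    # Mass-balanced direction prior: an activated locus adds (2^e - 1) x MPV
    # of library mass while a repressed one removes only (1 - 2^-e) x MPV, so
    # a 50/50 prior would systematically inflate the F2 library total and turn
    # every other feature's relative abundance genuinely non-additive. The
    # prior below makes the planted mass perturbation zero-mean, i.e. the
    # non-additivity is per-locus regulation rather than a global change in
    # small-RNA output.
    up = 2.0 ** cfg.effect_log2fc - 1.0
    down = 1.0 - 2.0 ** (-cfg.effect_log2fc)
    p_act = down / (up + down) if (up + down) > 0 else 0.5
    activated = rng.random(n) < p_act
    factor = np.ones(n)
    factor[nonadd & activated] = 2.0 ** cfg.effect_log2fc
    factor[nonadd & ~activated] = 2.0 ** (-cfg.effect_log2fc)
    category = np.where(nonadd, np.where(activated, "activated", "repressed"), "additive")

    # Fixed-depth libraries measure relative abundance, so the planted truth
    # must live in proportion space: scale each genotype's mean vector to a
    # common total expressed mass. Additive features then have F2 proportion
    # exactly equal to the mid-parent proportion, and planted effects are not
    # confounded by the mass that non-additive loci add to or remove from the
    # F2 library.
    t0 = (mean_p1.sum() + mean_p2.sum()) / 2.0
    mean_p1 = mean_p1 * (t0 / mean_p1.sum())
    mean_p2 = mean_p2 * (t0 / mean_p2.sum())
    mpv = (mean_p1 + mean_p2) / 2.0
    mean_f2 = mpv * factor
    rho = mean_f2.sum() / t0
    mean_f2 = mean_f2 / rho
    bad = (category == "activated") & (mean_f2 <= mpv)
    bad |= (category == "repressed") & (mean_f2 >= mpv)
    bad &= mpv > 0
    if bad.any():
        raise ValueError(
            "planted effects are too one-sided: renormalising the F2 library to "
            "the mid-parent total mass flips the sign of some planted categories; "
            "reduce frac_nonadditive or effect_log2fc")

    feats["mean_p1"] = mean_p1
    feats["mean_p2"] = mean_p2
    feats["mean_f2"] = mean_f2
    feats["category"] = category
    return feats


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _place_loci(rng: np.random.Generator, lengths: list[int], chrom_len: int,
                margin: int = 200) -> list[tuple[int, int]]:
    """Place loci left-to-right on one chromosome with pairwise gaps >= 400 nt."""
    k = len(lengths)
    if k == 0:
        return []
    required = sum(lengths) + LOCUS_SPACING * (k - 1) + 2 * margin
    if required > chrom_len:
        raise ValueError(
            f"cannot place {k} loci (total {sum(lengths)} nt) on a {chrom_len}-nt "
            f"chromosome at >= {LOCUS_SPACING} nt spacing; need >= {required} nt"
        )
    slack = chrom_len - required
    # distribute slack over the k+1 gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=k)) if slack > 0 else np.zeros(k, dtype=int)
    extras = np.diff(np.concatenate([[0], cuts]))
    intervals = []
    cursor = margin
    for i, length in enumerate(lengths):
        cursor += int(extras[i])
        intervals.append((cursor, cursor + length))
        cursor += length + LOCUS_SPACING
    return intervals


@dataclass
class SimData:
    """All synthetic study inputs plus the ground truth."""

    cfg: SimConfig
    features: pd.DataFrame          # one row per feature (see plan_features)
    truth: pd.DataFrame             # one row per planted locus, with coordinates
    genome_a: dict[str, str]
    genome_c: dict[str, str]
    mature: dict[str, str]          # planted mature miRNA name -> 21-mer
    decoys: dict[str, str]          # reference matures absent from the genome
    structural: dict[str, str]
    transcripts: dict[str, str]
    target_genes: dict[str, list[str]]  # miRNA -> transcripts carrying a site
    go_annotation: pd.DataFrame     # columns: gene, term

    def mature_reference(self) -> dict[str, str]:
        """miRBase-like reference: planted matures plus decoys."""
        out = dict(self.mature)
        out.update(self.decoys)
        return out

    def locus_sequence(self, row: pd.Series) -> str:
        genome = self.genome_a if row["subgenome"] == "A" else self.genome_c
        return genome[row["chrom"]][row["start"]:row["end"]]

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome_a": out / "genome_A.fasta",
            "genome_c": out / "genome_C.fasta",
            "mature": out / "mature_mirnas.fasta",
            "structural": out / "structural_rnas.fasta",
            "transcripts": out / "transcripts.fasta",
            "gff": out / "loci.gff3",
            "truth": out / "ground_truth.tsv",
            "go": out / "go_annotation.tsv",
        }
        write_fasta(paths["genome_a"], self.genome_a.items())
        write_fasta(paths["genome_c"], self.genome_c.items())
        write_fasta(paths["mature"], self.mature_reference().items())
        write_fasta(paths["structural"], self.structural.items())
        write_fasta(paths["transcripts"], self.transcripts.items())
        with open(paths["gff"], "w") as fh:
            fh.write("##gff-version 3\n")
            for _, r in self.truth.iterrows():
                attrs = (f"ID={r.locus_id};feature={r.feature_id};kind={r.kind};"
                         f"subgenome={r.subgenome};category={r.category}")
                fh.write("\t".join([
                    r.chrom, "allosrna_sim",
                    "miRNA_locus" if r.kind == "mirna" else "siRNA_locus",
                    str(r.start + 1), str(r.end), ".", "+", ".", attrs,
                ]) + "\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.go_annotation.to_csv(paths["go"], sep="\t", index=False, header=False)
        return paths


def make_genomes(cfg: SimConfig) -> SimData:
    """Build the two parental genomes with planted loci and all reference inputs."""
    rng = np.random.default_rng([cfg.seed, 0])
    features = plan_features(cfg)

    mature = {}
    for fid in features.loc[features["kind"] == "mirna", "feature_id"]:
        mature[fid] = _random_seq(rng, MATURE_LEN)

    sirna_lengths = {}
    for _, r in features[features["kind"] == "sirna"].iterrows():
        sirna_lengths[r.feature_id] = int(rng.integers(cfg.sirna_len_min, cfg.sirna_len_max + 1))

    genomes: dict[str, dict[str, str]] = {"A": {}, "C": {}}
    truth_rows = []
    for sub, n_chrom in (("A", cfg.n_chrom_a), ("C", cfg.n_chrom_c)):
        # every miRNA is planted once per subgenome; siRNA loci are private
        loci = [(fid, "mirna", MATURE_LEN) for fid in mature]
        loci += [(r.feature_id, "sirna", sirna_lengths[r.feature_id])
                 for _, r in features.iterrows()
                 if r.kind == "sirna" and r.subgenome == sub]
        per_chrom: list[list] = [[] for _ in range(n_chrom)]
        for i, locus in enumerate(loci):
            per_chrom[i % n_chrom].append(locus)
        for ci in range(n_chrom):
            chrom = f"chr{sub}{ci + 1}"
            seq = np.array(list(_random_seq(rng, cfg.chrom_len)))
            intervals = _place_loci(rng, [length for _, _, length in per_chrom[ci]],
                                    cfg.chrom_len)
            for (fid, kind, _length), (start, end) in zip(per_chrom[ci], intervals):
                if kind == "mirna":
                    seq[start:end] = list(mature[fid])
                    locus_id = f"{fid}_{sub}"
                else:
                    locus_id = fid
                truth_rows.append((locus_id, fid, kind, sub, chrom, start, end))
            genomes[sub][chrom] = "".join(seq)

    truth = pd.DataFrame(truth_rows, columns=[
        "locus_id", "feature_id", "kind", "subgenome", "chrom", "start", "end"])
    truth = truth.merge(
        features[["feature_id", "mean_p1", "mean_p2", "mean_f2", "category"]],
        on="feature_id", how="left")

    decoys = {f"decoy_miR{i + 1:02d}": _random_seq(rng, MATURE_LEN)
              for i in range(cfg.n_decoy_mirnas)}
    structural = {
        "rRNA_25S": _random_seq(rng, 2000),
        "rRNA_18S": _random_seq(rng, 1500),
        "tRNA_Gly": _random_seq(rng, 500),
        "snoRNA_U3": _random_seq(rng, 300),
    }

    transcripts = {}
    gene_ids = [f"gene{i + 1:04d}" for i in range(cfg.n_transcripts)]
    for gid in gene_ids:
        transcripts[gid] = _random_seq(rng, int(rng.integers(300, 801)))
    target_genes: dict[str, list[str]] = {}
    for fid, mseq in mature.items():
        chosen = rng.choice(gene_ids, size=min(cfg.n_targets_per_mirna, len(gene_ids)),
                            replace=False)
        site = revcomp(mseq)
        target_genes[fid] = sorted(chosen)
        for gid in chosen:
            t = transcripts[gid]
            pos = int(rng.integers(0, len(t) - len(site) + 1))
            transcripts[gid] = t[:pos] + site + t[pos + len(site):]

    all_targets = sorted({g for gs in target_genes.values() for g in gs})
    go_rows = []
    terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_terms)]
    for gid in gene_ids:
        for term in rng.choice(terms, size=int(rng.integers(1, 4)), replace=False):
            go_rows.append((gid, term))
    # one term genuinely associated with the planted target genes
    for gid in gene_ids:
        is_target = gid in all_targets
        if rng.random() < (0.7 if is_target else 0.02):
            go_rows.append((gid, "GO:2000001"))
    go = pd.DataFrame(sorted(set(go_rows)), columns=["gene", "term"])

    return SimData(cfg=cfg, features=features, truth=truth,
                   genome_a=genomes["A"], genome_c=genomes["C"],
                   mature=mature, decoys=decoys, structural=structural,
                   transcripts=transcripts, target_genes=target_genes,
                   go_annotation=go)


def _genotype_means(features: pd.DataFrame, genotype: str) -> np.ndarray:
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    return features[f"mean_{genotype.lower()}"].to_numpy(float)


def simulate_feature_counts(cfg: SimConfig, features: pd.DataFrame, genotype: str,
                            replicate: int) -> tuple[np.ndarray, int]:
    """Draw one library's per-feature read counts plus the structural-read count.

    Counts are gamma-Poisson around the genotype's true means, conditioned on
    the total library depth (a multinomial draw over gamma-jittered weights);
    ``dispersion == 0`` is the Poisson limit.
    """
    means = _genotype_means(features, genotype)
    rng = np.random.default_rng([cfg.seed, _GENOTYPE_CODE[genotype], replicate, 7])
    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        jitter = rng.gamma(shape, cfg.dispersion, size=means.size)
    else:
        jitter = np.ones_like(means)
    w = means * jitter
    total = w.sum()
    if total <= 0:
        raise ValueError("all feature means are zero for this genotype")
    w_struct = cfg.structural_frac / (1.0 - cfg.structural_frac) * total
    p = np.concatenate([w, [w_struct]])
    counts = rng.multinomial(cfg.read_depth, p / p.sum())
    return counts[:-1], int(counts[-1])


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for i in pos:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def simulate_library(cfg: SimConfig, sim: SimData, genotype: str,
                     replicate: int) -> list[tuple[str, str]]:
    """One replicate library as (read id, sequence-with-3'-adapter) records.

    miRNA reads are the exact mature 21-mer (a configurable fraction carries
    1-2 substitutions); siRNA reads are 21-24 nt substrings of the locus from
    either strand; structural reads are substrings of the contaminant RNAs.
    """
    counts, n_struct = simulate_feature_counts(cfg, sim.features, genotype, replicate)
    rng = np.random.default_rng([cfg.seed, _GENOTYPE_CODE[genotype], replicate, 11])

    locus_seq: dict[str, str] = {}
    for _, r in sim.truth.drop_duplicates("feature_id").iterrows():
        if r.kind == "sirna":
            locus_seq[r.feature_id] = sim.locus_sequence(r)

    def substring_reads(src: str, n: int) -> list[str]:
        lengths = rng.integers(21, 25, size=n)
        starts = np.floor(rng.random(n) * (len(src) - lengths + 1)).astype(int)
        minus = rng.random(n) < 0.5
        out = []
        for length, start, m in zip(lengths, starts, minus):
            seq = src[start:start + length]
            out.append(revcomp(seq) if m else seq)
        return out

    seqs: list[str] = []
    for (fid, kind), n in zip(sim.features[["feature_id", "kind"]].itertuples(index=False),
                              counts):
        n = int(n)
        if n == 0:
            continue
        if kind == "mirna":
            mut = rng.random(n) < cfg.mirna_mutation_frac
            n_subs = rng.integers(1, 3, size=n)
            for is_mut, n_sub in zip(mut, n_subs):
                seq = sim.mature[fid]
                if is_mut:
                    seq = _mutate(rng, seq, int(n_sub))
                seqs.append(seq)
        else:
            seqs.extend(substring_reads(locus_seq[fid], n))
    struct_names = list(sim.structural)
    struct_lens = np.array([len(sim.structural[s]) for s in struct_names], float)
    per_struct = rng.multinomial(n_struct, struct_lens / struct_lens.sum())
    for name, n in zip(struct_names, per_struct):
        if n:
            seqs.extend(substring_reads(sim.structural[name], int(n)))
    return [(f"{genotype}_rep{replicate}_read{k}", seq + cfg.adapter3)
            for k, seq in enumerate(seqs)]


def write_libraries(cfg: SimConfig, sim: SimData, outdir: str | os.PathLike) -> pd.DataFrame:
    """Write all replicate FASTQs; returns the sample sheet (sample, genotype, replicate, path)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for genotype in GENOTYPES:
        for rep in range(1, cfg.n_replicates + 1):
            path = out / f"{genotype}_rep{rep}.fastq"
            write_fastq(path, simulate_library(cfg, sim, genotype, rep))
            rows.append((f"{genotype}_rep{rep}", genotype, rep, str(path)))
    sheet = pd.DataFrame(rows, columns=["sample", "genotype", "replicate", "fastq"])
    sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    return sheet
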
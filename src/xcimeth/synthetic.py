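"""Synthetic WGBS/RNA-seq data with the statistical structure the
analyses assume, plus a ground-truth record for recovery tests.

The generator emulates a small diploid study of two sexes (default three
females, three males) over autosomal, X and Y contigs:

* **Dosage-driven coverage.**  Per CpG site and sample, coverage is the
  sum over allele copies of Poisson(per-allele depth): autosomes carry
  two copies in both sexes, the X two in females and one in males, Y
  contigs one copy in males and none in females — so female X depth is
  about twice male X depth and females contribute no Y reads.
* **Female-X hypomethylation.**  X sites are planted hypomethylated in
  females by a base amount, attenuated inside promoters in proportion to
  the promoter's CpG count (CpG-rich promoters lose the effect and can
  flip slightly hypermethylated).
* **Methylation-linked expression.**  Per-gene expression follows a
  monotone decreasing function of promoter methylation with lognormal
  noise; one Xist-like lncRNA on the X is expressed only in females and
  carries a 5' CpG island with allele-specific methylation (one allele
  near fully methylated, the other near fully unmethylated).

All randomness flows from one integer seed through per-purpose child
generators, so a fixed config reproduces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import meth_io
from .meth_io import GeneModel

MIN_CONTIG_LENGTH = 1000
READ_LENGTH = 150  # single-end stand-in for 150-bp chemistry


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ContigSpec:
    name: str
    linkage: str        # 'A' | 'X' | 'Y'
    length: int
    cpg_density: float  # expected CpG dinucleotides per bp


@dataclass(frozen=True)
class AsmLocusSpec:
    contig: str
    start0: int
    end0: int
    allele_a_meth: float = 0.95
    allele_b_meth: float = 0.05


@dataclass
class SimConfig:
    """Study-condition parameters for the generator (defaults ARE the
    emulated study: 3 females vs 3 males, ~15x autosomal coverage,
    female-X hypomethylation of 0.15 attenuated by promoter CpG count)."""

    seed: int = 0
    n_female: int = 3
    n_male: int = 3
    contig_specs: tuple[ContigSpec, ...] = (
        ContigSpec("chrA1", "A", 60_000, 0.02),
        ContigSpec("chrA2", "A", 60_000, 0.02),
        ContigSpec("chrX", "X", 60_000, 0.02),
        ContigSpec("contigY1", "Y", 15_000, 0.02),
        ContigSpec("contigY2", "Y", 15_000, 0.02),
    )
    per_allele_depth: float = 7.5
    autosomal_meth_mean: float = 0.75
    maleX_meth_mean: float = 0.75
    y_meth_mean: float = 0.30
    femaleX_hypo_base: float = 0.15
    cpg_count_attenuation: float = 0.002  # per promoter CpG
    site_meth_sd: float = 0.08
    promoter_site_sd: float = 0.03
    genes_per_contig: int = 8
    expression_scale: float = 50.0
    expression_slope: float = 3.0        # expr mean = scale * exp(-slope * meth)
    noise_sd: float = 0.8                # lognormal sigma on expression
    de_fraction: float = 0.05
    de_effect_log2: float = 1.5
    de_lfc_threshold: float = 1.0
    asm_allele_a_meth: float = 0.95
    asm_allele_b_meth: float = 0.05
    xist_like_gene_id: str = "gene_xist"
    asm_locus: AsmLocusSpec | None = None  # filled in by generate_genome

    def validate(self) -> None:
        fracs = [
            self.autosomal_meth_mean, self.maleX_meth_mean, self.y_meth_mean,
            self.femaleX_hypo_base, self.asm_allele_a_meth, self.asm_allele_b_meth,
            self.de_fraction,
        ]
        if any(not (0 <= f <= 1) for f in fracs):
            raise InvalidConfigError("all methylation/DE fractions must be in [0, 1]")
        if self.per_allele_depth <= 0:
            raise InvalidConfigError("per_allele_depth must be > 0")
        if self.n_female < 0 or self.n_male < 0:
            raise InvalidConfigError("sample counts must be >= 0")
        for spec in self.contig_specs:
            if spec.linkage not in ("A", "X", "Y"):
                raise InvalidConfigError(f"contig {spec.name}: class must be A/X/Y")
            if spec.length < MIN_CONTIG_LENGTH:
                raise InvalidConfigError(
                    f"contig {spec.name}: length {spec.length} < {MIN_CONTIG_LENGTH}"
                )
            if not (0 <= spec.cpg_density < 0.5):
                raise InvalidConfigError(f"contig {spec.name}: bad CpG density")

    @property
    def samples(self) -> list[tuple[str, str]]:
        return [(f"F{i + 1}", "female") for i in range(self.n_female)] + [
            (f"M{i + 1}", "male") for i in range(self.n_male)
        ]

    def sex_of(self) -> dict[str, str]:
        return dict(self.samples)


@dataclass
class SimTruth:
    contig_class: dict[str, str]
    sites: pd.DataFrame       # chrom,pos0,linkage,meth_f_a,meth_f_b,meth_m_a,meth_m_b
    genes: list[GeneModel]
    gene_truth: pd.DataFrame  # gene_id, promoter_male, promoter_female,
                              # true_promoter_delta_mf, n_cpg_promoter, de, sex_effect_log2
    de_genes: set[str]
    asm_locus: AsmLocusSpec
    xist_like_gene_id: str

    def allele_matrix(self, sex: str) -> np.ndarray:
        cols = ["meth_f_a", "meth_f_b"] if sex == "female" else ["meth_m_a", "meth_m_b"]
        return self.sites[cols].to_numpy()


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _strip_cg(seq: np.ndarray) -> None:
    """Mutate G -> A wherever a CG dinucleotide occurs (one pass suffices:
    the replacement letter cannot create a new CG)."""
    cg = (seq[:-1] == ord("C")) & (seq[1:] == ord("G"))
    seq[1:][cg] = ord("A")


def _plant_cpgs(seq: np.ndarray, density: float, rng: np.random.Generator) -> None:
    """Place CpG dinucleotides at ~Bernoulli(density) per position, greedily
    skipping overlaps so plantings never disturb each other."""
    if density <= 0 or len(seq) < 2:
        return
    hits = np.flatnonzero(rng.random(len(seq) - 1) < density)
    last = -2
    for i in hits:
        if i >= last + 2:
            seq[i] = ord("C")
            seq[i + 1] = ord("G")
            last = i


def _island_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """GC-rich, CpG-retaining sequence (O/E near 1 or above)."""
    letters = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)
    seq = rng.choice(letters, size=length, p=[0.2, 0.3, 0.3, 0.2])
    hits = np.flatnonzero(rng.random(length - 1) < 0.08)
    last = -2
    for i in hits:
        if i >= last + 2:
            seq[i] = ord("C")
            seq[i + 1] = ord("G")
            last = i
    return seq


def generate_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel], SimTruth]:
    """Build sequences, gene models and the ground-truth methylation record.

    Returns ``(sequences, genes, truth)``; the config's ``asm_locus`` is
    resolved (if unset) to the Xist-like gene's 5' CpG island.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    letters = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)

    sequences: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    xist_gene: GeneModel | None = None
    island_interval: tuple[str, int, int] | None = None
    first_x = next((s.name for s in config.contig_specs if s.linkage == "X"), None)

    for spec in config.contig_specs:
        seq = rng.choice(letters, size=spec.length)
        _strip_cg(seq)
        _plant_cpgs(seq, spec.cpg_density, rng)
        sequences[spec.name] = seq

        if spec.linkage == "Y":
            continue  # unplaced male-specific contigs carry no annotated genes
        slot = spec.length // config.genes_per_contig
        if slot < 5000:
            raise InvalidConfigError(
                f"contig {spec.name}: too short for {config.genes_per_contig} genes"
            )
        for gi in range(config.genes_per_contig):
            start = gi * slot
            # 2.2-kb margins leave room for the 2-kb promoter on either strand
            hi = min(3000, slot - 4400)
            lo = min(600, hi)
            body_len = int(rng.integers(lo, hi + 1))
            bs = start + 2200
            be = bs + body_len
            is_xist = spec.name == first_x and gi == 0
            strand = "+" if is_xist else ("+" if rng.random() < 0.5 else "-")
            gid = config.xist_like_gene_id if is_xist else f"gene_{spec.name}_{gi:02d}"
            transcripts = [(bs, be)]
            if rng.random() < 0.5 and body_len >= 1200:  # a shorter second isoform
                transcripts.append((bs, bs + body_len // 2))
            gene = GeneModel(
                gene_id=gid,
                chrom=spec.name,
                strand=strand,
                transcripts=tuple(sorted(transcripts)),
                biotype="lncRNA" if is_xist else "protein_coding",
                contig_length=spec.length,
            )
            genes.append(gene)
            if is_xist:
                xist_gene = gene
                # CpG island across the 5' end of the gene
                isl_len = 600
                isl_start = bs
                sequences[spec.name][isl_start:isl_start + isl_len] = _island_sequence(
                    isl_len, rng
                )
                island_interval = (spec.name, isl_start, isl_start + isl_len)

    if first_x is not None and xist_gene is None:
        raise InvalidConfigError("X contig present but no gene generated on it")
    if config.asm_locus is None and island_interval is not None:
        config.asm_locus = AsmLocusSpec(
            island_interval[0], island_interval[1], island_interval[2],
            config.asm_allele_a_meth, config.asm_allele_b_meth,
        )
    if config.asm_locus is not None:
        loc = config.asm_locus
        if loc.contig not in sequences or loc.end0 > len(sequences[loc.contig]) or loc.start0 < 0:
            raise InvalidConfigError("asm_locus outside contig bounds")

    seq_strings = {name: seq.tobytes().decode("ascii") for name, seq in sequences.items()}
    truth = _build_truth(config, seq_strings, genes)
    return seq_strings, genes, truth


def _build_truth(config: SimConfig, sequences: dict[str, str],
                 genes: list[GeneModel]) -> SimTruth:
    rng = np.random.default_rng([config.seed, 2])
    linkage_of = {s.name: s.linkage for s in config.contig_specs}

    # per-gene promoter CpG counts and methylation levels
    from .cpg_landscape import promoter_cpg_count

    prom_counts = promoter_cpg_count(genes, sequences=sequences).set_index("gene_id")["n_cpg"]
    gene_rows = []
    prom_level: dict[str, tuple[float, float]] = {}  # gene -> (male, female)
    for g in genes:
        level_m = float(np.clip(0.05 + 0.9 * rng.beta(2, 2), 0.01, 0.99))
        n_cpg = int(prom_counts[g.gene_id])
        if linkage_of[g.chrom] == "X":
            delta = float(np.clip(
                config.femaleX_hypo_base - config.cpg_count_attenuation * n_cpg,
                -0.05, 1.0,
            ))
        else:
            delta = 0.0
        level_f = float(np.clip(level_m - delta, 0.01, 0.99))
        prom_level[g.gene_id] = (level_m, level_f)
        gene_rows.append((g.gene_id, g.chrom, linkage_of[g.chrom], level_m, level_f,
                          level_m - level_f, n_cpg))
    gene_truth = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "linkage", "promoter_male", "promoter_female",
                 "true_promoter_delta_mf", "n_cpg_promoter"],
    )

    # site-level truth
    frames = []
    for spec in config.contig_specs:
        seq = np.frombuffer(sequences[spec.name].encode("ascii"), dtype=np.uint8)
        cpg_pos = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
        n = len(cpg_pos)
        if n == 0:
            continue
        link = spec.linkage
        base_mean = {"A": config.autosomal_meth_mean,
                     "X": config.maleX_meth_mean,
                     "Y": config.y_meth_mean}[link]
        level = np.clip(rng.normal(base_mean, config.site_meth_sd, size=n), 0.01, 0.99)

        # promoter sites track their gene's promoter level
        in_prom = np.full(n, "", dtype=object)
        for g in genes:
            if g.chrom != spec.name:
                continue
            ps, pe = g.promoter
            lo, hi = np.searchsorted(cpg_pos, [ps, pe])
            if hi > lo:
                in_prom[lo:hi] = g.gene_id
                lm, _ = prom_level[g.gene_id]
                level[lo:hi] = np.clip(
                    rng.normal(lm, config.promoter_site_sd, size=hi - lo), 0.01, 0.99
                )

        meth_f_a = np.full(n, np.nan)
        meth_f_b = np.full(n, np.nan)
        meth_m_a = np.full(n, np.nan)
        meth_m_b = np.full(n, np.nan)
        if link == "A":
            meth_f_a = meth_f_b = level.copy()
            meth_m_a = meth_m_b = level.copy()
        elif link == "X":
            meth_m_a = level.copy()
            female = level.copy()
            # base hypomethylation everywhere on the X...
            female -= config.femaleX_hypo_base
            # ...replaced inside promoters by the gene's attenuated level
            for g in genes:
                if g.chrom != spec.name:
                    continue
                ps, pe = g.promoter
                lo, hi = np.searchsorted(cpg_pos, [ps, pe])
                if hi > lo:
                    _, lf = prom_level[g.gene_id]
                    female[lo:hi] = np.clip(rng.normal(
                        lf, config.promoter_site_sd, size=hi - lo), 0.01, 0.99)
            female = np.clip(female, 0.01, 0.99)
            meth_f_a = female.copy()
            meth_f_b = female.copy()
        else:  # Y: males only
            meth_m_a = level.copy()

        frames.append(pd.DataFrame({
            "chrom": spec.name, "pos0": cpg_pos, "linkage": link,
            "promoter_of": in_prom,
            "meth_f_a": meth_f_a, "meth_f_b": meth_f_b,
            "meth_m_a": meth_m_a, "meth_m_b": meth_m_b,
        }))

    sites = (pd.concat(frames, ignore_index=True)
             if frames else pd.DataFrame(
                 columns=["chrom", "pos0", "linkage", "promoter_of",
                          "meth_f_a", "meth_f_b", "meth_m_a", "meth_m_b"]))

    # ASM locus: opposite allele states in females; methylated in males
    loc = config.asm_locus
    if loc is not None and len(sites):
        in_locus = (
            (sites["chrom"] == loc.contig)
            & (sites["pos0"] >= loc.start0)
            & (sites["pos0"] < loc.end0)
        )
        sites.loc[in_locus & sites["meth_f_a"].notna(), "meth_f_a"] = loc.allele_a_meth
        sites.loc[in_locus & sites["meth_f_b"].notna(), "meth_f_b"] = loc.allele_b_meth
        sites.loc[in_locus & sites["meth_m_a"].notna(), "meth_m_a"] = loc.allele_a_meth

    # DE genes: a random non-X-ist subset gets a planted sex effect
    gids = [g.gene_id for g in genes if g.gene_id != config.xist_like_gene_id]
    n_de = int(round(config.de_fraction * len(gids)))
    de_pick = list(rng.choice(gids, size=n_de, replace=False)) if n_de else []
    effects = {}
    for gid in de_pick:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        effects[gid] = sign * config.de_effect_log2
    gene_truth["sex_effect_log2"] = [
        effects.get(gid, 0.0) for gid in gene_truth["gene_id"]
    ]
    de_genes = {g for g, e in effects.items()
                if abs(e) >= config.de_lfc_threshold}
    if config.xist_like_gene_id in {g.gene_id for g in genes}:
        de_genes.add(config.xist_like_gene_id)

    return SimTruth(
        contig_class=linkage_of,
        sites=sites,
        genes=genes,
        gene_truth=gene_truth,
        de_genes=de_genes,
        asm_locus=loc,
        xist_like_gene_id=config.xist_like_gene_id,
    )


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def simulate_methylomes(config: SimConfig, truth: SimTruth) -> dict[str, pd.DataFrame]:
    """Per-sample pre-merge cytosine records (``chrom,pos0,strand,m,u,context``).

    Coverage at a CpG = sum over present alleles of Poisson(per-allele
    depth); methylated reads per allele are Binomial(allele coverage,
    allele methylation).  Site totals are split binomially between the two
    strand cytosines.  Sites on absent chromosomes (Y in females) are
    emitted with zero counts, as a cytosine report would.
    """
    out = {}
    sites = truth.sites
    for si, (sample, sex) in enumerate(config.samples):
        rng = np.random.default_rng([config.seed, 3, si])
        alleles = truth.allele_matrix(sex)          # (n_sites, 2), NaN = absent
        present = ~np.isnan(alleles)
        cov_a = np.where(present, rng.poisson(config.per_allele_depth, alleles.shape), 0)
        m_a = rng.binomial(cov_a, np.where(present, alleles, 0.0))
        cov = cov_a.sum(axis=1)
        m = m_a.sum(axis=1)
        u = cov - m
        # split between the + strand C (at pos0) and the - strand C (pos0+1)
        m_plus = rng.binomial(m, 0.5)
        u_plus = rng.binomial(u, 0.5)
        plus = pd.DataFrame({
            "chrom": sites["chrom"], "pos0": sites["pos0"], "strand": "+",
            "m": m_plus, "u": u_plus, "context": "CG",
        })
        minus = pd.DataFrame({
            "chrom": sites["chrom"], "pos0": sites["pos0"] + 1, "strand": "-",
            "m": m - m_plus, "u": u - u_plus, "context": "CG",
        })
        rec = pd.concat([plus, minus], ignore_index=True)
        rec = rec.sort_values(["chrom", "pos0", "strand"], kind="mergesort").reset_index(drop=True)
        out[sample] = rec
    return out


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression table (TPM-like), raw counts, and a DE-label table.

    Per gene and sample: mean = scale * exp(-slope * promoter methylation
    of the sample's sex), times the planted sex effect for DE genes, times
    lognormal noise.  The Xist-like gene is expressed only in females.
    The DE table mimics an external caller's output: observed log2
    fold-change plus a significance label from the generator's truth.
    """
    gt = truth.gene_truth.set_index("gene_id")
    samples = config.samples
    rng = np.random.default_rng([config.seed, 4])
    expr = pd.DataFrame(index=gt.index, columns=[s for s, _ in samples], dtype=float)
    for gid, row in gt.iterrows():
        for sample, sex in samples:
            meth = row["promoter_female"] if sex == "female" else row["promoter_male"]
            mean = config.expression_scale * np.exp(-config.expression_slope * meth)
            if row["sex_effect_log2"] and sex == "female":
                mean *= 2.0 ** row["sex_effect_log2"]
            if gid == truth.xist_like_gene_id:
                mean = config.expression_scale * 2.0 if sex == "female" else 0.0
            noise = np.exp(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 1.0
            expr.loc[gid, sample] = mean * noise
    counts = pd.DataFrame(
        rng.poisson(np.asarray(expr, dtype=float) * 10.0),
        index=expr.index, columns=expr.columns,
    )
    female_cols = [s for s, sex in samples if sex == "female"]
    male_cols = [s for s, sex in samples if sex == "male"]
    eps = 1e-3
    log2fc = np.log2((expr[female_cols].mean(axis=1) + eps)
                     / (expr[male_cols].mean(axis=1) + eps))
    significant = expr.index.isin(truth.de_genes)
    de = pd.DataFrame({
        "gene_id": expr.index,
        "log2fc_fm": log2fc.to_numpy(),
        "padj": np.where(significant, 1e-3, rng.uniform(0.2, 1.0, size=len(expr))),
        "significant": significant,
    }).reset_index(drop=True)
    return expr, counts, de


# ---------------------------------------------------------------------------
# per-read simulation at the ASM locus
# ---------------------------------------------------------------------------

def simulate_reads_at_locus(
    config: SimConfig,
    truth: SimTruth,
    n_reads: int = 60,
    sex: str = "female",
    allele_rates: tuple[float, float] | None = None,
    min_cpgs_per_read: int = 3,
    seed_offset: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-read CpG calls across the ASM locus.

    Reads are 150 bp, uniform starts, kept only if they span at least
    ``min_cpgs_per_read`` CpGs.  In females each read draws one of the two
    alleles at random and its CpG calls are Bernoulli at that allele's
    methylation rate; in males all reads come from the single allele.
    Returns ``(calls, read_truth)`` where read_truth records each read's
    allele.
    """
    loc = config.asm_locus
    if loc is None:
        raise InvalidConfigError("config has no asm_locus")
    spec = {s.name: s for s in config.contig_specs}.get(loc.contig)
    if spec is None or loc.start0 < 0 or loc.end0 > spec.length:
        raise InvalidConfigError("asm_locus outside contig bounds")
    rates = allele_rates if allele_rates is not None else (loc.allele_a_meth, loc.allele_b_meth)
    rng = np.random.default_rng([config.seed, 5, seed_offset])

    region_sites = truth.sites[
        (truth.sites["chrom"] == loc.contig)
        & (truth.sites["pos0"] >= loc.start0 - READ_LENGTH)
        & (truth.sites["pos0"] < loc.end0 + READ_LENGTH)
    ]["pos0"].to_numpy()
    region_sites.sort()

    lo_start = max(0, loc.start0 - READ_LENGTH + 1)
    hi_start = max(lo_start + 1, loc.end0 - 1)
    call_rows = []
    read_rows = []
    made = 0
    attempts = 0
    while made < n_reads:
        attempts += 1
        if attempts > 200 * n_reads:
            raise RuntimeError("could not place enough CpG-spanning reads at the locus")
        s = int(rng.integers(lo_start, hi_start))
        lo, hi = np.searchsorted(region_sites, [s, s + READ_LENGTH - 1])
        covered = region_sites[lo:hi]
        in_locus = covered[(covered >= loc.start0) & (covered < loc.end0)]
        if len(in_locus) < min_cpgs_per_read:
            continue
        allele = int(rng.integers(0, 2)) if sex == "female" else 0
        rate = rates[allele]
        calls = rng.random(len(covered)) < rate
        rid = f"read{made:05d}"
        for pos, call in zip(covered, calls):
            call_rows.append((rid, loc.contig, int(pos), bool(call)))
        read_rows.append((rid, "ab"[allele], s, s + READ_LENGTH))
        made += 1
    calls_df = pd.DataFrame(call_rows, columns=["read_id", "chrom", "pos0", "methylated"])
    read_truth = pd.DataFrame(read_rows, columns=["read_id", "allele", "start0", "end0"])
    return calls_df, read_truth


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    outdir: Path
    genome_fasta: Path
    gtf: Path
    sample_sheet: Path
    reports: dict[str, Path]
    expression: Path
    counts: Path
    de_table: Path
    read_calls: Path
    truth_json: Path
    truth_sites: Path


def write_bundle(config: SimConfig, outdir) -> tuple[SimBundle, SimTruth]:
    """Generate everything and write the on-disk input bundle the
    pipeline consumes, plus the truth record for recovery tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences, genes, truth = generate_genome(config)
    methylomes = simulate_methylomes(config, truth)
    expr, counts, de = simulate_expression(config, truth)

    genome_fasta = outdir / "genome.fa"
    meth_io.write_fasta(sequences, genome_fasta)
    gtf = outdir / "genes.gtf"
    meth_io.write_gtf(genes, gtf)

    reports = {}
    for sample, _ in config.samples:
        p = outdir / f"{sample}.CX_report.txt"
        meth_io.write_cytosine_report(methylomes[sample], p)
        reports[sample] = p

    sheet = outdir / "samples.tsv"
    meth_io.write_tsv(
        pd.DataFrame(
            {
                "sample": [s for s, _ in config.samples],
                "sex": [x for _, x in config.samples],
                "report": [str(reports[s]) for s, _ in config.samples],
            }
        ),
        sheet,
    )
    expression = outdir / "expression.tsv"
    meth_io.write_expression_table(expr, expression)
    counts_path = outdir / "counts.tsv"
    meth_io.write_expression_table(counts, counts_path)
    de_path = outdir / "de_table.tsv"
    meth_io.write_tsv(de, de_path)

    calls, read_truth = simulate_reads_at_locus(config, truth)
    read_calls = outdir / "read_calls.tsv"
    meth_io.write_read_calls(calls, read_calls)

    truth_sites = outdir / "truth_sites.tsv"
    meth_io.write_tsv(truth.sites, truth_sites)
    truth_json = outdir / "truth.json"
    loc = truth.asm_locus
    payload = {
        "contig_class": truth.contig_class,
        "de_genes": sorted(truth.de_genes),
        "xist_like_gene_id": truth.xist_like_gene_id,
        "asm_locus": None if loc is None else asdict(loc),
        "gene_truth": truth.gene_truth.to_dict(orient="records"),
        "read_truth": read_truth.to_dict(orient="records"),
        "seed": config.seed,
    }
    truth_json.write_text(json.dumps(payload, indent=1, sort_keys=True))

    bundle = SimBundle(outdir, genome_fasta, gtf, sheet, reports, expression,
                       counts_path, de_path, read_calls, truth_json, truth_sites)
    return bundle, truth
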
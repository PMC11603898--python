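"""End-to-end orchestration: read inputs, run every analysis stage in
dependency order, write TSV/JSON outputs with reproducibility metadata.

Stage order: input parsing -> strand merge & site filtering -> metagene
profiles / CpG landscape -> sex-differential analyses, sex-linkage
classification and (when read calls are provided) the ASM locus analysis.
Every run writes ``run_metadata.json`` carrying the package version and a
hash of the resolved configuration; two runs with the same config produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, asm, cpg_landscape, meth_io, profiles, sexdiff, sex_linkage
from .methylome import (
    CpGSiteTable,
    merge_symmetric_cpgs,
    regions_methylation_frame,
    site_fractional_methylation,
)

log = logging.getLogger("xcimeth")


@dataclass
class PipelineConfig:
    sample_sheet: str                 # TSV: sample, sex, report
    annotation: str                   # GTF
    expression: str | None = None
    de_table: str | None = None
    read_calls: str | None = None
    genome_fasta: str | None = None
    outdir: str = "xcimeth_out"
    annotation_format: str = "gtf"
    min_coverage: int = 5
    min_sites: int = 3
    delta_band: float = 0.05
    seed: int = 0
    asm_region: str | None = None     # "chrom:start-end" (0-based half-open)
    asm_flank: int = 0
    contig_prefix_unplaced: str = "contig"
    x_chromosomes: tuple[str, ...] = ("chrX",)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "x_chromosomes" in data:
            data["x_chromosomes"] = tuple(data["x_chromosomes"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("sample_sheet", "annotation"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: missing input {p!r}")
        for name in ("expression", "de_table", "read_calls", "genome_fasta"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: missing input {p!r}")


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, rng = region.rsplit(":", 1)
    s, e = rng.replace(",", "").split("-")
    return chrom, int(s), int(e)


def _chrom_class(chrom: str, config: PipelineConfig) -> str:
    if chrom in config.x_chromosomes:
        return "X"
    if chrom.startswith(config.contig_prefix_unplaced):
        return "unplaced"
    return "autosome"


def run(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns a summary dict (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    log.addHandler(handler)
    summary: dict = {"stages": {}}

    try:
        # ---- stage: inputs -------------------------------------------------
        log.info("stage io: reading inputs")
        sheet = meth_io.read_tsv(config.sample_sheet)
        sex_of = dict(zip(sheet["sample"], sheet["sex"]))
        n_female = sum(1 for s in sex_of.values() if s == "female")
        n_male = sum(1 for s in sex_of.values() if s == "male")
        sex_analyses = n_female >= 1 and n_male >= 1
        if not sex_analyses:
            log.warning("only one sex present (%d female / %d male): "
                        "sex-differential stages will be skipped", n_female, n_male)

        raw = {
            row["sample"]: meth_io.read_cytosine_report(row["report"], contexts=("CG",))
            for _, row in sheet.iterrows()
        }
        ann = meth_io.read_gene_annotation(config.annotation, fmt=config.annotation_format)
        genes = ann.genes
        summary["stages"]["io"] = {
            "n_samples": len(raw),
            "n_genes": len(genes),
            "n_strandless_excluded": ann.n_excluded_strandless,
        }

        # ---- stage: core ---------------------------------------------------
        log.info("stage core: strand merge and site filtering")
        merged = {s: merge_symmetric_cpgs(df) for s, df in raw.items()}
        table = CpGSiteTable.from_sample_frames(merged)
        site_meth = site_fractional_methylation(table, min_coverage=config.min_coverage)
        site_out = site_meth.fractions.reset_index()
        meth_io.write_tsv(site_out, outdir / "site_methylation.tsv")
        summary["stages"]["core"] = {
            "n_sites": len(table),
            "qualifying_proportion": {
                k: round(float(v), 4) for k, v in site_meth.qualifying_proportion.items()
            },
        }

        # region summaries per sex and per sample
        regions = []
        for g in genes:
            ps, pe = g.promoter
            if pe > ps:
                regions.append((g.gene_id, "promoter", g.chrom, ps, pe))
            bs, be = g.gene_body
            regions.append((g.gene_id, "gene_body", g.chrom, bs, be))
        reg_df = pd.DataFrame(regions, columns=["gene_id", "kind", "chrom", "start0", "end0"])

        def summarise(sex_pool):
            frames = []
            for kind, sub in reg_df.groupby("kind"):
                f = regions_methylation_frame(
                    table,
                    list(zip(sub["gene_id"], sub["chrom"], sub["start0"], sub["end0"])),
                    min_coverage=config.min_coverage,
                    min_sites=config.min_sites,
                    sex_of=sex_of if sex_pool else None,
                )
                f.insert(1, "kind", kind)
                frames.append(f)
            out = pd.concat(frames, ignore_index=True)
            return out.rename(columns={"region_id": "gene_id"})

        by_sex = summarise(True)
        meth_io.write_tsv(by_sex, outdir / "gene_methylation_by_sex.tsv")

        # ---- stage: profiles -----------------------------------------------
        log.info("stage profiles: metagene and expression ranks")
        profile = profiles.metagene_profile(table, genes)
        prof_df = pd.DataFrame({"bin": np.arange(profile.n_bins),
                                "weighted_meth": profile.values})
        meth_io.write_tsv(prof_df, outdir / "metagene_profile.tsv")
        summary["stages"]["profiles"] = {
            "n_genes_used": profile.n_genes_used,
            "n_genes_skipped": profile.n_genes_skipped,
        }

        expr = None
        if config.expression:
            expr = meth_io.read_expression_table(config.expression)
            abundance = expr.mean(axis=1)
            ranks = profiles.assign_expression_ranks(abundance)
            meth_io.write_tsv(ranks.reset_index().rename(columns={"index": "gene_id"}),
                              outdir / "expression_ranks.tsv")
            prom = by_sex[(by_sex["kind"] == "promoter")]
            prom_mean = prom.groupby("gene_id")["mean"].mean()
            corr_df = pd.DataFrame({"meth": prom_mean, "expression": abundance}).dropna()
            corr = profiles.spearman_meth_expression(corr_df, kind="promoter")
            summary["stages"]["profiles"]["promoter_expression_spearman"] = [
                dataclasses.asdict(c) for c in corr
            ]

        # ---- stage: cpg landscape -------------------------------------------
        if config.genome_fasta:
            log.info("stage cpg_landscape: O/E windows and promoter CpG counts")
            seqs = meth_io.read_fasta(config.genome_fasta)
            win_frames = []
            for chrom, seq in seqs.items():
                w = cpg_landscape.sliding_window_oe(seq, chrom=chrom)
                win_frames.append(w)
            windows = cpg_landscape.annotate_windows(
                pd.concat(win_frames, ignore_index=True), genes)
            meth_io.write_tsv(windows, outdir / "cpg_oe_windows.tsv")
            prom_counts = cpg_landscape.promoter_cpg_count(genes, sequences=seqs)
            meth_io.write_tsv(prom_counts, outdir / "promoter_cpg_counts.tsv")
        else:
            site_positions = {}
            idx = table.counts.index
            for chrom in idx.get_level_values(0).unique():
                site_positions[chrom] = idx.get_level_values(1)[
                    idx.get_level_values(0) == chrom].to_numpy()
            prom_counts = cpg_landscape.promoter_cpg_count(
                genes, site_positions=site_positions)
            meth_io.write_tsv(prom_counts, outdir / "promoter_cpg_counts.tsv")

        # ---- stage: sex differential ---------------------------------------
        if sex_analyses:
            log.info("stage sexdiff: site and gene deltas")
            deltas = sexdiff.per_site_delta(site_meth.fractions, sex_of)
            meth_io.write_tsv(deltas.reset_index(), outdir / "site_deltas.tsv")
            chrom_summary = sexdiff.per_chromosome_delta_summary(deltas)
            meth_io.write_tsv(chrom_summary.reset_index(), outdir / "chrom_delta_summary.tsv")

            de = meth_io.read_tsv(config.de_table) if config.de_table else None
            gene_deltas = sexdiff.per_gene_delta(by_sex, de, band=config.delta_band)
            meth_io.write_tsv(gene_deltas.reset_index(), outdir / "gene_deltas.tsv")
            class_counts = gene_deltas["sex_bias_class"].value_counts().to_dict()
            summary["stages"]["sexdiff"] = {"sex_bias_classes": class_counts}

            prom_sex = by_sex[by_sex["kind"] == "promoter"].pivot_table(
                index="gene_id", columns="group", values="mean", aggfunc="first"
            ).reset_index()
            if {"female", "male"} <= set(prom_sex.columns):
                binned = sexdiff.cpg_count_binning(prom_sex, prom_counts)
                meth_io.write_tsv(binned, outdir / "cpg_count_bins.tsv")

            if de is not None and "log2fc_fm" in de.columns:
                chrom_of = {g.gene_id: g.chrom for g in genes}
                de_idx = de.set_index("gene_id")
                cls = pd.Series(
                    {g: _chrom_class(c, config) for g, c in chrom_of.items()}
                ).reindex(de_idx.index)
                usable = cls.isin(["autosome", "X"])
                if usable.any() and cls[usable].nunique() == 2:
                    means, test = sexdiff.expression_fc_comparison(
                        de_idx.loc[usable, "log2fc_fm"], cls[usable])
                    summary["stages"]["sexdiff"]["log2fc_comparison"] = {
                        "group_means": {k: float(v) for k, v in means.items()},
                        "pvalue": test.pvalue,
                    }
                corr = sexdiff.delta_expression_correlation(gene_deltas)
                summary["stages"]["sexdiff"]["delta_expression_spearman"] = [
                    dataclasses.asdict(c) for c in corr
                ]

            # ---- stage: sex linkage ----------------------------------------
            log.info("stage sex_linkage: contig classification")
            records = sex_linkage.contig_depth_summary(raw, sex_of)
            calls = sex_linkage.classify_contigs(records)
            meth_io.write_tsv(calls, outdir / "sex_linkage_calls.tsv")
            summary["stages"]["sex_linkage"] = {
                "class_counts": calls["label"].value_counts().to_dict()
            }
            class_meth = sex_linkage.contig_class_methylation(calls, site_meth.fractions)
            meth_io.write_tsv(class_meth, outdir / "contig_class_methylation.tsv")
            for chrom in config.x_chromosomes:
                if any((df["chrom"] == chrom).any() for df in raw.values()):
                    windows, excluded = sex_linkage.windowed_depth_scan(
                        raw, sex_of, chrom, window=10_000)
                    meth_io.write_tsv(windows, outdir / f"depth_scan_{chrom}.tsv")
                    summary["stages"]["sex_linkage"][f"excluded_{chrom}"] = excluded

            # ---- stage: asm ------------------------------------------------
            if config.read_calls and config.asm_region:
                log.info("stage asm: read-level allele-specific methylation")
                calls_df = meth_io.read_read_calls(config.read_calls)
                chrom, s, e = _parse_region(config.asm_region)
                prof = asm.per_read_profiles(calls_df, chrom, s, e)
                meth_io.write_tsv(prof, outdir / "asm_read_profiles.tsv")
                call = asm.call_asm(prof)
                summary["stages"]["asm"] = dataclasses.asdict(call)
                track = asm.region_delta_track(
                    table, sex_of, chrom, s, e, flank=config.asm_flank)
                meth_io.write_tsv(track, outdir / "asm_delta_track.tsv")
        else:
            summary["stages"]["sexdiff"] = {"skipped": "requires both sexes"}
            summary["stages"]["sex_linkage"] = {"skipped": "requires both sexes"}

    except Exception:
        log.exception("pipeline failed; outputs from completed stages are intact")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    meta = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "multiple_testing_correction": "none (raw P values reported)",
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True, default=str))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True, default=str))
    return summary
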
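"""The synthetic-data generator: determinism, dosage structure, planted
effects, and the statistical links downstream analyses rely on."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xcimeth.methylome import CpGSiteTable, merge_symmetric_cpgs
from xcimeth.synthetic import (
    AsmLocusSpec,
    ContigSpec,
    InvalidConfigError,
    SimConfig,
    SimTruth,
    generate_genome,
    simulate_expression,
    simulate_methylomes,
    simulate_reads_at_locus,
    write_bundle,
)


def small_config(**kw):
    base = dict(
        seed=7,
        contig_specs=(
            ContigSpec("chrA1", "A", 30_000, 0.02),
            ContigSpec("chrX", "X", 30_000, 0.02),
            ContigSpec("contigY1", "Y", 10_000, 0.02),
        ),
        genes_per_contig=4,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_short_contig_rejected(self):
        with pytest.raises(InvalidConfigError, match="length"):
            SimConfig(contig_specs=(ContigSpec("c", "A", 500, 0.02),)).validate()

    def test_bad_class_rejected(self):
        with pytest.raises(InvalidConfigError, match="class"):
            SimConfig(contig_specs=(ContigSpec("c", "Z", 5000, 0.02),)).validate()

    def test_bad_depth_rejected(self):
        with pytest.raises(InvalidConfigError, match="depth"):
            SimConfig(per_allele_depth=0).validate()


class TestGenomeGeneration:
    def test_zero_density_contig_emits_no_sites(self):
        cfg = small_config(contig_specs=(
            ContigSpec("cA", "A", 30_000, 0.0),
            ContigSpec("cB", "A", 30_000, 0.02),
        ))
        _, _, truth = generate_genome(cfg)
        assert (truth.sites["chrom"] == "cA").sum() == 0
        assert (truth.sites["chrom"] == "cB").sum() > 0

    def test_determinism_same_seed_same_bytes(self, tmp_path):
        cfg1 = small_config(seed=3)
        cfg2 = small_config(seed=3)
        b1, _ = write_bundle(cfg1, tmp_path / "a")
        b2, _ = write_bundle(cfg2, tmp_path / "b")
        for p1, p2 in [
            (b1.genome_fasta, b2.genome_fasta), (b1.gtf, b2.gtf),
            (b1.expression, b2.expression), (b1.de_table, b2.de_table),
            (b1.read_calls, b2.read_calls), (b1.truth_sites, b2.truth_sites),
        ]:
            assert p1.read_bytes() == p2.read_bytes()
        for s in b1.reports:
            assert b1.reports[s].read_bytes() == b2.reports[s].read_bytes()

    def test_realized_cpg_count_in_binomial_range(self):
        cfg = SimConfig(seed=5, contig_specs=(ContigSpec("c", "A", 50_000, 0.02),),
                        genes_per_contig=8)
        seqs, _, truth = generate_genome(cfg)
        n = (truth.sites["chrom"] == "c").sum()
        assert 800 <= n <= 1200  # Binomial(50k, 0.02) +- ~6 sd, minus overlaps

    def test_realized_density_within_20pct_of_spec(self, sequences, sim_config):
        for spec in sim_config.contig_specs:
            seq = sequences[spec.name]
            realized = seq.count("CG") / len(seq)
            assert realized == pytest.approx(spec.cpg_density, rel=0.2)

    def test_each_gene_bearing_contig_has_genes(self, genes, sim_config):
        with_genes = {g.chrom for g in genes}
        for spec in sim_config.contig_specs:
            if spec.linkage in ("A", "X"):
                assert spec.name in with_genes
            else:
                assert spec.name not in with_genes

    def test_xist_gene_has_cpg_island_at_5prime(self, genes, truth, sim_config):
        xist = next(g for g in genes if g.gene_id == sim_config.xist_like_gene_id)
        assert truth.contig_class[xist.chrom] == "X"
        loc = truth.asm_locus
        assert loc.contig == xist.chrom
        bs, _ = xist.gene_body
        assert loc.start0 == bs  # island sits at the gene's 5' end

    def test_truth_sites_unique(self, truth):
        assert not truth.sites.duplicated(subset=["chrom", "pos0"]).any()


class TestMethylomes:
    def test_female_y_coverage_is_zero(self, methylomes, sim_config):
        for sample, sex in sim_config.samples:
            df = methylomes[sample]
            y = df[df["chrom"].str.startswith("contigY")]
            if sex == "female":
                assert (y["m"] + y["u"]).sum() == 0
            else:
                assert (y["m"] + y["u"]).sum() > 0

    def test_autosomal_coverage_mean_is_two_alleles(self):
        cfg = small_config(per_allele_depth=6.0,
                           contig_specs=(ContigSpec("cA", "A", 60_000, 0.02),),
                           genes_per_contig=4)
        _, _, truth = generate_genome(cfg)
        meth = simulate_methylomes(cfg, truth)
        merged = merge_symmetric_cpgs(meth["F1"])
        cov = merged["m"] + merged["u"]
        assert len(cov) >= 1000
        assert 11 <= cov.mean() <= 13  # sum of two Poisson(6) alleles

    def test_fully_methylated_truth_gives_m_equal_coverage(self):
        cfg = small_config()
        sites = pd.DataFrame({
            "chrom": "cA", "pos0": np.arange(0, 2000, 2), "linkage": "A",
            "promoter_of": "",
            "meth_f_a": 1.0, "meth_f_b": 1.0, "meth_m_a": 1.0, "meth_m_b": 1.0,
        })
        truth = SimTruth({"cA": "A"}, sites, [], pd.DataFrame(), set(), None, "g")
        meth = simulate_methylomes(cfg, truth)
        for df in meth.values():
            assert (df["u"] == 0).all()

    def test_female_male_x_coverage_ratio_near_two(self, methylomes, sim_config):
        cov = {}
        for sample, sex in sim_config.samples:
            df = methylomes[sample]
            x = df[df["chrom"] == "chrX"]
            cov.setdefault(sex, []).append((x["m"] + x["u"]).mean())
        ratio = np.mean(cov["female"]) / np.mean(cov["male"])
        assert 1.8 <= ratio <= 2.2

    def test_autosomal_coverage_balanced_between_sexes(self, methylomes, sim_config):
        cov = {}
        for sample, sex in sim_config.samples:
            df = methylomes[sample]
            a = df[df["chrom"] == "chrA1"]
            cov.setdefault(sex, []).append((a["m"] + a["u"]).mean())
        assert abs(1 - np.mean(cov["female"]) / np.mean(cov["male"])) < 0.2

    def test_empirical_site_methylation_tracks_truth(self, methylomes, truth, sim_config):
        # averaged over samples and sites at >= 15x pooled coverage, the
        # empirical fraction deviates from truth by < 0.03 per sex
        site_tbl = CpGSiteTable.from_sample_frames(
            {s: merge_symmetric_cpgs(df) for s, df in methylomes.items()})
        m, cov = site_tbl.m(), site_tbl.coverage()
        sites = truth.sites.set_index(["chrom", "pos0"])
        for sex, cols, tcols in [
            ("female", [s for s, x in sim_config.samples if x == "female"],
             ["meth_f_a", "meth_f_b"]),
            ("male", [s for s, x in sim_config.samples if x == "male"],
             ["meth_m_a", "meth_m_b"]),
        ]:
            pooled_cov = cov[cols].sum(axis=1)
            with np.errstate(invalid="ignore"):
                emp = m[cols].sum(axis=1) / pooled_cov
            true = sites[tcols].mean(axis=1).reindex(emp.index)
            ok = (pooled_cov >= 15) & true.notna()
            err = (emp[ok] - true[ok]).mean()
            assert abs(err) < 0.03


class TestExpression:
    def test_xist_like_gene_female_restricted(self, sim_config, truth):
        expr, _, _ = simulate_expression(sim_config, truth)
        xist = expr.loc[sim_config.xist_like_gene_id]
        females = [s for s, x in sim_config.samples if x == "female"]
        males = [s for s, x in sim_config.samples if x == "male"]
        assert xist[males].mean() < 0.01 * xist[females].mean()

    def test_noiseless_monotone_link_gives_rho_minus_one(self):
        cfg = small_config(noise_sd=0.0, de_fraction=0.0)
        _, _, truth = generate_genome(cfg)
        expr, _, _ = simulate_expression(cfg, truth)
        gt = truth.gene_truth.set_index("gene_id")
        gt = gt.drop(index=cfg.xist_like_gene_id)  # sex-restricted by construction
        males = [s for s, x in cfg.samples if x == "male"]
        rho = stats.spearmanr(gt["promoter_male"],
                              expr.loc[gt.index, males].mean(axis=1)).statistic
        assert rho == pytest.approx(-1.0)

    def test_default_noise_gives_moderate_negative_rho(self):
        rhos = []
        for seed in range(5):
            cfg = SimConfig(
                seed=100 + seed,
                contig_specs=(ContigSpec("cA1", "A", 1_250_000, 0.02),
                              ContigSpec("cA2", "A", 1_250_000, 0.02)),
                genes_per_contig=250,
            )
            _, _, truth = generate_genome(cfg)
            expr, _, _ = simulate_expression(cfg, truth)
            gt = truth.gene_truth.set_index("gene_id")
            males = [s for s, x in cfg.samples if x == "male"]
            rhos.append(stats.spearmanr(
                gt["promoter_male"], expr.loc[gt.index, males].mean(axis=1)).statistic)
        assert -0.8 <= np.mean(rhos) <= -0.2

    def test_de_labels_mark_planted_effects(self, sim_config, truth):
        _, _, de = simulate_expression(sim_config, truth)
        de = de.set_index("gene_id")
        assert set(de.index[de["significant"]]) == truth.de_genes
        gt = truth.gene_truth.set_index("gene_id")
        planted = set(gt.index[gt["sex_effect_log2"].abs() >= sim_config.de_lfc_threshold])
        assert planted | {sim_config.xist_like_gene_id} == truth.de_genes


class TestReadsAtLocus:
    def test_pure_allele_rates_give_binary_fractions(self, sim_config, truth):
        calls, _ = simulate_reads_at_locus(sim_config, truth, n_reads=40,
                                           allele_rates=(1.0, 0.0))
        frac = calls.groupby("read_id")["methylated"].mean()
        assert set(frac.unique()) <= {0.0, 1.0}

    def test_no_asm_gives_unimodal_middle(self, sim_config, truth):
        calls, _ = simulate_reads_at_locus(sim_config, truth, n_reads=200,
                                           allele_rates=(0.5, 0.5))
        frac = calls.groupby("read_id")["methylated"].mean()
        extreme = ((frac <= 0.1) | (frac >= 0.9)).mean()
        assert extreme < 0.2
        assert 0.35 <= frac.mean() <= 0.65

    def test_extreme_read_fraction_at_09_01_rates(self, sim_config, truth):
        calls, _ = simulate_reads_at_locus(sim_config, truth, n_reads=1000,
                                           allele_rates=(0.9, 0.1))
        frac = calls.groupby("read_id")["methylated"].mean()
        extreme = ((frac <= 0.1) | (frac >= 0.9)).mean()
        assert 0.55 <= extreme <= 0.95

    def test_reads_span_minimum_cpgs(self, sim_config, truth):
        calls, _ = simulate_reads_at_locus(sim_config, truth, n_reads=50)
        loc = truth.asm_locus
        in_locus = calls[(calls["pos0"] >= loc.start0) & (calls["pos0"] < loc.end0)]
        assert (in_locus.groupby("read_id").size() >= 3).all()

    def test_locus_outside_contig_rejected(self, sim_config, truth):
        cfg = small_config()
        cfg.asm_locus = AsmLocusSpec("chrX", 29_000, 31_000)
        with pytest.raises(InvalidConfigError, match="bounds"):
            simulate_reads_at_locus(cfg, truth)

    def test_read_truth_alleles_match_call_rates(self, sim_config, truth):
        calls, read_truth = simulate_reads_at_locus(sim_config, truth, n_reads=100)
        frac = calls.groupby("read_id")["methylated"].mean()
        merged = read_truth.set_index("read_id").join(frac.rename("frac"))
        assert merged.loc[merged["allele"] == "a", "frac"].mean() > 0.8
        assert merged.loc[merged["allele"] == "b", "frac"].mean() < 0.2
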
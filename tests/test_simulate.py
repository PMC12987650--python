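"""Synthetic-data generators: determinism, conservation, planted recovery."""

import numpy as np
import pytest
from scipy import stats

from lncevo.popgen import faywu_h, tajima_d, tile_windows, weighted_fst
from lncevo.simulate import (DiffSpec, ExprSpec, SimConfig, SweepSpec,
                             gen_counterparts, gen_dbd_rna, gen_expression,
                             gen_genome, gen_pathways, gen_population,
                             plant_triplex_sites, read_fasta, write_fasta,
                             write_vcf)
from lncevo.triplex import align_triplex, revcomp, scan_promoters, TriplexParams


class TestGenome:
    def test_annotation_and_promoter_windows(self):
        cfg = SimConfig(seed=0, n_genes=10)
        ref, ann = gen_genome(cfg)
        assert len(ann) == 10
        for r in ann.itertuples():
            if r.strand == "+":
                s, e = r.tss - 3500, r.tss + 1500
            else:
                s, e = r.tss - 1499, r.tss + 3501
            assert 0 <= s < e <= len(ref)
            assert e - s == 5000

    def test_seed_determinism_byte_identical(self, tmp_path):
        outs = []
        for run in range(2):
            cfg = SimConfig(seed=1, n_genes=4)
            ref, ann = gen_genome(cfg)
            path = tmp_path / f"g{run}.fa"
            write_fasta({"chr1": ref}, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_minus_strand_promoter_reverse_complemented(self):
        from lncevo.triplex import extract_promoters

        cfg = SimConfig(seed=2, n_genes=4)
        ref, ann = gen_genome(cfg)
        wins = {w.transcript_id: w for w in extract_promoters(ann, ref)}
        minus = ann[ann.strand == "-"].iloc[0]
        w = wins[minus.transcript_id]
        assert w.sequence == revcomp(ref[w.genome_start:w.genome_end])


class TestPlanting:
    def test_perfect_plant_gives_full_identity_alignment(self):
        cfg = SimConfig(seed=3, n_genes=2)
        ref, ann = gen_genome(cfg)
        rna = gen_dbd_rna(100, 1)
        ref, gt = plant_triplex_sites(ref, ann, rna, [(ann.gene_id[0], 100, 1.0)],
                                      rng=2)
        site = gt.planted_sites[0]
        tract = ref[site["genome_start"]:site["genome_end"]]
        if site["strand"] == "-":
            tract = revcomp(tract)
        pairs = align_triplex(rna[:100], tract)
        assert any(p.identity_percent == 100.0 and p.length == 100 for p in pairs)

    def test_partial_identity_plant_recovers_matching_affinity(self):
        cfg = SimConfig(seed=4, n_genes=2)
        ref, ann = gen_genome(cfg)
        rna = gen_dbd_rna(100, 2)
        ref, gt = plant_triplex_sites(ref, ann, rna, [(ann.gene_id[0], 100, 0.6)],
                                      rng=3)
        table, _ = scan_promoters({"L": rna}, ann, ref)
        site = gt.planted_sites[0]
        hit = table[(table.gene_id == site["gene_id"])
                    & (table.start < site["genome_end"])
                    & (table.end > site["genome_start"])]
        assert len(hit)
        assert abs(hit.affinity.max() - 60.0) <= 5.0

    def test_low_identity_plant_yields_no_strong_dbs(self):
        cfg = SimConfig(seed=5, n_genes=2)
        ref, ann = gen_genome(cfg)
        rna = gen_dbd_rna(100, 6)
        ref, gt = plant_triplex_sites(ref, ann, rna, [(ann.gene_id[0], 100, 0.4)],
                                      rng=4)
        table, _ = scan_promoters({"L": rna}, ann, ref)
        site = gt.planted_sites[0]
        hit = table[(table.gene_id == site["gene_id"])
                    & (table.dbs_class == "strong")
                    & (table.start < site["genome_end"])
                    & (table.end > site["genome_start"])]
        assert len(hit) == 0

    def test_invalid_plan_rejected(self):
        cfg = SimConfig(seed=6, n_genes=2)
        ref, ann = gen_genome(cfg)
        rna = gen_dbd_rna(200, 1)
        with pytest.raises(ValueError):
            plant_triplex_sites(ref, ann, rna, [(ann.gene_id[0], 100, 1.5)])
        with pytest.raises(ValueError):
            plant_triplex_sites(ref, ann, rna, [(ann.gene_id[0], 20, 1.0)])
        with pytest.raises(ValueError):
            plant_triplex_sites(ref, ann, rna, [(ann.gene_id[0], 6000, 1.0)])

    def test_strand_symmetric_recovery(self):
        # the same promoter content seen from a minus-strand gene (genomic
        # slice = reverse complement) must yield identical DBSs
        import pandas as pd

        rng = np.random.default_rng(8)
        rna = gen_dbd_rna(100, 3)
        promoter = "".join(rng.choice(list("ACGT"), 5000))
        tract = "".join({"T": "A", "C": "G", "G": "A"}[b] for b in rna)
        promoter = promoter[:1000] + tract + promoter[1000 + len(tract):]
        pad = "".join(rng.choice(list("ACGT"), 200))
        genome_plus = promoter + pad
        genome_minus = revcomp(promoter) + pad
        ann_plus = pd.DataFrame([{"gene_id": "g", "transcript_id": "g.t1",
                                  "chrom": "chr1", "tss": 3500, "strand": "+"}])
        ann_minus = pd.DataFrame([{"gene_id": "g", "transcript_id": "g.t1",
                                   "chrom": "chr1", "tss": 1499, "strand": "-"}])
        t_plus, _ = scan_promoters({"L": rna}, ann_plus, genome_plus)
        t_minus, _ = scan_promoters({"L": rna}, ann_minus, genome_minus)
        cols = ["promoter_start", "promoter_end", "affinity",
                "mean_identity_percent", "dbs_class"]
        assert t_plus[cols].round(9).values.tolist() == \
            t_minus[cols].round(9).values.tolist()


class TestPopulations:
    def test_neutral_mean_tajima_d_near_zero(self):
        cfg = SimConfig(seed=11, n_haplotypes_per_pop=50, theta=0.002,
                        populations=("CEU",))
        panels = gen_population(150000, cfg)
        ds = [tajima_d(panels["CEU"], w).tajima_D
              for w in tile_windows(0, 150000, 1500)]
        ds = [d for d in ds if not np.isnan(d)]
        assert len(ds) >= 90
        assert abs(np.mean(ds)) <= 0.3

    def test_sweep_window_drives_d_and_h_negative(self):
        neg_d = neg_h = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = SimConfig(seed=1000 + seed, n_haplotypes_per_pop=50, theta=0.01,
                            populations=("CEU",),
                            sweep_spec=SweepSpec(window=(0, 2000), skew=0.9,
                                                 pops=("CEU",)))
            st = faywu_h(gen_population(4000, cfg)["CEU"], (0, 2000))
            neg_d += st.tajima_D < 0
            neg_h += st.faywu_H < 0
        assert neg_d >= 0.9 * n_seeds
        assert neg_h >= 0.9 * n_seeds

    def test_no_differentiation_gives_low_fst(self):
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(seed=2000 + seed, n_haplotypes_per_pop=50, theta=0.01,
                            populations=("CEU", "YRI"), diff_spec=DiffSpec(fst=0.0))
            panels = gen_population(3000, cfg)
            f = weighted_fst(panels["CEU"], panels["YRI"], (0, 3000)).weighted_fst
            ok += f <= 0.05
        assert ok >= 0.95 * n_seeds

    def test_vcf_allele_counts_match_haplotype_matrix(self, tmp_path):
        from cyvcf2 import VCF

        cfg = SimConfig(seed=12, n_haplotypes_per_pop=20, theta=0.01,
                        populations=("CEU",))
        panels = gen_population(2000, cfg)
        panel = panels["CEU"]
        ref = "".join(np.random.default_rng(0).choice(list("ACGT"), 2000))
        path = tmp_path / "p.vcf"
        write_vcf(panel, ref, path)
        counts = []
        for rec in VCF(str(path)):
            gts = np.array([g[:2] for g in rec.genotypes])
            counts.append(int(gts.sum()))
        assert counts == panel.matrix.sum(axis=0).tolist()


class TestCounterparts:
    def test_zero_divergence_identical_and_deletions_missing(self):
        cfg = SimConfig(seed=13, divergence_chimp=0.0, divergence_archaic=0.0,
                        divergence_ancestor=0.0)
        ref = "ACGT" * 1000
        seqs, gt = gen_counterparts(ref, {"a": (0, 400), "b": (400, 800)},
                                    cfg, delete={"b"})
        assert seqs["chimp"]["a"] == ref[:400]
        assert "b" not in seqs["chimp"]
        assert gt.deleted_counterparts == ["b"]
        # archaic counterparts are still present for deleted chimp entries
        assert "b" in seqs["altai"]


class TestExpressionAndPathways:
    def test_low_noise_modules_have_high_within_correlation(self):
        cfg = SimConfig(seed=14)
        cfg.expr_spec = ExprSpec(n_modules=1, module_sizes=(10,), loading=1.0,
                                 noise_sd=0.05, n_noise_genes=5,
                                 n_noise_lncrnas=0, tissues=("t1",),
                                 samples_per_tissue=80)
        tpm, tissue, tg, _, _, gt = gen_expression(cfg)
        genes = [f"{g}.t1" for g in gt.module_members["module_1"]]
        sub = tpm.loc[genes].to_numpy()
        c = np.corrcoef(sub)
        iu = np.triu_indices(len(genes), 1)
        assert np.min(c[iu]) > 0.95

    def test_planted_eqtl_effect_recovered_by_ols(self):
        cfg = SimConfig(seed=15)
        cfg.expr_spec = ExprSpec(n_modules=1, module_sizes=(3,), noise_sd=0.3,
                                 tissues=("t1",), samples_per_tissue=100,
                                 n_noise_genes=0, n_noise_lncrnas=0,
                                 eqtls=(("MODG1_001", 0.5, 0.4),))
        tpm, tissue, tg, eqtl_table, geno, gt = gen_expression(cfg)
        es = eqtl_table[eqtl_table.gene == "MODG1_001"].es.iloc[0]
        assert abs(es - 0.5) <= 0.15

    def test_planted_pathway_hypergeometric_fdr(self):
        universe = [f"g{i}" for i in range(1000)]
        module = universe[:60]
        pathways, planted = gen_pathways(universe, module, rng=3)
        k = len(pathways[planted])
        p = stats.hypergeom.sf(k - 1, 1000, k, 60)
        assert p < 1e-10  # planted pathway fully inside the module

    def test_expression_determinism(self):
        runs = []
        for _ in range(2):
            cfg = SimConfig(seed=16)
            cfg.expr_spec = ExprSpec(n_modules=1, module_sizes=(5,),
                                     tissues=("t1",), samples_per_tissue=10,
                                     n_noise_genes=3, n_noise_lncrnas=2)
            tpm, *_ = gen_expression(cfg)
            runs.append(tpm.to_csv())
        assert runs[0] == runs[1]


def test_fasta_roundtrip(tmp_path):
    seqs = {"a": "ACGT" * 30, "b": "GGCC" * 10}
    write_fasta(seqs, tmp_path / "x.fa")
    assert read_fasta(tmp_path / "x.fa") == seqs


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(theta=-0.1)
    with pytest.raises(ValueError):
        SimConfig(n_genes=0)
    with pytest.raises(ValueError):
        SweepSpec(window=(0, 100), skew=1.5)
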
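"""End-to-end orchestration of the synthetic regulatory-evolution analysis.

Stages run in dependency order, each reading its inputs from and writing
its outputs to one output directory, so the CLI subcommands compose:

    simulate -> predict -> compare -> popgen -> expression -> egram

Every stage output embeds the config hash; a rerun with the same config
reproduces byte-identical files.  All thresholds default to the printed
values of the reference analysis (promoter window 3500/1500, affinity
60/36, distance thresholds 0.034/0.037, MAF 0.05/0.1, |ES| 0.5, |rho| 0.3,
FDRs 0.05/0.001/0.01, window sizes 1500/147, eGRAM affinity 60 / Pearson
0.5 / module size 50); the positive-selection thresholds are regenerated
from the synthetic genome background rather than taken from the reference
genome scan.
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

from . import distances, egram, expression, orthology, popgen, simulate, triplex

logger = logging.getLogger("lncevo")

STAGES = ("simulate", "predict", "hs-call", "compare", "popgen", "expression", "egram")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline thresholds and synthetic-study conditions."""

    seed: int = 0
    # promoter window
    promoter_upstream: int = 3500
    promoter_downstream: int = 1500
    # triplex / DBS
    tt_penalty: float = -1000.0
    cc_penalty: float = 0.0
    offset: int = 15
    min_identity_percent: float = 60.0
    min_nt: int = 50
    # distance / age thresholds
    age_distance: float = 0.034
    epoch_distance: float = 0.037
    epoch_top_fraction: float = 0.20
    # population genetics
    maf_common: float = 0.05
    maf_dbs: float = 0.1
    window_gene: int = 1500
    window_dbs: int = 147
    d_percentile: float = 10.0
    fst_percentile: float = 10.0
    fst_combiner: str = "mean"
    # expression
    es_min: float = 0.5
    rho_min: float = 0.3
    fdr_pairs: float = 0.05
    fdr_shift: float = 0.001
    min_tissue_samples: int = 10
    background_pairs: int = 2000
    # eGRAM
    affinity_min: float = 60.0
    pearson_min: float = 0.5
    module_size: int = 50
    enrich_fdr: float = 0.01
    # synthetic-study conditions
    n_genes: int = 72
    n_lnc_genes: int = 200
    n_hs: int = 66
    n_scan: int = 2
    dbd_length: int = 120
    n_haplotypes_per_pop: int = 200
    theta: float = 0.008
    divergence_chimp: float = 0.012
    divergence_archaic: float = 0.002
    divergence_ancestor: float = 0.004
    sweep_skew: float = 0.9
    n_deleted_counterparts: int = 2

    def to_text(self) -> str:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, val = line.split("=", 1)
            key, val = key.strip(), val.strip()
            if key not in types:
                raise PipelineError(f"unknown config key {key!r}")
            t = types[key]
            if t in ("int", int):
                kwargs[key] = int(val)
            elif t in ("float", float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]


def _header(cfg: PipelineConfig) -> str:
    from . import __version__

    return f"# lncevo {__version__} config={cfg.config_hash}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _read_tsv(path: Path) -> pd.DataFrame:
    if not path.exists():
        stage = path.stem
        raise PipelineError(f"missing upstream output {path.name} (run earlier stages)")
    return pd.read_csv(path, sep="\t", comment="#")


def _write_json(obj, path: Path, cfg: PipelineConfig) -> None:
    payload = {"_meta": {"config": cfg.config_hash}, "data": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)


# --- stages ----------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    """Generate every input: genome + annotation with planted triplex sites,
    lncRNA sequences, ortholog hit table, expression matrix, pathways."""
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(8)]
    sim = simulate.SimConfig(
        seed=cfg.seed,
        n_genes=cfg.n_genes,
        promoter_upstream=cfg.promoter_upstream,
        promoter_downstream=cfg.promoter_downstream,
        n_haplotypes_per_pop=cfg.n_haplotypes_per_pop,
        theta=cfg.theta,
        divergence_chimp=cfg.divergence_chimp,
        divergence_archaic=cfg.divergence_archaic,
        divergence_ancestor=cfg.divergence_ancestor,
    )
    reference, ann = simulate.gen_genome(sim, rngs[0])
    # two lncRNAs get planted target sites: a large module-sized set for the
    # first, a small set for the second
    lnc_names = [f"HSLNC{i+1}" for i in range(cfg.n_scan)]
    rnas = {name: simulate.gen_dbd_rna(cfg.dbd_length, rngs[1]) for name in lnc_names}
    genes = list(ann.gene_id)
    n1 = min(60, cfg.n_genes - 4)
    plan1 = [(g, cfg.dbd_length, 0.85) for g in genes[:n1]]
    plan2 = [(g, max(cfg.min_nt * 2, cfg.dbd_length - 10), 0.9)
             for g in genes[n1:n1 + 8]]
    reference, gt1 = simulate.plant_triplex_sites(
        reference, ann, rnas[lnc_names[0]], plan1,
        cfg.promoter_upstream, cfg.promoter_downstream, rngs[2])
    gt = gt1
    if cfg.n_scan > 1 and plan2:
        reference, gt2 = simulate.plant_triplex_sites(
            reference, ann, rnas[lnc_names[1]], plan2,
            cfg.promoter_upstream, cfg.promoter_downstream, rngs[2])
        gt.planted_sites.extend(gt2.planted_sites)
    simulate.write_fasta({"chr1": reference}, out / "genome.fa")
    simulate.write_fasta(rnas, out / "lncrnas.fa")
    _write_tsv(ann, out / "annotation.tsv", cfg)
    hits, hs_genes = simulate.gen_ortholog_hits(cfg.n_lnc_genes, cfg.n_hs, rng=rngs[3])
    _write_tsv(hits, out / "ortholog_hits.tsv", cfg)
    gt.to_json(out / "ground_truth.json")
    logger.info("simulate: %d genes, %d planted sites, %d lncRNA gene records",
                cfg.n_genes, len(gt.planted_sites), cfg.n_lnc_genes)


def stage_hs_call(cfg: PipelineConfig, out: Path) -> None:
    hits = orthology.read_hit_table(out / "ortholog_hits.tsv")
    genomes = sorted(hits.genome_id.unique())
    hs = orthology.call_hs_genes(hits, genomes)
    orthology.write_gene_list(hs, out / "hs_genes.tsv")
    logger.info("hs-call: %d human-specific genes of %d", len(hs),
                hits.gene_id.nunique())


def stage_predict(cfg: PipelineConfig, out: Path) -> None:
    genome = simulate.read_fasta(out / "genome.fa")["chr1"]
    rnas = simulate.read_fasta(out / "lncrnas.fa")
    ann = _read_tsv(out / "annotation.tsv")
    params = triplex.TriplexParams(
        tt_penalty=cfg.tt_penalty, cc_penalty=cfg.cc_penalty, offset=cfg.offset,
        min_identity_percent=cfg.min_identity_percent, min_nt=cfg.min_nt)
    table, dbds = triplex.scan_promoters(
        rnas, ann, genome, triplex.TriplexRuleset.preset("all"), params,
        cfg.promoter_upstream, cfg.promoter_downstream)
    table = table.copy()
    table.insert(0, "dbs_id", [f"DBS{i+1:05d}" for i in range(len(table))])
    _write_tsv(table, out / "dbs_table.tsv", cfg)
    bed = table[["chrom", "start", "end", "dbs_id", "affinity", "strand"]]
    bed.to_csv(out / "dbs.bed", sep="\t", index=False, header=False)
    dbd_rows = []
    for name, clusters in sorted(dbds.items()):
        for d in clusters:
            dbd_rows.append({"lncrna_id": name, "rank": d.rank,
                             "rna_start": d.rna_start, "rna_end": d.rna_end,
                             "n_dbs": d.n_dbs,
                             "summed_affinity": d.summed_affinity})
    _write_tsv(pd.DataFrame(dbd_rows), out / "dbd_table.tsv", cfg)
    logger.info("predict: %d DBSs (%d strong)", len(table),
                (table.dbs_class == "strong").sum())


def _strong_dbs(out: Path) -> pd.DataFrame:
    table = _read_tsv(out / "dbs_table.tsv")
    return table[table.dbs_class == "strong"].reset_index(drop=True)


def stage_compare(cfg: PipelineConfig, out: Path) -> None:
    genome = simulate.read_fasta(out / "genome.fa")["chr1"]
    strong = _strong_dbs(out)
    intervals = {r.dbs_id: (int(r.start), int(r.end)) for r in strong.itertuples()}
    delete = set(sorted(intervals)[: cfg.n_deleted_counterparts])
    sim = simulate.SimConfig(
        seed=cfg.seed, divergence_chimp=cfg.divergence_chimp,
        divergence_archaic=cfg.divergence_archaic,
        divergence_ancestor=cfg.divergence_ancestor)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[4])
    seqs, gt = simulate.gen_counterparts(genome, intervals, sim, delete, rng)
    for g in ("chimp", "altai", "denisovan", "vindija", "ancestor"):
        simulate.write_fasta(seqs[g], out / f"counterpart_{g}.fa")
    rows = []
    for dbs_id in sorted(intervals):
        human = seqs["modern"][dbs_id]
        k = {}
        for g in ("chimp", "altai", "denisovan", "vindija"):
            k[g] = distances.dbs_distance(human, seqs[g].get(dbs_id))
        age = distances.classify_age(k["chimp"], k["altai"], k["denisovan"],
                                     k["vindija"], cfg.age_distance)
        rows.append({"dbs_id": dbs_id, "k_chimp": k["chimp"],
                     "k_altai": k["altai"], "k_denisovan": k["denisovan"],
                     "k_vindija": k["vindija"],
                     "missing_chimp": dbs_id not in seqs["chimp"],
                     "age": age.age})
    dist = pd.DataFrame(rows)
    dist = distances.flag_epochs(dist, cfg.epoch_distance, cfg.epoch_distance,
                                 cfg.epoch_top_fraction)
    _write_tsv(dist, out / "distance_table.tsv", cfg)
    _, concordance = distances.ancestor_mode_distances(
        seqs["ancestor"],
        {g: seqs[g] for g in ("modern", "altai", "denisovan", "vindija", "chimp")})
    _write_json({"ancestor_concordance": concordance,
                 "deleted_counterparts": sorted(delete)},
                out / "compare_summary.json", cfg)
    logger.info("compare: %d counterpart sets, %d missing, concordance %.3f",
                len(intervals), len(delete), concordance)


def stage_popgen(cfg: PipelineConfig, out: Path) -> None:
    genome = simulate.read_fasta(out / "genome.fa")["chr1"]
    strong = _strong_dbs(out)
    # plant a sweep + differentiation on the first strong DBS of the genome
    target = strong.sort_values("start").iloc[0]
    sweep_win = (int(target.start), int(target.end))
    sim = simulate.SimConfig(
        seed=cfg.seed, n_haplotypes_per_pop=cfg.n_haplotypes_per_pop,
        theta=cfg.theta,
        sweep_spec=simulate.SweepSpec(window=sweep_win, skew=cfg.sweep_skew,
                                      pops=("CEU",)))
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[5])
    panels = simulate.gen_population(len(genome), sim, rng)
    for pop, panel in panels.items():
        simulate.write_vcf(panel, genome, out / f"panel_{pop}.vcf")
    pops = sorted(panels)
    # genome background at the DBS window size
    bg = {pop: [] for pop in pops}
    fst_bg = []
    wins = popgen.tile_windows(0, len(genome), cfg.window_dbs)
    pairs = [("CEU", "CHB"), ("CEU", "YRI"), ("CHB", "YRI")]
    for win in wins:
        for pop in pops:
            bg[pop].append(popgen.tajima_d(panels[pop], win).tajima_D)
        pw = {f"{a}-{b}": popgen.weighted_fst(panels[a], panels[b], win).weighted_fst
              for a, b in pairs}
        fst_bg.append(popgen.integrated_fst(pw, "CEU", cfg.fst_combiner))
    d_thr = {}
    for pop in pops:
        d_thr[pop], _ = popgen.genome_background(bg[pop], cfg.d_percentile, "lower")
    fst_thr, _ = popgen.genome_background(fst_bg, cfg.fst_percentile, "upper")
    thresholds = {"tajima_d": d_thr, "integrated_fst": fst_thr,
                  "window_dbs": cfg.window_dbs}
    _write_json(thresholds, out / "selection_thresholds.json", cfg)
    # per-DBS stats and joint calls
    rows = []
    calls = []
    for r in strong.itertuples():
        win = (int(r.start), int(r.end))
        d_vals = {}
        st_by_pop = {}
        for pop in pops:
            st = popgen.window_stats(panels[pop], win)
            st_by_pop[pop] = st
            d_vals[pop] = st.tajima_D
        pw = {f"{a}-{b}": popgen.weighted_fst(panels[a], panels[b], win).weighted_fst
              for a, b in pairs}
        fst_by_pop = {pop: popgen.integrated_fst(pw, pop, cfg.fst_combiner)
                      for pop in pops}
        n_snps, density = popgen.snp_density(panels["CEU"], win, cfg.maf_dbs)
        row = {"dbs_id": r.dbs_id, "start": win[0], "end": win[1],
               "snp_count": n_snps, "snp_per_base": density}
        for pop in pops:
            st = st_by_pop[pop]
            row[f"S_{pop}"] = st.S
            row[f"pi_{pop}"] = st.pi
            row[f"tajima_d_{pop}"] = st.tajima_D
            row[f"faywu_h_{pop}"] = st.faywu_H
            row[f"fst_int_{pop}"] = fst_by_pop[pop]
        for key, v in pw.items():
            row[f"fst_{key}"] = v
        rows.append(row)
        # the integrated Fst entering the joint rule is focal-population specific
        for pop in pops:
            pop_calls = popgen.joint_selection_call(
                r.dbs_id, d_vals, fst_by_pop[pop], d_thr, fst_thr)
            call = next(c for c in pop_calls if c.population == pop)
            calls.append({"dbs_id": r.dbs_id, "population": pop,
                          "is_positive": call.is_positive})
    _write_tsv(pd.DataFrame(rows), out / "popgen_stats.tsv", cfg)
    _write_tsv(pd.DataFrame(calls), out / "selection_calls.tsv", cfg)
    logger.info("popgen: %d DBS windows, %d positive calls",
                len(rows), sum(c["is_positive"] for c in calls))


def stage_expression(cfg: PipelineConfig, out: Path) -> None:
    strong = _strong_dbs(out)
    dist = _read_tsv(out / "distance_table.tsv")
    lncs = sorted(strong.lncrna_id.unique())
    targets = {l: sorted(strong[strong.lncrna_id == l].gene_id.unique())
               for l in lncs}
    # module m of the expression model = targets of lncRNA m; genes bound by
    # several lncRNAs are assigned to the first (modules partition the genes)
    gene_pool = []
    sizes = []
    assigned = set()
    for l in lncs:
        mine = [g for g in targets[l] if g not in assigned]
        assigned.update(mine)
        gene_pool.extend(mine)
        sizes.append(len(mine))
    # plant eQTLs inside the strong DBSs of the first lncRNA (one per target
    # gene, the last one below the effect-size threshold)
    eqtl_dbs = (strong[strong.lncrna_id == lncs[0]]
                .drop_duplicates("gene_id").head(60))
    effect_cycle = (0.8, 0.7, 0.9, 0.6, 1.0)
    effects = [effect_cycle[i % len(effect_cycle)] for i in range(len(eqtl_dbs))]
    if effects:
        effects[-1] = 0.2
    eqtls = tuple((r.gene_id, eff, 0.3)
                  for r, eff in zip(eqtl_dbs.itertuples(), effects))
    sim = simulate.SimConfig(seed=cfg.seed)
    sim.expr_spec = simulate.ExprSpec(
        n_modules=len(lncs), module_sizes=tuple(sizes), eqtls=eqtls)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[6])
    tpm, tissue, tgene, eqtl_table, geno, gt = simulate.gen_expression(
        sim, target_genes=gene_pool, rng=rng)
    # the planted regulators stand in for the scanned lncRNAs
    rename = {f"REG{i+1}.t1": f"{l}.t1" for i, l in enumerate(lncs)}
    tpm = tpm.rename(index=rename)
    tgene = tgene.rename(index=rename)
    tgene[list(rename.values())] = lncs
    # merge the expression ground truth into the simulation record
    full_gt = simulate.GroundTruth.from_json(out / "ground_truth.json")
    full_gt.module_members = gt.module_members
    full_gt.module_regulators = {
        name: [rename.get(r, r) for r in regs]
        for name, regs in gt.module_regulators.items()
    }
    full_gt.eqtl_effects = gt.eqtl_effects
    full_gt.to_json(out / "ground_truth.json")
    tpm_out = tpm.reset_index(names="transcript_id")
    _write_tsv(tpm_out, out / "expression_tpm.tsv", cfg)
    _write_tsv(tissue.rename_axis("sample").reset_index(), out / "sample_tissue.tsv", cfg)
    matrix = expression.ExpressionMatrix(tpm, tissue, tgene)
    # representative transcript = the (only) DBD-carrying transcript here
    pairs = []
    pair_dbs = {}
    for l in lncs:
        rep = expression.representative_transcript(l, matrix, {f"{l}.t1"})
        for r in strong[strong.lncrna_id == l].itertuples():
            t = f"{r.gene_id}.t1"
            if t in tpm.index:
                pairs.append((rep, t))
                pair_dbs[(rep, t)] = r.dbs_id
    corr = expression.pair_correlations(
        pairs, matrix, min_samples=cfg.min_tissue_samples,
        rho_min=cfg.rho_min, fdr=cfg.fdr_pairs)
    _write_tsv(corr, out / "pair_correlations.tsv", cfg)
    lnc_bg = [t for t in tpm.index if t.startswith("BGL")]
    coding_bg = [t for t in tpm.index if t.startswith("BGG")]
    frac, ci = expression.random_pair_background(
        matrix, lnc_bg, coding_bg, n_pairs=cfg.background_pairs, seed=cfg.seed,
        min_samples=cfg.min_tissue_samples)
    # tissue shift: distances of the DBSs behind significant pairs, per tissue
    dist_by_dbs = dist.set_index("dbs_id")
    shift_rows = []
    for r in corr[corr.significant].itertuples():
        dbs_id = pair_dbs.get((r.lncrna, r.target))
        if dbs_id is None or dbs_id not in dist_by_dbs.index:
            continue
        for genome in ("altai", "denisovan", "vindija"):
            shift_rows.append({"tissue": r.tissue, "genome": genome,
                               "distance": dist_by_dbs.loc[dbs_id, f"k_{genome}"]})
    shift_df = pd.DataFrame(shift_rows, columns=["tissue", "genome", "distance"])
    if len(shift_df):
        shift_summary, shift_tests = expression.tissue_shift_test(
            shift_df, fdr=cfg.fdr_shift)
    else:
        shift_summary = pd.DataFrame(columns=["tissue", "epoch"])
        shift_tests = pd.DataFrame(columns=["tissue", "genome", "ks_stat", "p"])
    _write_tsv(shift_summary, out / "tissue_shift.tsv", cfg)
    # eQTL analysis: positions planted inside the chosen DBSs
    snp_pos = {f"eqtl_snp_{j+1}": int((r.start + r.end) // 2)
               for j, r in enumerate(eqtl_dbs.itertuples())}
    eqtl_table = eqtl_table.assign(
        position=[snp_pos[s] for s in eqtl_table.snp_id])
    maf_rows = [{"snp_id": s, "population": p, "maf": 0.3}
                for s in snp_pos for p in ("CEU", "CHB", "YRI")]
    dbs_iv = strong[["dbs_id", "start", "end"]].copy()
    missing = set(dist[dist.missing_chimp].dbs_id) if "missing_chimp" in dist else set()
    for g in ("altai", "denisovan", "vindija"):
        dbs_iv[f"present_{g}"] = True  # archaic counterparts always mapped here
    records = expression.filter_eqtls(
        eqtl_table, pd.DataFrame(maf_rows), dbs_iv,
        maf_min=cfg.maf_dbs, es_min=cfg.es_min)
    _write_tsv(records, out / "eqtl_records.tsv", cfg)
    ann = _read_tsv(out / "annotation.tsv")
    prom_iv = []
    for r in ann.itertuples():
        s = r.tss - cfg.promoter_upstream if r.strand == "+" \
            else r.tss - cfg.promoter_downstream + 1
        prom_iv.append((int(s), int(s + cfg.promoter_upstream + cfg.promoter_downstream)))
    u_stat, u_p = expression.eqtl_density_compare(
        [(int(r.start), int(r.end)) for r in strong.itertuples()],
        prom_iv, list(snp_pos.values()))
    _write_json(
        {"n_pairs": len(pairs),
         "n_tests": int(len(corr)),
         "frac_significant": float(corr.significant.mean()) if len(corr) else None,
         "random_pair_fraction": frac,
         "random_pair_ci": list(ci),
         "eqtl_density_U": u_stat, "eqtl_density_p": u_p,
         "n_qualifying_eqtls": int(len(records))},
        out / "expression_summary.json", cfg)
    logger.info("expression: %d pair tests, %.1f%% significant, background %.2f%%",
                len(corr), 100 * corr.significant.mean() if len(corr) else 0.0,
                100 * frac)


def stage_egram(cfg: PipelineConfig, out: Path) -> None:
    strong = _strong_dbs(out)
    tpm = _read_tsv(out / "expression_tpm.tsv").set_index("transcript_id")
    tissue = _read_tsv(out / "sample_tissue.tsv").set_index("sample").iloc[:, 0]
    gt = simulate.GroundTruth.from_json(out / "ground_truth.json")
    lncs = sorted(strong.lncrna_id.unique())
    # gene-level expression: one transcript per gene in the synthetic data
    gene_expr = tpm.copy()
    gene_expr.index = [t.rsplit(".", 1)[0] for t in tpm.index]
    reg_expr = tpm.loc[[f"{l}.t1" for l in lncs]]
    reg_expr.index = lncs
    params = egram.EgramParams(
        affinity_min=cfg.affinity_min, pearson_min=cfg.pearson_min,
        module_size=cfg.module_size, enrich_fdr=cfg.enrich_fdr)
    binding = (strong.groupby(["lncrna_id", "gene_id"]).affinity.max()
               .reset_index()
               .rename(columns={"lncrna_id": "regulator", "gene_id": "gene"}))
    reg_sets = egram.coregulator_sets(reg_expr, params)
    targets = {l: egram.regulator_targets(l, binding, gene_expr, reg_expr, params)
               for l in lncs}
    modules = egram.form_modules(reg_sets, targets, gene_expr, params)
    universe = set(gene_expr.index)
    rngp = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[7])
    first_module = next(iter(gt.module_members.values())) if gt.module_members else []
    pathways, planted = simulate.gen_pathways(sorted(universe), first_module,
                                              rng=rngp)
    egram.write_gmt(pathways, out / "pathways.gmt")
    mod_payload = []
    for m in modules:
        enr = egram.enrich_pathways(m, pathways, universe, params)
        m.pathways = enr
        mod_payload.append({"regulators": list(m.regulators),
                            "n_genes": len(m.genes),
                            "genes": list(m.genes),
                            "mean_r": m.mean_r,
                            "enriched_pathways": list(enr.pathway)})
    _write_json(mod_payload, out / "modules.json", cfg)
    coreg = egram.cross_module_check(modules, [])
    _write_tsv(coreg, out / "coregulation.tsv", cfg)
    # cross-species self-comparison (identity ortholog map) as the built-in
    # sanity check of the comparison operation
    report = egram.compare_species_modules(
        modules, gene_expr, reg_expr, gene_expr, reg_expr,
        {g: g for g in gene_expr.index} | {l: l for l in lncs}, params)
    _write_tsv(report, out / "cross_species.tsv", cfg)
    # planted-module recovery
    best_jaccard = {}
    for name, members in gt.module_members.items():
        planted_set = set(members)
        j = 0.0
        for m in modules:
            g = set(m.genes)
            if g | planted_set:
                j = max(j, len(g & planted_set) / len(g | planted_set))
        best_jaccard[name] = j
    _write_json({"n_modules": len(modules),
                 "planted_jaccard": best_jaccard,
                 "planted_pathway": planted,
                 "planted_pathway_enriched": any(
                     planted in p["enriched_pathways"] for p in mod_payload)},
                out / "egram_summary.json", cfg)
    logger.info("egram: %d modules, jaccard %s", len(modules), best_jaccard)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "hs-call": stage_hs_call,
    "predict": stage_predict,
    "compare": stage_compare,
    "popgen": stage_popgen,
    "expression": stage_expression,
    "egram": stage_egram,
}

_STAGE_ORDER = ("simulate", "hs-call", "predict", "compare", "popgen",
                "expression", "egram")


def run_pipeline(cfg: PipelineConfig, outdir, stages=None) -> dict:
    """Run the requested stages (default: all) in dependency order."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages else list(_STAGE_ORDER)
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    (out / "config.txt").write_text(_header(cfg) + cfg.to_text())
    for stage in _STAGE_ORDER:
        if stage in stages:
            logger.info("running stage %s", stage)
            _STAGE_FUNCS[stage](cfg, out)
    return summarize(out)


def summarize(outdir) -> dict:
    """Collect the main computed quantities from a pipeline output directory."""
    out = Path(outdir)
    summary = {}
    f = out / "hs_genes.tsv"
    if f.exists():
        summary["n_hs_genes"] = int(len(pd.read_csv(f, sep="\t")))
    f = out / "dbs_table.tsv"
    if f.exists():
        t = pd.read_csv(f, sep="\t", comment="#")
        summary["n_dbs"] = int(len(t))
        summary["n_strong_dbs"] = int((t.dbs_class == "strong").sum())
        strong = t[t.dbs_class == "strong"]
        summary["mean_strong_length"] = float(strong.length.mean()) if len(strong) else None
    for name in ("compare_summary", "expression_summary", "egram_summary"):
        f = out / f"{name}.json"
        if f.exists():
            with open(f) as fh:
                summary[name] = json.load(fh)["data"]
    f = out / "selection_calls.tsv"
    if f.exists():
        calls = pd.read_csv(f, sep="\t", comment="#")
        summary["n_positive_calls"] = int(calls.is_positive.sum())
    return summary


def output_hashes(outdir) -> dict:
    """sha256 of every pipeline output file (for determinism checks)."""
    out = Path(outdir)
    hashes = {}
    for path in sorted(out.glob("*")):
        if path.is_file():
            hashes[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return hashes


def validate_inputs(paths: dict) -> list[str]:
    """Well-formedness report for a bundle of input files.

    `paths` may contain keys genome, annotation, vcfs (list), gmt.
    Returns a list of human-readable problems (empty = clean).
    """
    problems = []
    genome = None
    if "genome" in paths:
        try:
            seqs = simulate.read_fasta(paths["genome"])
            if not seqs:
                problems.append(f"{paths['genome']}: no FASTA records")
            else:
                genome = next(iter(seqs.values()))
        except Exception as exc:
            problems.append(f"{paths['genome']}: unreadable FASTA ({exc})")
    if "annotation" in paths:
        try:
            ann = pd.read_csv(paths["annotation"], sep="\t", comment="#")
            for col in ("gene_id", "transcript_id", "tss", "strand"):
                if col not in ann.columns:
                    problems.append(f"annotation: missing column {col}")
            if genome is not None and "tss" in ann.columns:
                bad = ann[(ann.tss < 0) | (ann.tss >= len(genome))]
                for r in bad.itertuples():
                    problems.append(
                        f"annotation: TSS {r.tss} of {r.transcript_id} outside contig")
        except Exception as exc:
            problems.append(f"annotation: unreadable ({exc})")
    for vcf_path in paths.get("vcfs", []):
        try:
            last = -1
            with open(vcf_path) as fh:
                for i, line in enumerate(fh, 1):
                    if line.startswith("#"):
                        continue
                    pos = int(line.split("\t", 3)[1])
                    if pos < last:
                        problems.append(
                            f"{vcf_path}: unsorted record at line {i} (POS {pos})")
                        break
                    last = pos
        except Exception as exc:
            problems.append(f"{vcf_path}: unreadable ({exc})")
    if "gmt" in paths:
        with open(paths["gmt"]) as fh:
            for i, line in enumerate(fh, 1):
                if line.strip() and len(line.rstrip("\n").split("\t")) < 3:
                    problems.append(f"{paths['gmt']}: malformed line {i}")
    return problems
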
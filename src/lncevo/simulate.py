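"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the shapes of the real inputs — promoter sequences
with plantable triplex sites, phased population haplotype panels with a
controllable site-frequency-spectrum skew and between-population
differentiation, chimpanzee/archaic counterpart sequences at controlled
per-base divergence (including deleted counterparts), TPM expression
matrices with planted regulator-driven modules and additive eQTL effects,
and pathway files with one planted enriched pathway — and record the
planted ground truth so downstream recovery can be quantified.

Design notes:

* Haplotype panels are NOT coalescent simulations.  Sites are independent
  (free recombination); each site's derived count is resampled from the
  neutral 1/i frequency spectrum (sweeps: a mixture skewed toward
  singletons and near-fixed derived alleles; differentiation:
  Balding–Nichols per-population frequencies).  This is sufficient to drive
  the signs of Tajima's D, Fay–Wu's H and Fst without linked-selection
  realism.
* Counterpart genomes use independent per-site substitutions (no indels)
  with a 2:1 transition:transversion ratio, chained modern → archaic →
  ancestor → chimpanzee so archaic genomes are intermediate.
* Expression is a latent-factor model on a shifted-Gaussian TPM scale;
  eQTL effects are additive per alternate allele, and the emitted effect
  sizes are re-estimated from the generated data by OLS (mimicking how
  consortium effect sizes are produced, rather than echoing the planted
  value).

Identical configs (same seed) produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import HaplotypePanel

__all__ = [
    "SweepSpec",
    "DiffSpec",
    "ExprSpec",
    "SimConfig",
    "GroundTruth",
    "gen_genome",
    "gen_dbd_rna",
    "plant_triplex_sites",
    "gen_population",
    "gen_counterparts",
    "gen_expression",
    "gen_pathways",
    "gen_ortholog_hits",
    "write_fasta",
    "read_fasta",
    "write_vcf",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SweepSpec:
    """Skew the site frequency spectrum inside a window for focal pops."""

    window: tuple[int, int]
    skew: float = 0.8  # probability a site uses the swept spectrum
    pops: tuple = ("CEU",)
    # in NON-focal populations, window sites are drawn at intermediate
    # frequency with probability skew*contrast: the planted locus keeps
    # ancestral diversity (D > 0) outside the swept population, the
    # configuration the joint selection rule is designed to detect
    contrast: float = 0.5

    def __post_init__(self):
        if not (0 <= self.skew <= 1):
            raise ValueError("skew must be in [0, 1]")
        if not (0 <= self.contrast <= 1):
            raise ValueError("contrast must be in [0, 1]")


@dataclass(frozen=True)
class DiffSpec:
    """Balding–Nichols differentiation between population frequencies."""

    fst: float = 0.0  # baseline differentiation for all sites

    def __post_init__(self):
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")


@dataclass
class ExprSpec:
    n_modules: int = 2
    module_sizes: tuple = (60, 60)
    loading: float = 1.0
    noise_sd: float = 0.3
    tissues: tuple = ("frontal_cortex", "cingulate_cortex", "liver", "lung")
    samples_per_tissue: int = 60
    n_noise_genes: int = 120
    n_noise_lncrnas: int = 40  # unrelated lncRNAs for the random-pair null
    base_tpm: float = 5.0
    eqtls: tuple = ()  # (gene_id, effect, maf) triples filled by the pipeline


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 24
    promoter_upstream: int = 3500
    promoter_downstream: int = 1500
    n_haplotypes_per_pop: int = 200
    # per-site diversity; scaled above the human genome-wide value so that
    # the short windows the analysis uses carry enough segregating sites at
    # synthetic scale for the window statistics to be defined
    theta: float = 0.008
    divergence_chimp: float = 0.012
    divergence_archaic: float = 0.002
    divergence_ancestor: float = 0.004
    populations: tuple = ("CEU", "CHB", "YRI")
    sweep_spec: SweepSpec | None = None
    diff_spec: DiffSpec | None = None
    expr_spec: ExprSpec = field(default_factory=ExprSpec)

    @property
    def promoter_len(self) -> int:
        return self.promoter_upstream + self.promoter_downstream

    def __post_init__(self):
        for name in ("theta", "divergence_chimp", "divergence_archaic",
                     "divergence_ancestor"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < 1 or self.n_haplotypes_per_pop < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class GroundTruth:
    """Coordinates and identities of everything planted."""

    planted_sites: list = field(default_factory=list)  # dicts per site
    deleted_counterparts: list = field(default_factory=list)  # dbs ids
    swept_windows: list = field(default_factory=list)
    module_members: dict = field(default_factory=dict)  # module -> [genes]
    module_regulators: dict = field(default_factory=dict)
    eqtl_effects: list = field(default_factory=list)
    enriched_pathway: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def gen_genome(cfg: SimConfig, rng=None) -> tuple[str, pd.DataFrame]:
    """Random reference with evenly spaced gene loci on alternating strands.

    Each transcript's strand-oriented promoter window
    [TSS-upstream, TSS+downstream) is fully contained in its locus, so
    windows never overlap.
    """
    rng = _rng(cfg.seed if rng is None else rng)
    up, down = cfg.promoter_upstream, cfg.promoter_downstream
    margin = 400
    locus = up + down + 2 * margin
    length = cfg.n_genes * locus
    seq = rng.choice(_BASES, size=length)
    rows = []
    for i in range(cfg.n_genes):
        base = i * locus
        strand = "+" if i % 2 == 0 else "-"
        tss = base + margin + (up if strand == "+" else down)
        rows.append(
            {"gene_id": f"G{i+1:03d}", "transcript_id": f"G{i+1:03d}.t1",
             "chrom": "chr1", "tss": tss, "strand": strand}
        )
    ann = pd.DataFrame(rows)
    # sanity: promoter windows must not overlap
    spans = []
    for r in ann.itertuples():
        s = r.tss - up if r.strand == "+" else r.tss - down + 1
        spans.append((s, s + up + down))
    spans.sort()
    for (s1, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("promoter windows overlap")
    return "".join(seq), ann


_DBD_WEIGHTS = {"T": 0.55, "C": 0.25, "G": 0.20}
# DNA base written for a pairing position (parallel-motif triad partner)
_PAIR_BASE = {"T": "A", "U": "A", "C": "G", "G": "A"}
# non-pairing, non-barrier base per RNA base
_MISMATCH_BASE = {"T": "C", "U": "C", "C": "T", "G": "T", "A": "C"}


def gen_dbd_rna(length: int = 120, rng=0) -> str:
    """A triplex-competent (pyrimidine-rich) RNA to serve as the DBD donor."""
    rng = _rng(rng)
    bases = list(_DBD_WEIGHTS)
    probs = np.array(list(_DBD_WEIGHTS.values()))
    return "".join(rng.choice(bases, size=length, p=probs))


def plant_triplex_sites(
    reference: str,
    annotation: pd.DataFrame,
    dbd_rna_seq: str,
    plan: list[tuple[str, int, float]],
    upstream: int = 3500,
    downstream: int = 1500,
    rng=0,
) -> tuple[str, GroundTruth]:
    """Write triplex tracts into promoters so the aligner recovers them.

    plan entries are (gene_id, length, identity) with identity in (0, 1] and
    length >= 50.  The tract is the parallel-motif DNA partner of the first
    `length` RNA bases, with evenly spaced mismatches written as
    non-pairing, non-barrier bases to hit the requested identity.
    """
    rng = _rng(rng)
    seq = list(reference)
    gt = GroundTruth()
    ann = annotation.set_index("gene_id")
    for gene, length, identity in plan:
        if not (0 < identity <= 1):
            raise ValueError("identity must be in (0, 1]")
        if length < 50:
            raise ValueError("tract length must be >= 50")
        if length > upstream + downstream:
            raise ValueError("tract longer than promoter")
        if length > len(dbd_rna_seq):
            raise ValueError("tract longer than the DBD RNA")
        row = ann.loc[gene]
        tss, strand = int(row.tss), row.strand
        gstart = tss - upstream if strand == "+" else tss - downstream + 1
        gend = gstart + upstream + downstream
        # offset inside the strand-oriented promoter window
        off = int(rng.integers(200, upstream + downstream - length - 200))
        rna = dbd_rna_seq[:length].upper().replace("U", "T")
        tract = [_PAIR_BASE[b] for b in rna]
        n_mis = length - int(np.ceil(identity * length))
        if n_mis > 0:
            # evenly spaced mismatches keep every window near the target identity
            idx = np.unique(np.round(np.linspace(0, length - 1, n_mis + 2)[1:-1]).astype(int))
            for j in idx:
                tract[j] = _MISMATCH_BASE[rna[j]]
        tract = "".join(tract)
        if strand == "+":
            g0 = gstart + off
            seq[g0:g0 + length] = tract
        else:
            from .triplex import revcomp

            g1 = gend - off
            g0 = g1 - length
            seq[g0:g1] = revcomp(tract)
        gt.planted_sites.append(
            {"gene_id": gene, "transcript_id": row.transcript_id,
             "genome_start": int(g0), "genome_end": int(g0 + length),
             "promoter_offset": off, "length": int(length),
             "identity": float(identity), "strand": strand}
        )
    return "".join(seq), gt


# --- population panels -----------------------------------------------------


def _neutral_counts(n_sites: int, grid: int, rng) -> np.ndarray:
    """Derived counts on a hidden grid, sampled from the 1/i spectrum."""
    i = np.arange(1, grid)
    w = 1.0 / i
    return rng.choice(i, size=n_sites, p=w / w.sum())


def gen_population(
    region_length: int,
    cfg: SimConfig,
    rng=None,
) -> dict[str, HaplotypePanel]:
    """Phased biallelic panels for the configured populations.

    The number of segregating sites follows Watterson's expectation
    E[S] = theta * L * a1(n).  Reference alleles are ancestral (derived =
    alternate).  Under a SweepSpec, sites in the window (focal populations)
    draw from a spectrum concentrated on singletons and near-fixed derived
    alleles; under a DiffSpec, per-population frequencies are
    Balding–Nichols draws around the shared frequency.
    """
    if cfg.theta <= 0:
        raise ValueError("theta must be > 0")
    rng = _rng(cfg.seed + 1 if rng is None else rng)
    n = cfg.n_haplotypes_per_pop
    a1 = np.sum(1.0 / np.arange(1, n))
    n_sites = rng.poisson(cfg.theta * region_length * a1)
    n_sites = max(int(n_sites), 1)
    positions = np.sort(rng.choice(region_length, size=min(n_sites, region_length),
                                   replace=False))
    grid = 2 * n
    x = _neutral_counts(len(positions), grid, rng) / grid
    panels = {}
    fst = cfg.diff_spec.fst if cfg.diff_spec else 0.0
    sweep = cfg.sweep_spec
    for pop in cfg.populations:
        p = x.copy()
        if fst > 0:
            a = x * (1 - fst) / fst
            b = (1 - x) * (1 - fst) / fst
            p = rng.beta(a, b)
        if sweep is not None:
            in_win = (positions >= sweep.window[0]) & (positions < sweep.window[1])
            if pop in sweep.pops:
                hit = in_win & (rng.random(len(positions)) < sweep.skew)
                lows = rng.random(len(positions)) < 0.6
                p = np.where(hit & lows, 1.0 / n, p)
                p = np.where(hit & ~lows, (n - 1.0) / n, p)
            else:
                hit = in_win & (rng.random(len(positions)) < sweep.skew * sweep.contrast)
                mids = rng.uniform(0.35, 0.65, len(positions))
                p = np.where(hit, mids, p)
        counts = rng.binomial(n, p)
        mat = np.zeros((n, len(positions)), dtype=np.int8)
        for s, c in enumerate(counts):
            if c > 0:
                carriers = rng.choice(n, size=c, replace=False)
                mat[carriers, s] = 1
        panels[pop] = HaplotypePanel(
            matrix=mat,
            positions=positions,
            ancestral=np.zeros(len(positions), dtype=np.int8),
            population=pop,
        )
    return panels


def write_vcf(panel: HaplotypePanel, reference: str, path, contig="chr1") -> None:
    """Phased VCF 4.2 for one population (haplotypes paired into samples)."""
    n = panel.n - (panel.n % 2)
    samples = [f"{panel.population}_{i+1:03d}" for i in range(n // 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(reference)}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s, pos in enumerate(panel.positions):
            ref = reference[pos]
            alt = _TRANSITION[ref]
            anc = {0: ref, 1: alt}.get(int(panel.ancestral[s]), ".")
            gts = "\t".join(
                f"{panel.matrix[2*i, s]}|{panel.matrix[2*i+1, s]}"
                for i in range(n // 2)
            )
            fh.write(f"{contig}\t{pos+1}\t.\t{ref}\t{alt}\t.\tPASS\tAA={anc}\tGT\t{gts}\n")


# --- counterpart genomes ---------------------------------------------------


def _mutate(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        base = arr[i]
        if base not in _TRANSITION:
            continue
        if rng.random() < 2.0 / 3.0:
            arr[i] = _TRANSITION[base]
        else:
            arr[i] = _TRANSVERSIONS[base][rng.integers(2)]
    return "".join(arr)


def gen_counterparts(
    reference: str,
    intervals: dict[str, tuple[int, int]],
    cfg: SimConfig,
    delete: set[str] | frozenset = frozenset(),
    rng=None,
) -> tuple[dict[str, dict[str, str]], GroundTruth]:
    """Counterpart sequences per genome for each DBS interval.

    Genomes are chained modern → archaic (altai/denisovan/vindija, each an
    independent draw at divergence_archaic) → ancestor (extra
    divergence_ancestor on the altai branch) → chimp (the remaining
    human–chimp divergence), so total human↔chimp divergence matches
    divergence_chimp and archaic genomes are intermediate.  DBS ids in
    `delete` get no chimpanzee counterpart.
    """
    rng = _rng(cfg.seed + 2 if rng is None else rng)
    # split the modern–archaic divergence 2:1 around their common node so
    # archaic genomes sit between the ancestor and modern humans
    d_shared = 2.0 * cfg.divergence_archaic / 3.0
    d_branch = cfg.divergence_archaic / 3.0
    rest = max(cfg.divergence_chimp - d_shared - cfg.divergence_ancestor, 0.0)
    out: dict[str, dict[str, str]] = {
        g: {} for g in ("modern", "altai", "denisovan", "vindija", "ancestor", "chimp")
    }
    gt = GroundTruth(deleted_counterparts=sorted(delete))
    for dbs_id in sorted(intervals):
        s, e = intervals[dbs_id]
        human = reference[s:e]
        out["modern"][dbs_id] = human
        node = _mutate(human, d_shared, rng)
        for g in ("altai", "denisovan", "vindija"):
            out[g][dbs_id] = _mutate(node, d_branch, rng)
        ancestor = _mutate(node, cfg.divergence_ancestor, rng)
        out["ancestor"][dbs_id] = ancestor
        if dbs_id not in delete:
            out["chimp"][dbs_id] = _mutate(ancestor, rest, rng)
    return out, gt


def write_archaic_vcf(reference: str, counterpart_seqs: dict[str, str],
                      intervals: dict[str, tuple[int, int]], path,
                      sample: str, contig="chr1", rng=0) -> None:
    """Single-sample VCF of an archaic genome's SNVs inside the DBS regions
    (hom-alt calls with synthetic QUALs)."""
    rng = _rng(rng)
    records = []
    for dbs_id in sorted(counterpart_seqs):
        s, e = intervals[dbs_id]
        cseq = counterpart_seqs[dbs_id]
        for off, (a, b) in enumerate(zip(reference[s:e], cseq)):
            if a != b:
                records.append((s + off + 1, a, b, float(rng.integers(30, 90))))
    records.sort()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(reference)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for pos, ref, alt, qual in records:
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t{qual:.1f}\tPASS\t.\tGT\t1/1\n")


# --- expression ------------------------------------------------------------


def gen_expression(
    cfg: SimConfig,
    target_genes: list[str] | None = None,
    rng=None,
):
    """TPM matrix with planted regulator-driven modules and eQTL effects.

    Returns (tpm DataFrame, sample→tissue Series, transcript→gene Series,
    eqtl_table DataFrame, genotype DataFrame, GroundTruth).
    """
    spec = cfg.expr_spec
    rng = _rng(cfg.seed + 3 if rng is None else rng)
    samples = []
    tissue_of = []
    for t in spec.tissues:
        for i in range(spec.samples_per_tissue):
            samples.append(f"{t}_s{i+1:03d}")
            tissue_of.append(t)
    n_samp = len(samples)
    gt = GroundTruth()
    rows = {}
    tg = {}
    # planted modules: regulator transcript + member genes share a latent factor
    gene_pool = list(target_genes or [])
    next_gene = 0
    for m in range(spec.n_modules):
        size = spec.module_sizes[m % len(spec.module_sizes)]
        reg = f"REG{m+1}"
        reg_t = f"{reg}.t1"
        f = rng.normal(0, 1, n_samp)
        rows[reg_t] = spec.base_tpm + f + rng.normal(0, 0.1, n_samp)
        tg[reg_t] = reg
        members = []
        for _ in range(size):
            if next_gene < len(gene_pool):
                gene = gene_pool[next_gene]
                next_gene += 1
            else:
                gene = f"MODG{m+1}_{len(members)+1:03d}"
            t_id = f"{gene}.t1"
            rows[t_id] = (spec.base_tpm + spec.loading * f
                          + rng.normal(0, spec.noise_sd, n_samp))
            tg[t_id] = gene
            members.append(gene)
        gt.module_members[f"module_{m+1}"] = members
        gt.module_regulators[f"module_{m+1}"] = [reg_t]
    # independent background genes and lncRNAs
    for i in range(spec.n_noise_genes):
        gene = f"BGG{i+1:03d}"
        t_id = f"{gene}.t1"
        rows[t_id] = spec.base_tpm + rng.normal(0, 1.0, n_samp)
        tg[t_id] = gene
    for i in range(spec.n_noise_lncrnas):
        gene = f"BGL{i+1:03d}"
        t_id = f"{gene}.t1"
        rows[t_id] = spec.base_tpm + rng.normal(0, 1.0, n_samp)
        tg[t_id] = gene
    tpm = pd.DataFrame(rows, index=samples).T
    # additive eQTL effects, re-estimated per tissue by OLS
    genotypes = {}
    eqtl_rows = []
    tissue_arr = np.array(tissue_of)
    for j, entry in enumerate(spec.eqtls):
        gene, effect, maf = entry[0], float(entry[1]), float(entry[2])
        t_id = f"{gene}.t1"
        if t_id not in tpm.index:
            continue
        snp_id = f"eqtl_snp_{j+1}"
        g = rng.binomial(2, maf, n_samp).astype(float)
        genotypes[snp_id] = g
        tpm.loc[t_id] = tpm.loc[t_id].to_numpy() + effect * g
        for t in spec.tissues:
            mask = tissue_arr == t
            gg, yy = g[mask], tpm.loc[t_id].to_numpy()[mask]
            if np.ptp(gg) == 0:
                continue
            slope = float(np.polyfit(gg, yy, 1)[0])
            eqtl_rows.append({"snp_id": snp_id, "gene": gene, "tissue": t,
                              "es": slope})
        gt.eqtl_effects.append({"snp_id": snp_id, "gene": gene,
                                "effect": effect, "maf": maf})
    tpm = tpm.clip(lower=0.01)
    eqtl_table = pd.DataFrame(eqtl_rows, columns=["snp_id", "gene", "tissue", "es"])
    geno = pd.DataFrame(genotypes, index=samples).T
    return (
        tpm,
        pd.Series(tissue_of, index=samples, name="tissue"),
        pd.Series(tg, name="gene_id"),
        eqtl_table,
        geno,
        gt,
    )


def gen_pathways(
    universe: list[str],
    planted_module_genes: list[str],
    n_random: int = 20,
    planted_size: int = 30,
    rng=0,
) -> tuple[dict[str, set], str]:
    """GMT-style pathway sets with one pathway planted inside a module."""
    rng = _rng(rng)
    planted = set(planted_module_genes[: min(planted_size, len(planted_module_genes))])
    pathways = {"PLANTED_PATHWAY": planted}
    pool = np.array(universe)
    for i in range(n_random):
        size = int(rng.integers(20, 80))
        pathways[f"RANDOM_{i+1:02d}"] = set(rng.choice(pool, size=min(size, len(pool)),
                                                       replace=False))
    return pathways, "PLANTED_PATHWAY"


def gen_ortholog_hits(
    n_genes: int,
    n_hs: int,
    genomes: tuple | None = None,
    exons_per_gene: int = 4,
    rng=0,
) -> tuple[pd.DataFrame, list[str]]:
    """Exon-hit table over 16 genomes with exactly `n_hs` human-specific genes.

    HS genes get at most half-exon hits everywhere; the rest get a clear
    ortholog (all exons hit) in at least one genome.
    """
    rng = _rng(rng)
    genomes = genomes or tuple(f"genome_{i+1:02d}" for i in range(16))
    rows = []
    hs_genes = []
    for i in range(n_genes):
        gene = f"LNC{i+1:03d}"
        is_hs = i < n_hs
        if is_hs:
            hs_genes.append(gene)
        for genome in genomes:
            if is_hs:
                n_hits = int(rng.integers(0, exons_per_gene // 2 + 1))  # <= half
            else:
                n_hits = exons_per_gene if genome == genomes[i % len(genomes)] \
                    else int(rng.integers(0, exons_per_gene + 1))
            for e in range(exons_per_gene):
                rows.append({"gene_id": gene, "exon_id": f"{gene}.e{e+1}",
                             "genome_id": genome, "hit": e < n_hits})
    return pd.DataFrame(rows), hs_genes


# --- plain-text format helpers --------------------------------------------


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
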
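"""Expression impact of lncRNA regulators: pair correlations, random-pair
backgrounds, tissue-wise DBS-distance shift tests, and eQTL filters.

The regulatory read-out of a lncRNA's DNA binding is tested as a
tissue-wise Spearman correlation between the lncRNA's representative
transcript and each target transcript (targets = transcripts whose promoter
carries a strong DBS).  Significance combines an effect-size floor
(|rho| > 0.3) with a Benjamini–Hochberg FDR < 0.05 over the whole
pair x tissue family.  A random-pair background estimates the chance rate
of such correlations.

The tissue-shift test asks, per tissue and archaic genome, whether the DBS
distances of the tissue's significantly correlated pairs are stochastically
larger than the all-tissue background (one-sided two-sample
Kolmogorov–Smirnov, BH-FDR < 0.001), and labels tissues with the epoch of
the earliest archaic genome the shift is consistent with (D / AD / ADV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "robust_expression",
    "representative_transcript",
    "pair_correlations",
    "random_pair_background",
    "tissue_shift_test",
    "filter_eqtls",
    "eqtl_density_compare",
]

RHO_MIN = 0.3
FDR_PAIRS = 0.05
FDR_SHIFT = 0.001


@dataclass
class ExpressionMatrix:
    """Transcript x sample TPM matrix with a sample→tissue map and a
    transcript→gene map."""

    tpm: pd.DataFrame  # index: transcript_id, columns: sample ids
    sample_tissue: pd.Series  # index: sample ids, values: tissue labels
    transcript_gene: pd.Series  # index: transcript_id, values: gene_id

    def __post_init__(self):
        if (self.tpm.values < 0).any():
            raise ValueError("TPM values must be >= 0")
        unlabeled = set(self.tpm.columns) - set(self.sample_tissue.index)
        if unlabeled:
            raise ValueError(f"samples without tissue label: {sorted(unlabeled)[:5]}")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.sample_tissue.unique())

    def tissue_samples(self, tissue: str) -> list[str]:
        s = self.sample_tissue[self.sample_tissue == tissue].index
        return [c for c in self.tpm.columns if c in set(s)]


def robust_expression(matrix: ExpressionMatrix, transcript: str, tissue: str) -> bool:
    """Robustly expressed iff the median TPM over the tissue's samples is
    strictly > 0.1."""
    samples = matrix.tissue_samples(tissue)
    if not samples:
        raise ValueError(f"tissue {tissue!r} has no samples")
    return float(matrix.tpm.loc[transcript, samples].median()) > 0.1


def representative_transcript(
    lncrna_gene: str,
    matrix: ExpressionMatrix,
    dbd_transcripts: set[str],
) -> str:
    """Among the gene's DBD-containing transcripts, the one with the highest
    overall median TPM; ties go to the lexicographically smallest id."""
    transcripts = matrix.transcript_gene[matrix.transcript_gene == lncrna_gene].index
    candidates = sorted(t for t in transcripts if t in dbd_transcripts)
    if not candidates:
        raise ValueError(f"no DBD-containing transcript for {lncrna_gene!r}")
    medians = matrix.tpm.loc[candidates].median(axis=1)
    return medians.sort_index().sort_values(kind="stable", ascending=False).index[0]


def pair_correlations(
    pairs: list[tuple[str, str]],
    matrix: ExpressionMatrix,
    tissues: list[str] | None = None,
    min_samples: int = 10,
    rho_min: float = RHO_MIN,
    fdr: float = FDR_PAIRS,
) -> pd.DataFrame:
    """Spearman correlation for every (lncRNA transcript, target transcript)
    pair in every tissue, BH-corrected jointly over the whole family.

    Pairs with a constant expression vector in a tissue are skipped there.
    """
    tissues = tissues or matrix.tissues
    rows = []
    pvals = []
    for tissue in tissues:
        samples = matrix.tissue_samples(tissue)
        if len(samples) < min_samples:
            continue
        sub = matrix.tpm[samples]
        for lnc, target in pairs:
            x = sub.loc[lnc].to_numpy()
            y = sub.loc[target].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = stats.spearmanr(x, y)
            if math.isnan(rho):
                continue
            rows.append(
                {"lncrna": lnc, "target": target, "tissue": tissue,
                 "rho": float(rho), "p": float(p), "n": len(samples)}
            )
            pvals.append(p)
    df = pd.DataFrame(rows, columns=["lncrna", "target", "tissue", "rho", "p", "n"])
    if len(df):
        df["fdr"] = multipletests(df.p.to_numpy(), method="fdr_bh")[1]
        df["significant"] = (df.rho.abs() > rho_min) & (df.fdr < fdr)
    else:
        df["fdr"] = []
        df["significant"] = []
    return df


def random_pair_background(
    matrix: ExpressionMatrix,
    lncrna_ids: list[str],
    coding_ids: list[str],
    n_pairs: int = 10000,
    seed: int = 0,
    tissues: list[str] | None = None,
    min_samples: int = 10,
) -> tuple[float, tuple[float, float]]:
    """Fraction of randomly sampled lncRNA–coding pairs (x tissues) passing
    the same significance rule, with a 95% binomial (normal) CI."""
    rng = np.random.default_rng(seed)
    if len(lncrna_ids) * len(coding_ids) < n_pairs:
        raise ValueError("not enough constructible pairs")
    seen = set()
    pairs = []
    while len(pairs) < n_pairs:
        l = lncrna_ids[rng.integers(len(lncrna_ids))]
        c = coding_ids[rng.integers(len(coding_ids))]
        if (l, c) not in seen:
            seen.add((l, c))
            pairs.append((l, c))
    df = pair_correlations(pairs, matrix, tissues=tissues, min_samples=min_samples)
    if not len(df):
        return float("nan"), (float("nan"), float("nan"))
    frac = float(df.significant.mean())
    n = len(df)
    se = math.sqrt(max(frac * (1 - frac), 1e-12) / n)
    return frac, (max(0.0, frac - 1.96 * se), min(1.0, frac + 1.96 * se))


_EPOCH_LABELS = {
    frozenset("ADV"): "ADV",
    frozenset("AD"): "AD",
    frozenset("D"): "D",
}


def tissue_shift_test(
    distance_table: pd.DataFrame,
    fdr: float = FDR_SHIFT,
    min_dbs: int = 5,
) -> pd.DataFrame:
    """Per-tissue, per-archaic-genome one-sided KS shift test.

    `distance_table` columns: tissue, genome (altai/denisovan/vindija),
    distance — one row per DBS of a significantly correlated pair expressed
    in that tissue.  For each genome, each tissue's distances are compared
    with the pooled all-tissue distances for that genome (alternative:
    tissue stochastically larger).  BH-FDR over all tissue x genome tests.
    Tissues with fewer than `min_dbs` distances are skipped.

    Returns one row per tissue with per-genome statistics and the epoch
    label (D / AD / ADV / none).
    """
    letter = {"altai": "A", "denisovan": "D", "vindija": "V"}
    tests = []
    for genome, sub in distance_table.groupby("genome"):
        background = sub.distance.to_numpy()
        for tissue, tsub in sub.groupby("tissue"):
            sample = tsub.distance.to_numpy()
            if len(sample) < min_dbs:
                continue
            # alternative="less": the tissue CDF lies below the background
            # CDF, i.e. tissue distances are stochastically larger
            ks = stats.ks_2samp(sample, background, alternative="less")
            tests.append(
                {"tissue": tissue, "genome": genome,
                 "ks_stat": float(ks.statistic), "p": float(ks.pvalue)}
            )
    df = pd.DataFrame(tests, columns=["tissue", "genome", "ks_stat", "p"])
    if len(df):
        df["fdr"] = multipletests(df.p.to_numpy(), method="fdr_bh")[1]
        df["significant"] = df.fdr < fdr
    else:
        df["fdr"] = []
        df["significant"] = []
    out = []
    for tissue, sub in df.groupby("tissue"):
        sig = frozenset(letter[g] for g in sub[sub.significant].genome)
        row = {"tissue": tissue, "epoch": _EPOCH_LABELS.get(sig, "none")}
        for _, r in sub.iterrows():
            row[f"ks_{r.genome}"] = r.ks_stat
            row[f"fdr_{r.genome}"] = r.fdr
        out.append(row)
    return pd.DataFrame(out), df


def filter_eqtls(
    eqtl_table: pd.DataFrame,
    maf_table: pd.DataFrame,
    dbs_intervals: pd.DataFrame,
    maf_min: float = 0.1,
    es_min: float = 0.5,
) -> pd.DataFrame:
    """Qualifying eQTLs inside DBSs, classed conserved / novel / other.

    eqtl_table: snp_id, position, gene, tissue, es (one row per tissue).
    maf_table: snp_id, population, maf.
    dbs_intervals: dbs_id, start, end, present_altai, present_denisovan,
    present_vindija (booleans: counterpart exists in that archaic genome).

    Qualifying: MAF >= maf_min in >= 1 population AND |ES| >= es_min in
    >= 1 tissue AND position inside a DBS.  conserved = the containing DBS
    has counterparts in all three archaic genomes; novel = in none.
    """
    max_maf = maf_table.groupby("snp_id").maf.max()
    best = (
        eqtl_table.assign(abs_es=eqtl_table.es.abs())
        .sort_values(["snp_id", "abs_es"], ascending=[True, False])
        .groupby("snp_id")
        .first()
        .reset_index()
    )
    rows = []
    for rec in best.itertuples():
        if max_maf.get(rec.snp_id, 0.0) < maf_min or rec.abs_es < es_min:
            continue
        hit = dbs_intervals[
            (dbs_intervals.start <= rec.position) & (rec.position < dbs_intervals.end)
        ]
        if hit.empty:
            continue
        present = hit[["present_altai", "present_denisovan", "present_vindija"]].to_numpy()
        if present.all():
            klass = "conserved"
        elif not present.any():
            klass = "novel"
        else:
            klass = "other"
        rows.append(
            {"snp_id": rec.snp_id, "position": rec.position, "gene": rec.gene,
             "tissue": rec.tissue, "es": rec.es,
             "maf_max": float(max_maf[rec.snp_id]), "eqtl_class": klass}
        )
    return pd.DataFrame(
        rows, columns=["snp_id", "position", "gene", "tissue", "es", "maf_max",
                       "eqtl_class"]
    )


def eqtl_density_compare(
    dbs_intervals: list[tuple[int, int]],
    promoter_intervals: list[tuple[int, int]],
    eqtl_positions,
) -> tuple[float, float]:
    """One-sided Mann–Whitney on per-interval eQTL density
    (alternative: DBS densities > promoter densities)."""
    if not dbs_intervals or not promoter_intervals:
        raise ValueError("both interval sets must be non-empty")
    pos = np.sort(np.asarray(list(eqtl_positions), dtype=np.int64))

    def density(iv):
        s, e = iv
        count = np.searchsorted(pos, e) - np.searchsorted(pos, s)
        return count / (e - s)

    d_dbs = [density(iv) for iv in dbs_intervals]
    d_prom = [density(iv) for iv in promoter_intervals]
    res = stats.mannwhitneyu(d_dbs, d_prom, alternative="greater")
    return float(res.statistic), float(res.pvalue)
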
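"""Cross-genome DBS counterparts, Kimura 2-parameter distances and age labels.

A DBS's *counterpart* is the sequence occupying its mapped coordinates in
another genome (chimpanzee, Altai/Vindija Neanderthal, Denisovan, or a
reconstructed primate ancestor).  Counterparts are built either from a
counterpart FASTA or by applying a genome's variants to the human reference.
Per-base distances use the Kimura 2-parameter (K2P) substitution model,

    K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)),

with P and Q the transition and transversion proportions over pairwise
compared sites (gaps and ambiguity codes excluded).  A DBS whose counterpart
is missing in a genome receives the sentinel distance 10.0 — well above the
largest observed real distance — rather than an undefined value.

Age labels follow two fixed thresholds: a DBS is *old* when diverged from
chimpanzee (K > 0.034/bp) yet identical to the Altai Neanderthal, and
*young* when diverged (> 0.034/bp) from the Altai Neanderthal or Denisovan.
Epoch flags A/D/V mark top-ranked DBSs whose distance to that archaic
genome exceeds 0.037.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_DISTANCE",
    "K2PSaturationError",
    "CounterpartRecord",
    "AgeLabel",
    "apply_variants",
    "k2p_distance",
    "tn93_distance",
    "dbs_distance",
    "classify_age",
    "flag_epochs",
    "ancestor_mode_distances",
]

MISSING_DISTANCE = 10.0

_PURINES = {"A", "G"}
_VALID = {"A", "C", "G", "T"}


class K2PSaturationError(ValueError):
    """Raised when the K2P logarithm arguments are non-positive."""


@dataclass
class CounterpartRecord:
    dbs_id: str
    genome_id: str
    sequence: str | None  # None = missing counterpart
    P: float = float("nan")
    Q: float = float("nan")
    K: float = float("nan")

    @property
    def missing(self) -> bool:
        return self.sequence is None


@dataclass
class AgeLabel:
    age: str  # old | young | other
    epochs: set = field(default_factory=set)  # subset of {C, A, D, V}


def apply_variants(reference: str, vcf_path, sample: str | None = None,
                   region_offset: int = 0) -> str:
    """Consensus sequence: reference with the sample's SNV alleles substituted.

    At loci with multiple calls the record with the highest QUAL wins (ties:
    first record in file order).  Indels and non-SNV records are skipped.
    Positions outside the reference raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_idx = 0
    if sample is not None:
        if sample not in vcf.samples:
            raise KeyError(f"sample {sample!r} not in VCF")
        sample_idx = vcf.samples.index(sample)
    best: dict[int, tuple[float, int, str]] = {}
    order = 0
    for rec in vcf:
        if not rec.ALT:
            continue
        alt = rec.ALT[0]
        if len(rec.REF) != 1 or len(alt) != 1 or alt not in _VALID:
            continue  # SNVs only
        pos = rec.POS - 1 - region_offset
        if pos < 0 or pos >= len(reference):
            raise ValueError(f"variant position {rec.POS} outside reference")
        gt = rec.genotypes[sample_idx] if rec.genotypes else [1]
        alleles = [a for a in gt[:-1] if a is not None and a >= 0]
        base = alt if any(a > 0 for a in alleles) else rec.REF
        qual = rec.QUAL if rec.QUAL is not None else 0.0
        prev = best.get(pos)
        # higher QUAL wins; earlier record wins ties
        if prev is None or qual > prev[0]:
            best[pos] = (qual, order, base)
        order += 1
    seq = list(reference)
    for pos, (_, _, base) in best.items():
        seq[pos] = base
    return "".join(seq)


def _compare_sites(seq_a: str, seq_b: str):
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    n = ts = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in _VALID or b not in _VALID:
            continue  # gaps / ambiguity excluded pairwise
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """(P, Q, K) under the Kimura 2-parameter model, per compared site."""
    n, ts, tv = _compare_sites(seq_a, seq_b)
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise K2PSaturationError(f"saturated: P={P:.4f} Q={Q:.4f}")
    K = -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # normalize -0.0
    return P, Q, K


def tn93_distance(seq_a: str, seq_b: str) -> float:
    """Tamura–Nei (1993) distance; used as an independent cross-check of K2P."""
    a = np.array(list(seq_a.upper()))
    b = np.array(list(seq_b.upper()))
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    bases = np.array(list("ACGT"))
    valid = np.isin(a, bases) & np.isin(b, bases)
    a, b = a[valid], b[valid]
    n = len(a)
    if n == 0:
        raise ValueError("no comparable sites")
    both = np.concatenate([a, b])
    freqs = {base: float(np.mean(both == base)) for base in "ACGT"}
    gR = freqs["A"] + freqs["G"]
    gY = freqs["C"] + freqs["T"]

    def is_purine(x):
        return (x == "A") | (x == "G")

    P1 = np.mean(((a == "A") & (b == "G")) | ((a == "G") & (b == "A")))
    P2 = np.mean(((a == "C") & (b == "T")) | ((a == "T") & (b == "C")))
    Q = np.mean((is_purine(a) != is_purine(b)))
    k1 = 2 * freqs["A"] * freqs["G"] / gR if gR > 0 else 0.0
    k2 = 2 * freqs["C"] * freqs["T"] / gY if gY > 0 else 0.0
    k3 = 2 * (gR * gY - freqs["A"] * freqs["G"] * gY / gR
              - freqs["C"] * freqs["T"] * gR / gY) if gR > 0 and gY > 0 else 0.0
    w1 = 1 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 1.0
    w2 = 1 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 1.0
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise K2PSaturationError("TN93 saturated")
    d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    return float(d)


def dbs_distance(human_seq: str, counterpart: str | None) -> float:
    """K2P distance to the counterpart, or exactly 10.0 when it is missing."""
    if counterpart is None:
        return MISSING_DISTANCE
    return k2p_distance(human_seq, counterpart)[2]


def classify_age(
    k_chimp: float,
    k_altai: float | None,
    k_denisovan: float | None,
    k_vindija: float | None = None,
    threshold: float = 0.034,
) -> AgeLabel:
    """Old: diverged from chimp (> threshold/bp) but identical to Altai.
    Young: diverged (> threshold/bp) from Altai or Denisovan.  A missing
    archaic distance yields "other"."""
    if k_altai is None or k_denisovan is None:
        return AgeLabel(age="other")
    if k_chimp is not None and k_chimp > threshold and k_altai == 0.0:
        return AgeLabel(age="old")
    if k_altai > threshold or k_denisovan > threshold:
        return AgeLabel(age="young")
    return AgeLabel(age="other")


def flag_epochs(
    distances: pd.DataFrame,
    archaic_threshold: float = 0.037,
    chimp_threshold: float = 0.037,
    top_fraction: float = 0.20,
) -> pd.DataFrame:
    """Epoch flags per DBS from a wide distance table.

    `distances` must have columns dbs_id, k_chimp, k_altai, k_denisovan,
    k_vindija.  Flag C iff k_chimp >= chimp_threshold; flags A/D/V iff the
    DBS is in the top `top_fraction` of the human–chimp distance ranking AND
    the corresponding archaic distance > archaic_threshold.
    """
    df = distances.copy()
    rank_cut = df.k_chimp.quantile(1.0 - top_fraction)
    in_top = df.k_chimp >= rank_cut
    flags = []
    for i, row in df.iterrows():
        f = set()
        if row.k_chimp >= chimp_threshold:
            f.add("C")
        if in_top.loc[i]:
            for letter, col in (("A", "k_altai"), ("D", "k_denisovan"), ("V", "k_vindija")):
                v = row.get(col)
                if v is not None and not pd.isna(v) and v > archaic_threshold:
                    f.add(letter)
        flags.append(",".join(sorted(f)))
    df["epoch_flags"] = flags
    return df


def ancestor_mode_distances(
    ancestor_seqs: dict[str, str],
    genome_seqs: dict[str, dict[str, str]],
    modern_genome: str = "modern",
    archaic_genomes: tuple = ("altai", "denisovan", "vindija"),
) -> tuple[pd.DataFrame, float]:
    """Distances from the reconstructed ancestor to every genome per DBS.

    Returns the per-DBS table and the concordance fraction: the fraction of
    DBSs where d(ancestor→modern) exceeds the mean of the ancestor→archaic
    distances (the sign expected if archaic genomes are intermediate).
    Exact ties — common for short DBSs with few substitutions — count 1/2.
    """
    rows = []
    concordant = 0.0
    total = 0
    for dbs_id, anc in sorted(ancestor_seqs.items()):
        row = {"dbs_id": dbs_id}
        for genome, seqs in genome_seqs.items():
            seq = seqs.get(dbs_id)
            row[f"k_{genome}"] = (
                float("nan") if seq is None else k2p_distance(anc, seq)[2]
            )
        rows.append(row)
        arch = [row.get(f"k_{g}") for g in archaic_genomes]
        arch = [a for a in arch if a is not None and not math.isnan(a)]
        d_mod = row.get(f"k_{modern_genome}")
        if arch and d_mod is not None and not math.isnan(d_mod):
            total += 1
            mean_arch = float(np.mean(arch))
            if d_mod > mean_arch:
                concordant += 1.0
            elif d_mod == mean_arch:
                concordant += 0.5
    table = pd.DataFrame(rows)
    concordance = concordant / total if total else float("nan")
    return table, concordance
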
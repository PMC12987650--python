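"""Independent naive reference implementations used as test oracles.

These are deliberately written from the textbook definitions (loops over
haplotype pairs, direct formula evaluation, exhaustive substring
enumeration) and share no code with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# --- triplex: exhaustive gapless substring enumeration ---------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_align(rna: str, dna: str, ruleset, params):
    """All maximal qualifying gapless substring pairs, by full enumeration."""
    rna = rna.upper().replace("U", "T")
    dna = dna.upper().replace("U", "T")
    out = []
    for motif, rev in (("parallel", False), ("antiparallel", True)):
        rules = ruleset.motif_rules(motif)
        if not rules:
            continue
        rseq = rna[::-1] if rev else rna
        cand = {}
        for i in range(len(rseq)):
            for j in range(len(dna)):
                maxl = min(len(rseq) - i, len(dna) - j)
                for L in range(params.min_nt, maxl + 1):
                    npair = 0
                    score = 0.0
                    ok = True
                    for t in range(L):
                        rb, db = rseq[i + t], dna[j + t]
                        purine = db if db in "AG" else _COMP[db]
                        paired = db in "AG" and (rb, purine) in rules
                        if paired:
                            npair += 1
                            score += 1.0
                        else:
                            if rb == "T" and db == "T":
                                pen = params.tt_penalty
                            elif rb == "C" and db == "C":
                                pen = params.cc_penalty
                            else:
                                pen = 0.0
                            if pen <= -900:
                                ok = False
                                break
                            score += pen
                    if (ok and score > 0
                            and 100.0 * npair >= params.min_identity_percent * L - 1e-9):
                        cand[(i, i + L, j, j + L)] = npair
        for (i1, i2, j1, j2), npair in cand.items():
            contained = any(
                a1 <= i1 and a2 >= i2 and b1 <= j1 and b2 >= j2
                and (a1, a2, b1, b2) != (i1, i2, j1, j2)
                for (a1, a2, b1, b2) in cand
            )
            if contained:
                continue
            L = i2 - i1
            if rev:
                rs, re = len(rseq) - i2, len(rseq) - i1
            else:
                rs, re = i1, i2
            out.append((rs, re, j1, j2, round(100.0 * npair / L, 6), motif))
    return sorted(out)


# --- popgen: textbook formulas ---------------------------------------------


def naive_pi(matrix) -> float:
    """Mean pairwise differences by looping over all haplotype pairs."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    total = 0
    for a, b in itertools.combinations(range(n), 2):
        total += int(np.sum(matrix[a] != matrix[b]))
    return total / (n * (n - 1) / 2)


def naive_tajima_d(matrix) -> float:
    matrix = np.asarray(matrix)
    n, _ = matrix.shape
    counts = matrix.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0 or n < 4:
        return float("nan")
    pi = naive_pi(matrix[:, seg])
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def naive_faywu_h(matrix, ancestral) -> float:
    """pi - theta_H over sites with known ancestral state."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    pi = 0.0
    theta_h = 0.0
    for s in range(matrix.shape[1]):
        if ancestral[s] == 0:
            d = int(matrix[:, s].sum())
        elif ancestral[s] == 1:
            d = n - int(matrix[:, s].sum())
        else:
            continue
        if d == 0 or d == n:
            continue
        pi += 2 * d * (n - d) / (n * (n - 1))
        theta_h += 2 * d * d / (n * (n - 1))
    return pi - theta_h


def naive_wc_fst(geno_a, geno_b) -> float:
    """Weir & Cockerham (1984) weighted Fst for two diploid samples.

    geno_*: (n_individuals, n_snps) arrays of alt-allele dosages 0/1/2.
    """
    geno_a = np.asarray(geno_a)
    geno_b = np.asarray(geno_b)
    num = den = 0.0
    r = 2
    for s in range(geno_a.shape[1]):
        n1, n2 = geno_a.shape[0], geno_b.shape[0]
        p1 = geno_a[:, s].sum() / (2 * n1)
        p2 = geno_b[:, s].sum() / (2 * n2)
        if (p1 == 0 and p2 == 0) or (p1 == 1 and p2 == 1):
            continue
        h1 = np.mean(geno_a[:, s] == 1)
        h2 = np.mean(geno_b[:, s] == 1)
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (s2 - 1 / (nbar - 1)
                         * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den else float("nan")


def naive_r2(col_i, col_j) -> float:
    x = np.asarray(col_i, dtype=float)
    y = np.asarray(col_j, dtype=float)
    pa, pb = x.mean(), y.mean()
    pab = np.mean((x == 1) & (y == 1))
    d = pab - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def bh_stepup(pvals, alpha=0.05):
    """Benjamini–Hochberg adjusted p-values, direct step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        adj[idx] = val
        prev = val
    return adj
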
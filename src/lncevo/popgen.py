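"""Window-based selection statistics over phased haplotype panels.

Implements the classic neutrality and differentiation statistics used to
scan regulatory loci for recent positive selection:

* Tajima's D — normalized difference between mean pairwise diversity (pi)
  and Watterson's estimator (S/a1); significantly negative values against a
  genome-wide background indicate directional selection.
* Fay–Wu's H = pi − theta_H, where theta_H weights the unfolded site
  frequency spectrum by the squared derived-allele count; negative H marks
  an excess of high-frequency derived alleles, a sweep signature.
* Weir–Cockerham Fst with ratio-of-sums ("weighted") combination across a
  window's SNPs, and an "integrated Fst" combining the three pairwise
  population values for a focal population.
* LD r-squared from phased haplotype frequencies, minor/derived allele
  frequencies, and SNP density.

The joint positive-selection call for a focal population requires both a
strongly negative Tajima's D in the focal population (with D > 0 in the
other two) and an integrated Fst above a genome-background threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypePanel",
    "WindowStats",
    "FstResult",
    "SelectionCall",
    "allele_freqs",
    "tajima_d",
    "faywu_h",
    "window_stats",
    "weighted_fst",
    "integrated_fst",
    "genome_background",
    "joint_selection_call",
    "ld_r2",
    "snp_density",
    "tile_windows",
]


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for one population.

    matrix: (n_haplotypes, n_sites) 0/1 array, 1 = alternate allele.
    positions: site coordinates (0-based).
    ancestral: per-site code 0 = ref ancestral, 1 = alt ancestral,
    -1 = unknown.
    """

    matrix: np.ndarray
    positions: np.ndarray
    ancestral: np.ndarray
    population: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (haplotypes x sites)")
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("positions do not match matrix width")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("haplotype matrix must be 0/1 (biallelic)")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def site_mask(self, window: tuple[int, int] | None) -> np.ndarray:
        if window is None:
            return np.ones(len(self.positions), dtype=bool)
        start, end = window
        return (self.positions >= start) & (self.positions < end)

    def derived_counts(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Derived-allele count per site; -1 where the ancestral is unknown."""
        if mask is None:
            mask = np.ones(len(self.positions), dtype=bool)
        alt = self.matrix[:, mask].sum(axis=0)
        anc = self.ancestral[mask]
        out = np.where(anc == 0, alt, np.where(anc == 1, self.n - alt, -1))
        return out.astype(np.int64)


@dataclass
class WindowStats:
    window: tuple[int, int] | None
    n: int
    S: int
    pi: float
    theta_w: float
    tajima_D: float  # nan when undefined (S == 0 or n < 4)
    theta_H: float = float("nan")
    faywu_H: float = float("nan")
    population: str = ""


@dataclass
class FstResult:
    pair_id: str
    window: tuple[int, int] | None
    a_sum: float
    abc_sum: float

    @property
    def weighted_fst(self) -> float:
        return self.a_sum / self.abc_sum if self.abc_sum != 0 else float("nan")


@dataclass
class SelectionCall:
    locus_id: str
    population: str
    is_positive: bool
    evidence: dict = field(default_factory=dict)


def _tajima_constants(n: int):
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def _pi_from_counts(counts: np.ndarray, n: int) -> float:
    """Mean pairwise differences from per-site allele counts (either allele)."""
    c = counts.astype(np.float64)
    return float(np.sum(2.0 * c * (n - c) / (n * (n - 1))))


def allele_freqs(panel: HaplotypePanel) -> pd.DataFrame:
    """Per-SNP minor and derived allele frequencies."""
    alt = panel.matrix.sum(axis=0)
    p = alt / panel.n
    maf = np.minimum(p, 1.0 - p)
    daf = np.where(
        panel.ancestral == 0, p, np.where(panel.ancestral == 1, 1.0 - p, np.nan)
    )
    return pd.DataFrame(
        {"position": panel.positions, "alt_freq": p, "maf": maf, "daf": daf}
    )


def tajima_d(panel: HaplotypePanel, window: tuple[int, int] | None = None) -> WindowStats:
    """Tajima (1989) D over the SNPs in `window` (None = all sites)."""
    mask = panel.site_mask(window)
    sub = panel.matrix[:, mask]
    n = panel.n
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    alt = sub.sum(axis=0)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    pi = _pi_from_counts(alt[seg], n)
    a1, e1, e2 = _tajima_constants(n) if n >= 2 else (1.0, 0.0, 0.0)
    theta_w = S / a1
    if S == 0 or n < 4:
        D = float("nan")
    else:
        D = (pi - theta_w) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return WindowStats(
        window=window, n=n, S=S, pi=pi, theta_w=theta_w, tajima_D=D,
        population=panel.population,
    )


def faywu_h(panel: HaplotypePanel, window: tuple[int, int] | None = None) -> WindowStats:
    """Fay & Wu (2000) H = pi − theta_H over derived-allele counts.

    Sites with unknown ancestral state are excluded from both pi and
    theta_H (H compares the same site set).  theta_H =
    sum_i 2 S_i i^2 / (n(n-1)).
    """
    mask = panel.site_mask(window)
    n = panel.n
    d = panel.derived_counts(mask)
    known = d >= 0
    if not known.any():
        st = tajima_d(panel, window)
        st.theta_H = float("nan")
        st.faywu_H = float("nan")
        return st
    dk = d[known]
    seg = (dk > 0) & (dk < n)
    dk = dk[seg]
    pi = _pi_from_counts(dk, n)
    theta_H = float(np.sum(2.0 * dk.astype(np.float64) ** 2 / (n * (n - 1))))
    st = tajima_d(panel, window)
    st.theta_H = theta_H
    st.faywu_H = pi - theta_H
    return st


def window_stats(panel: HaplotypePanel, window: tuple[int, int]) -> WindowStats:
    """D and H together for one window."""
    return faywu_h(panel, window)


def _wc_components(n1, n2, p1, p2, h1, h2):
    """Weir & Cockerham (1984) per-SNP variance components for r=2
    populations of diploid individuals.

    n: individuals sampled, p: alt frequency, h: observed heterozygote
    frequency.  Returns (a, b, c).
    """
    r = 2
    n_bar = (n1 + n2) / r
    nc = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / nc) * (
        s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def _diploidize(matrix: np.ndarray):
    """Pair consecutive haplotypes into individuals: genotype dosage and
    heterozygosity arrays of shape (n_ind, S)."""
    n = matrix.shape[0]
    if n % 2:
        matrix = matrix[: n - 1]
    g1 = matrix[0::2]
    g2 = matrix[1::2]
    return g1 + g2, g1 != g2


def weighted_fst(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    window: tuple[int, int] | None = None,
    pair_id: str = "",
) -> FstResult:
    """Weir–Cockerham weighted (ratio-of-sums) Fst over the window's SNPs.

    Haplotypes are paired into diploid individuals in panel order.  SNPs
    monomorphic across both populations contribute nothing.
    """
    if not np.array_equal(panel_a.positions, panel_b.positions):
        raise ValueError("panels must share the same SNP set")
    mask = panel_a.site_mask(window)
    dos_a, het_a = _diploidize(panel_a.matrix[:, mask])
    dos_b, het_b = _diploidize(panel_b.matrix[:, mask])
    n1, n2 = dos_a.shape[0], dos_b.shape[0]
    a_sum = abc_sum = 0.0
    any_poly = False
    for s in range(dos_a.shape[1]):
        p1 = dos_a[:, s].sum() / (2 * n1)
        p2 = dos_b[:, s].sum() / (2 * n2)
        if (p1 == 0 and p2 == 0) or (p1 == 1 and p2 == 1):
            continue
        any_poly = True
        h1 = het_a[:, s].mean()
        h2 = het_b[:, s].mean()
        a, b, c = _wc_components(n1, n2, p1, p2, h1, h2)
        a_sum += a
        abc_sum += a + b + c
    if not any_poly:
        return FstResult(pair_id=pair_id, window=window, a_sum=0.0, abc_sum=0.0)
    return FstResult(pair_id=pair_id, window=window, a_sum=a_sum, abc_sum=abc_sum)


def integrated_fst(
    pairwise: dict[str, float],
    focal: str,
    combiner: str = "mean",
) -> float:
    """Combine the three pairwise weighted Fst values for a focal population.

    `pairwise` maps "POP1-POP2" to weighted Fst.  Default combiner: mean of
    the two pairs involving the focal population ("max" also available).
    """
    vals = []
    for key, v in pairwise.items():
        pops = key.split("-")
        if focal in pops:
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return float("nan")
            vals.append(v)
    if len(vals) != 2:
        raise ValueError(f"expected 2 pairs involving {focal!r}, got {len(vals)}")
    if combiner == "mean":
        return float(np.mean(vals))
    if combiner == "max":
        return float(np.max(vals))
    raise ValueError(f"unknown combiner {combiner!r}")


def genome_background(
    values,
    percentile: float = 10.0,
    tail: str = "lower",
    min_windows: int = 100,
) -> tuple[float, int]:
    """Empirical percentile threshold from genome-wide window scores.

    tail="lower": the `percentile`-quantile (e.g. lower 10% of Tajima's D);
    tail="upper": the (100-percentile)-quantile (e.g. upper 10% of Fst).
    NaN scores are dropped.  Returns (threshold, n_windows_used).
    """
    arr = np.asarray([v for v in values if not (isinstance(v, float) and math.isnan(v))],
                     dtype=np.float64)
    arr = arr[~np.isnan(arr)]
    if len(arr) < min_windows:
        raise ValueError(f"too few background windows: {len(arr)} < {min_windows}")
    if tail == "lower":
        thr = float(np.quantile(arr, percentile / 100.0))
    elif tail == "upper":
        thr = float(np.quantile(arr, 1.0 - percentile / 100.0))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return thr, len(arr)


def joint_selection_call(
    locus_id: str,
    d_values: dict[str, float],
    fst_int: float,
    d_thresholds: dict[str, float],
    fst_threshold: float,
) -> list[SelectionCall]:
    """Positive selection in a focal population iff D(focal) < its threshold,
    D > 0 in BOTH other populations, and integrated Fst > the Fst threshold.

    Returns one call per population; undefined D or Fst yields no positive
    call for the affected populations.
    """
    calls = []
    pops = sorted(d_values)
    fst_ok = fst_int is not None and not math.isnan(fst_int) and fst_int > fst_threshold
    for focal in pops:
        d_focal = d_values[focal]
        others = [p for p in pops if p != focal]
        defined = not math.isnan(d_focal) and all(not math.isnan(d_values[p]) for p in others)
        positive = (
            defined
            and fst_ok
            and d_focal < d_thresholds[focal]
            and all(d_values[p] > 0.0 for p in others)
        )
        calls.append(
            SelectionCall(
                locus_id=locus_id,
                population=focal,
                is_positive=bool(positive),
                evidence={
                    "D": dict(d_values),
                    "integrated_fst": fst_int,
                    "d_threshold": d_thresholds[focal],
                    "fst_threshold": fst_threshold,
                },
            )
        )
    return calls


def ld_r2(panel: HaplotypePanel, site_i: int, site_j: int) -> float:
    """r² between two SNP columns from phased haplotype frequencies."""
    x = panel.matrix[:, site_i].astype(np.float64)
    y = panel.matrix[:, site_j].astype(np.float64)
    pa, pb = x.mean(), y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = np.mean(x * y)
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def snp_density(
    panel: HaplotypePanel,
    interval: tuple[int, int],
    maf_min: float = 0.1,
) -> tuple[int, float]:
    """(count, count per base) of SNPs with MAF >= maf_min in the interval."""
    start, end = interval
    if end <= start:
        raise ValueError("invalid interval")
    freqs = allele_freqs(panel)
    in_win = (freqs.position >= start) & (freqs.position < end)
    count = int(((freqs.maf >= maf_min) & in_win).sum())
    return count, count / (end - start)


def tile_windows(start: int, end: int, size: int, min_fraction: float = 0.5):
    """Non-overlapping tiles of `size` bp; a partial terminal tile is kept
    iff it covers at least `min_fraction` of a full window."""
    wins = []
    pos = start
    while pos < end:
        w_end = min(pos + size, end)
        if w_end - pos >= min_fraction * size:
            wins.append((pos, w_end))
        pos += size
    return wins
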
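"""Triplex-rule prediction of lncRNA DNA-binding domains (DBDs) and sites (DBSs).

LncRNAs can bind duplex DNA by laying a third strand into the major groove
(an RNA:DNA:DNA triplex).  Which RNA base can sit opposite which duplex base
pair is described by a small table of triad rules: Hoogsteen rules for the
parallel motif (third strand parallel to the purine strand of the duplex)
and reverse-Hoogsteen rules for the antiparallel motif.  A run of rule-
compatible juxtapositions forms a triplex-forming oligonucleotide (TFO) on
the RNA and a triplex-targeting site (TTS) on the DNA.

This module finds all maximal gapless TFO/TTS alignments between a lncRNA
and a promoter sequence, chains densely spaced TTSs into DBSs (and TFOs
into DBDs), scores each DBS by *affinity* = length x mean identity / 100,
and classifies DBSs as strong (affinity >= 60), weak (36 < affinity < 60)
or subthreshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TriplexRuleset",
    "TriplexParams",
    "TfoTtsPair",
    "DBS",
    "DBD",
    "PromoterWindow",
    "align_triplex",
    "cluster_tts",
    "cluster_tfo",
    "score_and_classify",
    "classify_affinity",
    "scan_promoters",
    "select_dbd1",
    "revcomp",
]

_COMP = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def revcomp(seq: str) -> str:
    """Reverse complement (U treated as T on the complement)."""
    return seq.translate(_COMP)[::-1]


# Triad rules as (rna_base, duplex_purine_base, motif).  The duplex base is
# read on the purine strand, so it is restricted to {A, G}.  Canonical codes:
# parallel motif T.A-T and C.G-C; antiparallel motif A.A-T, G.G-C and T.A-T.
# The "all" preset adds a documented extension (parallel G.A-T, antiparallel
# T.C-G is not representable -- duplex side must be a purine -- so the
# extension used is antiparallel C.A-T, a weak reverse-Hoogsteen triad).
_PARALLEL_CANONICAL = {("T", "A"), ("C", "G")}
_ANTIPARALLEL_CANONICAL = {("A", "A"), ("G", "G"), ("T", "A")}
_PARALLEL_EXT = {("G", "A")}
_ANTIPARALLEL_EXT = {("C", "A")}


@dataclass(frozen=True)
class TriplexRuleset:
    """A named set of triad rules.

    ``rules`` is a frozenset of (rna_base, duplex_purine_base, motif)
    triples with motif in {"parallel", "antiparallel"}.
    """

    name: str
    rules: frozenset

    def __post_init__(self):
        if not self.rules:
            raise ValueError("ruleset must be non-empty")
        for rna, pur, motif in self.rules:
            if pur not in ("A", "G"):
                raise ValueError(f"duplex purine base must be A or G, got {pur!r}")
            if motif not in ("parallel", "antiparallel"):
                raise ValueError(f"unknown motif {motif!r}")

    @classmethod
    def preset(cls, name: str = "all") -> "TriplexRuleset":
        par = {(r, d, "parallel") for r, d in _PARALLEL_CANONICAL}
        anti = {(r, d, "antiparallel") for r, d in _ANTIPARALLEL_CANONICAL}
        if name == "parallel":
            rules = par
        elif name == "antiparallel":
            rules = anti
        elif name == "canonical":
            rules = par | anti
        elif name == "all":
            rules = (
                par
                | anti
                | {(r, d, "parallel") for r, d in _PARALLEL_EXT}
                | {(r, d, "antiparallel") for r, d in _ANTIPARALLEL_EXT}
            )
        else:
            raise ValueError(f"unknown preset {name!r}")
        return cls(name=name, rules=frozenset(rules))

    def motif_rules(self, motif: str) -> set:
        return {(r, d) for r, d, m in self.rules if m == motif}

    def to_table(self) -> pd.DataFrame:
        rows = sorted(self.rules)
        return pd.DataFrame(rows, columns=["rna_base", "duplex_purine_base", "motif"])

    @classmethod
    def from_table(cls, df: pd.DataFrame, name: str = "custom") -> "TriplexRuleset":
        rules = frozenset(
            (r.rna_base, r.duplex_purine_base, r.motif) for r in df.itertuples()
        )
        return cls(name=name, rules=rules)


# Penalties at or below this value are hard barriers: a single occurrence
# disqualifies any segment containing it.
HARD_PENALTY = -900.0


@dataclass(frozen=True)
class TriplexParams:
    """Alignment parameters.

    tt_penalty / cc_penalty are per-position substitution scores for the
    T(rna)xT(dna) and C(rna)xC(dna) juxtapositions; all other non-pairing
    juxtapositions score 0 and paired positions score +1.  A reported
    segment must have positive total score, so the default tt_penalty of
    -1000 forbids segments spanning a T-T juxtaposition while cc_penalty 0
    merely dilutes identity.  offset is the maximum gap (bp) when chaining
    TTSs/TFOs into DBSs/DBDs.
    """

    tt_penalty: float = -1000.0
    cc_penalty: float = 0.0
    offset: int = 15
    min_identity_percent: float = 60.0
    min_nt: int = 50

    def __post_init__(self):
        if self.min_nt < 1:
            raise ValueError("min_nt must be >= 1")
        if not (0 < self.min_identity_percent <= 100):
            raise ValueError("min_identity_percent must be in (0, 100]")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass(frozen=True)
class TfoTtsPair:
    """One gapless local triplex alignment (0-based half-open intervals)."""

    rna_start: int
    rna_end: int
    dna_start: int
    dna_end: int
    identity_percent: float
    motif: str

    @property
    def length(self) -> int:
        return self.dna_end - self.dna_start


@dataclass
class DBS:
    """A chained cluster of TTSs on one promoter."""

    lncrna_id: str
    transcript_id: str
    start: int
    end: int
    members: list = field(default_factory=list)
    mean_identity_percent: float = 0.0
    affinity: float = 0.0
    dbs_class: str = ""
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DBD:
    """A chained cluster of TFOs on the lncRNA."""

    lncrna_id: str
    rna_start: int
    rna_end: int
    members: list = field(default_factory=list)
    rank: int = 0
    n_dbs: int = 0
    summed_affinity: float = 0.0


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-oriented promoter window around a TSS.

    The window covers [TSS - upstream, TSS + downstream) in transcription
    orientation; for minus-strand transcripts the sequence is the reverse
    complement of the genomic slice.
    """

    transcript_id: str
    gene_id: str
    genome_start: int
    genome_end: int
    strand: str
    sequence: str


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _position_arrays(rna: str, dna: str, rules: set, params: TriplexParams):
    """Pairing and penalty lookup matrices (rna x dna) for one motif."""
    alpha = "ACGT"
    idx = {c: i for i, c in enumerate(alpha)}
    pair_tab = np.zeros((5, 5), dtype=bool)
    pen_tab = np.zeros((5, 5), dtype=np.float64)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for rb in alpha:
        for db in alpha:
            purine = db if db in "AG" else comp[db]
            # a rule pairs the RNA base with the purine-strand base only if
            # that purine actually sits on the scanned strand
            paired = db in "AG" and (rb, purine) in rules
            pair_tab[idx[rb], idx[db]] = paired
            if not paired:
                if rb == "T" and db == "T":
                    pen_tab[idx[rb], idx[db]] = params.tt_penalty
                elif rb == "C" and db == "C":
                    pen_tab[idx[rb], idx[db]] = params.cc_penalty
    # ambiguity codes map to index 4: never paired, zero penalty
    lut = np.full(256, 4, dtype=np.uint8)
    for c, i in idx.items():
        lut[ord(c)] = i
    r_idx = lut[np.frombuffer(rna.encode(), dtype=np.uint8)]
    d_idx = lut[np.frombuffer(dna.encode(), dtype=np.uint8)]
    flat = (r_idx.astype(np.intp)[:, None] * 5) + d_idx.astype(np.intp)[None, :]
    paired = pair_tab.ravel()[flat]
    # penalties are looked up lazily per candidate diagonal
    return paired, (pen_tab, r_idx, d_idx)


def _maximal_windows(paired, penalty, params):
    """All maximal qualifying windows on one diagonal block.

    A window qualifies iff length >= min_nt, identity >= min_identity and
    total score (paired +1, unpaired penalty) > 0.  Returns (i, j, n_paired)
    tuples for windows not strictly contained in another qualifying window.
    """
    b = len(paired)
    w = params.min_nt
    if b < w:
        return []
    P = np.concatenate([[0], np.cumsum(paired)])
    G = np.concatenate([[0.0], np.cumsum(paired + penalty)])
    i = np.arange(b + 1)[:, None]
    j = np.arange(b + 1)[None, :]
    ln = j - i
    npair = P[None, :] - P[:, None]
    q = params.min_identity_percent
    qual = (
        (ln >= w)
        & (100.0 * npair >= q * ln - 1e-9)
        & (G[None, :] - G[:, None] > 0)
    )
    if not qual.any():
        return []
    # rectangle-sum over {i' <= i, j' >= j}: ==1 at (i,j) means no strict container
    cs = np.cumsum(np.cumsum(qual[:, ::-1], axis=0), axis=1)[:, ::-1]
    keep = qual & (cs == 1)
    out = []
    for ii, jj in zip(*np.nonzero(keep)):
        out.append((int(ii), int(jj), int(P[jj] - P[ii])))
    return out


def _scan_motif(rna: str, dna: str, rules: set, params: TriplexParams, motif: str,
                reverse_rna: bool):
    """Maximal qualifying gapless segments for one motif orientation."""
    rseq = rna[::-1] if reverse_rna else rna
    nr, nd = len(rseq), len(dna)
    paired, (pen_tab, r_idx, d_idx) = _position_arrays(rseq, dna, rules, params)
    pairs = []
    w = params.min_nt
    # Screen diagonals vectorized: a qualifying window of length >= w with
    # identity >= q exists on a diagonal iff the max subarray sum (length
    # >= w) of (paired - q) is >= 0.  Shear the matrix so each diagonal is a
    # column, then compute the running-min prefix-sum test for all columns.
    q = params.min_identity_percent / 100.0
    ncol = nr + nd - 1
    sheared = np.full((ncol, nr), -np.float32(q), dtype=np.float32)
    pq = paired.astype(np.float32)
    pq -= np.float32(q)
    for i in range(nr):
        sheared[nr - 1 - i: nr - 1 - i + nd, i] = pq[i]
    if nr >= w:
        T = np.zeros((ncol, nr + 1), dtype=np.float32)
        np.cumsum(sheared, axis=1, out=T[:, 1:])
        runmin = np.minimum.accumulate(T, axis=1)
        best = (T[:, w:] - runmin[:, :-w]).max(axis=1)
        # generous slack: float32 rounding can only add false candidates,
        # never hide a qualifying window from the exact per-diagonal pass
        candidates = np.flatnonzero(best >= -0.05)
    else:
        candidates = np.array([], dtype=np.intp)
    for c in candidates:
        k = int(c) - (nr - 1)
        i0 = max(0, -k)
        i1 = min(nr, nd - k)
        if i1 - i0 < w:
            continue
        ii = np.arange(i0, i1)
        jj = ii + k
        diag_paired = paired[ii, jj]
        diag_pen = pen_tab[r_idx[ii].astype(np.intp), d_idx[jj].astype(np.intp)]
        diag_hard = diag_pen <= HARD_PENALTY
        # split the diagonal at hard barriers; qualifying windows cannot span one
        bounds = np.flatnonzero(diag_hard)
        starts = np.concatenate([[0], bounds + 1])
        ends = np.concatenate([bounds, [i1 - i0]])
        for s, e in zip(starts, ends):
            if e - s < w:
                continue
            for a, bnd, npair in _maximal_windows(
                diag_paired[s:e].astype(np.int64), diag_pen[s:e], params
            ):
                ri = i0 + s + a
                rj = i0 + s + bnd
                length = rj - ri
                ident = 100.0 * npair / length
                if reverse_rna:
                    r_start, r_end = nr - rj, nr - ri
                else:
                    r_start, r_end = ri, rj
                pairs.append(
                    TfoTtsPair(
                        rna_start=r_start,
                        rna_end=r_end,
                        dna_start=ri + k,
                        dna_end=rj + k,
                        identity_percent=ident,
                        motif=motif,
                    )
                )
    return _drop_contained(pairs)


def _drop_contained(pairs: list[TfoTtsPair]) -> list[TfoTtsPair]:
    """Suppress pairs whose RNA and DNA intervals are both contained in
    another qualifying pair of the same motif (dense tracts otherwise yield
    one window per diagonal)."""
    keep = []
    for p in pairs:
        contained = any(
            q is not p
            and q.rna_start <= p.rna_start
            and q.rna_end >= p.rna_end
            and q.dna_start <= p.dna_start
            and q.dna_end >= p.dna_end
            for q in pairs
        )
        if not contained:
            keep.append(p)
    return keep


def align_triplex(
    rna_seq: str,
    dna_seq: str,
    ruleset: TriplexRuleset | None = None,
    params: TriplexParams | None = None,
) -> list[TfoTtsPair]:
    """Find all maximal gapless TFO/TTS alignments between an RNA and a DNA
    sequence (the DNA string is scanned as the putative purine-rich strand).

    The parallel motif aligns the RNA 5'->3' with the DNA; the antiparallel
    motif aligns the reversed RNA.  A position pairs iff a triad rule of the
    motif matches.  Segments must satisfy min_nt, min_identity and a positive
    score; segments contained in a longer qualifying segment on the same
    diagonal (same motif) are suppressed.
    """
    if not rna_seq or not dna_seq:
        raise ValueError("empty sequence")
    params = params or TriplexParams()
    ruleset = ruleset or TriplexRuleset.preset("all")
    rna = _norm(rna_seq)
    dna = _norm(dna_seq)
    pairs = []
    for motif, rev in (("parallel", False), ("antiparallel", True)):
        rules = ruleset.motif_rules(motif)
        if rules:
            pairs.extend(_scan_motif(rna, dna, rules, params, motif, rev))
    pairs.sort(key=lambda p: (p.dna_start, p.dna_end, p.rna_start, p.motif))
    return pairs


def classify_affinity(affinity: float) -> str:
    """strong iff affinity >= 60; weak iff 36 < affinity < 60; else subthreshold."""
    if affinity >= 60.0:
        return "strong"
    if affinity > 36.0:
        return "weak"
    return "subthreshold"


def score_and_classify(dbs: DBS) -> DBS:
    """Set affinity = length x mean identity / 100 and the strong/weak class."""
    if dbs.length <= 0:
        raise ValueError("DBS length must be > 0")
    idents = [m.identity_percent for m in dbs.members]
    dbs.mean_identity_percent = float(np.mean(idents)) if idents else 0.0
    dbs.affinity = dbs.length * dbs.mean_identity_percent / 100.0
    dbs.dbs_class = classify_affinity(dbs.affinity)
    return dbs


def _chain(intervals: list, offset: int) -> list:
    """Chain sorted (start, end, payload) intervals when the gap <= offset."""
    clusters = []
    current = []
    cur_end = None
    for start, end, payload in sorted(intervals, key=lambda t: (t[0], t[1])):
        if current and start - cur_end > offset:
            clusters.append(current)
            current = []
            cur_end = None
        current.append((start, end, payload))
        cur_end = end if cur_end is None else max(cur_end, end)
    if current:
        clusters.append(current)
    return clusters


def cluster_tts(
    pairs: list[TfoTtsPair],
    lncrna_id: str = "",
    transcript_id: str = "",
    params: TriplexParams | None = None,
) -> list[DBS]:
    """Chain TTSs whose DNA intervals overlap or lie within `offset` bp into
    DBSs (span = union hull, identity = unweighted mean of members)."""
    params = params or TriplexParams()
    out = []
    for members in _chain([(p.dna_start, p.dna_end, p) for p in pairs], params.offset):
        dbs = DBS(
            lncrna_id=lncrna_id,
            transcript_id=transcript_id,
            start=min(s for s, _, _ in members),
            end=max(e for _, e, _ in members),
            members=[p for _, _, p in members],
        )
        out.append(score_and_classify(dbs))
    return out


def cluster_tfo(
    pairs: list[TfoTtsPair],
    lncrna_id: str = "",
    params: TriplexParams | None = None,
) -> list[DBD]:
    """Chain TFOs on the lncRNA into DBDs using the same gap rule."""
    params = params or TriplexParams()
    out = []
    for members in _chain([(p.rna_start, p.rna_end, p) for p in pairs], params.offset):
        out.append(
            DBD(
                lncrna_id=lncrna_id,
                rna_start=min(s for s, _, _ in members),
                rna_end=max(e for _, e, _ in members),
                members=[p for _, _, p in members],
            )
        )
    return out


def extract_promoters(
    annotation: pd.DataFrame,
    genome: str,
    upstream: int = 3500,
    downstream: int = 1500,
) -> list[PromoterWindow]:
    """Strand-oriented promoter windows [TSS-upstream, TSS+downstream).

    Transcripts whose window would run off the contig are skipped.
    """
    windows = []
    for row in annotation.itertuples():
        tss, strand = int(row.tss), row.strand
        if strand == "+":
            gstart, gend = tss - upstream, tss + downstream
        else:
            gstart, gend = tss - downstream + 1, tss + upstream + 1
        if gstart < 0 or gend > len(genome):
            continue
        seq = genome[gstart:gend]
        if strand == "-":
            seq = revcomp(seq)
        windows.append(
            PromoterWindow(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                genome_start=gstart,
                genome_end=gend,
                strand=strand,
                sequence=seq,
            )
        )
    return windows


def _promoter_to_genome(win: PromoterWindow, start: int, end: int) -> tuple[int, int]:
    if win.strand == "+":
        return win.genome_start + start, win.genome_start + end
    return win.genome_end - end, win.genome_end - start


def scan_promoters(
    lncrnas: dict[str, str],
    annotation: pd.DataFrame,
    genome: str,
    ruleset: TriplexRuleset | None = None,
    params: TriplexParams | None = None,
    upstream: int = 3500,
    downstream: int = 1500,
) -> tuple[pd.DataFrame, dict[str, list[DBD]]]:
    """Predict DBSs of each lncRNA in every transcript's promoter window.

    Both promoter strands are scanned (either strand of the duplex can carry
    the purine tract).  Returns the DBS table (one row per DBS; genome
    coordinates 0-based half-open) and per-lncRNA DBD clusters built from
    all TFOs genome-wide.
    """
    params = params or TriplexParams()
    ruleset = ruleset or TriplexRuleset.preset("all")
    windows = extract_promoters(annotation, genome, upstream, downstream)
    rows = []
    all_pairs: dict[str, list] = {name: [] for name in lncrnas}
    dbs_members: dict[str, list] = {name: [] for name in lncrnas}
    for name, rna in lncrnas.items():
        for win in windows:
            for pstrand, seq in (("+", win.sequence), ("-", revcomp(win.sequence))):
                pairs = align_triplex(rna, seq, ruleset, params)
                if not pairs:
                    continue
                if pstrand == "-":
                    L = len(win.sequence)
                    pairs = [
                        TfoTtsPair(
                            p.rna_start, p.rna_end,
                            L - p.dna_end, L - p.dna_start,
                            p.identity_percent, p.motif,
                        )
                        for p in pairs
                    ]
                all_pairs[name].extend(pairs)
                for dbs in cluster_tts(pairs, name, win.transcript_id, params):
                    gs, ge = _promoter_to_genome(win, dbs.start, dbs.end)
                    rows.append(
                        {
                            "lncrna_id": name,
                            "transcript_id": win.transcript_id,
                            "gene_id": win.gene_id,
                            "chrom": "chr1",
                            "start": gs,
                            "end": ge,
                            "strand": win.strand,
                            "promoter_strand": pstrand,
                            "promoter_start": dbs.start,
                            "promoter_end": dbs.end,
                            "length": dbs.length,
                            "mean_identity_percent": dbs.mean_identity_percent,
                            "affinity": dbs.affinity,
                            "dbs_class": dbs.dbs_class,
                            "n_tts": len(dbs.members),
                        }
                    )
                    dbs_members[name].append((dbs.members, dbs.affinity))
    cols = [
        "lncrna_id", "transcript_id", "gene_id", "chrom", "start", "end",
        "strand", "promoter_strand", "promoter_start", "promoter_end",
        "length", "mean_identity_percent", "affinity", "dbs_class", "n_tts",
    ]
    table = pd.DataFrame(rows, columns=cols)
    table = table.sort_values(
        ["lncrna_id", "transcript_id", "start", "end"]
    ).reset_index(drop=True)

    dbds: dict[str, list[DBD]] = {}
    for name in lncrnas:
        clusters = cluster_tfo(all_pairs[name], name, params)
        pair_to_dbd = {}
        for d in clusters:
            d.n_dbs = 0
            d.summed_affinity = 0.0
            for p in d.members:
                pair_to_dbd[id(p)] = d
        # each DBS counts once toward every DBD contributing a member TFO
        for members, affinity in dbs_members[name]:
            hit = {id(pair_to_dbd[id(p)]) for p in members if id(p) in pair_to_dbd}
            for d in clusters:
                if id(d) in hit:
                    d.n_dbs += 1
                    d.summed_affinity += affinity
        clusters.sort(key=lambda d: (-d.n_dbs, -d.summed_affinity, d.rna_start))
        for i, d in enumerate(clusters):
            d.rank = i + 1
        dbds[name] = clusters
    return table, dbds


def select_dbd1(dbds: list[DBD]) -> DBD:
    """The DBD with the most genome-wide DBSs; ties broken by larger summed
    affinity, then by the 5'-most RNA span."""
    if not dbds:
        raise ValueError("no DBDs")
    return sorted(dbds, key=lambda d: (-d.n_dbs, -d.summed_affinity, d.rna_start))[0]
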
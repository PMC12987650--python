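"""eGRAM-style regulatory module discovery.

A module couples a set of co-regulators (lncRNAs and/or TFs whose expression
is mutually correlated) to the genes they both bind (binding affinity >=
affinity_min) and correlate with (|Pearson r| >= pearson_min).  Candidate
co-regulator sets are maximal cliques in the regulator correlation graph; a
candidate module (union of the members' target genes) is kept when it
reaches module_size genes.  Modules are annotated with hypergeometric
pathway enrichments (BH-FDR <= enrich_fdr) against the expression matrix's
gene universe, and can be compared across species through an ortholog map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EgramParams",
    "Module",
    "coregulator_sets",
    "regulator_targets",
    "form_modules",
    "enrich_pathways",
    "cross_module_check",
    "compare_species_modules",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class EgramParams:
    affinity_min: float = 60.0
    pearson_min: float = 0.5
    module_size: int = 50  # minimum gene count
    enrich_fdr: float = 0.01
    absolute_r: bool = True  # |r| for regulator-target correlation

    def __post_init__(self):
        if not (0 < self.pearson_min < 1):
            raise ValueError("pearson_min must be in (0, 1)")
        if self.affinity_min <= 0 or self.module_size <= 0 or self.enrich_fdr <= 0:
            raise ValueError("parameters must be positive")


@dataclass
class Module:
    regulators: tuple
    genes: tuple
    mean_r: float
    pathways: pd.DataFrame | None = field(default=None, repr=False)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def coregulator_sets(
    regulator_expr: pd.DataFrame,
    params: EgramParams | None = None,
) -> list[tuple]:
    """Maximal cliques in the pairwise regulator correlation graph
    (|r| >= pearson_min); isolated regulators form singleton sets.
    Deterministic ordering: sets sorted by members."""
    params = params or EgramParams()
    regs = sorted(regulator_expr.index)
    g = nx.Graph()
    g.add_nodes_from(regs)
    for i, a in enumerate(regs):
        xa = regulator_expr.loc[a].to_numpy()
        for b in regs[i + 1:]:
            r = _corr(xa, regulator_expr.loc[b].to_numpy())
            if not math.isnan(r):
                if (abs(r) if params.absolute_r else r) >= params.pearson_min:
                    g.add_edge(a, b)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    return sorted(cliques)


def regulator_targets(
    regulator: str,
    binding: pd.DataFrame,
    expr: pd.DataFrame,
    regulator_expr: pd.DataFrame,
    params: EgramParams | None = None,
) -> set[str]:
    """Genes bound by the regulator (affinity >= affinity_min) whose
    expression correlates (|r| >= pearson_min) with the regulator.

    binding: columns regulator, gene, affinity.  expr: gene x sample.
    """
    params = params or EgramParams()
    bound = binding[
        (binding.regulator == regulator) & (binding.affinity >= params.affinity_min)
    ].gene.unique()
    x = regulator_expr.loc[regulator].to_numpy()
    targets = set()
    for gene in bound:
        if gene not in expr.index:
            continue
        r = _corr(x, expr.loc[gene].to_numpy())
        if math.isnan(r):
            continue
        if (abs(r) if params.absolute_r else r) >= params.pearson_min:
            targets.add(gene)
    return targets


def _mean_pairwise_r(expr: pd.DataFrame, genes) -> float:
    sub = expr.loc[sorted(genes)].to_numpy(dtype=np.float64)
    if len(sub) < 2:
        return float("nan")
    c = np.corrcoef(sub)
    iu = np.triu_indices(len(sub), k=1)
    return float(np.nanmean(np.abs(c[iu])))


def form_modules(
    regulator_sets: list[tuple],
    targets: dict[str, set],
    expr: pd.DataFrame,
    params: EgramParams | None = None,
) -> list[Module]:
    """One candidate module per regulator set: the union of the members'
    target genes, kept iff it reaches module_size.  Modules may overlap."""
    params = params or EgramParams()
    modules = []
    for regs in regulator_sets:
        genes = set()
        for r in regs:
            genes |= targets.get(r, set())
        if len(genes) < params.module_size:
            continue
        modules.append(
            Module(
                regulators=tuple(regs),
                genes=tuple(sorted(genes)),
                mean_r=_mean_pairwise_r(expr, genes),
            )
        )
    modules.sort(key=lambda m: (-len(m.genes), m.regulators))
    return modules


def enrich_pathways(
    module: Module,
    pathways: dict[str, set],
    universe: set[str],
    params: EgramParams | None = None,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each pathway in the module's
    gene set, BH-corrected; rows with FDR <= enrich_fdr."""
    params = params or EgramParams()
    genes = set(module.genes) & universe
    M = len(universe)
    N = len(genes)
    rows = []
    for name, members in sorted(pathways.items()):
        K = len(members & universe)
        if K == 0:
            continue
        k = len(members & genes)
        # P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append({"pathway": name, "overlap": k, "pathway_size": K, "p": p})
    df = pd.DataFrame(rows, columns=["pathway", "overlap", "pathway_size", "p"])
    if len(df):
        df["fdr"] = multipletests(df.p.to_numpy(), method="fdr_bh")[1]
        df = df[df.fdr <= params.enrich_fdr].reset_index(drop=True)
    else:
        df["fdr"] = []
    return df


def cross_module_check(
    lnc_modules: list[Module],
    tf_modules: list[Module],
) -> pd.DataFrame:
    """Per-gene co-regulation flags across the two module families."""
    lnc_genes = set().union(*(set(m.genes) for m in lnc_modules)) if lnc_modules else set()
    tf_genes = set().union(*(set(m.genes) for m in tf_modules)) if tf_modules else set()
    rows = []
    for gene in sorted(lnc_genes | tf_genes):
        in_l, in_t = gene in lnc_genes, gene in tf_genes
        status = "co-regulated" if (in_l and in_t) else ("lncRNA-only" if in_l else "TF-only")
        rows.append({"gene": gene, "in_lncrna_module": in_l,
                     "in_tf_module": in_t, "status": status})
    return pd.DataFrame(rows, columns=["gene", "in_lncrna_module", "in_tf_module",
                                       "status"])


def compare_species_modules(
    modules_a: list[Module],
    expr_a: pd.DataFrame,
    regulator_expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    regulator_expr_b: pd.DataFrame,
    ortholog_map: dict[str, str],
    params: EgramParams | None = None,
) -> pd.DataFrame:
    """Per species-A module: how much of it survives in species B.

    A mapped gene counts as "in a B module" iff its B expression correlates
    (|r| >= pearson_min) with a mapped member regulator — the same criterion
    that admitted it to the A module, evaluated on B data.  Also reports the
    mean within-set |Pearson r| in B over mapped genes, and its ratio to the
    A value.  Modules with <50% ortholog coverage are skipped.
    """
    params = params or EgramParams()
    rows = []
    for idx, mod in enumerate(modules_a):
        mapped = {g: ortholog_map[g] for g in mod.genes
                  if g in ortholog_map and ortholog_map[g] in expr_b.index}
        if len(mapped) < 0.5 * len(mod.genes):
            continue
        regs_b = [ortholog_map[r] for r in mod.regulators
                  if r in ortholog_map and ortholog_map[r] in regulator_expr_b.index]
        n_in = 0
        for g_b in mapped.values():
            for r_b in regs_b:
                r = _corr(regulator_expr_b.loc[r_b].to_numpy(),
                          expr_b.loc[g_b].to_numpy())
                if not math.isnan(r) and (abs(r) if params.absolute_r else r) >= params.pearson_min:
                    n_in += 1
                    break
        r_a = _mean_pairwise_r(expr_a, list(mapped.keys()))
        r_b = _mean_pairwise_r(expr_b, list(mapped.values()))
        rows.append(
            {"module": idx, "n_genes": len(mod.genes), "n_mapped": len(mapped),
             "fraction_in_b_modules": n_in / len(mapped) if mapped else float("nan"),
             "mean_r_a": r_a, "mean_r_b": r_b,
             "r_ratio": r_b / r_a if r_a else float("nan")}
        )
    return pd.DataFrame(
        rows, columns=["module", "n_genes", "n_mapped", "fraction_in_b_modules",
                       "mean_r_a", "mean_r_b", "r_ratio"]
    )


def read_gmt(path) -> dict[str, set]:
    pathways = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                pathways[parts[0]] = set(parts[2:])
    return pathways


def write_gmt(pathways: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\tna\t{genes}\n")
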
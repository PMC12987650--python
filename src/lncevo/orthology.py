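"""Calling orthologous lncRNA genes and human-specific (HS) lncRNAs.

Orthology is decided per genome from an exon-level hit table (the output of
a structure-aware RNA homology search, consumed here as a TSV): a genome
carries an ortholog of a human lncRNA gene iff the number of its exons with
hits in that genome strictly exceeds half the gene's exon count.  A gene is
human-specific iff no ortholog is called in any of the surveyed genomes
(16 mammals in the reference analysis).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["call_ortholog", "call_hs_genes", "read_hit_table", "write_gene_list"]

REQUIRED_COLUMNS = ("gene_id", "exon_id", "genome_id", "hit")


def read_hit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    df["hit"] = df["hit"].astype(bool)
    return df


def call_ortholog(gene: str, genome: str, table: pd.DataFrame) -> bool:
    """True iff the genome's exon hits strictly exceed half the exon count."""
    sub = table[table.gene_id == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} not in hit table")
    if genome not in set(sub.genome_id):
        raise KeyError(f"genome {genome!r} not in hit table for gene {gene!r}")
    exon_count = sub.exon_id.nunique()
    hits = sub[(sub.genome_id == genome) & sub.hit].exon_id.nunique()
    return hits > exon_count / 2


def call_hs_genes(table: pd.DataFrame, genomes: list[str]) -> list[str]:
    """Genes with no ortholog called in ANY of `genomes`.

    A genome absent from a gene's rows is an error, never treated as
    "no ortholog".
    """
    hs = []
    for gene, sub in table.groupby("gene_id", sort=True):
        present = set(sub.genome_id)
        missing = set(genomes) - present
        if missing:
            raise ValueError(f"gene {gene!r} lacks genomes {sorted(missing)}")
        exon_count = sub.exon_id.nunique()
        has_ortholog = False
        for genome in genomes:
            hits = sub[(sub.genome_id == genome) & sub.hit].exon_id.nunique()
            if hits > exon_count / 2:
                has_ortholog = True
                break
        if not has_ortholog:
            hs.append(gene)
    return hs


def write_gene_list(genes: list[str], path) -> None:
    pd.DataFrame({"gene_id": genes}).to_csv(path, sep="\t", index=False)
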
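"""Hypergeometric gene-set over-representation analysis.

Given an experiment gene list of size R drawn against a background of N
genes, a gene set (ontology term) of size n, and an observed overlap r, the
enrichment p-value is the hypergeometric upper tail P(X >= r) and the
z-score is the overlap standardised by the hypergeometric mean and the
finite-population-corrected standard deviation:

    E[X]   = n R / N
    Var[X] = R (n/N) (1 - n/N) (N - R) / (N - 1)

Both statistics are symmetric in (R, n).  q-values are BH over the tested
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de_pipeline import adjust_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "hypergeom_enrichment",
    "select_pathway_genes",
    "enrich",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background-universe size N.

    Symbols are matched uppercased.  N must be supplied explicitly (the
    enrichment statistics depend on it).
    """

    sets: dict[str, set[str]]
    background: int

    def __post_init__(self) -> None:
        if self.background < 1:
            raise ValueError("background size must be positive")
        clean = {}
        for name, genes in self.sets.items():
            genes = {str(g).upper() for g in genes}
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(genes) > self.background:
                raise ValueError(f"gene set {name!r} larger than the background")
            clean[name] = genes
        self.sets = clean


@dataclass
class EnrichmentRow:
    """One tested gene set: overlap counts and enrichment statistics."""

    pathway: str
    r: int
    R: int
    n: int
    N: int
    zscore: float
    pvalue: float
    qvalue: float = float("nan")


def hypergeom_enrichment(r: int, R: int, n: int, N: int) -> tuple[float, float]:
    """Enrichment z-score and upper-tail hypergeometric p-value for overlap r.

    pvalue = P(X >= r) with X ~ Hypergeom(N, n, R) (survival function at
    r - 1); zscore = (r - nR/N) / sd with the finite-population-corrected
    standard deviation.  Validates 0 <= r <= min(R, n) <= N.
    """
    r, R, n, N = int(r), int(R), int(n), int(N)
    if N < 1 or R < 0 or n < 0 or N < max(R, n):
        raise ValueError(f"invalid counts: r={r}, R={R}, n={n}, N={N}")
    if r < 0 or r > min(R, n):
        raise ValueError(f"overlap r={r} outside [0, min(R, n)={min(R, n)}]")
    pvalue = float(hypergeom.sf(r - 1, N, n, R))
    mean = n * R / N
    var = R * (n / N) * (1 - n / N) * (N - R) / (N - 1)
    if var <= 0:
        raise ValueError("degenerate hypergeometric: zero variance")
    zscore = (r - mean) / np.sqrt(var)
    return float(zscore), min(pvalue, 1.0)


def select_pathway_genes(
    results: pd.DataFrame, fdr: float = 0.01, min_abs_est: float = 0.585
) -> list[str]:
    """Genes entering pathway analysis: p_adj < fdr and |estimate| > min_abs_est.

    Both inequalities strict — this is the pathway-selection rule, slightly
    tighter on the estimate than the DE-calling rule's >=.
    """
    sel = results[
        (results["p_adj"] < fdr) & (results["estimate"].abs() > min_abs_est)
    ]
    return sel["gene"].tolist()


def enrich(gene_list, sets: GeneSetCollection) -> list[EnrichmentRow]:
    """Test every set for over-representation of ``gene_list``; BH q-values.

    Genes are matched on uppercased symbols; rows come back sorted by
    q-value then p-value ascending.
    """
    genes = {str(g).upper() for g in gene_list}
    if not genes:
        raise ValueError("empty gene list")
    N = sets.background
    R = len(genes)
    rows = []
    for name, members in sets.sets.items():
        r = len(genes & members)
        z, p = hypergeom_enrichment(r, R, len(members), N)
        rows.append(EnrichmentRow(name, r, R, len(members), N, z, p))
    q = adjust_pvalues([row.pvalue for row in rows], "BH")
    for row, qv in zip(rows, q):
        row.qvalue = float(qv)
    rows.sort(key=lambda row: (row.qvalue, row.pvalue, row.pathway))
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "pathway": [x.pathway for x in rows],
            "r": [x.r for x in rows],
            "R": [x.R for x in rows],
            "n": [x.n for x in rows],
            "N": [x.N for x in rows],
            "zscore": [x.zscore for x in rows],
            "pvalue": [x.pvalue for x in rows],
            "qvalue": [x.qvalue for x in rows],
        }
    )
    df["sig_p05"] = df["pvalue"] < 0.05
    df["sig_q05"] = df["qvalue"] < 0.05
    return df
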
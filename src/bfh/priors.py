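"""Informative priors for the disease-group coefficient from bulk RNA-seq.

A companion bulk study provides, per gene, the group-difference coefficient
from a covariate-adjusted linear regression.  That coefficient becomes the
prior mean of the single-cell group coefficient beta_1; its prior variance
is, by default, the square root of the coefficient's estimated sampling
variance — a deliberate moderation that widens an otherwise overly
concentrated prior (bulk studies are much larger than single-cell ones).
The intercept and remaining covariates keep non-informative N(0, 100)
priors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .hybrid_core import GaussianPrior, RankDeficiencyError, _collinear_columns

logger = logging.getLogger(__name__)

__all__ = [
    "BulkStudy",
    "GenePrior",
    "build_priors_from_bulk",
    "noninformative_prior",
    "assemble_full_prior",
]

NONINFORMATIVE_VARIANCE = 100.0


@dataclass
class BulkStudy:
    """Bulk RNA-seq expression with group labels and adjustment covariates.

    expr is samples x genes; ``covariates`` (samples x k, optional) are
    adjustment variables such as age, sex, race and smoking history.
    """

    expr: np.ndarray
    gene_names: list[str]
    group: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.group = np.asarray(self.group, dtype=float).ravel()
        self.gene_names = list(self.gene_names)
        if self.expr.shape != (self.group.shape[0], len(self.gene_names)):
            raise ValueError("expr must be samples x genes matching group and names")
        if len(np.unique(self.group)) != 2:
            raise ValueError("bulk study must contain exactly two groups")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.group.shape[0]:
                raise ValueError("covariates must have one row per sample")


@dataclass
class GenePrior:
    """Gaussian prior N(mean, variance) for one gene's group coefficient."""

    gene: str
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError(f"prior variance must be positive, got {self.variance}")


def build_priors_from_bulk(
    bulk: BulkStudy, moderation: str = "sqrt"
) -> list[GenePrior]:
    """Per-gene group-coefficient priors from covariate-adjusted bulk OLS.

    For each gene, fit expression ~ intercept + group (+ covariates); the
    group coefficient is the prior mean.  ``moderation`` controls the prior
    variance: ``sqrt`` (default) takes the square root of the coefficient's
    sampling variance, ``none`` uses it as-is, ``factor:k`` multiplies it
    by k.
    """
    n = bulk.group.shape[0]
    cols = [np.ones(n), bulk.group]
    if bulk.covariates is not None:
        cols.extend(bulk.covariates.T)
    Z = np.column_stack(cols)
    p = Z.shape[1]
    if np.linalg.matrix_rank(Z) < p:
        cols_bad = _collinear_columns(Z)
        raise RankDeficiencyError(
            f"bulk design is rank-deficient; collinear column(s): {cols_bad}"
        )
    ztz_inv = linalg.inv(Z.T @ Z)
    betas = ztz_inv @ (Z.T @ bulk.expr)  # p x genes
    resid = bulk.expr - Z @ betas
    sigma2 = (resid**2).sum(axis=0) / (n - p)
    coef_var = ztz_inv[1, 1] * sigma2

    if moderation == "sqrt":
        prior_var = np.sqrt(coef_var)
    elif moderation == "none":
        prior_var = coef_var
    elif moderation.startswith("factor:"):
        prior_var = coef_var * float(moderation.split(":", 1)[1])
    else:
        raise ValueError(f"unknown moderation rule {moderation!r}")

    return [
        GenePrior(gene=g, mean=float(betas[1, j]), variance=float(prior_var[j]))
        for j, g in enumerate(bulk.gene_names)
    ]


def noninformative_prior(p: int) -> GaussianPrior:
    """Flat default prior: mean zero, covariance diag(100, ..., 100)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return GaussianPrior(np.zeros(p), np.eye(p) * NONINFORMATIVE_VARIANCE)


def assemble_full_prior(
    gene_prior: GenePrior, p: int, group_idx: int
) -> GaussianPrior:
    """Embed a gene's group prior in a p-dimensional prior, flat elsewhere."""
    if not 0 <= group_idx < p:
        raise IndexError(f"group_idx {group_idx} out of range for p={p}")
    mean = np.zeros(p)
    mean[group_idx] = gene_prior.mean
    var = np.full(p, NONINFORMATIVE_VARIANCE)
    var[group_idx] = gene_prior.variance
    return GaussianPrior(mean, np.diag(var))


def match_genes(
    single_cell_genes: list[str], priors: list[GenePrior]
) -> dict[str, GenePrior]:
    """Case-insensitive (uppercased-symbol) matching of priors to genes.

    Genes without a bulk prior fall back to the non-informative default
    downstream; the intersection size is logged.
    """
    table = {pr.gene.upper(): pr for pr in priors}
    out = {}
    for g in single_cell_genes:
        pr = table.get(g.upper())
        if pr is not None:
            out[g] = pr
        else:
            logger.info("no bulk prior for gene %s; non-informative fallback", g)
    logger.info(
        "matched %d of %d single-cell genes to bulk priors",
        len(out),
        len(single_cell_genes),
    )
    return out


def priors_to_frame(priors: list[GenePrior]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [p.gene for p in priors],
            "prior_mean": [p.mean for p in priors],
            "prior_var": [p.variance for p in priors],
        }
    )


def priors_from_frame(df: pd.DataFrame) -> list[GenePrior]:
    return [
        GenePrior(gene=str(r.gene), mean=float(r.prior_mean), variance=float(r.prior_var))
        for r in df.itertuples()
    ]
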
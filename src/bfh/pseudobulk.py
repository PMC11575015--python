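"""Probability-weighted pseudo-bulk aggregation of single-cell counts.

Each cell carries a probability of belonging to the cell type of interest
(e.g. alveolar macrophages), produced upstream by a cell-type classifier.
Rather than hard-assigning cells, expression is summarised per subject as a
weighted mean of counts with those probabilities as weights; the mean
probability per subject, negative-log transformed, becomes the design
covariate X2.  Hard-assignment pseudo-bulk is the special case weight in
{0, 1}.

Gene and cell quality filters: genes are kept when their average count
across cells exceeds ``min_mean`` (default 0.1); cells are dropped when
their detected-gene count falls strictly below the lower 2-percentile or
their mitochondrial count fraction exceeds 10%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = ["CellData", "PseudoBulkTable", "filter_genes", "filter_cells", "aggregate"]

MITO_PREFIXES = ("MT-", "mt-")


def _as_dense(counts) -> np.ndarray:
    if sparse.issparse(counts):
        return np.asarray(counts.todense(), dtype=float)
    return np.asarray(counts, dtype=float)


@dataclass
class CellData:
    """Gene x cell counts with per-cell subject, weight, and per-subject group.

    counts may be dense or scipy.sparse (genes as rows).  ``group`` maps
    subject id -> binary label (0 control, 1 disease).  ``mito_flag`` marks
    mitochondrial genes; when omitted it is derived from gene-name prefixes
    (default ``MT-``/``mt-``).
    """

    counts: object
    gene_names: list[str]
    subject_id: np.ndarray
    group: dict
    weight: np.ndarray
    mito_flag: np.ndarray | None = None
    mito_prefixes: tuple[str, ...] = MITO_PREFIXES

    def __post_init__(self) -> None:
        self.gene_names = list(self.gene_names)
        self.subject_id = np.asarray(self.subject_id)
        self.weight = np.asarray(self.weight, dtype=float)
        g, c = self.counts.shape
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} count rows")
        if self.subject_id.shape[0] != c or self.weight.shape[0] != c:
            raise ValueError("subject_id and weight must have one entry per cell")
        if np.any((self.weight < 0) | (self.weight > 1)):
            raise ValueError("weights must lie in [0, 1]")
        if not sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts, dtype=float)
            if np.any(self.counts < 0):
                raise ValueError("counts must be non-negative")
        missing = set(np.unique(self.subject_id)) - set(self.group)
        if missing:
            raise ValueError(f"subjects without a group label: {sorted(missing)}")
        if self.mito_flag is None:
            self.mito_flag = np.array(
                [name.startswith(self.mito_prefixes) for name in self.gene_names]
            )
        else:
            self.mito_flag = np.asarray(self.mito_flag, dtype=bool)
            if self.mito_flag.shape[0] != g:
                raise ValueError("mito_flag must have one entry per gene")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "CellData":
        gene_mask = (
            np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        )
        cell_mask = (
            np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        )
        counts = self.counts[gene_mask][:, cell_mask]
        return CellData(
            counts=counts,
            gene_names=[n for n, k in zip(self.gene_names, gene_mask) if k],
            subject_id=self.subject_id[cell_mask],
            group=self.group,
            weight=self.weight[cell_mask],
            mito_flag=self.mito_flag[gene_mask],
            mito_prefixes=self.mito_prefixes,
        )


@dataclass
class PseudoBulkTable:
    """Per-subject weighted mean expression plus design covariates.

    Y is subjects x genes; X1 the group label; X2 the negative log of the
    subject's mean cell-type probability; n_cells the cells aggregated.
    """

    subjects: list
    gene_names: list[str]
    Y: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    n_cells: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "subject": self.subjects,
                "group": self.X1,
                "X2": self.X2,
                "n_cells": self.n_cells,
            }
        )
        expr = pd.DataFrame(self.Y, columns=self.gene_names)
        return pd.concat([meta, expr], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PseudoBulkTable":
        meta_cols = ["subject", "group", "X2", "n_cells"]
        genes = [c for c in df.columns if c not in meta_cols]
        return cls(
            subjects=df["subject"].tolist(),
            gene_names=genes,
            Y=df[genes].to_numpy(float),
            X1=df["group"].to_numpy(float),
            X2=df["X2"].to_numpy(float),
            n_cells=df["n_cells"].to_numpy(int),
        )


def filter_genes(data: CellData, min_mean: float = 0.1) -> CellData:
    """Keep genes whose mean count across all cells strictly exceeds ``min_mean``."""
    if data.n_genes == 0 or data.n_cells == 0:
        raise ValueError("empty CellData")
    totals = np.asarray(data.counts.sum(axis=1)).ravel()
    keep = totals / data.n_cells > min_mean
    if not keep.any():
        raise ValueError(f"no gene has mean expression > {min_mean}")
    logger.info("filter_genes: kept %d of %d genes", int(keep.sum()), data.n_genes)
    return data.subset(gene_mask=keep)


def filter_cells(
    data: CellData, low_pct: float = 2.0, max_mito: float = 0.10
) -> CellData:
    """Drop low-complexity and high-mitochondrial cells.

    A cell is removed when its detected-gene count (genes with count > 0) is
    strictly below the ``low_pct`` percentile of that distribution (linear
    interpolation), or when its mitochondrial count fraction exceeds
    ``max_mito``.
    """
    counts = data.counts
    if sparse.issparse(counts):
        detected = np.asarray((counts > 0).sum(axis=0)).ravel()
        total = np.asarray(counts.sum(axis=0)).ravel()
        mito = np.asarray(counts[data.mito_flag].sum(axis=0)).ravel()
    else:
        detected = (counts > 0).sum(axis=0)
        total = counts.sum(axis=0)
        mito = counts[data.mito_flag].sum(axis=0)
    cutoff = np.percentile(detected, low_pct)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 1.0)
    keep = (detected >= cutoff) & (mito_frac <= max_mito)
    dropped_subjects = set(np.unique(data.subject_id)) - set(
        np.unique(data.subject_id[keep])
    )
    for s in sorted(map(str, dropped_subjects)):
        logger.warning("filter_cells: all cells of subject %s removed", s)
    logger.info("filter_cells: kept %d of %d cells", int(keep.sum()), data.n_cells)
    return data.subset(cell_mask=keep)


def aggregate(data: CellData, log_base: float | None = None) -> PseudoBulkTable:
    """Weighted pseudo-bulk: per-subject weighted mean counts and covariates.

    Y[s, g] = sum_i w_i c[g, i] / sum_i w_i over cells i of subject s;
    X2[s] = -log(mean weight of subject s), natural log unless ``log_base``
    is given; X1[s] = group(s).
    """
    subjects = sorted(np.unique(data.subject_id).tolist())
    counts = _as_dense(data.counts)
    G = data.n_genes
    Y = np.empty((len(subjects), G))
    X1 = np.empty(len(subjects))
    X2 = np.empty(len(subjects))
    n_cells = np.empty(len(subjects), dtype=int)
    for k, s in enumerate(subjects):
        mask = data.subject_id == s
        w = data.weight[mask]
        wsum = w.sum()
        if wsum <= 0:
            raise ValueError(f"subject {s!r} has zero total weight")
        Y[k] = counts[:, mask] @ w / wsum
        mean_w = w.mean()
        X2[k] = -np.log(mean_w)
        if log_base is not None:
            X2[k] /= np.log(log_base)
        X1[k] = data.group[s]
        n_cells[k] = int(mask.sum())
    return PseudoBulkTable(
        subjects=subjects,
        gene_names=list(data.gene_names),
        Y=Y,
        X1=X1,
        X2=X2,
        n_cells=n_cells,
    )
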
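"""Readers and writers for the pipeline's file formats.

Counts arrive either as a MatrixMarket triplet directory (matrix.mtx with
features.tsv / barcodes.tsv sidecars, 10x convention, 1-based indices) or a
dense CSV with genes as rows.  Cell metadata is a TSV with columns
``barcode, subject, weight``; subject metadata a TSV with ``subject,
group``.  Gene sets use GMT.  All text is UTF-8; floats are written with 6
significant digits so outputs are byte-stable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .enrichment import GeneSetCollection
from .pseudobulk import CellData, PseudoBulkTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "read_cell_data",
    "write_counts_csv",
    "write_pseudobulk",
    "read_pseudobulk",
    "write_results",
    "read_gmt",
    "read_config",
]

FLOAT_FORMAT = "%.6g"


def _dedupe(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            new = f"{name}.{seen[name]}"
            logger.warning("duplicated gene name %s renamed to %s", name, new)
            out.append(new)
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_counts(path) -> tuple[object, list[str], list[str]]:
    """Read a counts matrix: returns (genes x cells matrix, gene names, barcodes).

    ``path`` is either a directory holding ``matrix.mtx`` + ``features.tsv``
    + ``barcodes.tsv`` (1-based MatrixMarket indices) or a CSV with genes as
    rows and a leading gene-name column.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        feats = path / "features.tsv"
        bars = path / "barcodes.tsv"
        for f in (mtx, feats, bars):
            if not f.exists():
                raise FileNotFoundError(f"missing {f.name} in {path}")
        counts = sparse.csc_matrix(scipy_io.mmread(mtx))
        genes = pd.read_csv(feats, sep="\t", header=None)[0].astype(str).tolist()
        barcodes = pd.read_csv(bars, sep="\t", header=None)[0].astype(str).tolist()
        if counts.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"matrix {counts.shape} does not match {len(genes)} features x "
                f"{len(barcodes)} barcodes"
            )
    else:
        df = pd.read_csv(path, index_col=0)
        genes = [str(g) for g in df.index]
        barcodes = [str(c) for c in df.columns]
        counts = df.to_numpy(dtype=float)
    if sparse.issparse(counts):
        if counts.nnz and counts.min() < 0:
            raise ValueError(f"negative counts in {path}")
    elif np.any(np.asarray(counts) < 0):
        raise ValueError(f"negative counts in {path}")
    return counts, _dedupe(genes), barcodes


def read_cell_data(counts_path, cell_meta_path, subject_meta_path) -> CellData:
    """Assemble a CellData from counts plus cell and subject metadata TSVs."""
    counts, genes, barcodes = read_counts(counts_path)
    cells = pd.read_csv(cell_meta_path, sep="\t", dtype={"barcode": str, "subject": str})
    for col in ("barcode", "subject", "weight"):
        if col not in cells.columns:
            raise ValueError(f"cell metadata is missing column {col!r}")
    cells = cells.set_index("barcode").reindex(barcodes)
    if cells["subject"].isna().any():
        missing = [b for b, s in zip(barcodes, cells["subject"]) if pd.isna(s)]
        raise ValueError(f"barcodes without metadata: {missing[:5]}")
    subjects = pd.read_csv(subject_meta_path, sep="\t", dtype={"subject": str})
    group = dict(zip(subjects["subject"], subjects["group"].astype(int)))
    return CellData(
        counts=counts,
        gene_names=genes,
        subject_id=cells["subject"].to_numpy(),
        group=group,
        weight=cells["weight"].to_numpy(float),
    )


def write_counts_csv(path, counts, gene_names, barcodes) -> None:
    if sparse.issparse(counts):
        counts = np.asarray(counts.todense())
    pd.DataFrame(counts, index=gene_names, columns=barcodes).to_csv(
        path, float_format=FLOAT_FORMAT
    )


def write_pseudobulk(path, pb: PseudoBulkTable) -> None:
    pb.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_pseudobulk(path) -> PseudoBulkTable:
    return PseudoBulkTable.from_frame(pd.read_csv(path))


def write_results(path, results: pd.DataFrame) -> None:
    results.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_gmt(path, background: int) -> GeneSetCollection:
    """GMT: one set per line — name, description, then member genes (tab-separated)."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, desc, genes")
            sets[parts[0]] = set(parts[2:])
    return GeneSetCollection(sets=sets, background=background)


def read_config(path) -> dict:
    """Flat ``key = value`` config file; values stay strings."""
    cfg = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg
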
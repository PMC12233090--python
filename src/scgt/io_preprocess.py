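"""Loading, gene alignment, normalization and per-gene standardization.

Both modalities enter as genes x cells matrices: raw counts for the
scRNA-seq reference, gene activity scores for the scATAC-seq query.
They are restricted to their common genes, LogNormalized, and then each
gene is standardized to zero mean / unit standard deviation *within its
own dataset* — the two modalities are standardized independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
import pandas as pd

REFERENCE = "reference"
QUERY = "query"


@dataclass
class OmicsDataset:
    """A genes x cells matrix with identifiers, optional labels and a modality tag.

    Parameters
    ----------
    matrix
        Dense ``(n_genes, n_cells)`` array of counts or activity scores.
    gene_ids, cell_ids
        Ordered identifiers for rows and columns.
    labels
        Per-cell type names; required for the reference modality at load
        time, absent for the query.
    modality
        Either ``"reference"`` or ``"query"``.
    """

    matrix: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    labels: Optional[np.ndarray] = None
    modality: str = REFERENCE

    def __post_init__(self) -> None:
        if sp.issparse(self.matrix):
            self.matrix = np.asarray(self.matrix.todense(), dtype=float)
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (genes x cells)")
        if self.matrix.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but {len(self.gene_ids)} gene ids"
            )
        if self.matrix.shape[1] != len(self.cell_ids):
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids are not allowed")
        if self.modality not in (REFERENCE, QUERY):
            raise ValueError(f"modality must be 'reference' or 'query', got {self.modality!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != self.matrix.shape[1]:
                raise ValueError(
                    f"{len(self.labels)} labels for {self.matrix.shape[1]} cells"
                )

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, indices: np.ndarray) -> "OmicsDataset":
        return OmicsDataset(
            matrix=self.matrix[indices, :],
            gene_ids=self.gene_ids[indices],
            cell_ids=self.cell_ids,
            labels=self.labels,
            modality=self.modality,
        )


@dataclass
class StandardizedMatrix:
    """Per-gene standardized matrix with the statistics used."""

    matrix: np.ndarray
    per_gene_mean: np.ndarray
    per_gene_sd: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]


def _read_lines(path: Path) -> np.ndarray:
    with open(path) as fh:
        return np.asarray([line.strip() for line in fh if line.strip() != ""], dtype=object)


def load_dataset(
    path: str | Path,
    format: str,
    labels_path: Optional[str | Path] = None,
    *,
    modality: str = REFERENCE,
    orientation: str = "genes_by_cells",
    genes_path: Optional[str | Path] = None,
    cells_path: Optional[str | Path] = None,
    label_key: str = "cell_type",
) -> OmicsDataset:
    """Load a dataset from mtx, csv/tsv or h5ad into genes x cells orientation.

    For ``mtx``, gene/cell identifiers come from sidecar text files (one id
    per line), by default ``<stem>.genes.txt`` and ``<stem>.cells.txt`` next
    to the matrix file.  For ``csv``/``tsv``, rows are genes with an index
    column of gene ids and a header of cell ids.  For ``h5ad`` the AnnData
    cells x genes convention is assumed and transposed on load, with labels
    taken from ``obs[label_key]`` when present.

    ``orientation`` applies to mtx/csv only: ``"genes_by_cells"`` (on-disk
    rows are genes) or ``"cells_by_genes"`` (transposed on load).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")

    labels = None
    if format == "mtx":
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:  # mmread raises bare ValueError with record info
            raise ValueError(f"malformed Matrix Market file {path}: {exc}") from exc
        mat = np.asarray(sp.coo_matrix(mat).todense(), dtype=float)
        if orientation == "cells_by_genes":
            mat = mat.T
        stem = path.with_suffix("")
        gpath = Path(genes_path) if genes_path is not None else Path(str(stem) + ".genes.txt")
        cpath = Path(cells_path) if cells_path is not None else Path(str(stem) + ".cells.txt")
        gene_ids = _read_lines(gpath)
        cell_ids = _read_lines(cpath)
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ValueError(f"malformed {format} file {path}: {exc}") from exc
        if orientation == "cells_by_genes":
            df = df.T
        mat = df.to_numpy(dtype=float)
        gene_ids = df.index.to_numpy(dtype=object)
        cell_ids = df.columns.to_numpy(dtype=object)
    elif format == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        mat = adata.X
        if sp.issparse(mat):
            mat = np.asarray(mat.todense(), dtype=float)
        else:
            mat = np.asarray(mat, dtype=float)
        mat = mat.T  # AnnData stores cells x genes
        gene_ids = adata.var_names.to_numpy(dtype=object)
        cell_ids = adata.obs_names.to_numpy(dtype=object)
        if label_key in adata.obs.columns:
            labels = adata.obs[label_key].to_numpy(dtype=object)
    else:
        raise ValueError(f"unknown format {format!r}")

    if labels_path is not None:
        labels = _read_lines(Path(labels_path))
        if len(labels) != mat.shape[1]:
            raise ValueError(
                f"labels file has {len(labels)} entries but the matrix has {mat.shape[1]} cells"
            )
    return OmicsDataset(matrix=mat, gene_ids=gene_ids, cell_ids=cell_ids,
                        labels=labels, modality=modality)


def align_common_genes(
    ref: OmicsDataset, query: OmicsDataset, *, case_insensitive: bool = False
) -> tuple[OmicsDataset, OmicsDataset]:
    """Restrict both datasets to their shared genes, sorted lexicographically.

    Matching is exact-string and case-sensitive unless ``case_insensitive``
    is set, in which case both sides are lowercased before intersecting.
    """
    ref_ids = ref.gene_ids
    query_ids = query.gene_ids
    if case_insensitive:
        ref_ids = np.asarray([g.lower() for g in ref_ids], dtype=object)
        query_ids = np.asarray([g.lower() for g in query_ids], dtype=object)
    common = sorted(set(ref_ids) & set(query_ids))
    if len(common) == 0:
        raise ValueError(
            "reference and query share no gene identifiers; "
            "harmonize gene naming (e.g. symbol vs Ensembl id, case) and retry"
        )
    ref_pos = {g: i for i, g in enumerate(ref_ids)}
    query_pos = {g: i for i, g in enumerate(query_ids)}
    ref_idx = np.asarray([ref_pos[g] for g in common], dtype=int)
    query_idx = np.asarray([query_pos[g] for g in common], dtype=int)
    ref_out = ref.subset_genes(ref_idx)
    query_out = query.subset_genes(query_idx)
    if case_insensitive:  # both sides carry the lowercased, matched ids
        ref_out.gene_ids = np.asarray(common, dtype=object)
        query_out.gene_ids = np.asarray(common, dtype=object)
    return ref_out, query_out


def lognormalize(ds: OmicsDataset, scale_factor: float = 1e4) -> OmicsDataset:
    """LogNormalize: x_ij -> ln(1 + scale_factor * x_ij / colsum_j).

    Library-size normalization per cell followed by log1p, applied
    identically to counts and gene activity scores.  All-zero cells pass
    through as zeros with a warning.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    X = ds.matrix
    if np.any(X < 0):
        raise ValueError("negative entries are not valid counts/activities")
    colsum = X.sum(axis=0)
    zero_cols = colsum == 0
    if np.any(zero_cols):
        warnings.warn(
            f"{int(zero_cols.sum())} cell(s) have zero total signal and pass through as zeros"
        )
    safe = np.where(zero_cols, 1.0, colsum)
    out = np.log1p(scale_factor * X / safe[None, :])
    return OmicsDataset(matrix=out, gene_ids=ds.gene_ids, cell_ids=ds.cell_ids,
                        labels=ds.labels, modality=ds.modality)


def standardize_genes(ds: OmicsDataset) -> StandardizedMatrix:
    """Standardize each gene over this dataset's cells: (x - mu_i) / theta_i.

    theta_i is the population standard deviation (divide by n).  Genes with
    zero variance are set to all-zero rows.
    """
    X = ds.matrix
    mu = X.mean(axis=1)
    sd = X.std(axis=1)  # population (ddof=0)
    safe = np.where(sd == 0, 1.0, sd)
    out = (X - mu[:, None]) / safe[:, None]
    out[sd == 0, :] = 0.0
    return StandardizedMatrix(matrix=out, per_gene_mean=mu, per_gene_sd=sd)


def write_predictions_tsv(
    path: str | Path,
    cell_ids: Sequence[str],
    predicted: Sequence[str],
    confidence: Sequence[float],
) -> None:
    """Write predictions as a three-column TSV: cell_id, predicted_type, confidence."""
    df = pd.DataFrame(
        {"cell_id": list(cell_ids), "predicted_type": list(predicted),
         "confidence": list(confidence)}
    )
    df.to_csv(path, sep="\t", index=False)
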
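"""Integration-quality metrics: silhouette F1, MAP, cell-type ASW, accuracy.

All metrics operate on the joint embedding with cells as rows and use
Euclidean distance.  The silhouette F1 trades biological separation
(cell-type silhouette, larger is better) against modality mixing (omics
silhouette, smaller is better):

    Sil_F1 = 2 * [1 - (1 + Sil_omic)/2] * [(1 + Sil_celltype)/2]
             / ( [1 - (1 + Sil_omic)/2] + [(1 + Sil_celltype)/2] )

MAP averages, per cell, the precision at each type-matched position among
its W ordered nearest neighbors (0 when no neighbor matches); cell-type ASW
rescales the mean cell-type silhouette to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .hybrid_graph import UNKNOWN

#: returned where a silhouette is undefined (a labeling with a single class)
UNDEFINED = float("nan")


@dataclass
class MetricsReport:
    sil_celltype: float
    sil_omics: float
    sil_f1: float
    map_score: float
    celltype_asw: float
    accuracy: Optional[float]
    confusion: Optional[pd.DataFrame]

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = {
            "sil_celltype": self.sil_celltype,
            "sil_omics": self.sil_omics,
            "sil_f1": self.sil_f1,
            "map_score": self.map_score,
            "celltype_asw": self.celltype_asw,
            "accuracy": self.accuracy,
        }
        if self.confusion is not None:
            payload["confusion"] = {
                "true_types": list(self.confusion.index),
                "predicted_types": list(self.confusion.columns),
                "matrix": self.confusion.to_numpy().tolist(),
            }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _mean_silhouette(embedding: np.ndarray, labels: np.ndarray) -> float:
    labels = np.asarray(labels, dtype=object)
    if len(set(labels)) < 2:
        warnings.warn("silhouette undefined for a single class; returning NaN")
        return UNDEFINED
    return float(silhouette_score(embedding, labels, metric="euclidean"))


def combine_silhouettes(sil_celltype: float, sil_omics: float) -> float:
    """Harmonic mean of the mixing term 1-(1+Sil_omic)/2 and the bio term (1+Sil_celltype)/2."""
    mix = 1.0 - (1.0 + sil_omics) / 2.0   # 1 = perfectly mixed modalities
    bio = (1.0 + sil_celltype) / 2.0      # 1 = perfectly separated cell types
    if mix + bio == 0:
        return 0.0
    return 2.0 * mix * bio / (mix + bio)


def silhouette_f1(
    embedding: np.ndarray,
    celltype_labels: Sequence[str],
    omics_labels: Sequence[str],
) -> tuple[float, float, float]:
    """(Sil_celltype, Sil_omic, Sil_F1) on the joint embedding (cells x dims)."""
    embedding = np.asarray(embedding, dtype=float)
    sil_ct = _mean_silhouette(embedding, np.asarray(celltype_labels, dtype=object))
    sil_om = _mean_silhouette(embedding, np.asarray(omics_labels, dtype=object))
    if np.isnan(sil_ct) or np.isnan(sil_om):
        return sil_ct, sil_om, UNDEFINED
    return sil_ct, sil_om, combine_silhouettes(sil_ct, sil_om)


def mean_average_precision(
    embedding: np.ndarray, celltype_labels: Sequence[str], W: int = 30
) -> float:
    """Mean over cells of the average precision at type-matched neighbor ranks.

    For each cell, its W ordered nearest neighbors (Euclidean, self excluded)
    are scanned; precision is accumulated at every rank whose neighbor shares
    the cell's type, averaged over the matched ranks, and 0 when none match.
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(celltype_labels, dtype=object)
    n = len(embedding)
    if W < 1:
        raise ValueError("W must be >= 1")
    if W >= n:
        raise ValueError("W must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=W + 1, algorithm="brute", metric="euclidean")
    nn.fit(embedding)
    idx = nn.kneighbors(embedding, return_distance=False)
    aps = np.zeros(n)
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:W]
        match = np.asarray([labels[j] == labels[i] for j in neigh], dtype=float)
        if match.sum() == 0:
            aps[i] = 0.0
            continue
        ranks = np.arange(1, W + 1)
        precision_at = np.cumsum(match) / ranks
        aps[i] = float((precision_at * match).sum() / match.sum())
    return float(aps.mean())


def cell_type_asw(embedding: np.ndarray, celltype_labels: Sequence[str]) -> float:
    """Cell-type average silhouette width mapped to [0, 1]: (mean sil + 1) / 2."""
    sil = _mean_silhouette(np.asarray(embedding, dtype=float),
                           np.asarray(celltype_labels, dtype=object))
    if np.isnan(sil):
        return UNDEFINED
    return (sil + 1.0) / 2.0


def label_transfer_accuracy(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    reference_types: Optional[Sequence[str]] = None,
    unknown_label: str = UNKNOWN,
) -> float:
    """Fraction of query cells whose prediction matches the ground truth.

    In corrected mode (``reference_types`` given), ground-truth labels absent
    from the reference type set are first mapped to ``unknown_label``, so an
    "Unknown" prediction for a query-only type counts as correct.
    """
    true = np.asarray(true_labels, dtype=object)
    pred = np.asarray(predicted_labels, dtype=object)
    if len(true) != len(pred):
        raise ValueError("label vectors must have equal length")
    if reference_types is not None:
        ref_set = set(reference_types)
        true = np.asarray(
            [t if t in ref_set else unknown_label for t in true], dtype=object
        )
    return float(np.mean(true == pred))


def confusion_matrix_normalized(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> pd.DataFrame:
    """Row-normalized confusion matrix: rows are true types, columns predicted."""
    true = np.asarray(true_labels, dtype=object)
    pred = np.asarray(predicted_labels, dtype=object)
    counts = pd.crosstab(pd.Series(true, name="true"), pd.Series(pred, name="predicted"))
    return counts.div(counts.sum(axis=1), axis=0)


def compute_report(
    embedding: np.ndarray,
    celltype_labels: Sequence[str],
    omics_labels: Sequence[str],
    true_query_labels: Optional[Sequence[str]] = None,
    predicted_query_labels: Optional[Sequence[str]] = None,
    W: int = 30,
    reference_types: Optional[Sequence[str]] = None,
) -> MetricsReport:
    """Full metric suite on a joint embedding (cells x dims)."""
    sil_ct, sil_om, f1 = silhouette_f1(embedding, celltype_labels, omics_labels)
    map_score = mean_average_precision(embedding, celltype_labels, W=W)
    asw = cell_type_asw(embedding, celltype_labels)
    accuracy = None
    confusion = None
    if true_query_labels is not None and predicted_query_labels is not None:
        accuracy = label_transfer_accuracy(
            true_query_labels, predicted_query_labels, reference_types=reference_types
        )
        confusion = confusion_matrix_normalized(true_query_labels, predicted_query_labels)
    return MetricsReport(
        sil_celltype=sil_ct,
        sil_omics=sil_om,
        sil_f1=f1,
        map_score=map_score,
        celltype_asw=asw,
        accuracy=accuracy,
        confusion=confusion,
    )
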
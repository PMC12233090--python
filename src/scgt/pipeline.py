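"""End-to-end orchestration: preprocess -> hybrid graph -> train -> predict."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .gt_network import (
    ForwardOutput,
    GTParams,
    PredictionResult,
    init_gt_params,
    predict_with_confidence,
)
from .hybrid_graph import (
    BipartiteAdjacency,
    HybridGraph,
    IntraAdjacency,
    build_and_filter,
    type_order_of,
)
from .io_preprocess import OmicsDataset, align_common_genes, lognormalize, standardize_genes
from .losses_training import TrainConfig, TrainResult, train


@dataclass
class GraphConfig:
    n_pcs: int = 30
    k_inter: int = 5
    k_intra: int = 10
    hops: int = 4


@dataclass
class ModelConfig:
    d_enc: int = 256
    d: int = 64
    m_rf: int = 35
    n_layers: int = 2
    tau: float = 0.25
    activation: str = "elu"
    local_normalize: bool = False


@dataclass
class IntegrationResult:
    model: GTParams
    output: ForwardOutput
    predictions: PredictionResult
    training_log: list
    type_order: list
    ref_cell_ids: np.ndarray
    query_cell_ids: np.ndarray
    graph: HybridGraph
    arq_raw: BipartiteAdjacency
    arq_filtered: BipartiteAdjacency
    aqq: IntraAdjacency

    @property
    def embedding(self) -> np.ndarray:
        """Joint embedding with cells as rows (reference block first)."""
        return self.output.H.T

    @property
    def omics_labels(self) -> np.ndarray:
        n_ref = len(self.ref_cell_ids)
        n_query = len(self.query_cell_ids)
        return np.asarray(["reference"] * n_ref + ["query"] * n_query, dtype=object)


def run_integration(
    ref: OmicsDataset,
    query: OmicsDataset,
    *,
    seed: int = 0,
    scale_factor: float = 1e4,
    graph_config: Optional[GraphConfig] = None,
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
    unknown_threshold: Optional[float] = None,
    query_true_labels: Optional[Sequence[str]] = None,
) -> IntegrationResult:
    """Run the full scGT pipeline on a labeled reference and unlabeled query.

    All randomness (PCA solvers, network initialization, Gumbel noise)
    derives from ``seed``.  ``query_true_labels`` is used only for logging
    transfer accuracy during training.
    """
    if ref.labels is None:
        raise ValueError("the reference dataset must carry per-cell labels")
    graph_config = graph_config or GraphConfig()
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    train_config.seed = seed

    ref_a, query_a = align_common_genes(ref, query)
    Xr = standardize_genes(lognormalize(ref_a, scale_factor))
    Xq = standardize_genes(lognormalize(query_a, scale_factor))

    hybrid, arq, arq_f, arr, aqq = build_and_filter(
        Xr,
        Xq,
        ref_a.labels,
        n_components=graph_config.n_pcs,
        k_inter=graph_config.k_inter,
        k_intra=graph_config.k_intra,
        hops=graph_config.hops,
        seed=seed,
    )

    types = type_order_of(ref_a.labels)
    t_index = {t: i for i, t in enumerate(types)}
    ref_label_idx = np.asarray([t_index[t] for t in ref_a.labels], dtype=int)

    model = init_gt_params(
        Xr.n_genes,
        types,
        seed=seed,
        d_enc=model_config.d_enc,
        d=model_config.d,
        m_rf=model_config.m_rf,
        n_layers=model_config.n_layers,
        tau=model_config.tau,
        activation=model_config.activation,
        local_normalize=model_config.local_normalize,
    )

    X = np.concatenate([Xr.matrix, Xq.matrix], axis=1)
    result: TrainResult = train(
        X, model, hybrid, arq_f, aqq, ref_label_idx, train_config,
        query_true_labels=query_true_labels,
    )

    n_ref = Xr.n_cells
    query_global = np.arange(n_ref, n_ref + Xq.n_cells)
    preds = predict_with_confidence(
        result.output.P, query_global, types, unknown_threshold=unknown_threshold
    )
    return IntegrationResult(
        model=result.model,
        output=result.output,
        predictions=preds,
        training_log=result.log,
        type_order=types,
        ref_cell_ids=ref_a.cell_ids,
        query_cell_ids=query_a.cell_ids,
        graph=hybrid,
        arq_raw=arq,
        arq_filtered=arq_f,
        aqq=aqq,
    )
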
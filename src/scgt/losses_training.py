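"""Composite loss (hard / cross-entropy / query regularization) and training.

The total loss is the unweighted sum of three terms:

* hard regularization — mean squared embedding distance over the filtered
  inter-dataset pairs, per embedding dimension, relaxed by epsilon and
  clamped at zero; pulls matched reference/query cells together;
* cross-entropy — over the supervised set, which starts as the labeled
  reference cells and optionally grows by promoting query cells whose
  prediction confidence exceeds a high threshold (0.95 by default);
* query graph regularization — penalizes disagreement of predicted types
  across intra-query edges, relaxed by epsilon.  The printed form uses a
  0/1 agreement indicator whose gradient vanishes almost everywhere, so
  training uses the probability-agreement surrogate sum_t P_{t,i} P_{t,j}
  (which equals the indicator exactly for one-hot columns); the indicator
  form is computed and logged alongside.

Optimization is full-graph Adam with L2 weight decay; Gumbel noise is
resampled every training forward pass and zeroed for the per-epoch
inference pass used for promotion, logging and the final output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc.flatten import flatten
from autograd.tracer import getval

from .gt_network import (
    ForwardOutput,
    GTParams,
    network_forward,
    predict_with_confidence,
)
from .hybrid_graph import BipartiteAdjacency, HybridGraph, IntraAdjacency


@dataclass
class TrainConfig:
    """Training hyperparameters; epsilon relaxations default to 0.1."""

    epochs: int = 300
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    optimizer: str = "adam"
    eps_hard: float = 0.1
    eps_query: float = 0.1
    promotion_threshold: float = 0.95
    promotion_enabled: bool = True
    promotion_every: int = 1
    unknown_threshold: Optional[float] = None  # reporting only
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.promotion_threshold <= 1):
            raise ValueError("promotion_threshold must be in (0, 1]")
        if self.eps_hard < 0 or self.eps_query < 0:
            raise ValueError("epsilon relaxations must be >= 0")


@dataclass
class SupervisedSet:
    """Cells contributing to the cross-entropy term.

    The first ``n_reference`` entries are the reference cells with their
    true labels and are immutable; the remainder are promoted query cells
    whose working labels track the current predictions.
    """

    indices: np.ndarray       # global cell indices
    label_idx: np.ndarray     # indices into the type ordering
    n_reference: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.label_idx = np.asarray(self.label_idx, dtype=int)
        if len(self.indices) != len(self.label_idx):
            raise ValueError("indices and labels must align")
        if len(self.indices) < self.n_reference:
            raise ValueError("supervised set cannot be smaller than the reference block")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def n_promoted(self) -> int:
        return len(self) - self.n_reference


def hard_regularization_loss(H, arq_f: BipartiteAdjacency, eps: float = 0.1):
    """max( mean over filtered pairs of ||H_i^R - H_j^Q||^2 / d - eps, 0 ).

    Query columns of H sit at offset n_ref.  Identically zero when the
    filtered pair set is empty.
    """
    if len(arq_f) == 0:
        return 0.0
    d = getval(H).shape[0]
    i = arq_f.pairs[:, 0]
    j = arq_f.pairs[:, 1] + arq_f.n_ref
    diff = H[:, i] - H[:, j]
    mean_sq = anp.mean(anp.sum(diff * diff, axis=0)) / d
    return anp.maximum(mean_sq - eps, 0.0)


def cross_entropy_loss(P, sup: SupervisedSet):
    """-mean over the supervised set of log P_{label, i}."""
    if len(sup) == 0:
        raise ValueError("supervised set is empty: cannot train without labels")
    picked = P[sup.label_idx, sup.indices]
    return -anp.mean(anp.log(picked + 1e-12))


def query_graph_regularization(
    P,
    aqq: IntraAdjacency,
    eps: float = 0.1,
    n_offset: int = 0,
):
    """Query-graph term: (differentiable surrogate, logged indicator form).

    The indicator form is ``max(1 - mean_edges I[pred_i == pred_j] - eps, 0)``
    exactly as printed; the surrogate replaces the indicator with the
    agreement probability ``sum_t P_{t,i} P_{t,j}``, which coincides with it
    for one-hot probability columns.  Both are returned; only the surrogate
    carries gradient.
    """
    if len(aqq) == 0:
        return 0.0, 0.0
    i = aqq.pairs[:, 0] + n_offset
    j = aqq.pairs[:, 1] + n_offset
    agree_prob = anp.sum(P[:, i] * P[:, j], axis=0)
    surrogate = anp.maximum(1.0 - anp.mean(agree_prob) - eps, 0.0)

    P_val = getval(P)
    pred = P_val.argmax(axis=0)
    agree = float(np.mean(pred[i] == pred[j]))
    indicator = max(1.0 - agree - eps, 0.0)
    return surrogate, indicator


def total_loss(hard, entropy, query):
    """Unweighted sum L = L_hard + L_entropy + L_query."""
    return hard + entropy + query


def promote_confident_cells(
    P: np.ndarray,
    sup: SupervisedSet,
    threshold: float,
    query_global_indices: np.ndarray,
) -> SupervisedSet:
    """Grow the supervised set with query cells predicted above ``threshold``.

    Newly confident query cells are added with their predicted label; labels
    of previously promoted cells are refreshed to the current prediction.
    Reference cells are never relabeled, and the set never shrinks.
    """
    query_global_indices = np.asarray(query_global_indices, dtype=int)
    cols = P[:, query_global_indices]
    conf = cols.max(axis=0)
    pred = cols.argmax(axis=0)

    indices = list(sup.indices[: sup.n_reference])
    labels = list(sup.label_idx[: sup.n_reference])
    promoted = {
        int(c): int(l)
        for c, l in zip(sup.indices[sup.n_reference:], sup.label_idx[sup.n_reference:])
    }
    for q, c, p in zip(query_global_indices, conf, pred):
        if int(q) in promoted:
            promoted[int(q)] = int(p)  # refresh to the current prediction
        elif c > threshold:
            promoted[int(q)] = int(p)
    for q in sorted(promoted):
        indices.append(q)
        labels.append(promoted[q])
    return SupervisedSet(
        indices=np.asarray(indices, dtype=int),
        label_idx=np.asarray(labels, dtype=int),
        n_reference=sup.n_reference,
    )


@dataclass
class TrainResult:
    model: GTParams
    output: ForwardOutput
    log: list  # one dict per epoch
    supervised: SupervisedSet


def train(
    X: np.ndarray,
    model: GTParams,
    graph: HybridGraph,
    arq_f: BipartiteAdjacency,
    aqq: IntraAdjacency,
    ref_label_idx: Sequence[int],
    config: TrainConfig,
    query_true_labels: Optional[Sequence[str]] = None,
) -> TrainResult:
    """Full-graph training loop around the composite loss.

    ``X`` is the (genes, nR+nQ) standardized column-concatenation
    [X^R, X^Q]; ``ref_label_idx`` are the reference cells' label indices in
    ``model.type_order``.  ``query_true_labels``, when given, is used only
    to log transfer accuracy per epoch.  Deterministic given
    ``config.seed`` up to floating-point reduction order.
    """
    n_ref = graph.n_ref
    n_query = graph.n_query
    n = n_ref + n_query
    if X.shape[1] != n:
        raise ValueError(f"X has {X.shape[1]} cells but the graph has {n} nodes")
    ref_label_idx = np.asarray(ref_label_idx, dtype=int)
    if len(ref_label_idx) != n_ref:
        raise ValueError("need one label index per reference cell")

    adj = graph.to_sparse()
    query_global = np.arange(n_ref, n)
    sup = SupervisedSet(
        indices=np.arange(n_ref), label_idx=ref_label_idx, n_reference=n_ref
    )
    rng = np.random.default_rng(config.seed)
    term_log: dict = {}

    def loss_fn(params, gumbel, sup_now):
        H, C, P = network_forward(params, model, X, adj, gumbel)
        l_hard = hard_regularization_loss(H, arq_f, config.eps_hard)
        l_ce = cross_entropy_loss(P, sup_now)
        l_query, l_query_ind = query_graph_regularization(
            P, aqq, config.eps_query, n_offset=n_ref
        )
        term_log["hard"] = float(getval(l_hard))
        term_log["entropy"] = float(getval(l_ce))
        term_log["query"] = float(getval(l_query))
        term_log["query_indicator"] = float(l_query_ind)
        return total_loss(l_hard, l_ce, l_query)

    grad_fn = value_and_grad(loss_fn)

    flat_p, unflatten = flatten(model.params)
    m_state = np.zeros_like(flat_p)
    v_state = np.zeros_like(flat_p)
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    params = model.params
    log: list[dict] = []

    for epoch in range(config.epochs):
        gumbel = [rng.gumbel(size=n) for _ in range(model.n_layers)]
        loss_val, grads = grad_fn(params, gumbel, sup)
        if not np.isfinite(loss_val):
            bad = [k for k in ("hard", "entropy", "query") if not np.isfinite(term_log[k])]
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: offending term(s) {bad or ['total']}"
            )
        flat_g, _ = flatten(grads)
        flat_p, unflatten = flatten(params)
        flat_g = flat_g + config.weight_decay * flat_p
        m_state = b1 * m_state + (1 - b1) * flat_g
        v_state = b2 * v_state + (1 - b2) * flat_g ** 2
        mhat = m_state / (1 - b1 ** (epoch + 1))
        vhat = v_state / (1 - b2 ** (epoch + 1))
        flat_p = flat_p - config.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
        params = unflatten(flat_p)

        # inference pass: promotion, accuracy logging
        H, C, P = network_forward(params, model, X, adj, None)
        P = np.asarray(P)
        if config.promotion_enabled and (epoch + 1) % config.promotion_every == 0:
            sup = promote_confident_cells(
                P, sup, config.promotion_threshold, query_global
            )
        entry = {
            "epoch": epoch,
            "loss": float(loss_val),
            "l_hard": term_log["hard"],
            "l_entropy": term_log["entropy"],
            "l_query": term_log["query"],
            "l_query_indicator": term_log["query_indicator"],
            "n_promoted": sup.n_promoted,
        }
        if query_true_labels is not None:
            pred = predict_with_confidence(P, query_global, model.type_order)
            entry["accuracy"] = float(
                np.mean(pred.predicted == np.asarray(query_true_labels, dtype=object))
            )
        log.append(entry)

    model.params = params
    H, C, P = network_forward(params, model, X, adj, None)
    out = ForwardOutput(H=np.asarray(H), C=np.asarray(C), P=np.asarray(P))
    return TrainResult(model=model, output=out, log=log, supervised=sup)
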
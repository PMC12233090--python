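"""The scGT network: encoder, kernelized Gumbel-Softmax attention, classifier.

The architecture is a one-layer encoder (genes -> d_enc, ELU), followed by
two graph-transformer layers, followed by a single linear classifier over
the reference type set.  Each transformer layer combines

* a *global* attention term over all nR+nQ cells, computed with positive
  random features so that the softmax kernel factorizes and the cost stays
  linear in the number of cells (no n x n matrix is ever formed), with
  per-source Gumbel perturbations e^{g_j / tau} during training; and
* a *local* term: a sigmoid(beta)-gated sum of the value vectors of the
  cell's neighbors in the hybrid graph.

All tensors are column-major over cells: a layer input/output is a
(dim, nR+nQ) array, reference block first.

Implemented on numpy with `autograd` supplying reverse-mode gradients; the
sparse-adjacency product used by the local term carries a custom vector-
Jacobian product so the graph never densifies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import autograd.numpy as anp
import numpy as np
import scipy.sparse as sp
from autograd.extend import primitive, defvjp
from autograd.tracer import getval

from .hybrid_graph import UNKNOWN, HybridGraph

_EPS_DENOM = 1e-8


@primitive
def spmm(A, B):
    """Sparse @ dense product; A is a constant adjacency, B is differentiated."""
    return A @ B


defvjp(spmm, None, lambda ans, A, B: lambda g: A.T @ g)


def _sigmoid(x):
    return 1.0 / (1.0 + anp.exp(-x))


def _elu(x):
    return anp.where(x > 0, x, anp.exp(anp.minimum(x, 0.0)) - 1.0)


@dataclass
class GTParams:
    """Learnable parameters plus fixed hyperparameters of the scGT network.

    ``params`` is a nested dict of arrays (the trainable leaves):
    ``enc_W, enc_b``, per-layer ``Wq, Wk, Wv, beta``, and ``clf_W, clf_b``.
    ``W_rf`` holds the positive-random-feature projections, drawn once
    N(0, I_d) at initialization and never trained.
    """

    params: dict
    W_rf: np.ndarray
    tau: float
    n_types: int
    type_order: list
    d_enc: int
    d: int
    m_rf: int
    n_layers: int
    activation: str = "elu"
    local_normalize: bool = False

    @property
    def n_genes(self) -> int:
        return self.params["enc_W"].shape[1]


def init_gt_params(
    n_genes: int,
    type_order: Sequence[str],
    seed: int = 0,
    *,
    d_enc: int = 256,
    d: int = 64,
    m_rf: int = 35,
    n_layers: int = 2,
    tau: float = 0.25,
    activation: str = "elu",
    local_normalize: bool = False,
) -> GTParams:
    """Glorot-initialized parameters; beta starts at 0 so the local gate is 0.5."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)

    def glorot(fan_out, fan_in):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_out, fan_in))

    layers = []
    d_in = d_enc
    for _ in range(n_layers):
        layers.append(
            {
                "Wq": glorot(d, d_in),
                "Wk": glorot(d, d_in),
                "Wv": glorot(d, d_in),
                "beta": np.zeros(()),
            }
        )
        d_in = d
    params = {
        "enc_W": glorot(d_enc, n_genes),
        "enc_b": np.zeros(d_enc),
        "layers": layers,
        # zero-init final layer: initial P is uniform, so confidence-gated
        # promotion cannot latch onto random initial predictions
        "clf_W": np.zeros((len(type_order), d)),
        "clf_b": np.zeros(len(type_order)),
    }
    W_rf = rng.standard_normal((m_rf, d))
    return GTParams(
        params=params,
        W_rf=W_rf,
        tau=tau,
        n_types=len(type_order),
        type_order=list(type_order),
        d_enc=d_enc,
        d=d,
        m_rf=m_rf,
        n_layers=n_layers,
        activation=activation,
        local_normalize=local_normalize,
    )


def random_feature_map(x: np.ndarray, W_rf: np.ndarray) -> np.ndarray:
    """Positive random feature map for the softmax kernel.

    phi(x) = exp(-||x||^2 / 2) / sqrt(m_rf) * (exp(w_k^T x))_k, with rows of
    ``W_rf`` drawn i.i.d. N(0, I_d).  E[phi(x)^T phi(y)] = exp(x^T y -
    (||x||^2 + ||y||^2)/2), an unbiased estimator of the (normalized)
    softmax kernel; all entries are strictly positive.

    Accepts a single d-vector or a (d, n) column stack.
    """
    x = anp.asarray(x)
    m_rf = W_rf.shape[0]
    single = x.ndim == 1
    X = x[:, None] if single else x
    expo = W_rf @ X - 0.5 * anp.sum(X * X, axis=0)[None, :]
    out = anp.exp(expo) / anp.sqrt(m_rf)
    return out[:, 0] if single else out


def encoder_forward(X: np.ndarray, params: dict, activation: str = "elu") -> np.ndarray:
    """One fully-connected layer over the concatenated [X^R, X^Q] columns."""
    W, b = params["enc_W"], params["enc_b"]
    if getval(X).shape[0] != W.shape[1]:
        raise ValueError(
            f"encoder expects {W.shape[1]} genes, got {getval(X).shape[0]}"
        )
    pre = anp.dot(W, X) + b[:, None]
    if activation == "elu":
        return _elu(pre)
    if activation == "identity":
        return pre
    raise ValueError(f"unknown activation {activation!r}")


def attention_layer(
    h: np.ndarray,
    adj: Optional[sp.spmatrix],
    layer_params: dict,
    W_rf: np.ndarray,
    tau: float,
    gumbel: Optional[np.ndarray] = None,
    local_normalize: bool = False,
) -> np.ndarray:
    """One kernelized Gumbel-Softmax message-passing layer.

    Output column i is the random-feature-factorized global attention
    ``phi(q_i/tau)^T sum_j e^{g_j/tau} phi(k_j/tau) v_j^T`` normalized by
    ``phi(q_i/tau)^T sum_w e^{g_w/tau} phi(k_w/tau)``, plus the local term
    ``sigma(beta) * sum_{j: A_ij=1} v_j``.  Only the two cached sums over j
    are formed, so the cost is O(n * m_rf * d).

    ``gumbel`` is a length-n vector of standard Gumbel draws (training) or
    None / zeros (inference).  Exponent shifts that provably cancel in the
    numerator/denominator ratio keep the exponentials finite.
    """
    Wq, Wk, Wv = layer_params["Wq"], layer_params["Wk"], layer_params["Wv"]
    beta = layer_params["beta"]
    n = getval(h).shape[1]
    Q = anp.dot(Wq, h) / tau
    K = anp.dot(Wk, h) / tau
    V = anp.dot(Wv, h)
    g = np.zeros(n) if gumbel is None else np.asarray(gumbel, dtype=float)

    # log phi up to the 1/sqrt(m_rf) factor, which cancels in the ratio
    Eq = anp.dot(W_rf, Q) - 0.5 * anp.sum(Q * Q, axis=0)[None, :]
    Ek = anp.dot(W_rf, K) - 0.5 * anp.sum(K * K, axis=0)[None, :] + (g / tau)[None, :]
    # per-column shift for phi(q_i) and one global shift for the keys: both
    # scale numerator and denominator identically
    Phi_q = anp.exp(Eq - anp.max(Eq, axis=0, keepdims=True))
    Phi_k = anp.exp(Ek - anp.max(Ek))

    S = anp.dot(Phi_k, V.T)          # (m_rf, d): sum_j w_j phi(k_j) v_j^T
    z = anp.sum(Phi_k, axis=1)       # (m_rf,):   sum_w w_w phi(k_w)
    num = anp.dot(S.T, Phi_q)        # (d, n)
    den = anp.dot(z, Phi_q)          # (n,)
    den_val = getval(den)
    if isinstance(den_val, np.ndarray) and np.any(den_val == 0):
        warnings.warn("zero attention denominator; stabilized with eps=1e-8")
    out = num / (den + _EPS_DENOM)[None, :]

    if adj is not None and adj.nnz > 0:
        agg = spmm(adj, V.T).T       # (d, n): sum over graph neighbors of v_j
        if local_normalize:
            deg = np.maximum(np.asarray(adj.sum(axis=1)).ravel(), 1.0)
            agg = agg / deg[None, :]
        out = out + _sigmoid(beta) * agg
    return out


def classifier_forward(H: np.ndarray, params: dict) -> np.ndarray:
    """Single affine layer projecting the embedding onto the |T_R| type logits."""
    return anp.dot(params["clf_W"], H) + params["clf_b"][:, None]


def softmax_probabilities(C: np.ndarray) -> np.ndarray:
    """Column-wise softmax, stabilized by per-column max subtraction."""
    shifted = C - anp.max(C, axis=0, keepdims=True)
    e = anp.exp(shifted)
    return e / anp.sum(e, axis=0, keepdims=True)


@dataclass
class ForwardOutput:
    """Joint embedding, logits and probabilities for all nR + nQ cells."""

    H: np.ndarray  # (d, nR+nQ)
    C: np.ndarray  # (|T_R|, nR+nQ)
    P: np.ndarray  # (|T_R|, nR+nQ), columns sum to 1


def network_forward(
    params: dict,
    model: GTParams,
    X: np.ndarray,
    adj: Optional[sp.spmatrix],
    gumbel: Optional[list] = None,
) -> tuple:
    """Full forward pass; ``gumbel`` is one length-n draw per layer, or None.

    ``params`` is passed separately from ``model`` so autograd can
    differentiate through it; use ``model.params`` for a plain forward.
    """
    h = encoder_forward(X, params, activation=model.activation)
    for l, lp in enumerate(params["layers"]):
        g = gumbel[l] if gumbel is not None else None
        h = attention_layer(
            h, adj, lp, model.W_rf, model.tau, gumbel=g,
            local_normalize=model.local_normalize,
        )
    H = h
    C = classifier_forward(H, params)
    P = softmax_probabilities(C)
    return H, C, P


def forward(
    model: GTParams,
    X: np.ndarray,
    graph: Optional[HybridGraph],
    *,
    train_mode: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> ForwardOutput:
    """Inference-friendly forward pass.

    In training mode fresh Gumbel noise is drawn per layer from ``rng``; at
    inference the noise is identically zero, so the pass is deterministic.
    """
    adj = graph.to_sparse() if graph is not None else None
    n = X.shape[1]
    gumbel = None
    if train_mode:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for Gumbel noise")
        gumbel = [rng.gumbel(size=n) for _ in range(model.n_layers)]
    H, C, P = network_forward(model.params, model, X, adj, gumbel)
    return ForwardOutput(H=np.asarray(H), C=np.asarray(C), P=np.asarray(P))


@dataclass
class PredictionResult:
    """Per-query-cell predicted type and confidence."""

    query_indices: np.ndarray
    predicted: np.ndarray    # type names, possibly "Unknown"
    confidence: np.ndarray   # column max of P
    argmax_type: np.ndarray  # type names before thresholding


def predict_with_confidence(
    P: np.ndarray,
    query_indices: Sequence[int],
    type_order: Sequence[str],
    unknown_threshold: Optional[float] = None,
) -> PredictionResult:
    """Argmax type and max-probability confidence per query cell.

    With an ``unknown_threshold``, cells whose confidence falls below it are
    labeled "Unknown".  Ties resolve to the smallest type index.
    """
    query_indices = np.asarray(query_indices, dtype=int)
    cols = P[:, query_indices]
    best = cols.argmax(axis=0)  # smallest index on ties
    conf = cols.max(axis=0)
    types = np.asarray(list(type_order), dtype=object)
    argmax_type = types[best]
    predicted = argmax_type.copy()
    if unknown_threshold is not None:
        predicted[conf < unknown_threshold] = UNKNOWN
    return PredictionResult(
        query_indices=query_indices,
        predicted=predicted,
        confidence=conf,
        argmax_type=argmax_type,
    )


def save_checkpoint(model: GTParams, path: str | Path) -> None:
    """Archive named tensors plus a JSON hyperparameter block."""
    flat: dict[str, np.ndarray] = {
        "enc_W": model.params["enc_W"],
        "enc_b": model.params["enc_b"],
        "clf_W": model.params["clf_W"],
        "clf_b": model.params["clf_b"],
        "W_rf": model.W_rf,
    }
    for l, lp in enumerate(model.params["layers"]):
        for k, v in lp.items():
            flat[f"layer{l}_{k}"] = np.asarray(v)
    hyper = {
        "tau": model.tau,
        "type_order": model.type_order,
        "d_enc": model.d_enc,
        "d": model.d,
        "m_rf": model.m_rf,
        "n_layers": model.n_layers,
        "activation": model.activation,
        "local_normalize": model.local_normalize,
    }
    flat["hyper_json"] = np.frombuffer(json.dumps(hyper).encode(), dtype=np.uint8)
    np.savez(path, **flat)


def load_checkpoint(path: str | Path) -> GTParams:
    with np.load(path, allow_pickle=False) as data:
        hyper = json.loads(bytes(data["hyper_json"]).decode())
        layers = []
        for l in range(hyper["n_layers"]):
            layers.append(
                {
                    "Wq": data[f"layer{l}_Wq"],
                    "Wk": data[f"layer{l}_Wk"],
                    "Wv": data[f"layer{l}_Wv"],
                    "beta": data[f"layer{l}_beta"],
                }
            )
        params = {
            "enc_W": data["enc_W"],
            "enc_b": data["enc_b"],
            "layers": layers,
            "clf_W": data["clf_W"],
            "clf_b": data["clf_b"],
        }
        return GTParams(
            params=params,
            W_rf=data["W_rf"],
            tau=float(hyper["tau"]),
            n_types=len(hyper["type_order"]),
            type_order=list(hyper["type_order"]),
            d_enc=int(hyper["d_enc"]),
            d=int(hyper["d"]),
            m_rf=int(hyper["m_rf"]),
            n_layers=int(hyper["n_layers"]),
            activation=hyper["activation"],
            local_normalize=bool(hyper["local_normalize"]),
        )
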
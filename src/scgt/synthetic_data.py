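"""Synthetic paired "RNA" / "ATAC-activity" data with shared cluster structure.

Both modalities sample the same per-type gene-mean program (on the log
scale); the query modality additionally carries a per-gene mean offset that
emulates the systematic shift between expression counts and gene activity
scores.  Counts are negative-binomial around the exponentiated means and
then thinned to a target per-modality sparsity.  Type lists may differ
between modalities (reference-only / query-only types) so that unknown-type
rejection and non-transfer of absent types can be exercised.

Defaults emulate a targeted-panel-scale experiment: 800 cells per modality,
200 genes, four equally frequent well-separated types, a moderate modality
shift and sparsity typical of gene-level summaries over an informative panel (60%
zeros for expression, 65% for gene activity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .hybrid_graph import BipartiteAdjacency
from .io_preprocess import QUERY, REFERENCE, OmicsDataset


@dataclass
class SyntheticConfig:
    """Generator settings; ``n_types`` counts all types across both lists."""

    n_ref: int = 800
    n_query: int = 800
    n_genes: int = 200
    n_types: int = 4
    type_proportions: Optional[Sequence[float]] = None  # uniform when None
    cluster_separation: float = 16.0   # Euclidean distance between type means (log scale)
    de_fraction: float = 0.2          # fraction of genes carrying each type's program
    omics_shift_scale: float = 0.3    # sd of the per-gene modality mean offset
    noise_sd: float = 0.3             # per-cell, per-gene log-mean jitter
    sparsity: tuple[float, float] = (0.6, 0.65)  # (reference, query) zero fraction
    ref_only_types: tuple[str, ...] = ()
    query_only_types: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sparsity, (int, float)):
            self.sparsity = (float(self.sparsity), float(self.sparsity))
        if not all(0 <= s < 1 for s in self.sparsity):
            raise ValueError("sparsity must be in [0, 1)")
        if set(self.ref_only_types) & set(self.query_only_types):
            raise ValueError("a type cannot be both reference-only and query-only")
        names = self.type_names
        for t in (*self.ref_only_types, *self.query_only_types):
            if t not in names:
                raise ValueError(f"unknown type {t!r} in an only-list")
        if self.type_proportions is not None:
            p = np.asarray(self.type_proportions, dtype=float)
            if len(p) != self.n_types:
                raise ValueError("type_proportions must have n_types entries")
            if not np.isclose(p.sum(), 1.0):
                raise ValueError("type_proportions must sum to 1")

    @property
    def type_names(self) -> list[str]:
        return [f"type_{i}" for i in range(self.n_types)]

    def modality_types(self, modality: str) -> list[str]:
        if modality == REFERENCE:
            excluded = set(self.query_only_types)
        else:
            excluded = set(self.ref_only_types)
        return [t for t in self.type_names if t not in excluded]


#: negative-binomial dispersion phi in var = mu + phi * mu^2
NB_DISPERSION = 0.5


def _sample_modality(
    rng: np.random.Generator,
    config: SyntheticConfig,
    log_means: dict,
    n_cells: int,
    modality: str,
    offset: np.ndarray,
    sparsity: float,
) -> tuple[np.ndarray, np.ndarray]:
    types = config.modality_types(modality)
    if config.type_proportions is None:
        probs = np.full(len(types), 1.0 / len(types))
    else:
        all_p = dict(zip(config.type_names, config.type_proportions))
        probs = np.asarray([all_p[t] for t in types], dtype=float)
        probs = probs / probs.sum()
    assignment = rng.choice(len(types), size=n_cells, p=probs)
    labels = np.asarray([types[a] for a in assignment], dtype=object)

    mu_log = np.stack([log_means[t] for t in labels], axis=1)  # genes x cells
    mu_log = mu_log + offset[:, None]
    if config.noise_sd > 0:
        mu_log = mu_log + rng.normal(0.0, config.noise_sd, size=mu_log.shape)
    lam = np.exp(mu_log)

    r = 1.0 / NB_DISPERSION  # NB size parameter
    p = r / (r + lam)
    counts = rng.negative_binomial(r, p).astype(float)

    # thin to the requested zero fraction (exact when feasible)
    total = counts.size
    target_zeros = int(round(sparsity * total))
    flat = counts.ravel()
    nonzero_idx = np.flatnonzero(flat)
    current_zeros = total - len(nonzero_idx)
    if current_zeros > target_zeros:
        warnings.warn(
            f"natural sparsity {current_zeros / total:.2f} already exceeds the "
            f"target {sparsity:.2f}; leaving counts unthinned"
        )
    else:
        kill = rng.choice(nonzero_idx, size=target_zeros - current_zeros, replace=False)
        flat[kill] = 0.0
    return flat.reshape(counts.shape), labels


def generate(config: SyntheticConfig) -> tuple[OmicsDataset, OmicsDataset, np.ndarray]:
    """Draw (reference with labels, query without labels, ground-truth query labels).

    Per-type log-mean programs are drawn once and shared across modalities:
    mu_t = baseline + separation * u_t with u_t a sparse unit direction
    supported on a random ``de_fraction`` subset of genes, so
    ``cluster_separation`` is the Euclidean distance between a type's mean
    program and the shared baseline, concentrated marker-gene style.
    """
    rng = np.random.default_rng(config.seed)
    baseline = rng.normal(0.7, 0.4, size=config.n_genes)
    n_de = max(1, int(round(config.de_fraction * config.n_genes)))
    log_means = {}
    for t in config.type_names:
        # marker-gene-like program: the type's log-fold-changes concentrate
        # on a random gene subset, with the program's Euclidean norm equal
        # to cluster_separation
        genes_t = rng.choice(config.n_genes, size=n_de, replace=False)
        direction = np.zeros(config.n_genes)
        direction[genes_t] = rng.choice([-1.0, 1.0], size=n_de) * rng.uniform(
            0.5, 1.5, size=n_de
        )
        direction /= np.linalg.norm(direction)
        log_means[t] = baseline + config.cluster_separation * direction
    offset_q = rng.normal(0.0, config.omics_shift_scale, size=config.n_genes)

    ref_mat, ref_labels = _sample_modality(
        rng, config, log_means, config.n_ref, REFERENCE,
        np.zeros(config.n_genes), config.sparsity[0],
    )
    q_mat, q_labels = _sample_modality(
        rng, config, log_means, config.n_query, QUERY, offset_q, config.sparsity[1]
    )
    genes = np.asarray([f"gene_{i}" for i in range(config.n_genes)], dtype=object)
    ref = OmicsDataset(
        matrix=ref_mat,
        gene_ids=genes,
        cell_ids=np.asarray([f"ref_{i}" for i in range(config.n_ref)], dtype=object),
        labels=ref_labels,
        modality=REFERENCE,
    )
    query = OmicsDataset(
        matrix=q_mat,
        gene_ids=genes.copy(),
        cell_ids=np.asarray([f"query_{i}" for i in range(config.n_query)], dtype=object),
        labels=None,
        modality=QUERY,
    )
    return ref, query, q_labels


def connection_correctness(
    arq: BipartiteAdjacency,
    ref_labels: Sequence[str],
    query_labels: Sequence[str],
) -> float:
    """Fraction of pairs whose true endpoint types agree."""
    if len(arq) == 0:
        return float("nan")
    ref_labels = np.asarray(ref_labels, dtype=object)
    query_labels = np.asarray(query_labels, dtype=object)
    i, j = arq.pairs[:, 0], arq.pairs[:, 1]
    return float(np.mean(ref_labels[i] == query_labels[j]))


def plant_connection_noise(
    arq: BipartiteAdjacency,
    flip_fraction: float,
    ref_labels: Sequence[str],
    query_labels: Sequence[str],
    seed: int = 0,
) -> BipartiteAdjacency:
    """Replace a fraction of pairs with random type-violating pairs.

    A harness for evaluating the inter-connection filter: the planted pairs
    connect cells of *different* true types, so filter precision/recall can
    be measured against ground truth.
    """
    if not (0 <= flip_fraction <= 1):
        raise ValueError("flip_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ref_labels = np.asarray(ref_labels, dtype=object)
    query_labels = np.asarray(query_labels, dtype=object)
    pairs = [tuple(p) for p in arq.pairs]
    n_flip = int(round(flip_fraction * len(pairs)))
    keep_idx = rng.choice(len(pairs), size=len(pairs) - n_flip, replace=False)
    kept = {pairs[k] for k in keep_idx}
    existing = set(kept)
    planted: list[tuple[int, int]] = []
    attempts = 0
    while len(planted) < n_flip and attempts < 100 * max(n_flip, 1):
        i = int(rng.integers(arq.n_ref))
        j = int(rng.integers(arq.n_query))
        attempts += 1
        if ref_labels[i] == query_labels[j] or (i, j) in existing:
            continue
        planted.append((i, j))
        existing.add((i, j))
    if len(planted) < n_flip:
        warnings.warn("could not plant the full requested number of violating pairs")
    all_pairs = np.asarray(sorted(kept | set(planted)), dtype=int).reshape(-1, 2)
    return BipartiteAdjacency(pairs=all_pairs, n_ref=arq.n_ref, n_query=arq.n_query)
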
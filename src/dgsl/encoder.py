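"""Cross-view lightweight graph propagation.

The encoder follows the LightGCN recipe: no feature-transformation matrices
and no nonlinear activations, just repeated multiplication by a normalized
adjacency with an explicit self-loop, ``x^{(l)} = (Ã + I) x^{(l-1)}``. It is
run on three views — the bipartite association graph over the stacked
disease+gene embeddings, and the two homogeneous neighbor graphs — after
which per-layer embeddings are pooled (mean over depths 0..L by default)
and the association-view and neighbor-view pooled embeddings are fused by
elementwise summation.

Because every step is linear, the map from initial to pooled embeddings is
itself a fixed matrix ``pool(Ã) = (1/(L+1)) Σ_l (Ã+I)^l``; the training loop
precomputes it once per graph (see :func:`pooling_operator`), which makes a
full-batch epoch a handful of dense matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .graphs import NormalizedAdjacency

__all__ = [
    "EncoderConfig",
    "EmbeddingState",
    "propagate",
    "pool_layers",
    "fuse_views",
    "score_pair",
    "pooling_operator",
]


@dataclass
class EncoderConfig:
    """Architecture switches for the cross-view encoder.

    embed_dim
        Dimension d of all embeddings (default 64).
    num_layers
        Propagation depth L on every view (default 2).
    layer_pooling
        ``mean`` averages layers 0..L (uniform 1/(L+1) weights); ``sum``
        adds them. Mean keeps logit scale independent of L.
    use_disease_view / use_gene_view
        Ablation switches; a disabled neighbor view contributes zero to the
        fused embedding.
    """

    embed_dim: int = 64
    num_layers: int = 2
    layer_pooling: Literal["mean", "sum"] = "mean"
    use_disease_view: bool = True
    use_gene_view: bool = True

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.layer_pooling not in ("mean", "sum"):
            raise ValueError("layer_pooling must be 'mean' or 'sum'")


@dataclass
class EmbeddingState:
    """Pooled and fused embeddings from one forward pass.

    ``pooled_assoc_*`` come from the bipartite association view (the stacked
    propagation split back into disease and gene blocks); ``pooled_d`` /
    ``pooled_g`` from the homogeneous neighbor views (zero when the view is
    disabled); ``fused_*`` are their sums and feed the pair scorer.
    """

    pooled_assoc_d: np.ndarray
    pooled_assoc_g: np.ndarray
    pooled_d: np.ndarray
    pooled_g: np.ndarray
    fused_d: np.ndarray
    fused_g: np.ndarray


def propagate(adj: NormalizedAdjacency | np.ndarray, x0: np.ndarray, num_layers: int) -> list[np.ndarray]:
    """Run ``x^{(l)} = (Ã + I) x^{(l-1)}`` and return all L+1 layers."""
    a = adj.values if isinstance(adj, NormalizedAdjacency) else np.asarray(adj)
    x0 = np.asarray(x0)
    if a.shape[0] != a.shape[1] or a.shape[1] != x0.shape[0]:
        raise ValueError(f"adjacency {a.shape} does not match embeddings {x0.shape}")
    layers = [x0]
    for _ in range(num_layers):
        x = layers[-1]
        layers.append(a @ x + x)
    return layers


def pool_layers(layers: list[np.ndarray], mode: Literal["mean", "sum"] = "mean") -> np.ndarray:
    """Combine per-depth embeddings into one matrix."""
    if not layers:
        raise ValueError("cannot pool an empty layer list")
    shapes = {l.shape for l in layers}
    if len(shapes) != 1:
        raise ValueError("layer matrices must share a shape")
    stacked = sum(layers[1:], layers[0].copy())
    if mode == "mean":
        return stacked / len(layers)
    if mode == "sum":
        return stacked
    raise ValueError(f"unknown pooling mode {mode!r}")


def fuse_views(pooled_assoc: np.ndarray, pooled_neighbor: np.ndarray | None) -> np.ndarray:
    """Elementwise sum of the two views; a disabled view contributes zero."""
    if pooled_neighbor is None:
        return pooled_assoc.copy()
    if pooled_assoc.shape != pooled_neighbor.shape:
        raise ValueError("view embeddings must share a shape")
    return pooled_assoc + pooled_neighbor


def score_pair(fused_d_row: np.ndarray, fused_g_row: np.ndarray) -> tuple[float, float]:
    """Association score of one disease-gene pair.

    The raw model output is the inner product of the fused embeddings; the
    logistic function maps it to a probability so it can enter a
    cross-entropy loss.
    """
    fused_d_row = np.asarray(fused_d_row)
    fused_g_row = np.asarray(fused_g_row)
    if fused_d_row.shape != fused_g_row.shape:
        raise ValueError("embedding vectors must have equal dimension")
    logit = float(fused_d_row @ fused_g_row)
    return logit, float(1.0 / (1.0 + np.exp(-logit)))


def pooling_operator(adj: NormalizedAdjacency | np.ndarray, num_layers: int,
                     mode: Literal["mean", "sum"] = "mean") -> np.ndarray:
    """The matrix M with pool(propagate(Ã, X)) == M @ X.

    Equals ``w Σ_{l=0}^{L} (Ã+I)^l`` with w = 1/(L+1) for mean pooling and
    1 for sum pooling. Exact because propagation is linear in X.
    """
    a = adj.values if isinstance(adj, NormalizedAdjacency) else np.asarray(adj)
    n = a.shape[0]
    p = a + np.eye(n)
    acc = np.eye(n)
    power = np.eye(n)
    for _ in range(num_layers):
        power = p @ power
        acc += power
    if mode == "mean":
        acc /= num_layers + 1
    return acc
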
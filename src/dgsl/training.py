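"""Multi-task optimization of the cross-view model.

The trainable parameters are the initial disease and gene embeddings
``E_d`` (m x d), ``E_g`` (n x d) and the projection head (d_vec, T_mat,
c_vec). The objective combines

* a weighted binary cross-entropy over all supervised disease-gene cells,
  with the balance factor γ = |S⁻|/|S⁺| up-weighting the rare observed
  associations, and
* hinge alignment losses ``Σ max(0, 1 − s·ŝ)`` per side, where s is the
  learnable bounded association-view pair similarity and ŝ the neighbor
  view dot product,

as ``L = L_bce + α (L_ssl^d + L_ssl^g)``.

Training is full batch: one optimization step per epoch scores every
disease-gene cell. Because propagation is linear, each view collapses to a
precomputed pooling operator (:func:`dgsl.encoder.pooling_operator`), and
both the forward pass and the analytic backward pass are a few dense
matrix products. Gradients are exact (hand-derived; verified against
finite differences in the test suite) and parameters are updated with
Adam. Xavier initialization is used for E_d, E_g and T_mat; d_vec and
c_vec start at zero so the projected similarity is uninformative (0.5)
until trained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from ._rng import substream
from .alignment import PairSample, ProjectionHead, sample_pairs
from .encoder import EmbeddingState, EncoderConfig, pooling_operator
from .graphs import (
    AssociationMatrix,
    NeighborGraph,
    normalize_bipartite,
    normalize_homogeneous,
)

__all__ = [
    "TrainConfig",
    "LossBreakdown",
    "TrainResult",
    "weighted_bce_loss",
    "ssl_alignment_loss",
    "contrastive_ssl_loss",
    "total_loss",
    "train",
]

PROB_CLIP = 1e-7


@dataclass
class TrainConfig:
    """Optimization hyperparameters and ablation switches.

    alpha
        Balance factor on the alignment losses (default 0.01).
    learning_rate
        Adam step size (default 0.01).
    epochs
        Full-batch steps (default 300).
    pair_count
        Same-type pairs sampled per step and side for alignment (default 64).
    ssl_mode
        ``denoise`` is the hinge alignment objective; ``contrastive``
        replaces it with an InfoNCE objective over the two views of the
        same entities; ``off`` disables the auxiliary task.
    use_ssl_d / use_ssl_g
        Per-side switches for the auxiliary task.
    mask_test_pairs
        When true, cells in the association's train_mask are excluded from
        both the positive and negative supervision sets. The default
        (false) follows the objective's definition of the negative set as
        *all* unknown pairs: held-out cells are zeros in the training
        matrix and are therefore trained as negatives. The masked
        convention removes that contamination but, on small dense
        problems, lets a high-capacity model identify held-out cells as
        exactly the unsupervised ones — an optimistic leak.
    patience
        Early-stopping patience on validation AUPRC; only active when a
        validation set is passed to :func:`train`.
    """

    alpha: float = 0.01
    learning_rate: float = 0.01
    epochs: int = 300
    pair_count: int = 64
    seed: int = 0
    use_ssl_d: bool = True
    use_ssl_g: bool = True
    ssl_mode: Literal["denoise", "contrastive", "off"] = "denoise"
    mask_test_pairs: bool = False
    cl_temperature: float = 0.2
    negative_slope: float = 0.01
    patience: int = 30

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class LossBreakdown:
    bce: float
    ssl_d: float
    ssl_g: float
    total: float
    gamma: float


@dataclass
class TrainResult:
    state: EmbeddingState
    head: ProjectionHead
    history: list[LossBreakdown]
    params: dict[str, np.ndarray]
    probabilities: np.ndarray  # m x n matrix from the final forward pass


# ---------------------------------------------------------------------------
# loss functions


def _supervision_weights(assoc: AssociationMatrix, mask_test_pairs: bool) -> tuple[np.ndarray, np.ndarray, float]:
    """(positive weight matrix γ·1[S⁺], negative weight matrix 1[S⁻], γ)."""
    y = assoc.values
    sup = np.ones_like(y)
    if mask_test_pairs:
        for i, j in assoc.train_mask:
            sup[i, j] = 0.0
    n_pos = float((y * sup).sum())
    n_neg = float(((1.0 - y) * sup).sum())
    if n_pos == 0:
        raise ValueError("no positive supervision cells: gamma undefined")
    gamma = n_neg / n_pos
    return gamma * y * sup, (1.0 - y) * sup, gamma


def weighted_bce_loss(
    probs: np.ndarray, assoc: AssociationMatrix, mask_test_pairs: bool = False
) -> tuple[float, float]:
    """γ-weighted binary cross-entropy over all supervised cells.

    ``loss = −(1/(n·m)) [ γ Σ_{S⁺} log p + Σ_{S⁻} log(1−p) ]`` with
    γ = |S⁻|/|S⁺|. Probabilities are clipped away from {0,1} before the
    logs. Cells in the association's train_mask belong to neither set.
    """
    w_pos, w_neg, gamma = _supervision_weights(assoc, mask_test_pairs)
    p = np.clip(probs, PROB_CLIP, 1.0 - PROB_CLIP)
    m, n = assoc.shape
    loss = -(np.sum(w_pos * np.log(p)) + np.sum(w_neg * np.log1p(-p))) / (m * n)
    return float(loss), gamma


def ssl_alignment_loss(assoc_view_sims: Sequence[float], neighbor_view_sims: Sequence[float]) -> float:
    """Hinge alignment ``Σ max(0, 1 − s·ŝ)`` over sampled pairs."""
    s = np.asarray(assoc_view_sims, dtype=np.float64)
    shat = np.asarray(neighbor_view_sims, dtype=np.float64)
    if s.shape != shat.shape:
        raise ValueError("similarity lists must have equal length")
    return float(np.sum(np.maximum(0.0, 1.0 - s * shat)))


def contrastive_ssl_loss(
    anchors: np.ndarray, positives: np.ndarray, temperature: float = 0.2
) -> float:
    """InfoNCE over the two views of the same sampled entities.

    Each entity's association-view embedding is the anchor, its
    neighbor-view embedding the positive, the other sampled entities'
    neighbor-view embeddings the negatives; logits are cosine similarities
    over temperature. Returns the mean per-anchor loss.
    """
    anchors = np.asarray(anchors, dtype=np.float64)
    positives = np.asarray(positives, dtype=np.float64)
    if anchors.shape != positives.shape:
        raise ValueError("anchors and positives must share a shape")
    if anchors.shape[0] < 2:
        raise ValueError("contrastive loss needs at least 2 entities")
    a = anchors / (np.linalg.norm(anchors, axis=1, keepdims=True) + 1e-12)
    b = positives / (np.linalg.norm(positives, axis=1, keepdims=True) + 1e-12)
    logits = (a @ b.T) / temperature
    logits -= logits.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(logits).sum(axis=1))
    return float(np.mean(log_z - np.diag(logits)))


def total_loss(bce: float, ssl_d: float, ssl_g: float, alpha: float, gamma: float) -> LossBreakdown:
    """Combine components: total = bce + α (ssl_d + ssl_g)."""
    return LossBreakdown(bce, ssl_d, ssl_g, bce + alpha * (ssl_d + ssl_g), gamma)


# ---------------------------------------------------------------------------
# the model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class CrossViewModel:
    """Forward/backward machinery shared by training and prediction.

    Holds the precomputed pooling operators of the three views and the
    parameter dict {E_d, E_g, d_vec, T_mat, c_vec}. Gradients are analytic;
    :meth:`loss_and_grads` returns both so finite-difference checks can
    exercise exactly the path training uses.
    """

    def __init__(
        self,
        assoc: AssociationMatrix,
        disease_graph: NeighborGraph | None,
        gene_graph: NeighborGraph | None,
        enc: EncoderConfig,
        cfg: TrainConfig,
    ):
        self.assoc = assoc
        self.enc = enc
        self.cfg = cfg
        self.m, self.n = assoc.shape
        self.pool_bi = pooling_operator(normalize_bipartite(assoc), enc.num_layers, enc.layer_pooling)
        self.pool_d = (
            pooling_operator(normalize_homogeneous(disease_graph), enc.num_layers, enc.layer_pooling)
            if (enc.use_disease_view and disease_graph is not None)
            else None
        )
        self.pool_g = (
            pooling_operator(normalize_homogeneous(gene_graph), enc.num_layers, enc.layer_pooling)
            if (enc.use_gene_view and gene_graph is not None)
            else None
        )
        self.w_pos, self.w_neg, self.gamma = _supervision_weights(assoc, cfg.mask_test_pairs)

    def init_params(self, seed: int) -> dict[str, np.ndarray]:
        rng = substream(seed, "init")
        d = self.enc.embed_dim

        def xavier(rows: int, cols: int) -> np.ndarray:
            bound = np.sqrt(6.0 / (rows + cols))
            return rng.uniform(-bound, bound, size=(rows, cols))

        return {
            "E_d": xavier(self.m, d),
            "E_g": xavier(self.n, d),
            "T_mat": xavier(d, 2 * d),
            "d_vec": np.zeros(d),
            "c_vec": np.zeros(d),
        }

    def embed(self, params: dict[str, np.ndarray]) -> EmbeddingState:
        e0 = np.vstack([params["E_d"], params["E_g"]])
        pooled_bi = self.pool_bi @ e0
        ea_d, ea_g = pooled_bi[: self.m], pooled_bi[self.m :]
        en_d = self.pool_d @ params["E_d"] if self.pool_d is not None else np.zeros_like(ea_d)
        en_g = self.pool_g @ params["E_g"] if self.pool_g is not None else np.zeros_like(ea_g)
        return EmbeddingState(ea_d, ea_g, en_d, en_g, ea_d + en_d, ea_g + en_g)

    def probabilities(self, state: EmbeddingState) -> np.ndarray:
        return _sigmoid(state.fused_d @ state.fused_g.T)

    # -- loss + analytic gradients ------------------------------------------------

    def loss_and_grads(
        self,
        params: dict[str, np.ndarray],
        pairs_d: PairSample | None,
        pairs_g: PairSample | None,
    ) -> tuple[LossBreakdown, dict[str, np.ndarray], EmbeddingState]:
        cfg, d = self.cfg, self.enc.embed_dim
        state = self.embed(params)
        grads = {k: np.zeros_like(v) for k, v in params.items()}

        # main task: weighted BCE over all supervised cells
        z = state.fused_d @ state.fused_g.T
        p = _sigmoid(z)
        p_clip = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
        bce = -(np.sum(self.w_pos * np.log(p_clip)) + np.sum(self.w_neg * np.log1p(-p_clip))) / (self.m * self.n)
        g_z = -(self.w_pos * (1.0 - p) - self.w_neg * p) / (self.m * self.n)
        g_fused_d = g_z @ state.fused_g
        g_fused_g = g_z.T @ state.fused_d

        # fused = pooled_assoc + pooled_neighbor, so both receive g_fused
        g_ea_d, g_en_d = g_fused_d.copy(), g_fused_d.copy()
        g_ea_g, g_en_g = g_fused_g.copy(), g_fused_g.copy()

        ssl_d = ssl_g = 0.0
        if cfg.ssl_mode == "denoise":
            if cfg.use_ssl_d and pairs_d is not None:
                ssl_d = self._denoise_side(params, grads, state.pooled_assoc_d, state.pooled_d,
                                           g_ea_d, g_en_d, pairs_d, cfg.alpha)
            if cfg.use_ssl_g and pairs_g is not None:
                ssl_g = self._denoise_side(params, grads, state.pooled_assoc_g, state.pooled_g,
                                           g_ea_g, g_en_g, pairs_g, cfg.alpha)
        elif cfg.ssl_mode == "contrastive":
            if cfg.use_ssl_d and pairs_d is not None:
                ssl_d = self._contrastive_side(state.pooled_assoc_d, state.pooled_d,
                                               g_ea_d, g_en_d, pairs_d, cfg.alpha)
            if cfg.use_ssl_g and pairs_g is not None:
                ssl_g = self._contrastive_side(state.pooled_assoc_g, state.pooled_g,
                                               g_ea_g, g_en_g, pairs_g, cfg.alpha)

        # back through the (linear) pooling operators
        g_e0 = self.pool_bi.T @ np.vstack([g_ea_d, g_ea_g])
        grads["E_d"] += g_e0[: self.m]
        grads["E_g"] += g_e0[self.m :]
        if self.pool_d is not None:
            grads["E_d"] += self.pool_d.T @ g_en_d
        if self.pool_g is not None:
            grads["E_g"] += self.pool_g.T @ g_en_g

        breakdown = total_loss(float(bce), ssl_d, ssl_g, cfg.alpha, self.gamma)
        return breakdown, grads, state

    def _denoise_side(
        self,
        params: dict[str, np.ndarray],
        grads: dict[str, np.ndarray],
        ea: np.ndarray,
        en: np.ndarray,
        g_ea: np.ndarray,
        g_en: np.ndarray,
        pairs: PairSample,
        alpha: float,
    ) -> float:
        """Hinge alignment loss for one side; accumulates α-scaled gradients."""
        d = self.enc.embed_dim
        slope = self.cfg.negative_slope
        idx_a = np.array([a for a, _ in pairs.pair_indices])
        idx_b = np.array([b for _, b in pairs.pair_indices])
        x = np.hstack([ea[idx_a], ea[idx_b]])
        u = x @ params["T_mat"].T + ea[idx_a] + ea[idx_b] + params["c_vec"]
        h = np.where(u >= 0, u, slope * u)
        z = h @ params["d_vec"]
        s = _sigmoid(z)
        shat = np.sum(en[idx_a] * en[idx_b], axis=1)
        margin = 1.0 - s * shat
        loss = float(np.sum(np.maximum(0.0, margin)))

        active = margin > 0
        # d loss / ds and / dŝ on active pairs, α-scaled into the total
        g_s = np.where(active, -shat, 0.0) * alpha
        g_shat = np.where(active, -s, 0.0) * alpha
        g_z = g_s * s * (1.0 - s)
        grads["d_vec"] += h.T @ g_z
        g_u = (g_z[:, None] * params["d_vec"][None, :]) * np.where(u >= 0, 1.0, slope)
        grads["T_mat"] += g_u.T @ x
        grads["c_vec"] += g_u.sum(axis=0)
        ga = g_u @ params["T_mat"][:, :d] + g_u
        gb = g_u @ params["T_mat"][:, d:] + g_u
        np.add.at(g_ea, idx_a, ga)
        np.add.at(g_ea, idx_b, gb)
        np.add.at(g_en, idx_a, g_shat[:, None] * en[idx_b])
        np.add.at(g_en, idx_b, g_shat[:, None] * en[idx_a])
        return loss

    def _contrastive_side(
        self,
        ea: np.ndarray,
        en: np.ndarray,
        g_ea: np.ndarray,
        g_en: np.ndarray,
        pairs: PairSample,
        alpha: float,
    ) -> float:
        """InfoNCE between the two views of the sampled entities."""
        # reuse the pair sample's first indices as the entity batch
        idx = np.unique(np.array([a for a, _ in pairs.pair_indices]))
        if idx.size < 2:
            idx = np.arange(min(2, ea.shape[0]))
        tau = self.cfg.cl_temperature
        u, v = ea[idx], en[idx]
        nu = np.linalg.norm(u, axis=1, keepdims=True) + 1e-12
        nv = np.linalg.norm(v, axis=1, keepdims=True) + 1e-12
        a, b = u / nu, v / nv
        logits = (a @ b.T) / tau
        shift = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(shift)
        softmax = expl / expl.sum(axis=1, keepdims=True)
        loss = float(np.mean(np.log(expl.sum(axis=1)) - np.diag(shift)))

        c = idx.size
        g_logits = (softmax - np.eye(c)) / c * alpha
        g_a = (g_logits @ b) / tau
        g_b = (g_logits.T @ a) / tau
        # back through row normalization: grad_u = (g_a - (g_a·a) a) / |u|
        g_u = (g_a - (np.sum(g_a * a, axis=1, keepdims=True)) * a) / nu
        g_v = (g_b - (np.sum(g_b * b, axis=1, keepdims=True)) * b) / nv
        np.add.at(g_ea, idx, g_u)
        np.add.at(g_en, idx, g_v)
        return loss


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    assoc: AssociationMatrix,
    disease_graph: NeighborGraph | None,
    gene_graph: NeighborGraph | None,
    enc: EncoderConfig | None = None,
    cfg: TrainConfig | None = None,
    validation: tuple[Sequence[tuple[int, int]], Sequence[int]] | None = None,
    callback: Callable[[int, LossBreakdown], None] | None = None,
) -> TrainResult:
    """Fit the cross-view model with full-batch Adam.

    ``validation`` is an optional (pairs, labels) tuple; when given,
    training stops early once validation average precision has not improved
    for ``cfg.patience`` epochs and the best parameters are restored.
    Raises on a non-finite loss.
    """
    enc = enc or EncoderConfig()
    cfg = cfg or TrainConfig()
    model = CrossViewModel(assoc, disease_graph, gene_graph, enc, cfg)
    params = model.init_params(cfg.seed)
    opt = _Adam(params, cfg.learning_rate)
    history: list[LossBreakdown] = []

    best_ap, best_params, stale = -np.inf, None, 0
    if validation is not None:
        from sklearn.metrics import average_precision_score

        val_pairs, val_labels = validation
        vi = np.array([i for i, _ in val_pairs])
        vj = np.array([j for _, j in val_pairs])
        val_labels = np.asarray(val_labels)

    need_pairs = cfg.ssl_mode != "off" and (cfg.use_ssl_d or cfg.use_ssl_g)
    for epoch in range(cfg.epochs):
        pd = pg = None
        if need_pairs:
            if cfg.use_ssl_d and model.m >= 2:
                pd = sample_pairs(model.m, cfg.pair_count, cfg.seed, "disease", step=epoch)
            if cfg.use_ssl_g and model.n >= 2:
                pg = sample_pairs(model.n, cfg.pair_count, cfg.seed, "gene", step=epoch)
        breakdown, grads, state = model.loss_and_grads(params, pd, pg)
        if not np.isfinite(breakdown.total):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: bce={breakdown.bce} "
                f"ssl_d={breakdown.ssl_d} ssl_g={breakdown.ssl_g}"
            )
        opt.step(params, grads)
        history.append(breakdown)
        if callback is not None:
            callback(epoch, breakdown)

        if validation is not None:
            probs = model.probabilities(model.embed(params))
            ap = average_precision_score(val_labels, probs[vi, vj])
            if ap > best_ap:
                best_ap, stale = ap, 0
                best_params = {k: v.copy() for k, v in params.items()}
            else:
                stale += 1
                if stale >= cfg.patience:
                    break

    if best_params is not None:
        params = best_params
    state = model.embed(params)
    head = ProjectionHead(params["d_vec"], params["T_mat"], params["c_vec"], cfg.negative_slope)
    return TrainResult(state, head, history, params, model.probabilities(state))
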
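"""Finite-difference gradient checking against the analytic backward pass."""

import numpy as np

from dgsl.alignment import sample_pairs
from dgsl.encoder import EncoderConfig
from dgsl.graphs import AssociationMatrix, NeighborGraph
from dgsl.training import CrossViewModel, TrainConfig


def toy_model(ssl_mode="denoise", alpha=0.5, seed=0, m=3, n=3, embed_dim=3):
    """Small dense problem exercising every term of the objective."""
    rng = np.random.default_rng(seed)
    vals = np.zeros((m, n))
    vals[rng.random((m, n)) < 0.5] = 1.0
    vals[0, 0] = 1.0
    vals[m - 1, n - 1] = 0.0
    assoc = AssociationMatrix(vals, [f"d{i}" for i in range(m)], [f"g{j}" for j in range(n)])

    def ring(size):
        adj = np.zeros((size, size))
        for i in range(size):
            adj[i, (i + 1) % size] = adj[(i + 1) % size, i] = 1.0
        return NeighborGraph(adj, 1)

    enc = EncoderConfig(embed_dim=embed_dim, num_layers=2)
    cfg = TrainConfig(seed=seed, alpha=alpha, ssl_mode=ssl_mode, pair_count=6)
    model = CrossViewModel(assoc, ring(m), ring(n), enc, cfg)
    params = model.init_params(seed)
    # move the head off its zero initialization so its gradients are non-trivial
    params["d_vec"] = rng.normal(size=embed_dim) * 0.5
    params["c_vec"] = rng.normal(size=embed_dim) * 0.5
    pairs_d = sample_pairs(m, cfg.pair_count, cfg.seed, "disease", step=0)
    pairs_g = sample_pairs(n, cfg.pair_count, cfg.seed, "gene", step=0)
    return model, params, pairs_d, pairs_g


def relative_gradient_errors(model, params, pairs_d, pairs_g, eps=1e-6):
    """Max relative elementwise error between analytic and central-difference
    gradients, per parameter."""
    _, grads, _ = model.loss_and_grads(params, pairs_d, pairs_g)
    errors = {}
    for name, value in params.items():
        numeric = np.zeros_like(value)
        flat = value.ravel()
        num_flat = numeric.ravel()
        for idx in range(flat.size):
            orig = flat[idx]
            flat[idx] = orig + eps
            up, _, _ = model.loss_and_grads(params, pairs_d, pairs_g)
            flat[idx] = orig - eps
            down, _, _ = model.loss_and_grads(params, pairs_d, pairs_g)
            flat[idx] = orig
            num_flat[idx] = (up.total - down.total) / (2 * eps)
        scale = np.maximum(np.abs(numeric), np.abs(grads[name]))
        denom = np.where(scale > 1e-8, scale, 1.0)
        errors[name] = float(np.max(np.abs(numeric - grads[name]) / denom))
    return errors
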
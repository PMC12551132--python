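"""Cross-view semantic alignment for denoising.

For a randomly sampled same-type pair (two diseases or two genes) the model
computes two similarities: a *learnable, bounded* one in the association
view,

    s = sigmoid( d · LeakyReLU( T [e_a; e_b] + e_a + e_b + c ) ),

and a plain dot product ŝ between the pair's neighbor-view embeddings.
The hinge penalty ``max(0, 1 − s·ŝ)`` (see :mod:`dgsl.training`) pushes the
two views to agree on pair semantics while keeping the influence of any
single noisy neighborhood edge bounded — the denoising property.

Because ``s`` is bounded in (0,1) and ``ŝ`` is not, alignment pressure
flows asymmetrically: neighbor-view similarity must grow to meet the
margin, but a pair the association view deems dissimilar (s small) can
never be forced there by a spurious neighbor edge alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._rng import substream

__all__ = [
    "ProjectionHead",
    "PairSample",
    "projected_similarity",
    "neighborhood_similarity",
    "sample_pairs",
]


@dataclass
class ProjectionHead:
    """Learnable similarity projection d, T, c with a leaky-rectifier.

    ``T_mat`` mixes the concatenated pair embedding (d x 2d), ``c_vec`` is a
    bias, ``d_vec`` projects the activated hidden vector to a scalar that a
    logistic squashes into (0,1). ``negative_slope`` is the leaky-rectifier
    slope (conventional 0.01).
    """

    d_vec: np.ndarray
    T_mat: np.ndarray
    c_vec: np.ndarray
    negative_slope: float = 0.01

    def __post_init__(self) -> None:
        dim = self.d_vec.shape[0]
        if self.T_mat.shape != (dim, 2 * dim) or self.c_vec.shape != (dim,):
            raise ValueError("projection head parameter shapes are inconsistent")

    @classmethod
    def init(cls, embed_dim: int, rng: np.random.Generator, negative_slope: float = 0.01) -> "ProjectionHead":
        """Xavier-uniform T; zero d and c so the head starts uninformative (s=0.5)."""
        bound = np.sqrt(6.0 / (embed_dim + 2 * embed_dim))
        t = rng.uniform(-bound, bound, size=(embed_dim, 2 * embed_dim))
        return cls(np.zeros(embed_dim), t, np.zeros(embed_dim), negative_slope)


@dataclass
class PairSample:
    """Same-type index pairs drawn for one alignment step."""

    pair_indices: list[tuple[int, int]]
    side: Literal["disease", "gene"]

    def __post_init__(self) -> None:
        for a, b in self.pair_indices:
            if a == b:
                raise ValueError("self-pairs are not allowed")

    @property
    def count(self) -> int:
        return len(self.pair_indices)


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def projected_similarity(head: ProjectionHead, e_a: np.ndarray, e_b: np.ndarray) -> float:
    """Learnable association-view similarity, strictly in (0,1).

    Not symmetric in (e_a, e_b) in general: T acts on the *concatenation*
    [e_a; e_b], whose halves are weighted differently.
    """
    e_a = np.asarray(e_a, dtype=np.float64)
    e_b = np.asarray(e_b, dtype=np.float64)
    dim = head.d_vec.shape[0]
    if e_a.shape != (dim,) or e_b.shape != (dim,):
        raise ValueError("embedding dimension does not match projection head")
    hidden = _leaky(head.T_mat @ np.concatenate([e_a, e_b]) + e_a + e_b + head.c_vec, head.negative_slope)
    z = float(head.d_vec @ hidden)
    if z >= 0:
        s = 1.0 / (1.0 + np.exp(-z))
    else:
        ez = np.exp(z)
        s = ez / (1.0 + ez)
    # the logistic is strictly inside (0,1); keep the float result there too
    return float(np.clip(s, 1e-12, 1.0 - 1e-12))


def neighborhood_similarity(e_a: np.ndarray, e_b: np.ndarray) -> float:
    """Plain (unbounded) dot product between neighbor-view embeddings."""
    return float(np.asarray(e_a) @ np.asarray(e_b))


def sample_pairs(
    num_entities: int,
    count: int,
    rng_seed: int,
    side: Literal["disease", "gene"] = "disease",
    step: int = 0,
) -> PairSample:
    """Draw ``count`` ordered pairs uniformly, excluding self-pairs.

    A step-indexed seeded stream gives fresh pairs every optimization step
    while keeping runs reproducible.
    """
    if num_entities < 2:
        raise ValueError("need at least 2 entities to sample pairs")
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = substream(rng_seed, f"pairs-{side}", step)
    first = rng.integers(0, num_entities, size=count)
    # second index drawn over the remaining n-1 slots, shifted past the first
    second = rng.integers(0, num_entities - 1, size=count)
    second = np.where(second >= first, second + 1, second)
    return PairSample(list(zip(first.tolist(), second.tolist())), side)
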
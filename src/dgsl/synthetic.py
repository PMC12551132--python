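"""Seeded generator of bipartite association data with planted clusters.

Emulates the statistical structure the method assumes in curated
disease-gene data: associations concentrate inside latent disease/gene
modules, and annotation overlap (symptoms, GO terms) is predictive of
module co-membership. Each disease and gene is assigned one of
``n_clusters`` latent clusters; an association (i, j) appears with
probability ``p_in`` when clusters match, ``p_out`` otherwise. Every
cluster owns ``terms_per_cluster`` signature annotation terms; an entity
keeps each signature term of its cluster with probability
``term_keep_prob`` and additionally receives ``background_terms_per_entity``
uniformly random background terms (the annotation-noise dial: lower keep
probability and more background terms weaken the similarity signal).

Defaults are sized so one cross-validation fold trains in seconds on a
single CPU while still exhibiting the cluster signal the encoder is meant
to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._rng import substream
from .graphs import AnnotationSets, AssociationMatrix, write_annotation_tsv, write_association_tsv

__all__ = ["SyntheticConfig", "SyntheticData", "generate"]


@dataclass
class SyntheticConfig:
    m: int = 200
    n: int = 300
    n_clusters: int = 5
    p_in: float = 0.15
    p_out: float = 0.01
    terms_per_cluster: int = 20
    term_keep_prob: float = 0.8
    background_terms_per_entity: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_clusters > min(self.m, self.n):
            raise ValueError("n_clusters must not exceed min(m, n)")
        if not 0 <= self.term_keep_prob <= 1:
            raise ValueError("term_keep_prob must be in [0, 1]")


@dataclass
class SyntheticData:
    assoc: AssociationMatrix
    disease_annotations: AnnotationSets
    gene_annotations: AnnotationSets
    disease_clusters: np.ndarray
    gene_clusters: np.ndarray

    def write(self, out_dir: str | Path) -> None:
        """Emit the TSV dialects graph construction reads, plus cluster labels."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_association_tsv(self.assoc, out / "associations.tsv")
        write_annotation_tsv(self.disease_annotations, out / "disease_annotations.tsv")
        write_annotation_tsv(self.gene_annotations, out / "gene_annotations.tsv")
        with open(out / "clusters.tsv", "w") as fh:
            for ent, c in zip(self.assoc.row_ids, self.disease_clusters):
                fh.write(f"{ent}\t{c}\n")
            for ent, c in zip(self.assoc.col_ids, self.gene_clusters):
                fh.write(f"{ent}\t{c}\n")


def _annotations(
    prefix: str,
    clusters: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    term_pool: list[str],
) -> AnnotationSets:
    ids = [f"{prefix}{i:04d}" for i in range(len(clusters))]
    sets: list[set[str]] = []
    for c in clusters:
        signature = [f"t{c}_{t}" for t in range(cfg.terms_per_cluster)]
        keep = rng.random(cfg.terms_per_cluster) < cfg.term_keep_prob
        terms = {s for s, k in zip(signature, keep) if k}
        if cfg.background_terms_per_entity:
            bg = rng.choice(len(term_pool), size=cfg.background_terms_per_entity, replace=False)
            terms |= {term_pool[int(b)] for b in bg}
        sets.append(terms)
    return AnnotationSets(ids, sets)


def generate(cfg: SyntheticConfig) -> SyntheticData:
    """Draw one dataset; fully determined by ``cfg`` including its seed."""
    rng = substream(cfg.seed, "synthetic")
    d_clusters = rng.integers(0, cfg.n_clusters, size=cfg.m)
    g_clusters = rng.integers(0, cfg.n_clusters, size=cfg.n)

    same = d_clusters[:, None] == g_clusters[None, :]
    prob = np.where(same, cfg.p_in, cfg.p_out)
    values = (rng.random((cfg.m, cfg.n)) < prob).astype(np.float64)

    expected = cfg.p_in * same.sum() + cfg.p_out * (~same).sum()
    if expected < 100:
        import warnings

        warnings.warn(
            f"expected positive count {expected:.0f} is small; "
            "10-fold cross-validation folds may be degenerate",
            stacklevel=2,
        )

    # shared pool of off-signature terms for background noise
    pool = [f"bg_{t}" for t in range(cfg.n_clusters * cfg.terms_per_cluster)]
    d_ann = _annotations("D", d_clusters, cfg, rng, pool)
    g_ann = _annotations("G", g_clusters, cfg, rng, pool)

    assoc = AssociationMatrix(values, d_ann.entity_ids, g_ann.entity_ids)
    return SyntheticData(assoc, d_ann, g_ann, d_clusters, g_clusters)
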
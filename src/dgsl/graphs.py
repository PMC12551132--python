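"""Similarity-guided graph construction.

Builds the three graphs the encoder propagates on:

* the bipartite disease-gene association view, symmetrically normalized as
  ``D^{-1/2} [[0, A], [A^T, 0]] D^{-1/2}``;
* two homogeneous neighbor views (disease-disease, gene-gene) obtained by
  computing Dice-coefficient similarity between annotation sets (symptom
  sets for diseases, GO term sets for genes), keeping each node's top-k
  most similar other nodes, and normalizing the symmetrized result the
  same way.

Entities with empty annotation sets gain no neighbors, and zero-degree
rows/columns of any view normalize to zero: isolated nodes simply keep
their initial embeddings under propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "AnnotationSets",
    "AssociationMatrix",
    "NeighborGraph",
    "NormalizedAdjacency",
    "dice_similarity",
    "build_similarity_matrix",
    "topk_neighbor_graph",
    "normalize_bipartite",
    "normalize_homogeneous",
    "read_association_tsv",
    "write_association_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "write_similarity_tsv",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class AnnotationSets:
    """Per-entity term sets (symptoms for diseases, GO terms for genes)."""

    entity_ids: list[str]
    terms: list[set[str]]

    def __post_init__(self) -> None:
        if len(self.entity_ids) != len(self.terms):
            raise ValueError("entity_ids and terms must have equal length")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity id in AnnotationSets")

    def __len__(self) -> int:
        return len(self.entity_ids)


@dataclass
class AssociationMatrix:
    """Binary m x n disease-gene incidence with optional supervision mask.

    ``train_mask`` holds (i, j) cells excluded from supervision (e.g. test-fold
    positives during cross-validation); masked cells are zero in ``values`` so
    they contribute nothing to the propagation graph either.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    train_mask: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("association matrix shape does not match id lists")
        uniq = set(self.values.ravel().tolist())
        if not uniq <= {0.0, 1.0}:
            raise ValueError("association matrix entries must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def positives(self) -> list[tuple[int, int]]:
        """Index pairs of the 1-entries, row-major order."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))

    def masked(self, mask: Iterable[tuple[int, int]]) -> "AssociationMatrix":
        """Copy with the given cells zeroed and excluded from supervision."""
        mask = set((int(i), int(j)) for i, j in mask)
        vals = self.values.copy()
        for i, j in mask:
            vals[i, j] = 0.0
        return AssociationMatrix(vals, list(self.row_ids), list(self.col_ids), self.train_mask | mask)


@dataclass
class NeighborGraph:
    """Binary homogeneous adjacency from top-k similarity sparsification."""

    adjacency: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("neighbor graph adjacency must be square")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("neighbor graph must have zero diagonal")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class NormalizedAdjacency:
    """Symmetrically normalized adjacency, bipartite or homogeneous."""

    values: np.ndarray
    kind: Literal["bipartite", "homogeneous"]


# ---------------------------------------------------------------------------
# similarity


def dice_similarity(set_a: set, set_b: set) -> float:
    """Dice coefficient 2|a∩b| / (|a|+|b|); 0 when both sets are empty.

    Two entities with no recorded annotations carry no evidence of
    relatedness, so the 0/0 case is defined as 0 rather than 1.
    """
    denom = len(set_a) + len(set_b)
    if denom == 0:
        return 0.0
    return 2.0 * len(set_a & set_b) / denom


def build_similarity_matrix(annotations: AnnotationSets) -> np.ndarray:
    """All-pairs Dice similarity over an annotation collection.

    Vectorized through a binary entity x term incidence matrix:
    ``|a∩b|`` is its Gram matrix. Diagonal is 1 for entities with at least
    one term and 0 for empty-set entities (they gain no neighbors).
    """
    n = len(annotations)
    if n == 0:
        raise ValueError("annotation collection is empty")
    vocab: dict[str, int] = {}
    for terms in annotations.terms:
        for t in terms:
            vocab.setdefault(t, len(vocab))
    sizes = np.array([len(t) for t in annotations.terms], dtype=np.float64)
    if not vocab:
        return np.zeros((n, n))
    inc = np.zeros((n, len(vocab)))
    for i, terms in enumerate(annotations.terms):
        for t in terms:
            inc[i, vocab[t]] = 1.0
    inter = inc @ inc.T
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, 2.0 * inter / np.where(denom > 0, denom, 1.0), 0.0)
    return sim


def topk_neighbor_graph(
    sim: np.ndarray,
    k: int,
    symmetrize: Literal["or", "mutual"] = "or",
) -> NeighborGraph:
    """Keep each node's k most similar other nodes, then symmetrize.

    The node itself is never selected. Ties are broken by ascending entity
    index so the graph is deterministic under a fixed input ordering.
    Similarity 0 still counts toward the top-k rank (a row of all-zero
    similarities from an unannotated entity contributes no edge only if
    every candidate ties at 0 — such rows are dropped explicitly).
    """
    sim = np.asarray(sim, dtype=np.float64)
    n = sim.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of entities ({n})")
    keep = np.zeros((n, n))
    for i in range(n):
        row = sim[i].copy()
        row[i] = -np.inf
        # stable: among equal similarities the lower index wins
        order = np.argsort(-row, kind="stable")
        chosen = order[:k]
        chosen = chosen[row[chosen] > 0.0]
        keep[i, chosen] = 1.0
    if symmetrize == "or":
        adj = np.maximum(keep, keep.T)
    elif symmetrize == "mutual":
        adj = keep * keep.T
    else:
        raise ValueError(f"unknown symmetrization {symmetrize!r}")
    np.fill_diagonal(adj, 0.0)
    return NeighborGraph(adj, k)


# ---------------------------------------------------------------------------
# normalization


def _sym_normalize(adj: np.ndarray) -> np.ndarray:
    deg = adj.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return inv_sqrt[:, None] * adj * inv_sqrt[None, :]


def normalize_bipartite(assoc: AssociationMatrix) -> NormalizedAdjacency:
    """Normalized bidirectional adjacency of the association view.

    Stacks ``Ā = [[0, A], [A^T, 0]]`` with diseases at indices [0, m) and
    genes at [m, m+n), then returns ``D^{-1/2} Ā D^{-1/2}``. Zero-degree
    rows/columns normalize to zero.
    """
    a = assoc.values
    m, n = a.shape
    big = np.zeros((m + n, m + n))
    big[:m, m:] = a
    big[m:, :m] = a.T
    return NormalizedAdjacency(_sym_normalize(big), "bipartite")


def normalize_homogeneous(graph: NeighborGraph) -> NormalizedAdjacency:
    """``D^{-1/2} A D^{-1/2}`` for a symmetric zero-diagonal neighbor graph."""
    adj = graph.adjacency
    if not np.array_equal(adj, adj.T):
        raise ValueError("neighbor graph must be symmetric; symmetrize first")
    return NormalizedAdjacency(_sym_normalize(adj), "homogeneous")


# ---------------------------------------------------------------------------
# TSV interchange


def read_association_tsv(path: str | Path, header: bool = False) -> AssociationMatrix:
    """Read `disease_id<TAB>gene_id` rows into a binary incidence matrix.

    The entity vocabularies are the ids seen in the file, in first-seen order.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}")
            pairs.append((fields[0], fields[1]))
    row_ids: dict[str, int] = {}
    col_ids: dict[str, int] = {}
    for d, g in pairs:
        row_ids.setdefault(d, len(row_ids))
        col_ids.setdefault(g, len(col_ids))
    values = np.zeros((len(row_ids), len(col_ids)))
    for d, g in pairs:
        values[row_ids[d], col_ids[g]] = 1.0
    return AssociationMatrix(values, list(row_ids), list(col_ids))


def write_association_tsv(assoc: AssociationMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, j in assoc.positives():
            fh.write(f"{assoc.row_ids[i]}\t{assoc.col_ids[j]}\n")


def read_annotation_tsv(
    path: str | Path,
    entity_ids: Sequence[str] | None = None,
    header: bool = False,
) -> AnnotationSets:
    """Read `entity_id<TAB>term_id` rows.

    When ``entity_ids`` is given (the closed vocabulary from an association
    file) the output follows that order and unseen entities get empty sets;
    ids in the file but not in the vocabulary raise.
    """
    seen: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}")
            ent, term = fields
            if ent not in seen:
                seen[ent] = set()
                order.append(ent)
            seen[ent].add(term)
    if entity_ids is None:
        return AnnotationSets(order, [seen[e] for e in order])
    extra = set(order) - set(entity_ids)
    if extra:
        raise ValueError(f"{path}: annotation entities not in vocabulary: {sorted(extra)[:5]}")
    return AnnotationSets(list(entity_ids), [seen.get(e, set()) for e in entity_ids])


def load_dataset(
    association_path: str | Path,
    disease_annotation_path: str | Path,
    gene_annotation_path: str | Path,
    strict: bool = False,
) -> tuple[AssociationMatrix, AnnotationSets, AnnotationSets]:
    """Read the three TSV files with a shared entity vocabulary.

    The disease (gene) vocabulary is the union of ids in the association
    file and the corresponding annotation file, association-file order
    first; entities seen only in annotations get all-zero association rows
    or columns. ``strict`` instead requires the annotation files to
    introduce no new entities.
    """
    assoc = read_association_tsv(association_path)
    d_raw = read_annotation_tsv(disease_annotation_path)
    g_raw = read_annotation_tsv(gene_annotation_path)

    def union(base: list[str], extra: list[str], what: str, path) -> list[str]:
        known = set(base)
        new = [e for e in extra if e not in known]
        if new and strict:
            raise ValueError(f"{path}: {what} entities absent from the association file: {new[:5]}")
        return base + new

    row_ids = union(list(assoc.row_ids), d_raw.entity_ids, "disease", disease_annotation_path)
    col_ids = union(list(assoc.col_ids), g_raw.entity_ids, "gene", gene_annotation_path)
    values = np.zeros((len(row_ids), len(col_ids)))
    values[: assoc.values.shape[0], : assoc.values.shape[1]] = assoc.values
    full = AssociationMatrix(values, row_ids, col_ids)
    d_terms = dict(zip(d_raw.entity_ids, d_raw.terms))
    g_terms = dict(zip(g_raw.entity_ids, g_raw.terms))
    d_ann = AnnotationSets(row_ids, [d_terms.get(e, set()) for e in row_ids])
    g_ann = AnnotationSets(col_ids, [g_terms.get(e, set()) for e in col_ids])
    return full, d_ann, g_ann


def write_annotation_tsv(annotations: AnnotationSets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ent, terms in zip(annotations.entity_ids, annotations.terms):
            for term in sorted(terms):
                fh.write(f"{ent}\t{term}\n")


def write_similarity_tsv(sim: np.ndarray, entity_ids: Sequence[str], path: str | Path) -> None:
    """Dense similarity export with entity ids as header row and column."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(entity_ids) + "\n")
        for ent, row in zip(entity_ids, sim):
            fh.write(ent + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
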
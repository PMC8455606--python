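"""Low-dimensional term embeddings from graph diffusion.

Random walk with restart (RWR) on the weighted undirected ontology graph
yields, per term, an equilibrium visiting distribution over all terms:

    S = alpha * (I - (1 - alpha) * P)^{-1}

with P the row-normalized weighted adjacency and alpha the restart
probability.  Rows of S are probability distributions; cosine similarity
between rows is the ontology-based term similarity.  The seen-term block
of S, symmetrized, is factored by SVD into the term embedding E used as
label-side features by the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .ontology import OntologyGraph

__all__ = ["DiffusionMatrix", "TermEmbedding", "rwr", "ontology_similarity", "svd_embed"]

# dense closed-form solve below this node count; iterative propagation above
_DENSE_LIMIT = 2000
_ITER_TOL = 1e-8
_MAX_ITERS = 1000


@dataclass
class DiffusionMatrix:
    """Term x term RWR equilibrium scores; rows sum to 1."""

    matrix: np.ndarray
    restart_prob: float
    term_ids: list[str]

    def restrict(self, ids: Sequence[str]) -> np.ndarray:
        """Sub-matrix over ``ids`` (rows and columns), in the given order."""
        index = {t: i for i, t in enumerate(self.term_ids)}
        idx = np.asarray([index[t] for t in ids])
        return self.matrix[np.ix_(idx, idx)]

    def rows_for(self, ids: Sequence[str]) -> np.ndarray:
        """Rows for ``ids``, all columns, in term order."""
        index = {t: i for i, t in enumerate(self.term_ids)}
        idx = np.asarray([index[t] for t in ids])
        return self.matrix[idx, :]


@dataclass
class TermEmbedding:
    """Rank-q spectral embedding of the seen-term diffusion block."""

    matrix: np.ndarray  # (n_seen, q)
    seen_term_ids: list[str]

    @property
    def q(self) -> int:
        return self.matrix.shape[1]


def _transition_matrix(graph: OntologyGraph) -> sp.csr_array:
    adj = graph.adjacency().astype(float)
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    isolated = degrees == 0
    # isolated nodes self-transition so the walk stays a Markov chain
    if isolated.any():
        adj = adj.tolil()
        for i in np.flatnonzero(isolated):
            adj[i, i] = 1.0
        adj = adj.tocsr()
        degrees = np.asarray(adj.sum(axis=1)).ravel()
    inv_deg = sp.diags_array(1.0 / degrees)
    return (inv_deg @ adj).tocsr()


def rwr(graph: OntologyGraph, restart_prob: float) -> DiffusionMatrix:
    """Random walk with restart equilibrium distributions for every term.

    restart_prob (alpha) in (0, 1] controls locality: alpha = 1 keeps all
    mass on the seed; small alpha lets mass spread across the graph.
    """
    if not (0.0 < restart_prob <= 1.0):
        raise ValueError(f"restart probability must be in (0, 1], got {restart_prob}")
    if graph.n_terms == 0:
        raise ValueError("empty graph")
    n = graph.n_terms
    alpha = float(restart_prob)
    P = _transition_matrix(graph)

    if n <= _DENSE_LIMIT:
        A = np.eye(n) - (1.0 - alpha) * P.toarray()
        S = alpha * np.linalg.inv(A)
    else:
        S = _iterative_rwr(P, alpha)
    return DiffusionMatrix(matrix=S, restart_prob=alpha, term_ids=list(graph.term_ids))


def _iterative_rwr(P: sp.csr_array, alpha: float) -> np.ndarray:
    """Power iteration X <- alpha*I + (1-alpha) X P, all seeds at once."""
    n = P.shape[0]
    X = np.eye(n)
    restart = alpha * np.eye(n)
    for _ in range(_MAX_ITERS):
        X_new = restart + (1.0 - alpha) * (X @ P)
        if np.max(np.abs(X_new - X)) < _ITER_TOL:
            return X_new
        X = X_new
    warnings.warn("RWR iteration did not reach tolerance; returning last iterate")
    return X


def ontology_similarity(diffusion: DiffusionMatrix) -> np.ndarray:
    """Ontology-based term similarity: cosine between RWR equilibrium rows."""
    S = diffusion.matrix
    norms = np.linalg.norm(S, axis=1)
    if np.any(norms == 0):
        raise ValueError("diffusion matrix has a zero row")
    C = (S / norms[:, None]) @ (S / norms[:, None]).T
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C


def svd_embed(diffusion: DiffusionMatrix, seen_ids: Sequence[str], q: int) -> TermEmbedding:
    """Embed seen terms: symmetrize the seen block of S and take a rank-q SVD.

    Only seen terms are embedded — restricting rows and columns of the
    diffusion matrix to terms with annotated training cells keeps the
    representation compact; unseen terms receive probability mass later
    through score propagation, not through E.  Returns E = U_q sqrt(Sigma_q).
    """
    seen_ids = list(seen_ids)
    if not seen_ids:
        raise ValueError("no seen terms to embed")
    missing = set(seen_ids) - set(diffusion.term_ids)
    if missing:
        raise ValueError(f"seen ids not in diffusion matrix: {sorted(missing)}")
    if q < 1:
        raise ValueError(f"embedding dimension must be >= 1, got {q}")
    if q > len(seen_ids):
        warnings.warn(
            f"requested q={q} exceeds number of seen terms ({len(seen_ids)}); clipping"
        )
        q = len(seen_ids)

    block = diffusion.restrict(seen_ids)
    sym = (block + block.T) / 2.0
    U, sigma, _ = np.linalg.svd(sym, hermitian=False)
    E = U[:, :q] * np.sqrt(sigma[:q])
    return TermEmbedding(matrix=E, seen_term_ids=seen_ids)


def default_q(n_seen: int, cap: int = 500) -> int:
    """Default embedding dimension: min(cap, n_seen - 1), at least 1."""
    return max(1, min(cap, n_seen - 1))
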
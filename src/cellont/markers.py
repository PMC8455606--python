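"""Marker-gene identification from predicted term probabilities.

Because the predicted probability of a term is defined for every cell —
and, after graph propagation, for every term including ones never seen in
training — a marker gene can be called for any term as a gene whose
expression tracks that term's probability across cells.  Spearman rank
correlation is used so that all cells contribute and the statistic is
insensitive to monotone transforms of expression; genes with correlation
at or above a threshold (default 0.4) are markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

__all__ = [
    "MarkerTable",
    "identify_markers",
    "classify_by_markers",
    "evaluate_marker_recovery",
    "spearman_matrix",
]

DEFAULT_THRESHOLD = 0.4


@dataclass
class MarkerTable:
    """Per-term marker calls plus the full term x gene correlation matrix."""

    markers: dict[str, list[tuple[str, float]]]  # term -> [(gene, rho)] desc
    threshold: float
    term_ids: list[str]
    gene_ids: list[str]
    rho: np.ndarray | None = None  # (n_terms, n_genes)

    def genes_for(self, term_id: str) -> list[str]:
        return [g for g, _ in self.markers.get(term_id, [])]

    def to_tsv(self, term_names: Mapping[str, str] | None = None) -> str:
        rows = ["term_id\tterm_name\tgene\trho"]
        for term in self.term_ids:
            name = (term_names or {}).get(term, term)
            for gene, rho in self.markers.get(term, []):
                rows.append(f"{term}\t{name}\t{gene}\t{rho:.6g}")
        return "\n".join(rows) + "\n"


def _rank_standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-tie ranks, centered and scaled; flags constant columns."""
    ranks = np.apply_along_axis(rankdata, 0, values)
    ranks -= ranks.mean(axis=0, keepdims=True)
    scale = np.sqrt((ranks**2).sum(axis=0))
    constant = scale == 0
    scale[constant] = 1.0
    return ranks / scale, constant


def spearman_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Spearman rho between every column of A and every column of B.

    Average ranks for ties; a constant column correlates 0 with everything
    (conservative: never called a marker) rather than being undefined.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("column vectors must share length")
    if A.shape[0] < 2:
        raise ValueError("correlation undefined for fewer than 2 observations")
    Ra, const_a = _rank_standardize(A)
    Rb, const_b = _rank_standardize(B)
    rho = Ra.T @ Rb
    rho[const_a, :] = 0.0
    rho[:, const_b] = 0.0
    return np.clip(rho, -1.0, 1.0)


def identify_markers(
    P: np.ndarray,
    M: np.ndarray,
    term_ids: Sequence[str],
    gene_ids: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
    keep_rho: bool = True,
) -> MarkerTable:
    """Call marker genes for every term from probability/expression rank agreement.

    Parameters
    ----------
    P
        cells x terms predicted probabilities (typically the propagated
        ensemble output, so unseen terms are covered too).
    M
        cells x genes expression, same cell order as ``P``.
    threshold
        Signed Spearman cutoff; only positive correlations qualify.
    """
    P = np.asarray(P, dtype=float)
    M = np.asarray(M, dtype=float)
    if P.shape[0] != M.shape[0]:
        raise ValueError("probability and expression matrices disagree on cells")
    rho = spearman_matrix(P, M)  # (terms, genes)
    gene_arr = np.asarray(list(gene_ids))
    markers: dict[str, list[tuple[str, float]]] = {}
    for ti, term in enumerate(term_ids):
        hits = np.flatnonzero(rho[ti] >= threshold)
        order = hits[np.argsort(-rho[ti][hits], kind="stable")]
        markers[term] = [(str(gene_arr[j]), float(rho[ti, j])) for j in order]
    return MarkerTable(
        markers=markers,
        threshold=threshold,
        term_ids=list(term_ids),
        gene_ids=list(gene_ids),
        rho=rho if keep_rho else None,
    )


def classify_by_markers(
    M: np.ndarray,
    gene_ids: Sequence[str],
    table: MarkerTable,
) -> np.ndarray:
    """Score cells against terms by mean expression of each term's markers.

    Rows are rank scores, not probabilities.  Terms without usable markers
    score 0 for every cell (with a warning); marker genes absent from the
    input are dropped with a warning.
    """
    M = np.asarray(M, dtype=float)
    index = {g: i for i, g in enumerate(gene_ids)}
    scores = np.zeros((M.shape[0], len(table.term_ids)))
    for ti, term in enumerate(table.term_ids):
        genes = table.genes_for(term)
        cols = [index[g] for g in genes if g in index]
        dropped = len(genes) - len(cols)
        if dropped:
            warnings.warn(f"term {term}: {dropped} marker genes absent from input, dropped")
        if not cols:
            warnings.warn(f"term {term}: no usable marker genes; scoring 0")
            continue
        scores[:, ti] = M[:, cols].mean(axis=1)
    return scores


def evaluate_marker_recovery(
    predicted_rho: np.ndarray,
    curated: np.ndarray,
    term_ids: Sequence[str],
) -> dict[str, float]:
    """Per-term AUROC of the correlation ranking against curated marker sets.

    ``curated`` is a terms x genes binary matrix (1 = known marker).
    Terms whose truth vector is degenerate (all 0 or all 1) are skipped.
    """
    predicted_rho = np.asarray(predicted_rho, dtype=float)
    curated = np.asarray(curated)
    if predicted_rho.shape != curated.shape:
        raise ValueError("score and truth matrices must share shape")
    out: dict[str, float] = {}
    for ti, term in enumerate(term_ids):
        truth = curated[ti].astype(int)
        if truth.min() == truth.max():
            warnings.warn(f"term {term}: degenerate curated vector, skipped")
            continue
        out[term] = float(roc_auc_score(truth, predicted_rho[ti]))
    return out
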
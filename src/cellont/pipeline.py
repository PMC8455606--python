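"""End-to-end annotation pipeline.

Sequences the three stages — map user labels to ontology terms, embed the
ontology graph, train the expression classifier and propagate its scores —
behind one object.  The default ensemble trains one model per combination
of edge-augmentation cutoff d_c in {2, 3, 4} and restart probability
alpha in {0.5, 0.6, 0.7, 0.8} (12 members) and averages the propagated
score matrices.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import model as _model
from .embedding import DiffusionMatrix, default_q, rwr, svd_embed
from .expression import AnnotatedMatrix
from .ontology import OntologyGraph
from .text import HashedNgramEncoder, TextEmbeddingTable, embed_texts

__all__ = ["AnnotatorConfig", "OntologyAnnotator"]

DEFAULT_DCS = (2, 3, 4)
DEFAULT_ALPHAS = (0.5, 0.6, 0.7, 0.8)


@dataclass
class AnnotatorConfig:
    """Hyperparameters of the full pipeline (defaults follow the method)."""

    dcs: tuple[int, ...] = DEFAULT_DCS
    restart_probs: tuple[float, ...] = DEFAULT_ALPHAS
    sim_threshold: float = 0.8
    q: int | None = None  # None -> min(500, n_seen - 1)
    h: int = _model.DEFAULT_HIDDEN
    epochs: int = _model.DEFAULT_EPOCHS
    learning_rate: float = _model.DEFAULT_LR
    seed: int = 0
    use_text_weights: bool = True
    propagate: bool = True  # False = no-propagation ablation
    exclude_non_leaf: bool = False

    def to_dict(self) -> dict:
        return {
            "dcs": list(self.dcs),
            "restart_probs": list(self.restart_probs),
            "sim_threshold": self.sim_threshold,
            "q": self.q,
            "h": self.h,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "use_text_weights": self.use_text_weights,
            "propagate": self.propagate,
            "exclude_non_leaf": self.exclude_non_leaf,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


class OntologyAnnotator:
    """Zero-shot cell type annotation against an ontology graph.

    Parameters
    ----------
    graph
        The ontology; all score matrices use its term order.
    config
        Pipeline hyperparameters; see :class:`AnnotatorConfig`.

    After :meth:`fit`, :meth:`predict` returns a cells x all-terms
    probability matrix covering seen and unseen terms alike (unless the
    no-propagation ablation is configured, in which case unseen terms
    score exactly zero).
    """

    def __init__(self, graph: OntologyGraph, config: AnnotatorConfig | None = None) -> None:
        self.graph = graph
        self.config = config or AnnotatorConfig()
        self.term_ids: list[str] = list(graph.term_ids)
        self.text_table: TextEmbeddingTable = embed_texts(
            graph.definitions(), HashedNgramEncoder()
        )
        self.members: list[tuple[_model.ModelParams, _model.TermFeatureMatrix, DiffusionMatrix]] = []
        self.seen_term_ids: list[str] = []
        self.gene_ids: list[str] = []

    # ------------------------------------------------------------------
    def _graph_variant(self, d_c: int) -> OntologyGraph:
        g = self.graph
        if self.config.use_text_weights:
            g = g.apply_edge_weights(self.text_table.similarity)
        if d_c > 2:
            g = g.augment_edges(
                self.text_table.similarity, d_c=d_c,
                sim_threshold=self.config.sim_threshold,
            )
        return g

    def fit(self, expression: AnnotatedMatrix, cell_labels: Sequence[str]) -> "OntologyAnnotator":
        """Train the ensemble on annotated cells.

        ``cell_labels`` holds one ontology term id per cell (already
        mapped from free text if needed).  Terms with at least one
        training cell are the seen terms.
        """
        cfg = self.config
        labels = list(cell_labels)
        if len(labels) != expression.shape[0]:
            raise ValueError("one label per cell required")
        unknown = set(labels) - set(self.graph.term_index)
        if unknown:
            raise ValueError(f"labels not in the ontology: {sorted(unknown)}")

        self.seen_term_ids = sorted(set(labels))
        self.gene_ids = list(expression.gene_ids)
        seen_index = {t: i for i, t in enumerate(self.seen_term_ids)}
        Y = np.zeros((len(labels), len(self.seen_term_ids)))
        Y[np.arange(len(labels)), [seen_index[t] for t in labels]] = 1.0

        M = expression.values
        q = cfg.q if cfg.q is not None else default_q(len(self.seen_term_ids))

        self.members = []
        member_seed = cfg.seed
        for d_c in cfg.dcs:
            gvar = self._graph_variant(d_c)
            for alpha in cfg.restart_probs:
                diffusion = rwr(gvar, alpha)
                emb = svd_embed(diffusion, self.seen_term_ids, q)
                X = _model.build_feature_matrix(emb)
                params = _model.train(
                    M, Y, X,
                    h=cfg.h,
                    seed=member_seed,
                    epochs=cfg.epochs,
                    learning_rate=cfg.learning_rate,
                    gene_ids=self.gene_ids,
                )
                params.metadata.update({"d_c": d_c, "alpha": alpha})
                self.members.append((params, X, diffusion))
                member_seed += 1
        return self

    # ------------------------------------------------------------------
    def predict(self, expression: AnnotatedMatrix | np.ndarray) -> np.ndarray:
        """Cells x all-terms probabilities in the graph's term order."""
        if not self.members:
            raise RuntimeError("annotator is not fitted")
        Z = expression.values if isinstance(expression, AnnotatedMatrix) else np.asarray(expression)
        if isinstance(expression, AnnotatedMatrix) and expression.gene_ids != self.gene_ids:
            raise ValueError("gene order differs from training; align with expression.align_to_genes")

        if self.config.propagate:
            scores = _model.ensemble_predict(self.members, Z)
        else:
            # ablation: average raw seen-term softmax, unseen terms score 0
            seen_pos = [self.graph.term_index[t] for t in self.seen_term_ids]
            scores = np.zeros((Z.shape[0], self.graph.n_terms))
            for params, X, _ in self.members:
                P_seen = _model.predict(Z, params, X)
                scores[:, seen_pos] += P_seen / len(self.members)

        if self.config.exclude_non_leaf:
            scores = self._restrict_to_leaves(scores)
        return scores

    def _restrict_to_leaves(self, scores: np.ndarray) -> np.ndarray:
        """Zero out candidates that have a descendant among candidates and renormalize."""
        candidates = {t for t, j in self.graph.term_index.items() if scores[:, j].max() > 0}
        keep = {
            t for t in candidates if not (self.graph.descendants(t) & candidates)
        }
        out = scores.copy()
        for t in candidates - keep:
            out[:, self.graph.term_index[t]] = 0.0
        totals = np.clip(out.sum(axis=1, keepdims=True), 1e-12, None)
        return out / totals

    def predict_table(self, expression: AnnotatedMatrix, top_k: int = 3):
        """Per-cell top-k terms as a tidy DataFrame (cell_id, rank, term, p)."""
        import pandas as pd

        scores = self.predict(expression)
        top = np.argsort(-scores, axis=1, kind="stable")[:, :top_k]
        rows = []
        names = {t.term_id: t.name for t in self.graph.terms}
        for i, cell in enumerate(expression.cell_ids):
            for r in range(top.shape[1]):
                j = top[i, r]
                tid = self.term_ids[j]
                rows.append((cell, r + 1, tid, names[tid], scores[i, j]))
        return pd.DataFrame(rows, columns=["cell_id", "rank", "term_id", "term_name", "probability"])

    def manifest(self) -> dict:
        """Provenance record sufficient to reproduce a fitted model."""
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config.hash(),
            "n_terms": self.graph.n_terms,
            "seen_terms": self.seen_term_ids,
            "n_genes": len(self.gene_ids),
            "n_members": len(self.members),
        }
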
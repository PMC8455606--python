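"""Bilinear softmax classifier over ontology term embeddings.

The model scores a cell against a term by an inner product between a
nonlinear transform of the cell's expression and the term's feature
vector:

    logit(cell i, term j) = Relu(Relu(M_i W1) W2) X_j^T

where X = [E | I] stacks the graph embedding of each term with an
identity block acting as per-term bias.  Training minimizes softmax
cross-entropy over the seen terms (terms with at least one annotated
training cell); unseen terms receive probability mass afterwards by
propagating the seen-term scores along the graph diffusion
(:func:`propagate_scores`).  Robustness comes from averaging an ensemble
of models trained on different graph variants (edge-augmentation cutoff
d_c) and diffusion locality levels (restart probability alpha).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .embedding import DiffusionMatrix, TermEmbedding

__all__ = [
    "TermFeatureMatrix",
    "ModelParams",
    "build_feature_matrix",
    "train",
    "predict",
    "propagate_scores",
    "ensemble_predict",
    "save_model",
    "load_model",
]

DEFAULT_HIDDEN = 5
DEFAULT_LR = 1e-2
DEFAULT_EPOCHS = 300
MINIBATCH_THRESHOLD = 10_000
MINIBATCH_SIZE = 128


@dataclass
class TermFeatureMatrix:
    """X = [E | I]: label-side features of the bilinear model."""

    X: np.ndarray  # (n_terms_out, q + n_terms_out)
    term_ids: list[str]
    q: int


@dataclass
class ModelParams:
    """Trained weights plus the metadata needed to reuse them."""

    W1: np.ndarray  # (n_genes, h)
    W2: np.ndarray  # (h, q + c_out)
    h: int
    gene_ids: list[str]
    metadata: dict = field(default_factory=dict)


def build_feature_matrix(embedding: TermEmbedding) -> TermFeatureMatrix:
    """Concatenate the identity bias block to the term embedding."""
    E = embedding.matrix
    if E.size == 0:
        raise ValueError("empty term embedding")
    c = E.shape[0]
    X = np.hstack([E, np.eye(c)])
    return TermFeatureMatrix(X=X, term_ids=list(embedding.seen_term_ids), q=E.shape[1])


def _relu(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(M: np.ndarray, W1: np.ndarray, W2: np.ndarray, X: np.ndarray):
    A1 = M @ W1
    H1 = _relu(A1)
    A2 = H1 @ W2
    H2 = _relu(A2)
    logits = H2 @ X.T
    return A1, H1, A2, H2, logits


def _init_weights(rng: np.random.Generator, shape: tuple[int, int], scheme: str) -> np.ndarray:
    if scheme == "zeros":
        return np.zeros(shape)
    if scheme == "uniform":
        bound = 1.0 / np.sqrt(shape[0])
        return rng.uniform(-bound, bound, size=shape)
    raise ValueError(f"unknown init scheme {scheme!r}")


def train(
    M: np.ndarray,
    Y: np.ndarray,
    X: TermFeatureMatrix,
    *,
    h: int = DEFAULT_HIDDEN,
    seed: int = 0,
    epochs: int = DEFAULT_EPOCHS,
    learning_rate: float = DEFAULT_LR,
    gene_ids: Sequence[str] | None = None,
    init: str = "uniform",
    batch_size: int | None = None,
) -> ModelParams:
    """Fit W1, W2 by ADAM on softmax cross-entropy.

    Parameters
    ----------
    M
        cells x genes expression (log-transformed recommended).
    Y
        cells x seen-terms one-hot label matrix, columns aligned with
        ``X.term_ids``; every row must have exactly one positive.
    X
        Term feature matrix from :func:`build_feature_matrix`.
    h
        Hidden width; small by design since the number of seen terms is
        often small.
    batch_size
        Full batch by default; datasets above 10k cells fall back to
        mini-batches of 128.

    Deterministic for a fixed seed.
    """
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if M.shape[0] != Y.shape[0]:
        raise ValueError("expression and label matrices disagree on cell count")
    if Y.shape[1] != X.X.shape[0]:
        raise ValueError("label columns do not match term feature rows")
    row_sums = Y.sum(axis=1)
    if np.any(row_sums == 0):
        bad = int(np.flatnonzero(row_sums == 0)[0])
        raise ValueError(f"training cell {bad} has an all-zero label row")

    n_cells, n_genes = M.shape
    d_out = X.X.shape[1]
    rng = np.random.default_rng(seed)
    W1 = _init_weights(rng, (n_genes, h), init)
    W2 = _init_weights(rng, (h, d_out), init)

    if batch_size is None:
        batch_size = MINIBATCH_SIZE if n_cells > MINIBATCH_THRESHOLD else n_cells

    # ADAM state
    mW1 = np.zeros_like(W1); vW1 = np.zeros_like(W1)
    mW2 = np.zeros_like(W2); vW2 = np.zeros_like(W2)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    Xmat = X.X
    losses: list[float] = []

    for _ in range(epochs):
        order = rng.permutation(n_cells) if batch_size < n_cells else np.arange(n_cells)
        epoch_loss = 0.0
        for start in range(0, n_cells, batch_size):
            idx = order[start : start + batch_size]
            Mb, Yb = M[idx], Y[idx]
            A1, H1, A2, H2, logits = _forward(Mb, W1, W2, Xmat)
            P = _softmax(logits)
            batch_loss = -np.mean(
                np.log(np.clip((P * Yb).sum(axis=1), 1e-12, None))
            )
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite training loss at step {step}; "
                    f"|W1|max={np.abs(W1).max():.3g}, |W2|max={np.abs(W2).max():.3g}"
                )
            epoch_loss += batch_loss * len(idx)

            dlogits = (P - Yb) / len(idx)
            dH2 = dlogits @ Xmat
            dA2 = dH2 * (A2 > 0)
            gW2 = H1.T @ dA2
            dH1 = dA2 @ W2.T
            dA1 = dH1 * (A1 > 0)
            gW1 = Mb.T @ dA1

            step += 1
            for W, g, mm, vv in ((W1, gW1, mW1, vW1), (W2, gW2, mW2, vW2)):
                mm *= beta1; mm += (1 - beta1) * g
                vv *= beta2; vv += (1 - beta2) * g * g
                mhat = mm / (1 - beta1**step)
                vhat = vv / (1 - beta2**step)
                W -= learning_rate * mhat / (np.sqrt(vhat) + eps)
        losses.append(epoch_loss / n_cells)

    return ModelParams(
        W1=W1,
        W2=W2,
        h=h,
        gene_ids=list(gene_ids) if gene_ids is not None else [],
        metadata={
            "seed": seed,
            "epochs": epochs,
            "learning_rate": learning_rate,
            "loss_curve": losses,
            "term_ids": list(X.term_ids),
        },
    )


def predict(Z: np.ndarray, params: ModelParams, X: TermFeatureMatrix) -> np.ndarray:
    """Per-cell probabilities over the model's (seen) terms; rows on the simplex."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[None, :]
    if Z.shape[1] != params.W1.shape[0]:
        raise ValueError(
            f"input has {Z.shape[1]} genes but the model was trained on "
            f"{params.W1.shape[0]}; align gene order via expression preprocessing first"
        )
    *_, logits = _forward(Z, params.W1, params.W2, X.X)
    return _softmax(logits)


def propagate_scores(
    P_seen: np.ndarray,
    diffusion: DiffusionMatrix,
    seen_ids: Sequence[str],
) -> np.ndarray:
    """Extend seen-term scores to every ontology term via graph diffusion.

    score(cell, t) = sum_s P_seen(cell, s) * D(s, t), row-renormalized to
    the simplex.  Accepts any external seen-term score matrix, so this
    step is usable standalone on the output of other classifiers.
    Returns a cells x all-terms matrix in ``diffusion.term_ids`` order.
    """
    P_seen = np.asarray(P_seen, dtype=float)
    seen_ids = list(seen_ids)
    if P_seen.shape[1] != len(seen_ids):
        raise ValueError("score columns do not match seen term ids")
    row_sums = P_seen.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        warnings.warn("input scores not on the simplex; renormalizing rows")
        P_seen = P_seen / np.clip(row_sums[:, None], 1e-12, None)
    D_rows = diffusion.rows_for(seen_ids)  # (n_seen, n_terms)
    extended = P_seen @ D_rows
    totals = np.clip(extended.sum(axis=1, keepdims=True), 1e-12, None)
    return extended / totals


def ensemble_predict(
    members: Sequence[tuple[ModelParams, TermFeatureMatrix, DiffusionMatrix]],
    Z: np.ndarray,
) -> np.ndarray:
    """Average propagated score matrices over ensemble members.

    Each member is (params, X, diffusion); members must share the global
    term order of their diffusion matrices.
    """
    if not members:
        raise ValueError("empty ensemble")
    term_order = members[0][2].term_ids
    total = None
    for params, X, diffusion in members:
        if diffusion.term_ids != term_order:
            raise ValueError("ensemble members disagree on term order")
        P_seen = predict(Z, params, X)
        P_all = propagate_scores(P_seen, diffusion, X.term_ids)
        total = P_all if total is None else total + P_all
    return total / len(members)


def save_model(path: str, params: ModelParams, X: TermFeatureMatrix) -> None:
    """Save weights + term order + gene order + config as one .npz archive."""
    meta = dict(params.metadata)
    meta.pop("loss_curve", None)
    np.savez(
        path,
        W1=params.W1,
        W2=params.W2,
        X=X.X,
        q=np.asarray([X.q]),
        h=np.asarray([params.h]),
        term_ids=np.asarray(X.term_ids, dtype=object),
        gene_ids=np.asarray(params.gene_ids, dtype=object),
        config=np.asarray([json.dumps(meta)], dtype=object),
    )


def load_model(path: str) -> tuple[ModelParams, TermFeatureMatrix]:
    data = np.load(path, allow_pickle=True)
    term_ids = [str(t) for t in data["term_ids"]]
    params = ModelParams(
        W1=data["W1"],
        W2=data["W2"],
        h=int(data["h"][0]),
        gene_ids=[str(g) for g in data["gene_ids"]],
        metadata=json.loads(str(data["config"][0])),
    )
    X = TermFeatureMatrix(X=data["X"], term_ids=term_ids, q=int(data["q"][0]))
    return params, X
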
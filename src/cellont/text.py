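"""Text embedding of term definitions and free-text label mapping.

Cell-type definitions and user labels are embedded into one vector space;
cosine similarity between them drives both the edge weights of the
ontology working graph and the mapping of free-text annotations onto
controlled-vocabulary terms.  The default encoder is a hashed character
3-gram frequency vector (dimension 512, L2-normalized): deterministic,
dependency-free, and adequate because only the cosine geometry of the
embeddings matters downstream.  Any encoder implementing
``encode(text) -> unit vector`` can be dropped in.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TextEncoder",
    "HashedNgramEncoder",
    "TextEmbeddingTable",
    "LabelMapping",
    "embed_texts",
    "cosine_similarity",
    "map_free_text",
    "bipartite_match",
]


class TextEncoder(Protocol):
    """Deterministic map from a string to a fixed-dimension unit vector."""

    tag: str

    def encode(self, text: str) -> np.ndarray: ...


class HashedNgramEncoder:
    """Character n-gram hashing encoder.

    Lower-cases the text, pads with sentinels, hashes every character
    n-gram with CRC32 into ``dim`` buckets and L2-normalizes the counts.
    CRC32 is pinned (not Python's salted ``hash``) so two processes
    produce bitwise-identical vectors.
    """

    def __init__(self, dim: int = 512, n: int = 3) -> None:
        if dim < 1 or n < 1:
            raise ValueError("dim and n must be positive")
        self.dim = dim
        self.n = n
        self.tag = f"hashed-{n}gram-{dim}"

    def encode(self, text: str) -> np.ndarray:
        if not text:
            raise ValueError("cannot encode an empty string")
        padded = "^" + text.lower() + "$"
        vec = np.zeros(self.dim, dtype=np.float64)
        n = self.n
        if len(padded) < n:
            padded = padded + "$" * (n - len(padded))
        for i in range(len(padded) - n + 1):
            gram = padded[i : i + n]
            bucket = zlib.crc32(gram.encode("utf-8")) % self.dim
            vec[bucket] += 1.0
        norm = np.linalg.norm(vec)
        if norm == 0:  # pragma: no cover - non-empty text always has a gram
            raise ValueError(f"text produced a zero vector: {text!r}")
        return vec / norm


@dataclass
class TextEmbeddingTable:
    """Unit-norm embedding vectors keyed by term id or user label."""

    keys: list[str]
    vectors: np.ndarray  # (n_keys, dim), rows unit-norm
    encoder_tag: str
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.keys) != len(set(self.keys)):
            raise ValueError("embedding table keys must be unique")
        if self.vectors.shape[0] != len(self.keys):
            raise ValueError("vector count does not match key count")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("embedding vectors must be unit-norm")
        self._index = {k: i for i, k in enumerate(self.keys)}

    def vector(self, key: str) -> np.ndarray:
        return self.vectors[self._index[key]]

    def similarity(self, a: str, b: str) -> float:
        return float(self.vector(a) @ self.vector(b))

    def pairwise(self) -> np.ndarray:
        """Full cosine similarity matrix over the table's keys."""
        return self.vectors @ self.vectors.T


@dataclass
class LabelMapping:
    """One free-text label mapped onto the ontology vocabulary."""

    source_label: str
    matched_term: str | None
    similarity: float
    shortlist: list[tuple[str, float]]  # (term_id, cosine), descending


def embed_texts(texts: Mapping[str, str], encoder: TextEncoder | None = None) -> TextEmbeddingTable:
    """Embed a key -> text mapping into a :class:`TextEmbeddingTable`."""
    if not texts:
        raise ValueError("no texts to embed")
    encoder = encoder or HashedNgramEncoder()
    keys = list(texts)
    rows = []
    for key in keys:
        text = texts[key]
        if not text:
            raise ValueError(f"empty text for key {key!r}")
        rows.append(encoder.encode(text))
    return TextEmbeddingTable(keys=keys, vectors=np.asarray(rows), encoder_tag=encoder.tag)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def bipartite_match(weights: np.ndarray, floor: float = 0.0) -> dict[int, int]:
    """Maximum-weight bipartite matching between sources (rows) and targets (columns).

    Returns a partial injective assignment ``{source_idx: target_idx}``
    maximizing total weight; edges with weight <= ``floor`` are never
    used, so a source may remain unmatched.  Exact (blossom algorithm).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        return {}
    if not np.all(np.isfinite(weights)):
        raise ValueError("matching weights must be finite")
    n_src, n_tgt = weights.shape
    graph = nx.Graph()
    for i in range(n_src):
        for j in range(n_tgt):
            if weights[i, j] > floor:
                graph.add_edge(("s", i), ("t", j), weight=float(weights[i, j]))
    matching = nx.max_weight_matching(graph, maxcardinality=False)
    out: dict[int, int] = {}
    for a, b in matching:
        if a[0] == "t":
            a, b = b, a
        out[a[1]] = b[1]
    return out


def map_free_text(
    labels: Sequence[str],
    term_table: TextEmbeddingTable,
    top_k: int = 5,
    encoder: TextEncoder | None = None,
    refine: bool = False,
) -> list[LabelMapping]:
    """Map free-text annotations onto ontology terms by embedding cosine.

    Each label gets a shortlist of the ``top_k`` most similar terms; the
    rank-1 term is the match.  With ``refine=True`` a maximum-weight
    bipartite matching reassigns labels so no two labels share a term
    (useful when a dataset's annotation columns are known to be distinct
    cell types).  Ties in rank break by ascending term id.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not labels:
        return []
    encoder = encoder or HashedNgramEncoder()
    if encoder.tag != term_table.encoder_tag:
        raise ValueError(
            f"encoder {encoder.tag!r} does not match table encoder {term_table.encoder_tag!r}"
        )
    label_vecs = np.asarray([encoder.encode(lab) for lab in labels])
    sims = label_vecs @ term_table.vectors.T  # (labels, terms)
    term_ids = term_table.keys
    # stable sort: descending similarity, ties by ascending term id
    id_order = np.argsort(term_ids)  # positions sorted by term id
    k = min(top_k, len(term_ids))

    mappings: list[LabelMapping] = []
    for li, label in enumerate(labels):
        row = sims[li][id_order]
        top = np.argsort(-row, kind="stable")[:k]
        shortlist = [(term_ids[id_order[j]], float(row[j])) for j in top]
        mappings.append(
            LabelMapping(
                source_label=label,
                matched_term=shortlist[0][0],
                similarity=shortlist[0][1],
                shortlist=shortlist,
            )
        )

    if refine:
        assignment = bipartite_match(sims)
        for li, mapping in enumerate(mappings):
            if li in assignment:
                ti = assignment[li]
                mapping.matched_term = term_ids[ti]
                mapping.similarity = float(sims[li, ti])
            else:
                mapping.matched_term = None
                mapping.similarity = float("nan")
    return mappings
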
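"""Synthetic ontologies and expression data for offline testing.

The generator builds the conditions the annotation method relies on:

* a rooted is_a tree (optionally with extra cross edges) whose term
  definitions share phrase stems along ancestry, so text similarity
  correlates with graph proximity;
* per-term gene signatures that diffuse along the graph
  (guilt-by-association: neighboring terms have similar expression), with
  a mixing weight ``beta`` controlling how strongly;
* noisy cell profiles drawn per term from a Poisson count model with
  per-cell depth variation;
* synonym/typo corruption of term-name labels, to exercise free-text
  label mapping.

Everything is deterministic under ``seed`` (numpy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import AnnotatedMatrix
from .ontology import OntologyGraph, OntologyTerm, build_graph, write_obo

__all__ = [
    "FixtureConfig",
    "make_ontology",
    "make_signatures",
    "sample_cells",
    "corrupt_labels",
    "default_synonyms",
    "standard_fixture",
]

# word stock for generated names/definitions; stems are inherited along
# ancestry so parent/child definitions genuinely share text
_STEMS = [
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "theta", "kappa",
    "lambda", "sigma", "omega", "basal", "ciliated", "granular", "cortical",
    "medullary", "ventral", "dorsal", "apical", "luminal", "mural", "stellate",
    "cuboidal", "columnar", "fusiform", "dendritic", "follicular", "marginal",
    "transitional", "intercalated", "parietal", "chief", "mucous", "serous",
    "pigmented", "sensory", "secretory", "migratory", "resident", "progenitor",
]


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic dataset."""

    n_terms: int = 40
    branching: int = 2
    n_genes: int = 120
    beta: float = 0.5  # signature diffusion strength along the graph
    cells_per_term: int = 30
    noise: float = 1.0  # 0 = deterministic profiles; >0 = Poisson counts
    seed: int = 0
    markers_per_term: int = 3
    signature_background: float = 0.5
    signature_strength: float = 5.0
    extra_edges: int = 0  # optional DAG cross edges

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if self.branching < 1:
            raise ValueError("branching must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if self.cells_per_term < 1:
            raise ValueError("cells_per_term must be >= 1")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


def make_ontology(cfg: FixtureConfig) -> tuple[str, OntologyGraph]:
    """Generate a rooted is_a tree with names and definition sentences.

    Each term inherits its ancestors' stems, so the definition of a child
    shares phrases with its parent; a character-n-gram text encoder then
    sees higher similarity for graph-near pairs.  Returns the OBO text and
    the parsed graph (the OBO round-trips through ``parse_obo``).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_terms
    if cfg.branching == 1 and n > 2:
        pass  # a chain is a valid (degenerate) tree
    parents: list[int | None] = [None]
    for i in range(1, n):
        # complete-ish tree: parent of node i under branching factor b
        parents.append((i - 1) // cfg.branching)

    stems: list[list[str]] = []
    names: list[str] = []
    used: set[str] = set()
    for i in range(n):
        own = _STEMS[int(rng.integers(len(_STEMS)))]
        lineage = (stems[parents[i]] if parents[i] is not None else []) + [own]
        stems.append(lineage)
        name = " ".join(lineage[-2:]) + " cell"
        if name in used:
            name = f"{lineage[-1]} type {i} cell"
        used.add(name)
        names.append(name)

    terms: list[OntologyTerm] = []
    for i in range(n):
        lineage_txt = " ".join(stems[i])
        definition = (
            f"A {names[i]} of the {lineage_txt} lineage"
            + (f", a specialized {names[parents[i]]}." if parents[i] is not None else ".")
        )
        terms.append(
            OntologyTerm(
                term_id=_term_id(i),
                name=names[i],
                definition=definition,
                parent_ids=[_term_id(parents[i])] if parents[i] is not None else [],
            )
        )

    # optional extra is_a edges turn the tree into a DAG
    for _ in range(cfg.extra_edges):
        child = int(rng.integers(1, n))
        anc = int(rng.integers(0, child))
        pid = _term_id(anc)
        if pid not in terms[child].parent_ids and anc != parents[child]:
            terms[child].parent_ids.append(pid)

    obo_text = write_obo(terms, header="synthetic-cell-taxonomy")
    return obo_text, build_graph(terms)


def make_signatures(
    graph: OntologyGraph,
    n_genes: int,
    beta: float,
    seed: int,
    markers_per_term: int = 3,
    background: float = 0.5,
    strength: float = 5.0,
    n_smooth: int = 3,
) -> np.ndarray:
    """Per-term mean-expression signatures diffused along the graph.

    Each term first gets an independent signature: low background rates
    plus ``markers_per_term`` elevated genes drawn for that term.  The
    signatures are then smoothed ``n_smooth`` times as
    ``sig <- (1 - beta) * sig + beta * neighbor_mean(sig)``, so graph-near
    terms end up with correlated expression; ``beta = 0`` leaves them
    independent.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_terms = graph.n_terms
    sig = rng.gamma(shape=2.0, scale=background / 2.0, size=(n_terms, n_genes))
    for i in range(n_terms):
        own = rng.choice(n_genes, size=min(markers_per_term, n_genes), replace=False)
        sig[i, own] += strength

    if beta > 0:
        adj = graph.adjacency().toarray()
        deg = adj.sum(axis=1)
        safe_deg = np.where(deg > 0, deg, 1.0)
        for _ in range(n_smooth):
            neighbor_mean = (adj @ sig) / safe_deg[:, None]
            neighbor_mean[deg == 0] = sig[deg == 0]
            sig = (1.0 - beta) * sig + beta * neighbor_mean
    return sig


def sample_cells(
    signatures: np.ndarray,
    graph: OntologyGraph,
    cells_per_term: int,
    noise: float = 1.0,
    seed: int = 0,
    term_ids: list[str] | None = None,
) -> AnnotatedMatrix:
    """Draw labeled cell profiles from the term signatures.

    With ``noise > 0`` counts are Poisson with rate = signature scaled by
    a per-cell lognormal depth factor (sigma = 0.1 * noise); ``noise = 0``
    returns each term's signature row verbatim (deterministic mode, for
    exact-output tests).  ``term_ids`` restricts which terms get cells
    (e.g. leaves only); default is every term.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    if cells_per_term < 1:
        raise ValueError("cells_per_term must be >= 1")
    rng = np.random.default_rng(seed)
    all_ids = graph.term_ids
    term_ids = list(term_ids) if term_ids is not None else list(all_ids)
    index = {t: i for i, t in enumerate(all_ids)}
    n_genes = signatures.shape[1]

    rows = []
    labels = []
    cell_ids = []
    for term in term_ids:
        sig = signatures[index[term]]
        for c in range(cells_per_term):
            if noise == 0:
                profile = sig.copy()
            else:
                depth = rng.lognormal(mean=0.0, sigma=0.1 * noise)
                profile = rng.poisson(sig * depth).astype(float)
            rows.append(profile)
            labels.append(term)
            cell_ids.append(f"{term}.cell{c}")
    return AnnotatedMatrix(
        values=np.asarray(rows),
        cell_ids=cell_ids,
        gene_ids=[f"gene{g}" for g in range(n_genes)],
        labels=labels,
    )


def default_synonyms(graph: OntologyGraph) -> dict[str, list[str]]:
    """Synonym/typo variants for each term name (plural, truncation, article)."""
    out: dict[str, list[str]] = {}
    for t in graph.terms:
        out[t.name] = [
            t.name + "s",
            t.name.replace("cell", "cel"),
            "the " + t.name,
        ]
    return out


def corrupt_labels(
    labels: list[str],
    synonym_dict: dict[str, list[str]],
    rate: float,
    seed: int = 0,
) -> list[str]:
    """Replace each label by a synonym/typo variant with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate > 0 and not synonym_dict:
        raise ValueError("synonym dictionary is empty")
    rng = np.random.default_rng(seed)
    out = []
    for lab in labels:
        variants = synonym_dict.get(lab, [])
        if variants and rng.random() < rate:
            out.append(variants[int(rng.integers(len(variants)))])
        else:
            out.append(lab)
    return out


@dataclass
class Fixture:
    """One fully generated synthetic dataset."""

    config: FixtureConfig
    obo_text: str
    graph: OntologyGraph
    signatures: np.ndarray
    expression: AnnotatedMatrix  # labels attached
    labeled_term_ids: list[str]


def standard_fixture(seed: int = 0, cfg: FixtureConfig | None = None) -> Fixture:
    """The default study conditions: 40-term binary tree, beta = 0.5,
    30 cells per term, Poisson noise.

    Cells are sampled only at leaf terms so the labels are mutually
    exclusive (no labeled term is an ancestor of another), matching how
    curated datasets annotate to the most fine-grained type.
    """
    cfg = cfg or FixtureConfig(seed=seed)
    obo_text, graph = make_ontology(cfg)
    signatures = make_signatures(
        graph,
        cfg.n_genes,
        cfg.beta,
        seed=cfg.seed + 1,
        markers_per_term=cfg.markers_per_term,
        background=cfg.signature_background,
        strength=cfg.signature_strength,
    )
    leaves = sorted(graph.leaves())
    expr = sample_cells(
        signatures,
        graph,
        cfg.cells_per_term,
        noise=cfg.noise,
        seed=cfg.seed + 2,
        term_ids=leaves,
    )
    return Fixture(
        config=cfg,
        obo_text=obo_text,
        graph=graph,
        signatures=signatures,
        expression=expr,
        labeled_term_ids=leaves,
    )
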
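"""Cell-type ontology graphs.

The ontology is kept in two coupled views: the directed ``is_a`` DAG
(child -> parent), used for descendant queries and mutual-exclusivity
filtering, and a weighted undirected working graph over the same nodes,
used for random-walk diffusion and hop distances.  Edge weights default
to 1.0 and may carry text-description similarities in (0, 1].
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import obonet

__all__ = [
    "OntologyTerm",
    "OntologyGraph",
    "OntologyError",
    "parse_obo",
    "build_graph",
    "read_edge_list",
    "write_obo",
    "load_ontology",
]

#: sentinel returned by :meth:`OntologyGraph.hop_distance` for disconnected pairs
INF_DISTANCE = math.inf


class OntologyError(ValueError):
    """Raised for malformed ontology input or invalid graph queries."""


@dataclass
class OntologyTerm:
    """A single ontology term.

    ``definition`` falls back to ``name`` when the source carries no
    ``def:`` line, so it is always non-empty for valid terms.
    """

    term_id: str
    name: str
    definition: str = ""
    parent_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.definition:
            self.definition = self.name


_DEF_QUOTE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _clean_definition(raw: str) -> str:
    """Extract the quoted sentence from an OBO ``def:`` value."""
    m = _DEF_QUOTE.search(raw)
    if m:
        return m.group(1).replace('\\"', '"')
    return raw.strip()


def _validate_obo_stanzas(text: str) -> None:
    in_term = False
    has_id = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("["):
            if in_term and not has_id:
                raise OntologyError(
                    f"malformed [Term] stanza ending before line {lineno}: missing 'id:'"
                )
            in_term = stripped == "[Term]"
            has_id = False
        elif in_term and stripped.startswith("id:"):
            if not stripped[3:].strip():
                raise OntologyError(f"malformed 'id:' line at line {lineno}")
            has_id = True
    if in_term and not has_id:
        raise OntologyError("malformed [Term] stanza at end of file: missing 'id:'")


def parse_obo(source) -> list[OntologyTerm]:
    """Parse OBO flat-file text into a list of :class:`OntologyTerm`.

    Parameters
    ----------
    source
        A path, an open text stream, or the OBO text itself.

    Only ``[Term]`` stanzas are considered; obsolete terms are dropped;
    only ``is_a`` targets become parents.  Term order follows file order.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and ("\n" in source or "[Term]" in source):
        text = source
    else:
        with open(source, "rt") as fh:
            text = fh.read()

    _validate_obo_stanzas(text)
    if not text.lstrip().startswith("format-version"):
        text = "format-version: 1.2\nontology: unnamed\n\n" + text
    try:
        graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - obonet raises varied types
        raise OntologyError(f"failed to parse OBO input: {exc}") from exc

    terms: list[OntologyTerm] = []
    for term_id, data in graph.nodes(data=True):
        name = data.get("name", term_id)
        definition = _clean_definition(data.get("def", "")) or name
        parents = [
            parent
            for _, parent, key in graph.out_edges(term_id, keys=True)
            if key == "is_a"
        ]
        terms.append(
            OntologyTerm(term_id=term_id, name=name, definition=definition,
                         parent_ids=parents)
        )
    if not terms:
        raise OntologyError("empty ontology: no [Term] stanzas found")
    return terms


def write_obo(terms: Sequence[OntologyTerm], header: str = "cellont") -> str:
    """Serialize terms back to OBO text (inverse of :func:`parse_obo`)."""
    lines = [f"format-version: 1.2", f"ontology: {header}", ""]
    for t in terms:
        lines.append("[Term]")
        lines.append(f"id: {t.term_id}")
        lines.append(f"name: {t.name}")
        if t.definition != t.name:
            escaped = t.definition.replace('"', '\\"')
            lines.append(f'def: "{escaped}" []')
        for p in t.parent_ids:
            lines.append(f"is_a: {p}")
        lines.append("")
    return "\n".join(lines)


class OntologyGraph:
    """Directed is_a DAG plus weighted undirected working graph.

    Term indexing is 0-based in input order; every matrix produced
    downstream (diffusion, scores, labels) uses this order.
    """

    def __init__(self, terms: Sequence[OntologyTerm],
                 undirected: nx.Graph, directed: nx.DiGraph) -> None:
        self.terms = list(terms)
        self.term_index: dict[str, int] = {t.term_id: i for i, t in enumerate(self.terms)}
        self._undirected = undirected
        self._directed = directed

    # -- basic accessors -------------------------------------------------
    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def term(self, term_id: str) -> OntologyTerm:
        return self.terms[self._check(term_id)]

    def definitions(self) -> dict[str, str]:
        """term_id -> definition text (falls back to the name)."""
        return {t.term_id: t.definition for t in self.terms}

    def _check(self, term_id: str) -> int:
        try:
            return self.term_index[term_id]
        except KeyError:
            raise OntologyError(f"unknown term id: {term_id!r}") from None

    # -- graph views -----------------------------------------------------
    def undirected_edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["weight"]) for a, b, d in self._undirected.edges(data=True)]

    def adjacency(self):
        """Weighted undirected adjacency as a scipy sparse matrix in term order."""
        return nx.to_scipy_sparse_array(
            self._undirected, nodelist=self.term_ids, weight="weight", format="csr"
        )

    # -- queries ----------------------------------------------------------
    def hop_distance(self, a: str, b: str) -> float:
        """Unweighted shortest-path length on the undirected view.

        Returns ``math.inf`` for pairs in different connected components.
        """
        self._check(a)
        self._check(b)
        try:
            return float(nx.shortest_path_length(self._undirected, a, b))
        except nx.NetworkXNoPath:
            return INF_DISTANCE

    def descendants(self, a: str) -> set[str]:
        """All terms reachable from below via is_a (excludes ``a`` itself)."""
        self._check(a)
        # edges run child -> parent, so descendants are the DAG ancestors
        return set(nx.ancestors(self._directed, a))

    def leaves(self) -> set[str]:
        """Terms with no descendants."""
        return {t.term_id for t in self.terms if self._directed.in_degree(t.term_id) == 0}

    # -- edge augmentation -------------------------------------------------
    def augment_edges(
        self,
        text_sim: Callable[[str, str], float] | Mapping[tuple[str, str], float],
        d_c: int,
        sim_threshold: float = 0.8,
    ) -> "OntologyGraph":
        """Add text-similarity edges between near-but-unlinked terms.

        A new undirected edge (weight = similarity) is added for every pair
        with hop distance in (1, d_c) whose text similarity exceeds
        ``sim_threshold``.  ``d_c = 2`` adds nothing.  Returns a new graph;
        the input is untouched.
        """
        if d_c < 2:
            raise OntologyError(f"d_c must be >= 2, got {d_c}")
        if callable(text_sim):
            sim = text_sim
        else:
            table = dict(text_sim)
            sim = lambda a, b: table.get((a, b), table.get((b, a), 0.0))

        und = self._undirected.copy()
        if d_c > 2:
            for a in self.term_ids:
                # nodes within hop distance < d_c of a
                near = nx.single_source_shortest_path_length(
                    self._undirected, a, cutoff=d_c - 1
                )
                for b, dist in near.items():
                    if dist <= 1 or b <= a:
                        continue
                    if und.has_edge(a, b):
                        continue
                    s = float(sim(a, b))
                    if s > sim_threshold:
                        und.add_edge(a, b, weight=s)
        return OntologyGraph(self.terms, und, self._directed.copy())

    def apply_edge_weights(
        self, text_sim: Callable[[str, str], float] | Mapping[tuple[str, str], float]
    ) -> "OntologyGraph":
        """Reweight existing undirected edges by text similarity (clipped to (0, 1])."""
        if callable(text_sim):
            sim = text_sim
        else:
            table = dict(text_sim)
            sim = lambda a, b: table.get((a, b), table.get((b, a), 1.0))
        und = self._undirected.copy()
        for a, b in und.edges():
            w = float(sim(a, b))
            und[a][b]["weight"] = min(1.0, max(w, 1e-6))
        return OntologyGraph(self.terms, und, self._directed.copy())

    def to_edge_list(self) -> str:
        """Export the undirected weighted graph as TSV (term_a, term_b, weight)."""
        rows = ["\t".join((a, b, f"{w:.6g}")) for a, b, w in self.undirected_edges()]
        return "\n".join(rows) + "\n"


def build_graph(
    terms: Sequence[OntologyTerm],
    edge_weights: Mapping[tuple[str, str], float] | None = None,
) -> OntologyGraph:
    """Build an :class:`OntologyGraph` from parsed terms.

    One undirected edge per unordered is_a pair (deduplicated when both
    stanzas assert the relation); weight from ``edge_weights`` when given,
    else 1.0.  Raises if the is_a relations contain a cycle.
    """
    known = {t.term_id for t in terms}
    directed = nx.DiGraph()
    undirected = nx.Graph()
    for t in terms:
        directed.add_node(t.term_id)
        undirected.add_node(t.term_id)
    weights = dict(edge_weights or {})

    def weight_for(a: str, b: str) -> float:
        return float(weights.get((a, b), weights.get((b, a), 1.0)))

    for t in terms:
        for p in t.parent_ids:
            if p not in known:
                warnings.warn(
                    f"term {t.term_id}: parent {p!r} not in ontology, dropped",
                    stacklevel=2,
                )
                continue
            if p == t.term_id:
                continue  # self is_a carries no information
            directed.add_edge(t.term_id, p)
            undirected.add_edge(t.term_id, p, weight=weight_for(t.term_id, p))

    if not nx.is_directed_acyclic_graph(directed):
        cycle = nx.find_cycle(directed)
        raise OntologyError(f"is_a relations contain a cycle: {cycle}")
    return OntologyGraph(terms, undirected, directed)


def read_edge_list(source, weighted: bool = True) -> OntologyGraph:
    """Build a graph from a (child, parent[, weight]) TSV.

    Accepts Allen-style taxonomies that do not ship as OBO.  Terms are
    created in first-appearance order with the id doubling as name.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    elif isinstance(source, str) and "\t" in source:
        lines = source.splitlines()
    else:
        with open(source, "rt") as fh:
            lines = fh.read().splitlines()

    order: list[str] = []
    parents: dict[str, list[str]] = {}
    weights: dict[tuple[str, str], float] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise OntologyError(f"edge list line {lineno}: expected >= 2 columns")
        child, parent = parts[0], parts[1]
        for t in (child, parent):
            if t not in parents:
                parents[t] = []
                order.append(t)
        parents[child].append(parent)
        if weighted and len(parts) >= 3:
            weights[(child, parent)] = float(parts[2])

    terms = [OntologyTerm(term_id=t, name=t, parent_ids=parents[t]) for t in order]
    if not terms:
        raise OntologyError("empty edge list")
    return build_graph(terms, edge_weights=weights or None)


def load_ontology(path: str) -> OntologyGraph:
    """Load an ontology from an OBO file or an edge-list TSV, by extension."""
    if str(path).endswith((".tsv", ".txt")):
        return read_edge_list(path)
    return build_graph(parse_obo(path))
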
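"""Core data containers: association matrix, disease ontology DAG, similarity matrices.

All matrices are dense numpy float64 arrays with explicit axis labels.
Names are normalized (trimmed, case-folded, internal whitespace collapsed)
before any matrix is built, so that association tables and ontology term
names can be matched exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "normalize_name",
    "AssociationMatrix",
    "DiseaseDAG",
    "SimilarityMatrix",
    "SIMILARITY_KINDS",
]

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Trim, case-fold and collapse internal whitespace of an entity name."""
    return _WS.sub(" ", name.strip()).casefold()


@dataclass
class AssociationMatrix:
    """0/1 adjacency Y over named circRNAs (rows) x diseases (columns)."""

    values: np.ndarray
    circ_names: list[str]
    disease_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.circ_names = [normalize_name(n) for n in self.circ_names]
        self.disease_names = [normalize_name(n) for n in self.disease_names]
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        nc, nd = self.values.shape
        if nc < 1 or nd < 1:
            raise ValueError("association matrix must be at least 1x1")
        if nc != len(self.circ_names) or nd != len(self.disease_names):
            raise ValueError(
                f"label/shape mismatch: values {self.values.shape}, "
                f"{len(self.circ_names)} circRNA names, "
                f"{len(self.disease_names)} disease names"
            )
        if len(set(self.circ_names)) != nc:
            raise ValueError("circRNA names not unique after normalization")
        if len(set(self.disease_names)) != nd:
            raise ValueError("disease names not unique after normalization")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_circ(self) -> int:
        return self.values.shape[0]

    @property
    def n_dis(self) -> int:
        return self.values.shape[1]

    @property
    def n_positive(self) -> int:
        return int(self.values.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Indices (i, j) of the Y=1 cells, row-major order."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.circ_names), list(self.disease_names)
        )


@dataclass
class DiseaseDAG:
    """Rooted ontology DAG: terms with names, child->parent is-a edges.

    Internally a networkx DiGraph with edges directed child -> parent, so every
    maximal path from a term ends at a root (a term with no parents).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    @classmethod
    def from_terms(
        cls,
        terms: dict[str, str],
        edges: list[tuple[str, str]],
    ) -> "DiseaseDAG":
        """Build from ``{term_id: name}`` and (child_id, parent_id) is-a edges."""
        g = nx.DiGraph()
        for tid, name in terms.items():
            g.add_node(tid, name=name, norm_name=normalize_name(name))
        for child, parent in edges:
            if child not in g or parent not in g:
                raise ValueError(f"is-a edge references unknown term: {child} -> {parent}")
            g.add_edge(child, parent)
        return cls(g)

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def roots(self) -> list[str]:
        return [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]

    def name_of(self, term: str) -> str:
        return self.graph.nodes[term]["name"]

    def parents(self, term: str) -> list[str]:
        return list(self.graph.successors(term))

    def children(self, term: str) -> list[str]:
        return list(self.graph.predecessors(term))

    def term_for_name(self, name: str) -> str | None:
        """Term id whose normalized name matches, or None."""
        target = normalize_name(name)
        for tid, data in self.graph.nodes(data=True):
            if data.get("norm_name") == target:
                return tid
        return None

    def ancestors_and_self(self, term: str) -> set[str]:
        """The term and all ancestors reachable through is-a edges."""
        return {term} | nx.descendants(self.graph, term)


SIMILARITY_KINDS = (
    "semantic",      # SS: disease-disease, ontology based
    "functional",    # FS: circRNA-circRNA, from associated disease groups
    "gip_circ",      # GC: Gaussian interaction profile kernel over Y rows
    "gip_dis",       # GD: GIP kernel over Y columns
    "integrated_circ",  # SC: FS where nonzero, else GC
    "integrated_dis",   # SD: SS where nonzero, else GD
)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1]."""

    values: np.ndarray
    labels: list[str]
    kind: str

    _SYM_TOL = 1e-9

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [normalize_name(n) for n in self.labels]
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix must be square over its {n} labels, "
                f"got shape {self.values.shape}"
            )
        if np.abs(self.values - self.values.T).max(initial=0.0) > self._SYM_TOL:
            raise ValueError(f"{self.kind} similarity matrix is not symmetric")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError(f"{self.kind} similarity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(normalize_name(label))
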
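"""Gene Ontology containers: the term DAG and protein annotation tables.

The DAG is stored as a child -> parents map with one aspect tag per term
(BP, CC or MF).  Two readers are provided: OBO format (via :mod:`obonet`) and
a plain three-column ``term TAB parent TAB aspect`` table (``-`` for roots),
which is the dialect the synthetic generators write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "AnnotationTable",
    "load_ontology_table",
    "write_ontology_table",
    "load_obo",
    "load_annotations",
    "write_annotations",
]

_OBO_NAMESPACES = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}


@dataclass
class OntologyDAG:
    """Acyclic is-a hierarchy of ontology terms.

    ``parents`` maps every term to its (possibly empty) parent set; ``aspect``
    tags each term with BP/CC/MF.  Acyclicity is checked on construction.
    """

    parents: dict[str, frozenset[str]]
    aspect: dict[str, str]

    def __post_init__(self) -> None:
        self.parents = {t: frozenset(p) for t, p in self.parents.items()}
        for term, parents in self.parents.items():
            for p in parents:
                if p not in self.parents:
                    raise ValueError(f"parent {p!r} of {term!r} is not a term")
        for term in self.parents:
            if term not in self.aspect:
                raise ValueError(f"term {term!r} has no aspect tag")
        self._topo_order = self._topological_order()  # raises on cycles
        self._children: dict[str, set[str]] = {t: set() for t in self.parents}
        for term, parents in self.parents.items():
            for p in parents:
                self._children[p].add(term)
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    @property
    def roots(self) -> set[str]:
        return {t for t, p in self.parents.items() if not p}

    def children(self, term: str) -> set[str]:
        return set(self._children[term])

    def _topological_order(self) -> list[str]:
        """Parents-before-children order; raises ValueError on cycles."""
        ts = TopologicalSorter({t: set(p) for t, p in self.parents.items()})
        try:
            return list(ts.static_order())
        except CycleError as exc:
            raise ValueError(f"ontology contains a cycle: {exc.args[1]}") from exc

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including ``term`` itself."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        result = {term}
        for p in self.parents[term]:
            result |= self.ancestors(p)
        out = frozenset(result)
        self._ancestor_cache[term] = out
        return out


@dataclass
class AnnotationTable:
    """Protein -> GO term sets; the annotation corpus behind information content.

    ``corpus_size`` is the number of proteins with at least one annotation.
    """

    annotations: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.annotations = {p: frozenset(t) for p, t in self.annotations.items()}

    @property
    def corpus_size(self) -> int:
        return sum(1 for terms in self.annotations.values() if terms)

    def terms_of(self, protein: str) -> frozenset[str]:
        return self.annotations.get(protein, frozenset())

    def validate_against(self, dag: OntologyDAG) -> None:
        known = dag.terms
        for protein, terms in self.annotations.items():
            unknown = terms - known
            if unknown:
                raise ValueError(
                    f"protein {protein!r} annotated with unknown terms {sorted(unknown)[:5]}"
                )


def load_ontology_table(path) -> OntologyDAG:
    """Read a ``term TAB parent TAB aspect`` table; parent ``-`` marks a root."""
    parents: dict[str, set[str]] = {}
    aspect: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            term, parent, asp = fields[0], fields[1], fields[2]
            parents.setdefault(term, set())
            if parent != "-":
                parents[term].add(parent)
                parents.setdefault(parent, set())
            if term in aspect and aspect[term] != asp:
                raise ValueError(f"{path}: conflicting aspect for {term!r}")
            aspect[term] = asp
    # parents seen only on the right inherit the aspect of their first child
    for term in parents:
        if term not in aspect:
            child_aspects = {a for t, a in aspect.items() if term in parents.get(t, ())}
            aspect[term] = next(iter(child_aspects)) if child_aspects else "BP"
    return OntologyDAG({t: frozenset(p) for t, p in parents.items()}, aspect)


def write_ontology_table(dag: OntologyDAG, path) -> None:
    with open(path, "w") as handle:
        for term in sorted(dag.terms):
            ps = sorted(dag.parents[term]) or ["-"]
            for p in ps:
                handle.write(f"{term}\t{p}\t{dag.aspect[term]}\n")


def load_obo(path) -> OntologyDAG:
    """Read an OBO-format ontology (id / is_a / namespace stanzas)."""
    import obonet

    graph = obonet.read_obo(path)
    parents: dict[str, frozenset[str]] = {}
    aspect: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        # obonet stores is_a as edges child -> parent with key "is_a"
        ps = {v for _, v, k in graph.out_edges(term, keys=True) if k == "is_a"}
        parents[term] = frozenset(ps)
        ns = data.get("namespace", "biological_process")
        aspect[term] = _OBO_NAMESPACES.get(ns, ns)
    return OntologyDAG(parents, aspect)


def load_annotations(path) -> AnnotationTable:
    """Read a GAF-like ``protein TAB term [TAB aspect ...]`` table.

    Extra columns are tolerated and ignored; the aspect of a term is a
    property of the ontology, not of the annotation line.
    """
    annotations: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected at least 2 columns")
            annotations.setdefault(fields[0], set()).add(fields[1])
    return AnnotationTable({p: frozenset(t) for p, t in annotations.items()})


def write_annotations(ann: AnnotationTable, path) -> None:
    with open(path, "w") as handle:
        for protein in sorted(ann.annotations):
            for term in sorted(ann.annotations[protein]):
                handle.write(f"{protein}\t{term}\n")
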
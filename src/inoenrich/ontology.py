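"""Interaction-type ontology: parsing, traversal, keyword indexing.

The enrichment pipeline consumes a rooted DAG of molecular interaction
types (regulation, cleavage reaction, phosphorylation, ...).  Each term
may carry literature-mining keywords -- surface-form variants such as
``myristoylate / myristoylates / myristoylated`` -- attached through a
``has_literature_mining_keywords`` annotation.  Only the ``is_a``
subsumption hierarchy is modelled; interactor roles, pathway branches
and upper-level (BFO-style) alignment are irrelevant to the statistics
and are ignored.

Exchange format is a flat OBO-subset dialect, one ``[Term]`` stanza per
term::

    [Term]
    id: INO_0000140
    name: neutralization
    is_a: INO_0000002
    property_value: has_literature_mining_keywords "neutralize|neutralization"

``is_obsolete: true`` marks terms dropped at parse time.  IDs are
normalised to underscore form (``INO:0000140`` -> ``INO_0000140``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "InteractionTerm",
    "OntologyGraph",
    "KeywordIndex",
    "OntologyError",
    "parse_ontology",
    "serialize_ontology",
    "ancestors",
    "descendants",
    "build_keyword_index",
    "extract_subhierarchy",
]


class OntologyError(ValueError):
    """Raised for malformed ontology input (cycles, dangling IDs, ...)."""


def normalize_id(term_id: str) -> str:
    """Normalise a CURIE to underscore form: ``INO:0000140 -> INO_0000140``."""
    return term_id.strip().replace(":", "_")


@dataclass(frozen=True)
class InteractionTerm:
    """One node of the interaction-type ontology."""

    term_id: str
    label: str
    parent_ids: tuple[str, ...] = ()
    keywords: tuple[str, ...] = ()
    is_obsolete: bool = False


@dataclass
class OntologyGraph:
    """A rooted DAG of interaction-type terms (``is_a`` edges only)."""

    terms: dict[str, InteractionTerm]
    root_id: str
    # parent -> child edges; built once, reused for every traversal
    _dag: nx.DiGraph = field(init=False, repr=False, compare=False)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parent_ids:
                if p not in self.terms:
                    raise OntologyError(
                        f"dangling parent: term {t.term_id!r} lists unknown parent {p!r}"
                    )
                g.add_edge(p, t.term_id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"cyclic ontology: cycle through {cycle[0][0]!r}")
        if self.root_id not in self.terms:
            raise OntologyError(f"root term {self.root_id!r} not present")
        # every non-root term must reach the root along is_a
        reachable = set(nx.descendants(g, self.root_id)) | {self.root_id}
        orphans = set(self.terms) - reachable
        if orphans:
            raise OntologyError(
                f"term(s) not connected to root {self.root_id!r}: {sorted(orphans)}"
            )
        object.__setattr__(self, "_dag", g)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def children(self, term_id: str) -> set[str]:
        return set(self._dag.successors(term_id))

    def ancestors_of(self, term_id: str) -> frozenset[str]:
        """Strict ancestors of *term_id* (cached)."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id!r}")
        cached = self._ancestor_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.ancestors(self._dag, term_id))
            self._ancestor_cache[term_id] = cached
        return cached


@dataclass
class KeywordIndex:
    """Lowercase keyword string -> set of term IDs declaring it."""

    entries: dict[str, frozenset[str]]

    def __getitem__(self, keyword: str) -> frozenset[str]:
        return self.entries[keyword.lower()]

    def __contains__(self, keyword: str) -> bool:
        return keyword.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def keywords(self) -> Iterable[str]:
        return self.entries.keys()


# ---------------------------------------------------------------------------
# parsing / serialisation

_KEYWORD_PROPERTY = "has_literature_mining_keywords"


def _parse_stanzas(text: str) -> list[dict]:
    stanzas: list[dict] = []
    current: dict | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line == "[Term]":
            current = {"keywords": [], "parents": [], "obsolete": False}
            stanzas.append(current)
            continue
        if line.startswith("[") and line.endswith("]"):
            current = None  # non-Term stanza ([Typedef] etc.): skip
            continue
        if current is None:
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "id":
            current["id"] = normalize_id(value)
        elif key == "name":
            current["name"] = value
        elif key == "is_a":
            # strip trailing "! label" comments found in real OBO exports
            current["parents"].append(normalize_id(value.split("!")[0]))
        elif key == "is_obsolete":
            current["obsolete"] = value.lower() == "true"
        elif key == "property_value" and value.startswith(_KEYWORD_PROPERTY):
            quoted = value[len(_KEYWORD_PROPERTY):].strip()
            if not (quoted.startswith('"') and quoted.rstrip().endswith('"')):
                raise OntologyError(
                    f"line {lineno}: malformed keyword annotation: {raw!r}"
                )
            kws = quoted.strip().strip('"')
            current["keywords"].extend(
                k.strip().lower() for k in kws.split("|") if k.strip()
            )
    return stanzas


def parse_ontology(path: str | Path, root_id: str) -> OntologyGraph:
    """Parse an ontology file and restrict it to *root_id* and its descendants.

    Obsolete terms are excluded; keywords are lowercased and deduplicated
    (first occurrence order preserved).  Raises :class:`OntologyError` on a
    cycle (naming one member), a dangling parent (naming the missing ID),
    or an absent root.
    """
    root_id = normalize_id(root_id)
    text = Path(path).read_text(encoding="utf-8")
    terms: dict[str, InteractionTerm] = {}
    for st in _parse_stanzas(text):
        if "id" not in st:
            raise OntologyError("[Term] stanza without an id")
        if st["obsolete"]:
            continue
        tid = st["id"]
        if tid in terms:
            raise OntologyError(f"duplicate term id {tid!r}")
        seen: dict[str, None] = dict.fromkeys(st["keywords"])
        terms[tid] = InteractionTerm(
            term_id=tid,
            label=st.get("name", tid),
            parent_ids=tuple(dict.fromkeys(st["parents"])),
            keywords=tuple(seen),
        )
    if root_id not in terms:
        raise OntologyError(f"root term {root_id!r} not found in {path}")
    # restrict to the root's branch before the rooted-DAG validation, so
    # sibling branches in the file are simply ignored
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for t in terms.values():
        for p in t.parent_ids:
            if p not in terms:
                raise OntologyError(
                    f"dangling parent: term {t.term_id!r} lists unknown parent {p!r}"
                )
            g.add_edge(p, t.term_id)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyError(f"cyclic ontology: cycle through {cycle[0][0]!r}")
    keep = set(nx.descendants(g, root_id)) | {root_id}
    restricted = {
        tid: InteractionTerm(
            term_id=t.term_id,
            label=t.label,
            parent_ids=tuple(p for p in t.parent_ids if p in keep),
            keywords=t.keywords,
        )
        for tid, t in terms.items()
        if tid in keep
    }
    return OntologyGraph(terms=restricted, root_id=root_id)


def serialize_ontology(graph: OntologyGraph) -> str:
    """Render a graph back to the OBO-subset dialect (stable term order)."""
    out: list[str] = []
    for tid in sorted(graph.terms):
        t = graph.terms[tid]
        out.append("[Term]")
        out.append(f"id: {t.term_id}")
        out.append(f"name: {t.label}")
        for p in t.parent_ids:
            out.append(f"is_a: {p}")
        if t.keywords:
            joined = "|".join(t.keywords)
            out.append(f'property_value: {_KEYWORD_PROPERTY} "{joined}"')
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# traversal

def ancestors(graph: OntologyGraph, term_id: str) -> set[str]:
    """All strict ``is_a`` ancestors of *term_id* (root included, self excluded)."""
    return set(graph.ancestors_of(term_id))


def descendants(graph: OntologyGraph, term_id: str) -> set[str]:
    """All strict ``is_a`` descendants of *term_id*."""
    if term_id not in graph:
        raise KeyError(f"unknown term {term_id!r}")
    return set(nx.descendants(graph._dag, term_id))


def build_keyword_index(graph: OntologyGraph) -> KeywordIndex:
    """Invert the per-term keyword annotations into keyword -> term-set."""
    entries: dict[str, set[str]] = {}
    for t in graph.terms.values():
        for kw in t.keywords:
            entries.setdefault(kw, set()).add(t.term_id)
    return KeywordIndex({k: frozenset(v) for k, v in entries.items()})


def extract_subhierarchy(
    graph: OntologyGraph, seed_terms: Iterable[str]
) -> OntologyGraph:
    """Minimal subgraph containing the seeds plus their computed intermediates.

    Every term lying on some ``is_a`` path from a seed up to the root is
    retained, so the result is itself a rooted DAG; parent links are
    restricted to the kept set.  This mirrors how reported sub-hierarchies
    are completed with intermediate ancestors so that significant terms
    stay connected to the root.
    """
    seeds = {normalize_id(s) for s in seed_terms}
    unknown = seeds - set(graph.terms)
    if unknown:
        raise KeyError(f"unknown seed term(s): {sorted(unknown)}")
    keep: set[str] = set()
    for s in seeds:
        keep.add(s)
        keep |= graph.ancestors_of(s)
    keep.add(graph.root_id)
    sub = {
        tid: InteractionTerm(
            term_id=t.term_id,
            label=t.label,
            parent_ids=tuple(p for p in t.parent_ids if p in keep),
            keywords=t.keywords,
        )
        for tid, t in ((tid, graph.terms[tid]) for tid in keep)
    }
    return OntologyGraph(terms=sub, root_id=graph.root_id)


def labels(graph: OntologyGraph) -> Mapping[str, str]:
    """Convenience map term_id -> label."""
    return {tid: t.label for tid, t in graph.terms.items()}
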
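"""Term-annotated gene-pair networks with true-path propagation.

The counting unit of the enrichment test is the unique unordered gene
pair per interaction-type term.  A pair annotated to a term is
implicitly annotated to every ancestor of that term (true-path rule), so
a parent such as 'cleavage reaction' aggregates all its child types.
Distinct supporting documents are tracked per (term, pair) for the
"most frequent gene pair" report column only; they play no role in the
statistics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .ontology import OntologyGraph
from .tagging import InteractionRecord

__all__ = ["AnnotatedNetwork", "build_network", "subset_network", "write_network"]

Pair = tuple[str, str]


@dataclass
class AnnotatedNetwork:
    """term_id -> set of gene pairs (after propagation), plus the pair universe."""

    pairs_by_term: dict[str, set[Pair]] = field(default_factory=dict)
    universe: set[Pair] = field(default_factory=set)
    doc_count: dict[tuple[str, Pair], int] = field(default_factory=dict)

    def n_pairs(self, term_id: str) -> int:
        return len(self.pairs_by_term.get(term_id, ()))


def build_network(
    records: Iterable[InteractionRecord], graph: OntologyGraph
) -> AnnotatedNetwork:
    """Aggregate records into a propagated term -> pair-set map.

    Each record's pair is attached to every directly matched term and to
    every ancestor of it, up to the interaction root.  ``doc_count`` holds
    the number of distinct documents contributing (directly or through
    propagation) to each (term, pair); repeated sentences within one
    document count once.
    """
    docs: dict[tuple[str, Pair], set[str]] = {}
    pairs_by_term: dict[str, set[Pair]] = {}
    universe: set[Pair] = set()
    for rec in records:
        closure: set[str] = set()
        for tid in rec.term_ids:
            if tid not in graph:
                raise KeyError(f"record references unknown term {tid!r}")
            closure.add(tid)
            closure |= graph.ancestors_of(tid)
        universe.add(rec.gene_pair)
        for tid in closure:
            pairs_by_term.setdefault(tid, set()).add(rec.gene_pair)
            docs.setdefault((tid, rec.gene_pair), set()).add(rec.doc_id)
    return AnnotatedNetwork(
        pairs_by_term=pairs_by_term,
        universe=universe,
        doc_count={k: len(v) for k, v in docs.items()},
    )


def subset_network(
    records: Iterable[InteractionRecord],
    doc_ids: set[str],
    graph: OntologyGraph,
) -> AnnotatedNetwork:
    """Build the network restricted to records from the given documents."""
    return build_network((r for r in records if r.doc_id in doc_ids), graph)


def write_network(net: AnnotatedNetwork, path: str | Path) -> None:
    """TSV with header term_id, gene1, gene2, n_docs (one row per (term, pair))."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["term_id", "gene1", "gene2", "n_docs"])
        for tid in sorted(net.pairs_by_term):
            for pair in sorted(net.pairs_by_term[tid]):
                w.writerow([tid, pair[0], pair[1], net.doc_count[(tid, pair)]])
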
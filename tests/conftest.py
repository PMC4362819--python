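"""Shared fixtures: tiny hand-written ontologies and a domain lexicon."""

import random

import pytest
from hypothesis import settings

from inoenrich.ontology import (
    InteractionTerm,
    OntologyGraph,
    build_keyword_index,
    parse_ontology,
)
from inoenrich.tagging import GeneLexicon

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

# a small interaction branch containing the cleavage-type chain
# (mRNA cleavage is_a RNA cleavage is_a nucleic acid cleavage is_a
# cleavage reaction) plus keyword-annotated leaf terms
CLEAVAGE_OBO = """\
[Term]
id: INO_0000001
name: interaction
property_value: has_literature_mining_keywords "interacts|interact"

[Term]
id: MI_0194
name: cleavage reaction
is_a: INO_0000001
property_value: has_literature_mining_keywords "cleavage|cleaves"

[Term]
id: MI_0910
name: nucleic acid cleavage
is_a: MI_0194
property_value: has_literature_mining_keywords "nucleic acid cleavage"

[Term]
id: MI_0902
name: RNA cleavage
is_a: MI_0910
property_value: has_literature_mining_keywords "rna cleavage"

[Term]
id: MI_0571
name: mRNA cleavage
is_a: MI_0902
property_value: has_literature_mining_keywords "mrna cleavage"

[Term]
id: GO_0018377
name: protein myristoylation
is_a: INO_0000001
property_value: has_literature_mining_keywords "myristoylate|myristoylates|myristoylated|myristoylating|myristoylation"

[Term]
id: INO_0000140
name: neutralization
is_a: INO_0000001
property_value: has_literature_mining_keywords "neutralization|neutralize|neutralizes|neutralized"

[Term]
id: INO_0000190
name: impairment
is_a: INO_0000001
property_value: has_literature_mining_keywords "impaired|impairs|impairment"

[Term]
id: INO_0000999
name: retired interaction
is_a: INO_0000001
is_obsolete: true
"""

ROOT = "INO_0000001"


@pytest.fixture(scope="session")
def cleavage_path(tmp_path_factory):
    p = tmp_path_factory.mktemp("onto") / "cleavage.obo"
    p.write_text(CLEAVAGE_OBO)
    return p


@pytest.fixture(scope="session")
def cleavage_graph(cleavage_path):
    return parse_ontology(cleavage_path, ROOT)


@pytest.fixture(scope="session")
def cleavage_index(cleavage_graph):
    return build_keyword_index(cleavage_graph)


@pytest.fixture
def diamond_graph():
    """D is_a B, D is_a C, B is_a A, C is_a A."""
    terms = {
        "A": InteractionTerm("A", "a"),
        "B": InteractionTerm("B", "b", ("A",)),
        "C": InteractionTerm("C", "c", ("A",)),
        "D": InteractionTerm("D", "d", ("B", "C")),
    }
    return OntologyGraph(terms=terms, root_id="A")


@pytest.fixture(scope="session")
def cytokine_lexicon():
    return GeneLexicon(
        {
            "IL-12": "IL12A",
            "IL12A": "IL12A",
            "IFN-gamma": "IFNG",
            "IFNG": "IFNG",
            "CD4": "CD4",
            "TNF": "TNF",
        }
    )


def random_dag(rng: random.Random, n_terms: int) -> OntologyGraph:
    """Rooted random DAG with ids T00..; every non-root gets 1-2 earlier parents."""
    ids = [f"T{i:02d}" for i in range(n_terms)]
    terms = {ids[0]: InteractionTerm(ids[0], "root")}
    for i in range(1, n_terms):
        parents = {rng.choice(ids[:i])}
        if i > 1 and rng.random() < 0.4:
            parents.add(rng.choice(ids[:i]))
        terms[ids[i]] = InteractionTerm(ids[i], f"term {i}", tuple(sorted(parents)))
    return OntologyGraph(terms=terms, root_id=ids[0])
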
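"""Seeded synthetic ontologies, lexicons and corpora with planted enrichment.

The generator emulates the statistical structure the enrichment method
assumes: a background distribution of interaction-type usage over gene
pairs (Zipf-skewed, as term usage in literature is), and a concept
subset of documents in which selected terms are used at a multiple
("fold") of their background rate.  Sentences are unambiguous templates
("<GENE1> <keyword> <GENE2> in <context>.") so the dictionary tagger can
recover the ground truth almost perfectly; an optional hard mode emits
sentences carrying two interaction keywords, mimicking real abstracts
where e.g. a neutralization and an impairment keyword co-occur.

Scale: the real analysis behind this design ran over tens of millions
of abstracts with ~3e5 background gene pairs and ~6e3 concept pairs.
Defaults here keep the concept/background pair ratio (~2%) at a few
thousand background pairs, which is desk-scale yet large enough for the
planted effects to be recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ontology import InteractionTerm, OntologyGraph, serialize_ontology
from .tagging import GeneLexicon, InteractionRecord, SentenceUnit

__all__ = [
    "SimulationConfig",
    "SimulatedCorpus",
    "generate_ontology",
    "generate_lexicon",
    "generate_corpus",
    "write_bundle",
    "DEFAULT_BASE_VARIANTS",
]

DEFAULT_BASE_VARIANTS: tuple[str, ...] = (
    "vaccine",
    "vaccines",
    "vaccination",
    "vaccinated",
)
#: specific concept phrases that select documents without any base variant
DEFAULT_CONCEPT_TERMS: tuple[str, ...] = ("bcg immunization trial",)

_CONCEPT_CONTEXTS = (
    "a vaccine study",
    "a vaccination cohort",
    "bcg immunization trial subjects",
)
_BACKGROUND_CONTEXTS = (
    "a cell culture assay",
    "a mouse liver extract",
    "a yeast growth screen",
)
# words the pseudo-word generator must never emit (they appear in templates)
_RESERVED = {
    w
    for ctx in _CONCEPT_CONTEXTS + _BACKGROUND_CONTEXTS
    for w in ctx.split()
} | set(DEFAULT_BASE_VARIANTS) | {"in"}

ROOT_ID = "IT_0000001"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_terms: int = 20
    dag_density: float = 0.3
    n_genes: int = 120
    n_docs_whole: int = 2000
    concept_fraction: float = 0.02
    planted: tuple[tuple[str, float], ...] = ()
    n_pairs_whole: int = 5000
    zipf_exponent: float = 1.0
    hard_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if not (0 < self.concept_fraction <= 1):
            raise ValueError("concept_fraction must lie in (0, 1]")
        if not (0 <= self.dag_density <= 1):
            raise ValueError("dag_density must lie in [0, 1]")
        for tid, fold in self.planted:
            if fold <= 0:
                raise ValueError(f"planted fold for {tid} must be > 0")
        max_pairs = self.n_genes * (self.n_genes - 1) // 2
        if self.n_pairs_whole > max_pairs:
            raise ValueError(
                f"n_pairs_whole={self.n_pairs_whole} exceeds the "
                f"{max_pairs} distinct pairs of {self.n_genes} genes"
            )


# ---------------------------------------------------------------------------
# pseudo-word machinery (labels, keywords, gene symbols)

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def _pseudo_base(rng: np.random.Generator, taken: set[str]) -> str:
    """A unique pronounceable verb-like base, e.g. ``dovarute``."""
    while True:
        syll = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(3)
        )
        base = syll + "te"
        if base not in taken and base not in _RESERVED:
            taken.add(base)
            return base


def _inflections(base: str) -> list[str]:
    """Deterministic keyword variants of a verb base (cf. myristoylate/-ed/-ing)."""
    stem = base[:-1]  # drop trailing 'e'
    return [base, base + "s", base + "d", stem + "ing", stem + "ion"]


def generate_ontology(config: SimulationConfig) -> tuple[OntologyGraph, str]:
    """A rooted random DAG of interaction types with keyword annotations.

    Term ``i`` (in topological order) gets one uniformly chosen earlier
    parent, plus a second distinct parent with probability
    ``dag_density``.  Every term carries 2-5 inflected keyword variants
    of a unique pseudo-verb label.  Returns the graph and its
    OBO-dialect serialisation (byte-identical under a fixed seed).
    """
    rng = np.random.default_rng(config.seed)
    taken: set[str] = set()
    terms: dict[str, InteractionTerm] = {}
    ids = [f"IT_{i + 1:07d}" for i in range(config.n_terms)]
    for i, tid in enumerate(ids):
        base = _pseudo_base(rng, taken)
        if i == 0:
            terms[tid] = InteractionTerm(tid, "interaction", (), ("interacts",))
            continue
        n_kw = int(rng.integers(2, 6))
        kws = tuple(_inflections(base)[:n_kw])
        parents = [ids[int(rng.integers(i))]]
        if i >= 2 and rng.random() < config.dag_density:
            second = ids[int(rng.integers(i))]
            if second not in parents:
                parents.append(second)
        terms[tid] = InteractionTerm(tid, base[:-1] + "ion", tuple(parents), kws)
    graph = OntologyGraph(terms=terms, root_id=ROOT_ID)
    return graph, serialize_ontology(graph)


def generate_lexicon(config: SimulationConfig) -> tuple[GeneLexicon, str]:
    """Unique uppercase gene symbols (letters + trailing digit) with one
    hyphenated synonym each, e.g. ``KRTV2`` / ``KRTV-2``."""
    rng = np.random.default_rng(config.seed + 1_000_003)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    symbols: list[str] = []
    seen: set[str] = set()
    while len(symbols) < config.n_genes:
        stem = "".join(letters[rng.integers(26)] for _ in range(int(rng.integers(3, 6))))
        sym = stem + str(rng.integers(1, 10))
        if sym not in seen:
            seen.add(sym)
            symbols.append(sym)
    lines = ["symbol\tsynonyms"]
    entries: dict[str, str] = {}
    for sym in symbols:
        synonym = sym[:-1] + "-" + sym[-1]
        lines.append(f"{sym}\t{synonym}")
        entries[sym] = sym
        entries[synonym] = sym
    return GeneLexicon(entries), "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# corpus generation

@dataclass
class SimulatedCorpus:
    """A rendered corpus plus its generation ground truth."""

    sentences: list[SentenceUnit]
    truth: list[tuple[str, int, str, str, str]]  # doc, sent, gene1, gene2, term
    concept_doc_ids: set[str]
    base_variants: tuple[str, ...] = DEFAULT_BASE_VARIANTS
    concept_terms: tuple[str, ...] = DEFAULT_CONCEPT_TERMS
    term_probs: dict[str, float] = field(default_factory=dict)

    def corpus_tsv(self) -> str:
        rows = ["doc_id\tsent_id\ttext"]
        rows += [f"{s.doc_id}\t{s.sent_id}\t{s.text}" for s in self.sentences]
        return "\n".join(rows) + "\n"

    def truth_tsv(self) -> str:
        rows = ["doc_id\tsent_id\tgene1\tgene2\tterm_id"]
        rows += ["\t".join(map(str, r)) for r in self.truth]
        return "\n".join(rows) + "\n"

    def truth_records(self) -> list[InteractionRecord]:
        """Ground-truth interaction records (bypassing the text round trip)."""
        by_sent: dict[tuple[str, int, tuple[str, str]], set[str]] = {}
        for doc, sent, g1, g2, tid in self.truth:
            by_sent.setdefault((doc, sent, (g1, g2)), set()).add(tid)
        return [
            InteractionRecord(doc, sent, pair, frozenset(tids))
            for (doc, sent, pair), tids in sorted(by_sent.items())
        ]


def _term_distributions(
    config: SimulationConfig, graph: OntologyGraph
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(terms, background probs, concept probs) over non-root terms."""
    terms = sorted(t for t in graph.terms if t != graph.root_id)
    ranks = np.arange(1, len(terms) + 1, dtype=float)
    p = ranks ** -config.zipf_exponent
    p /= p.sum()
    base = dict(zip(terms, p))
    planted = dict(config.planted)
    unknown = set(planted) - set(terms)
    if unknown:
        raise ValueError(f"planted term(s) not in ontology: {sorted(unknown)}")
    q = np.array([base[t] * planted.get(t, 1.0) for t in terms])
    mass_planted = sum(base[t] * f for t, f in planted.items())
    if any(base[t] * f > 1 for t, f in planted.items()) or mass_planted > 1:
        raise ValueError("infeasible fold: fold x background probability exceeds 1")
    free = [i for i, t in enumerate(terms) if t not in planted]
    scale = (1.0 - mass_planted) / sum(q[free]) if free else 1.0
    q[free] *= scale
    return terms, p, q


def generate_corpus(
    config: SimulationConfig, graph: OntologyGraph, lexicon: GeneLexicon
) -> SimulatedCorpus:
    """Render a template-sentence corpus with planted concept-level shifts.

    Every background gene pair appears in exactly one sentence and is
    annotated with one interaction term drawn from a Zipf distribution;
    pairs of the concept subset draw the planted terms at ``fold`` times
    their background probability (others renormalised), so the observed
    enrichment fold of a planted leaf term converges to its target.
    """
    rng = np.random.default_rng(config.seed + 7_777_777)
    terms, p_bg, p_cc = _term_distributions(config, graph)
    symbols = sorted({v for v in lexicon.entries.values()})
    n_genes = len(symbols)
    # distinct unordered pairs, sampled without replacement via flat indices
    flat = rng.choice(n_genes * (n_genes - 1) // 2, config.n_pairs_whole, replace=False)
    tri = np.triu_indices(n_genes, k=1)
    pairs = [
        tuple(sorted((symbols[int(tri[0][f])], symbols[int(tri[1][f])])))
        for f in flat
    ]
    n_concept = max(1, round(config.concept_fraction * config.n_pairs_whole))
    n_cdocs = max(1, round(config.concept_fraction * config.n_docs_whole))
    n_bdocs = max(1, config.n_docs_whole - n_cdocs)
    cdocs = [f"C{i:06d}" for i in range(n_cdocs)]
    bdocs = [f"B{i:06d}" for i in range(n_bdocs)]

    kw_of = {t: graph.terms[t].keywords for t in terms}
    n_pairs = config.n_pairs_whole
    # all stochastic draws are vectorised up front so repeated simulation
    # runs (power / calibration loops) stay cheap
    t_draw = np.empty(n_pairs, dtype=int)
    t_draw[:n_concept] = rng.choice(len(terms), n_concept, p=p_cc)
    t_draw[n_concept:] = rng.choice(len(terms), n_pairs - n_concept, p=p_bg)
    doc_draw = np.empty(n_pairs, dtype=int)
    doc_draw[:n_concept] = rng.integers(len(cdocs), size=n_concept)
    doc_draw[n_concept:] = rng.integers(len(bdocs), size=n_pairs - n_concept)
    ctx_draw = rng.integers(len(_CONCEPT_CONTEXTS), size=n_pairs)
    kw_u = rng.random(n_pairs)
    hard_u = rng.random(n_pairs)
    t2_draw = np.empty(n_pairs, dtype=int)
    t2_draw[:n_concept] = rng.choice(len(terms), n_concept, p=p_cc)
    t2_draw[n_concept:] = rng.choice(len(terms), n_pairs - n_concept, p=p_bg)
    kw2_u = rng.random(n_pairs)

    sent_counter: dict[str, int] = {}
    sentences: list[SentenceUnit] = []
    truth: list[tuple[str, int, str, str, str]] = []
    for i, pair in enumerate(pairs):
        concept = i < n_concept
        tid = terms[t_draw[i]]
        doc = cdocs[doc_draw[i]] if concept else bdocs[doc_draw[i]]
        sid = sent_counter.get(doc, 0)
        sent_counter[doc] = sid + 1
        ctx_pool = _CONCEPT_CONTEXTS if concept else _BACKGROUND_CONTEXTS
        ctx = ctx_pool[ctx_draw[i] % len(ctx_pool)]
        kws = kw_of[tid]
        kw = kws[int(kw_u[i] * len(kws))]
        g1, g2 = pair
        extra_terms: list[str] = []
        other = terms[t2_draw[i]]
        if config.hard_mode and hard_u[i] < 0.3 and other != tid:
            kw2 = kw_of[other][int(kw2_u[i] * len(kw_of[other]))]
            text = f"{g1} {kw} and {kw2} {g2} in {ctx}."
            extra_terms.append(other)
        else:
            text = f"{g1} {kw} {g2} in {ctx}."
        sentences.append(SentenceUnit(doc, sid, text))
        truth.append((doc, sid, g1, g2, tid))
        for other in extra_terms:
            truth.append((doc, sid, g1, g2, other))
    used_docs = {s.doc_id for s in sentences}
    return SimulatedCorpus(
        sentences=sentences,
        truth=truth,
        concept_doc_ids=set(cdocs) & used_docs,
        term_probs=dict(zip(terms, p_bg)),
    )


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write ontology, lexicon, corpus, concept terms and ground truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, obo = generate_ontology(config)
    lexicon, lex_tsv = generate_lexicon(config)
    corpus = generate_corpus(config, graph, lexicon)
    paths = {
        "ontology": outdir / "ontology.obo",
        "lexicon": outdir / "lexicon.tsv",
        "corpus": outdir / "corpus.tsv",
        "concept_terms": outdir / "concept_terms.txt",
        "truth": outdir / "truth.tsv",
    }
    paths["ontology"].write_text(obo, encoding="utf-8")
    paths["lexicon"].write_text(lex_tsv, encoding="utf-8")
    paths["corpus"].write_text(corpus.corpus_tsv(), encoding="utf-8")
    paths["concept_terms"].write_text(
        "# specific concept phrases (base variants are CLI flags)\n"
        + "\n".join(corpus.concept_terms)
        + "\n",
        encoding="utf-8",
    )
    paths["truth"].write_text(corpus.truth_tsv(), encoding="utf-8")
    return paths
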
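"""Dictionary tagging of sentences: gene mentions, interaction keywords.

A sentence is tagged on two independent channels: gene symbols against a
lexicon of surface forms (HUGO-style symbols plus synonyms) and
interaction keywords against the ontology keyword index.  Matching is
case-insensitive, word-boundary anchored, longest-match-first with ties
broken leftmost; a token span is consumed by at most one match per
channel.  Tokens are maximal runs of ``[A-Za-z0-9-]`` so hyphenated
forms such as ``IL-12`` or ``IFN-gamma`` stay single tokens, matching
how gene symbols appear in abstracts.

Sentences carrying two or more distinct genes plus at least one
interaction keyword yield one :class:`InteractionRecord` per unordered
gene pair; these records are the raw material for network construction.
An optional externally-computed confidence score (e.g. from a sentence
classifier) can be attached and used to drop non-positive records.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ontology import KeywordIndex

__all__ = [
    "SentenceUnit",
    "GeneLexicon",
    "InteractionRecord",
    "LexiconError",
    "CorpusError",
    "tag_sentence",
    "extract_records",
    "filter_by_score",
    "select_concept_documents",
    "read_corpus",
    "read_lexicon",
    "read_concept_terms",
    "read_score_table",
    "write_records",
    "read_records",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9-]+")


class LexiconError(ValueError):
    """Raised when the gene lexicon is internally inconsistent."""


class CorpusError(ValueError):
    """Raised for malformed corpus input."""


@dataclass(frozen=True)
class SentenceUnit:
    doc_id: str
    sent_id: int
    text: str


@dataclass
class GeneLexicon:
    """Case-normalised surface form -> canonical (uppercase) gene symbol."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        self.entries = {k.lower(): v.upper() for k, v in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class InteractionRecord:
    """One extracted gene-pair interaction event.

    ``gene_pair`` is lexicographically ordered and never a self-pair;
    ``term_ids`` is the non-empty set of directly matched ontology terms.
    """

    doc_id: str
    sent_id: int
    gene_pair: tuple[str, str]
    term_ids: frozenset[str]
    score: float | None = None

    def __post_init__(self) -> None:
        a, b = self.gene_pair
        if a >= b:
            raise ValueError(f"gene pair not canonical: {self.gene_pair}")
        if not self.term_ids:
            raise ValueError("record with empty term_ids")


# ---------------------------------------------------------------------------
# matching

def _tokenize(text: str) -> list[tuple[str, int, int]]:
    """Lowercased tokens with character spans."""
    return [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _match_dictionary(
    tokens: Sequence[tuple[str, int, int]], phrases: Mapping[tuple[str, ...], object]
) -> list[tuple[int, int, object]]:
    """Greedy longest-match-first, left-to-right scan over token n-grams.

    Returns ``(start_token, n_tokens, value)`` triples; each token is
    consumed by at most one match.
    """
    if not phrases:
        return []
    max_len = max(len(k) for k in phrases)
    out: list[tuple[int, int, object]] = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for L in range(min(max_len, n - i), 0, -1):
            key = tuple(t[0] for t in tokens[i : i + L])
            if key in phrases:
                hit = (i, L, phrases[key])
                break
        if hit is not None:
            out.append(hit)
            i += hit[1]
        else:
            i += 1
    return out


def _phrase_map(surface_to_value: Mapping[str, object]) -> dict[tuple[str, ...], object]:
    return {
        tuple(t[0] for t in _tokenize(surface)): value
        for surface, value in surface_to_value.items()
        if surface.strip()
    }


def tag_sentence(
    sent: SentenceUnit, lex: GeneLexicon, index: KeywordIndex
) -> tuple[list[str], set[str]]:
    """Tag one sentence; returns (canonical gene mentions, matched term IDs).

    Gene mentions are deduplicated, order of first occurrence preserved.
    Keyword matches return the union of term IDs of every matched keyword
    (a keyword mapping to several interaction types contributes them all).
    """
    tokens = _tokenize(sent.text)
    genes: list[str] = []
    seen: set[str] = set()
    for _, _, sym in _match_dictionary(tokens, _cached_phrases(lex, lex.entries)):
        if sym not in seen:
            seen.add(sym)
            genes.append(sym)  # type: ignore[arg-type]
    term_ids: set[str] = set()
    for _, _, tids in _match_dictionary(tokens, _cached_phrases(index, index.entries)):
        term_ids |= tids  # type: ignore[arg-type]
    return genes, term_ids


def _cached_phrases(holder: object, surface_to_value: Mapping[str, object]):
    # compiled token-tuple map is cached on the lexicon/index instance
    cached = getattr(holder, "_compiled_phrases", None)
    if cached is None:
        cached = _phrase_map(surface_to_value)
        try:
            object.__setattr__(holder, "_compiled_phrases", cached)
        except (AttributeError, TypeError):
            pass
    return cached


def extract_records(
    sent: SentenceUnit, lex: GeneLexicon, index: KeywordIndex
) -> list[InteractionRecord]:
    """One record per unordered pair of distinct co-mentioned genes.

    Requires at least one matched interaction keyword; every record
    carries the full set of matched term IDs.  Scores are left unset.
    """
    genes, term_ids = tag_sentence(sent, lex, index)
    if len(genes) < 2 or not term_ids:
        return []
    tids = frozenset(term_ids)
    return [
        InteractionRecord(sent.doc_id, sent.sent_id, (g1, g2), tids)
        for g1, g2 in combinations(sorted(set(genes)), 2)
    ]


def filter_by_score(
    records: Iterable[InteractionRecord],
    score_table: Mapping[tuple[str, int, tuple[str, str]], float] | None = None,
) -> list[InteractionRecord]:
    """Attach external confidence scores and keep positively-scored records.

    Records with a table entry get that score; score <= 0 drops the
    record.  Records without an entry -- or all records when no table is
    supplied -- pass through unscored.
    """
    out: list[InteractionRecord] = []
    for rec in records:
        if score_table is None:
            out.append(rec)
            continue
        key = (rec.doc_id, rec.sent_id, rec.gene_pair)
        if key in score_table:
            s = float(score_table[key])
            if s > 0:
                out.append(replace(rec, score=s))
        else:
            out.append(rec)
    return out


def select_concept_documents(
    corpus: Iterable[SentenceUnit],
    base_variants: Sequence[str],
    concept_terms: Sequence[str] = (),
) -> set[str]:
    """Documents whose text mentions any base variant or specific concept term.

    Matching is case-insensitive and word-boundary anchored; multiword
    terms must appear as contiguous token sequences.  Selection is the
    union over both lists, so a document naming only a specific concept
    (e.g. a particular vaccine) is still selected.
    """
    phrases = {t.strip().lower() for t in (*base_variants, *concept_terms) if t.strip()}
    if not phrases:
        raise ValueError("empty union of concept match lists")
    keys = {tuple(t[0] for t in _tokenize(p)) for p in phrases}
    max_len = max(len(k) for k in keys)
    selected: set[str] = set()
    for sent in corpus:
        if sent.doc_id in selected:
            continue
        toks = [t[0] for t in _tokenize(sent.text)]
        for i in range(len(toks)):
            for L in range(1, min(max_len, len(toks) - i) + 1):
                if tuple(toks[i : i + L]) in keys:
                    selected.add(sent.doc_id)
                    break
            else:
                continue
            break
    return selected


# ---------------------------------------------------------------------------
# file formats

def read_corpus(path: str | Path) -> list[SentenceUnit]:
    """Read a sentence corpus: TSV (doc_id, sent_id, text) or JSONL."""
    path = Path(path)
    sents: list[SentenceUnit] = []
    seen: set[tuple[str, int]] = set()
    raw = path.read_text(encoding="utf-8")
    if path.suffix in {".jsonl", ".json"}:
        for lineno, line in enumerate(raw.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                sents.append(
                    SentenceUnit(str(obj["doc_id"]), int(obj["sent_id"]), obj["text"])
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSONL row: {exc}") from exc
    else:
        reader = csv.DictReader(io.StringIO(raw), delimiter="\t")
        if reader.fieldnames is None or not {"doc_id", "sent_id", "text"} <= set(
            reader.fieldnames
        ):
            raise CorpusError(f"{path}: expected header doc_id, sent_id, text")
        for lineno, row in enumerate(reader, start=2):
            try:
                if row["text"] is None:
                    raise ValueError("missing text column")
                sents.append(
                    SentenceUnit(row["doc_id"], int(row["sent_id"]), row["text"])
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise CorpusError(f"{path}:{lineno}: malformed row: {exc}") from exc
    for s in sents:
        if not s.text:
            raise CorpusError(f"{path}: empty sentence text at {s.doc_id}/{s.sent_id}")
        key = (s.doc_id, s.sent_id)
        if key in seen:
            raise CorpusError(f"{path}: duplicate sentence key {key}")
        seen.add(key)
    return sents


def read_lexicon(path: str | Path) -> GeneLexicon:
    """Read a gene lexicon TSV with header ``symbol, synonyms`` (pipe-joined).

    A surface form mapping to two canonical symbols is a load error.
    """
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "symbol" not in reader.fieldnames:
            raise LexiconError(f"{path}: expected header with a 'symbol' column")
        for row in reader:
            symbol = row["symbol"].strip().upper()
            if not symbol:
                continue
            surfaces = [symbol]
            syns = (row.get("synonyms") or "").strip()
            if syns:
                surfaces.extend(s.strip() for s in syns.split("|") if s.strip())
            for surf in surfaces:
                key = surf.lower()
                if entries.get(key, symbol) != symbol:
                    raise LexiconError(
                        f"surface form {surf!r} maps to both "
                        f"{entries[key]!r} and {symbol!r}"
                    )
                entries[key] = symbol
    return GeneLexicon(entries)


def read_concept_terms(path: str | Path) -> list[str]:
    """Plain text, one term per line; ``#`` comments and blanks skipped."""
    terms: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#")[0].strip()
        if line:
            terms.append(line.lower())
    return terms


def read_score_table(
    path: str | Path,
) -> dict[tuple[str, int, tuple[str, str]], float]:
    """TSV with header doc_id, sent_id, gene1, gene2, score."""
    table: dict[tuple[str, int, tuple[str, str]], float] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            g1, g2 = sorted((row["gene1"].upper(), row["gene2"].upper()))
            table[(row["doc_id"], int(row["sent_id"]), (g1, g2))] = float(row["score"])
    return table


def write_records(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Records TSV: doc_id, sent_id, gene1, gene2, term_ids (pipe-joined), score."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["doc_id", "sent_id", "gene1", "gene2", "term_ids", "score"])
        for r in records:
            w.writerow(
                [
                    r.doc_id,
                    r.sent_id,
                    r.gene_pair[0],
                    r.gene_pair[1],
                    "|".join(sorted(r.term_ids)),
                    "" if r.score is None else repr(r.score),
                ]
            )


def read_records(path: str | Path) -> list[InteractionRecord]:
    out: list[InteractionRecord] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                InteractionRecord(
                    doc_id=row["doc_id"],
                    sent_id=int(row["sent_id"]),
                    gene_pair=(row["gene1"], row["gene2"]),
                    term_ids=frozenset(row["term_ids"].split("|")),
                    score=float(row["score"]) if row.get("score") else None,
                )
            )
    return out
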
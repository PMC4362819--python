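"""Conservative per-term enrichment of a concept sub-network vs the whole network.

For each interaction-type term the 2x2 contingency table is

    ==================  ===================  =============
                        concept sub-network  whole network
    with the term       a                    A
    without the term    b                    B
    ==================  ===================  =============

where counts are unique annotated gene pairs after true-path
propagation, and the whole network *contains* the sub-network.  The
test is a one-sided Fisher's exact test with an EASE-style conservative
modification: for over-representation the evidence cell is shrunk to
``a - 1`` before the exact hypergeometric tail is summed, so that a
term supported by a single pair can never appear significant; for
under-representation the symmetric ``a + 1`` inflation is applied.
Tail sums are computed exactly in log space (no chi-square or normal
approximation).  Raw folds ``(a/(a+b)) / (A/(A+B))`` are computed from
unmodified counts; Benjamini-Hochberg correction runs across the set of
terms passing the minimum-pair filter, and a term is called
over-represented at BH p < alpha with fold >= the threshold (under:
fold <= its reciprocal).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .network import AnnotatedNetwork, Pair
from .ontology import OntologyGraph

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "build_table",
    "modified_fisher",
    "enrichment_fold",
    "bh_correct",
    "run_enrichment",
    "write_results",
    "hypergeom_sf_all",
    "hypergeom_cdf_all",
]

Direction = Literal["over", "under"]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of gene pairs with/without a term in sub and whole networks."""

    a: int
    b: int
    A: int
    B: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "A", "B"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a > self.A:
            raise ValueError("sub-network hits exceed whole-network hits (a > A)")
        if self.a + self.b > self.A + self.B:
            raise ValueError("sub-network total exceeds whole-network total")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    a: int
    b: int
    A: int
    B: int
    p_raw: float
    p_bh: float
    fold: float
    direction: Literal["over", "under", "none"]
    top_pair: Pair | None = None
    top_pair_docs: int | None = None


# ---------------------------------------------------------------------------
# exact hypergeometric tails in log space

_LGAMMA_CACHE: np.ndarray = gammaln(np.arange(2))


def _lgamma_table(up_to: int) -> np.ndarray:
    """gammaln(0..up_to), grown on demand (grid scans reuse it)."""
    global _LGAMMA_CACHE
    if len(_LGAMMA_CACHE) <= up_to:
        _LGAMMA_CACHE = gammaln(np.arange(max(up_to + 1, 2 * len(_LGAMMA_CACHE))))
    return _LGAMMA_CACHE


def _log_pmf_support(N: int, K: int, n: int) -> tuple[int, np.ndarray]:
    """Log hypergeometric pmf over the full support.

    X counts with-term pairs among ``n`` draws from a population of
    ``N`` with ``K`` successes.  Returns (xmin, log pmf for
    x = xmin..xmax).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric margins N={N}, K={K}, n={n}")
    xmin = max(0, n - (N - K))
    xmax = min(n, K)
    x = np.arange(xmin, xmax + 1)
    T = _lgamma_table(N + 2)
    logc = lambda nn, kk: T[nn + 1] - T[kk + 1] - T[nn - kk + 1]
    return xmin, logc(K, x) + logc(N - K, n - x) - logc(N, n)


def hypergeom_sf_all(N: int, K: int, n: int) -> tuple[int, np.ndarray]:
    """(xmin, P(X >= x) for every x in the support), exact log-space sums."""
    xmin, lp = _log_pmf_support(N, K, n)
    tail = np.logaddexp.accumulate(lp[::-1])[::-1]
    return xmin, np.exp(np.minimum(tail, 0.0))


def hypergeom_cdf_all(N: int, K: int, n: int) -> tuple[int, np.ndarray]:
    """(xmin, P(X <= x) for every x in the support)."""
    xmin, lp = _log_pmf_support(N, K, n)
    head = np.logaddexp.accumulate(lp)
    return xmin, np.exp(np.minimum(head, 0.0))


def _tail_prob(a: int, N: int, K: int, n: int, direction: Direction) -> float:
    if direction == "over":
        xmin, sf = hypergeom_sf_all(N, K, n)
        if a <= xmin:
            return 1.0
        if a > xmin + len(sf) - 1:
            return 0.0
        return float(sf[a - xmin])
    xmin, cdf = hypergeom_cdf_all(N, K, n)
    if a >= xmin + len(cdf) - 1:
        return 1.0
    if a < xmin:
        return 0.0
    return float(cdf[a - xmin])


def modified_fisher(
    table: ContingencyTable,
    direction: Direction,
    modified: bool = True,
    sided: Literal["one", "two"] = "one",
) -> float:
    """Exact Fisher p-value with the conservative evidence-cell shift.

    For ``direction='over'`` the sub-network with-term cell is replaced
    by ``max(a - 1, 0)``; for ``'under'`` by ``a + 1`` capped at
    ``min(a + b, A)``.  The 2x2 margins are recomputed from the shifted
    cell and the one-sided exact tail is summed (``P(X >= a')`` for
    over, ``P(X <= a')`` for under).  ``modified=False`` disables the
    shift; ``sided='two'`` instead sums the probability of every table
    at most as probable as the observed one (diagnostic only).
    """
    if direction not in ("over", "under"):
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    a, b, A, B = table.a, table.b, table.A, table.B
    if modified:
        if direction == "over":
            a = max(a - 1, 0)
        else:
            a = min(a + 1, min(table.a + table.b, A))
    N = a + b + A + B
    K = a + A
    n = a + b
    if sided == "two":
        xmin, lp = _log_pmf_support(N, K, n)
        if not (xmin <= a <= xmin + len(lp) - 1):
            return 1.0
        cutoff = lp[a - xmin] + 1e-7  # relative pmf tolerance for fp ties
        mask = lp <= cutoff
        from scipy.special import logsumexp

        return float(min(np.exp(logsumexp(lp[mask])), 1.0))
    return _tail_prob(a, N, K, n, direction)


def enrichment_fold(table: ContingencyTable) -> float | None:
    """Raw fold (a/(a+b)) / (A/(A+B)); None when the term is absent (A=0)."""
    if table.A == 0:
        return None
    if table.a + table.b == 0 or table.A + table.B == 0:
        raise ValueError("empty network in fold computation")
    return (table.a / (table.a + table.b)) / (table.A / (table.A + table.B))


def bh_correct(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    if len(p_values) == 0:
        raise ValueError("empty p-value list")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


class EmptySubnetworkError(ValueError):
    pass


def build_table(
    term_id: str, sub: AnnotatedNetwork, whole: AnnotatedNetwork
) -> ContingencyTable:
    """Contingency counts for one term (sub-network vs whole network)."""
    if not sub.universe:
        raise EmptySubnetworkError("empty sub-network")
    a = sub.n_pairs(term_id)
    A = whole.n_pairs(term_id)
    return ContingencyTable(
        a=a, b=len(sub.universe) - a, A=A, B=len(whole.universe) - A
    )


def _top_pair(
    term_id: str, sub: AnnotatedNetwork
) -> tuple[Pair | None, int | None]:
    pairs = sub.pairs_by_term.get(term_id)
    if not pairs:
        return None, None
    best = min(pairs, key=lambda p: (-sub.doc_count[(term_id, p)], p))
    return best, sub.doc_count[(term_id, best)]


_DIR_ORDER = {"over": 0, "under": 1, "none": 2}


def run_enrichment(
    sub: AnnotatedNetwork,
    whole: AnnotatedNetwork,
    graph: OntologyGraph,
    min_pairs: int = 5,
    alpha: float = 0.05,
    fold_threshold: float = 2.0,
    modified: bool = True,
    sided: Literal["one", "two"] = "one",
) -> list[EnrichmentResult]:
    """Test every term with >= *min_pairs* sub-network pairs.

    The candidate direction follows the raw fold (over if fold > 1,
    under otherwise); BH correction runs across the tested set only.
    Final calls additionally require the fold threshold, so a term can
    be significant by p yet called 'none' on effect size.  Results are
    sorted over-calls first, then under, then none, by adjusted p.
    """
    tested = sorted(
        t for t in sub.pairs_by_term if t in graph and sub.n_pairs(t) >= min_pairs
    )
    tables: list[ContingencyTable] = []
    folds: list[float] = []
    p_raws: list[float] = []
    kept: list[str] = []
    for t in tested:
        tab = build_table(t, sub, whole)
        fold = enrichment_fold(tab)
        if fold is None:  # term absent from whole network: cannot be assessed
            continue
        cand: Direction = "over" if fold > 1 else "under"
        kept.append(t)
        tables.append(tab)
        folds.append(fold)
        p_raws.append(modified_fisher(tab, cand, modified=modified, sided=sided))
    if not kept:
        return []
    p_bhs = bh_correct(p_raws)
    results: list[EnrichmentResult] = []
    for t, tab, fold, p_raw, p_bh in zip(kept, tables, folds, p_raws, p_bhs):
        if p_bh < alpha and fold >= fold_threshold:
            direction = "over"
        elif p_bh < alpha and fold <= 1.0 / fold_threshold:
            direction = "under"
        else:
            direction = "none"
        pair, ndocs = _top_pair(t, sub)
        results.append(
            EnrichmentResult(
                term_id=t,
                a=tab.a,
                b=tab.b,
                A=tab.A,
                B=tab.B,
                p_raw=p_raw,
                p_bh=p_bh,
                fold=fold,
                direction=direction,
                top_pair=pair,
                top_pair_docs=ndocs,
            )
        )
    results.sort(key=lambda r: (_DIR_ORDER[r.direction], r.p_bh, r.term_id))
    return results


def write_results(
    results: Iterable[EnrichmentResult],
    path: str | Path,
    labels: Mapping[str, str] | None = None,
) -> None:
    """Results TSV mirroring the report layout (fold, BH p, top gene pair)."""
    labels = labels or {}
    header = [
        "term_id", "label", "direction", "a", "sub_total", "A", "whole_total",
        "fold", "p_raw", "p_bh", "top_pair", "top_pair_docs",
    ]
    lines = ["\t".join(header)]
    for r in results:
        lines.append(
            "\t".join(
                [
                    r.term_id,
                    labels.get(r.term_id, ""),
                    r.direction,
                    str(r.a),
                    str(r.a + r.b),
                    str(r.A),
                    str(r.A + r.B),
                    f"{r.fold:.6g}",
                    f"{r.p_raw:.6g}",
                    f"{r.p_bh:.6g}",
                    "" if r.top_pair is None else f"{r.top_pair[0]}_{r.top_pair[1]}",
                    "" if r.top_pair_docs is None else str(r.top_pair_docs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
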
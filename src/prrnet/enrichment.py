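"""Hypergeometric over-representation analysis with FDR control.

Tests whether a query gene list overlaps each category of a gene-set
collection (e.g. KEGG pathways or GO terms in GMT format) more than
expected under uniform sampling from a gene universe. The raw p-value is
the hypergeometric upper tail P(X >= k); p-values are adjusted across all
tested categories with the Benjamini-Hochberg step-up procedure.

Two effect-size columns are reported per category: the enrichment ratio
R = k / (n*K/N) (observed over expected overlap, the value enrichment
servers usually label "OR"), and the conditional odds ratio of the
underlying 2x2. Both are emitted because published tables are often
ambiguous about which one they print.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "read_gmt",
    "hypergeometric_upper_tail",
    "bh_adjust",
    "enrich",
    "enrichment_frame",
]


def _norm(symbol: str) -> str:
    return " ".join(str(symbol).split()).upper()


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against.

    Every member of every set lies in the universe; by default the universe
    is the union of all annotated genes (the reference-set behavior of
    enrichment servers when no explicit background is given).
    """

    sets: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]


def read_gmt(
    source: str | IO[str],
    universe: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Parse a GMT stream/string: category_id <tab> description <tab> genes...

    With an explicit ``universe``, set members outside it are dropped; the
    default universe is the union of all set members.
    """
    text = source if isinstance(source, str) else source.read()
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {lineno}: need id, description, members")
        cid = parts[0].strip()
        if cid in sets:
            raise ValueError(f"duplicate category id {cid!r} at line {lineno}")
        members = frozenset(_norm(g) for g in parts[2:] if g.strip())
        if members:
            sets[cid] = (parts[1].strip(), members)
    if universe is not None:
        uni = frozenset(_norm(g) for g in universe)
        sets = {
            cid: (name, members & uni)
            for cid, (name, members) in sets.items()
            if members & uni
        }
    else:
        uni = frozenset().union(*(m for _, m in sets.values())) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=uni)


@dataclass(frozen=True, slots=True)
class EnrichmentRow:
    """One tested category: overlap, effect sizes, raw and adjusted p."""

    category_id: str
    name: str
    overlap_genes: frozenset[str]
    k: int  # overlap size
    n: int  # query size within the universe
    K: int  # category size
    N: int  # universe size
    enrichment_ratio: float
    odds_ratio: float
    p_raw: float
    p_adjusted: float


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space.

    k observed overlap, K category size, n draws (query size), N universe.
    """
    if not (0 <= k <= min(n, K) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    upper = min(n, K)
    support = np.arange(k, upper + 1)
    logpmf = hypergeom.logpmf(support, N, K, n)
    return float(min(np.exp(logsumexp(logpmf)), 1.0))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending-sorted p-values,
    clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def enrich(
    query: Iterable[str], collection: GeneSetCollection
) -> list[EnrichmentRow]:
    """Over-representation of a gene list in every category it touches.

    Categories with no overlap are omitted; BH adjustment runs across all
    categories with k >= 1. Rows come back sorted by adjusted then raw p.
    """
    query_in = frozenset(_norm(g) for g in query) & collection.universe
    if not query_in:
        raise ValueError(
            "query is disjoint from the collection universe "
            f"(universe size {len(collection.universe)}); check symbol conventions"
        )
    n, N = len(query_in), len(collection.universe)
    tested = []
    for cid, (name, members) in collection.sets.items():
        overlap = query_in & members
        if not overlap:
            continue
        k, K = len(overlap), len(members)
        expected = n * K / N
        ratio = k / expected
        denom = (n - k) * (K - k)
        odds = float("inf") if denom == 0 else k * (N - K - n + k) / denom
        tested.append(
            (cid, name, overlap, k, K, hypergeometric_upper_tail(k, K, n, N), ratio, odds)
        )
    adjusted = bh_adjust([t[5] for t in tested])
    rows = [
        EnrichmentRow(
            category_id=cid,
            name=name,
            overlap_genes=frozenset(overlap),
            k=k,
            n=n,
            K=K,
            N=N,
            enrichment_ratio=ratio,
            odds_ratio=odds,
            p_raw=p,
            p_adjusted=q,
        )
        for (cid, name, overlap, k, K, p, ratio, odds), q in zip(tested, adjusted)
    ]
    rows.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.category_id))
    return rows


def enrichment_frame(rows: Sequence[EnrichmentRow]):
    """Enrichment results as a DataFrame mirroring published table columns."""
    import pandas as pd

    return pd.DataFrame.from_records(
        [
            {
                "category_id": r.category_id,
                "name": r.name,
                "genes_in_category": ", ".join(sorted(r.overlap_genes)),
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "OR": r.enrichment_ratio,
                "odds_ratio": r.odds_ratio,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
            }
            for r in rows
        ],
        columns=[
            "category_id",
            "name",
            "genes_in_category",
            "k",
            "n",
            "K",
            "N",
            "OR",
            "odds_ratio",
            "p_raw",
            "p_adjusted",
        ],
    )
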
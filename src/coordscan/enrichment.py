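"""Over-representation testing of a gene list against GMT gene-set collections.

Hypergeometric upper-tail p-values (computed in log space via scipy's
survival function) with Benjamini–Hochberg step-up q-values. The background
universe is caller-supplied; by convention it is the set of genes that
survived variance filtering in the expression matrix — the universe the
correlation screen actually saw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    """Raised for malformed gene-set input or inconsistent counts."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Mapping term id → (description, member gene ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]
    source: str = ""

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise EnrichmentError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    description: str
    k: int  # overlap of query with the set, within background
    K: int  # set size within background
    n: int  # query size within background
    N: int  # background size
    p_value: float
    q_value: float


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: term \\t description \\t member genes..."""
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise EnrichmentError(f"{path.name} is empty")
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise EnrichmentError(
                f"{path.name}:{lineno}: expected at least 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        term, description = fields[0], fields[1]
        if term in sets:
            raise EnrichmentError(f"{path.name}:{lineno}: duplicate term id {term!r}")
        members = [g for g in fields[2:] if g]
        deduped = tuple(dict.fromkeys(members))
        if len(deduped) < len(members):
            logger.info(
                "%s:%d: removed %d duplicate member(s) in set %s",
                path.name, lineno, len(members) - len(deduped), term,
            )
        sets[term] = (description, deduped)
    return GeneSetCollection(sets=sets, source=path.name)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N):
        raise EnrichmentError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N} "
            "(need 0 <= k <= min(K, n) <= N)"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the pmf in log space internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise EnrichmentError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise EnrichmentError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.minimum(q_sorted, 1.0, out=q_sorted)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich(
    query: Sequence[str],
    background: Sequence[str],
    collection: GeneSetCollection,
    min_overlap: int = 2,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` within ``background``.

    Sets are intersected with the background before counting; only sets with
    overlap >= ``min_overlap`` are tested and reported. Results are sorted by
    ascending p with a deterministic tie-break on term id. Invariant to the
    ordering of ``query``.
    """
    bg = set(str(g) for g in background)
    if not bg:
        raise EnrichmentError("empty background")
    q = set(str(g) for g in query) & bg
    if not q:
        raise EnrichmentError("query is empty after intersection with background")
    N = len(bg)
    n = len(q)

    tested: list[tuple[str, str, int, int]] = []
    for term in sorted(collection.sets):
        description, members = collection.sets[term]
        in_bg = set(members) & bg
        K = len(in_bg)
        k = len(in_bg & q)
        if k >= min_overlap:
            tested.append((term, description, k, K))
    if not tested:
        return []

    p_values = [hypergeometric_tail(k, K, n, N) for _, _, k, K in tested]
    q_values = bh_fdr(p_values)
    results = [
        EnrichmentResult(term, desc, k, K, n, N, p, qv)
        for (term, desc, k, K), p, qv in zip(tested, p_values, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
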
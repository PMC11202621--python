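"""Gene-set enrichment statistics.

Two engines:

* a 2x2 chi-squared test with Yates continuity correction for the
  aging-gene question (rows: in the aging list or not; columns: bearing a
  somatic mutation or not), with the correction clamped at |O-E| so that
  it never over-corrects small deviations;
* a generic over-representation test (hypergeometric upper tail) over a
  user-supplied gene-set collection, with Benjamini-Hochberg FDR across
  sets. Defaults follow standard web-tool settings: adjusted p < 0.01 and
  a minimum overlap of two genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateTableError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table; rows: in list / not, columns: mutation-bearing / not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigurationError("contingency cells must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class EnrichmentStatResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    n_set: int
    n_overlap: int
    p_value: float
    adjusted_p: float
    significant: bool


def build_contingency(
    n_total: int, n_set: int, n_query: int, n_overlap: int
) -> ContingencyTable:
    """2x2 table from overlap margins.

    a = overlap; b = query outside the set; c = set outside the query;
    d = everything else.  Infeasible margins (any negative cell) raise.
    """
    a = n_overlap
    b = n_query - n_overlap
    c = n_set - n_overlap
    d = n_total - n_set - n_query + n_overlap
    if min(a, b, c, d) < 0:
        raise ConfigurationError(
            f"infeasible margins: total={n_total} set={n_set} "
            f"query={n_query} overlap={n_overlap}"
        )
    return ContingencyTable(a=a, b=b, c=c, d=d)


def chisq_yates(table: ContingencyTable) -> EnrichmentStatResult:
    """Chi-squared test with Yates continuity correction on a 2x2 table.

    statistic = sum over cells of (|O-E| - min(0.5, |O-E|))^2 / E, with E
    from the margin products; the clamp at |O-E| means the correction never
    overshoots when observed and expected nearly coincide.  df = 1.
    """
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise DegenerateTableError("zero margin in 2x2 table")
    expected = np.outer(row, col) / n
    diff = np.abs(obs - expected)
    corrected = diff - np.minimum(0.5, diff)
    statistic = float((corrected**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return EnrichmentStatResult(statistic=statistic, df=1, p_value=p)


def hypergeom_overrep(
    n_total: int, n_set: int, n_query: int, n_overlap: int
) -> float:
    """P(X >= n_overlap), X ~ Hypergeometric(n_total, n_set, n_query)."""
    build_contingency(n_total, n_set, n_query, n_overlap)  # feasibility check
    if n_overlap == 0:
        return 1.0
    # sf(k-1) is the upper tail P(X >= k); scipy evaluates it stably.
    return float(stats.hypergeom.sf(n_overlap - 1, n_total, n_set, n_query))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ConfigurationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _normalize(symbols: Iterable[str]) -> set[str]:
    return {s.strip().casefold() for s in symbols if s and s.strip()}


def enrich_gene_sets(
    query_genes: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    background_genes: Iterable[str],
    alpha: float = 0.01,
    min_overlap: int = 2,
) -> list[EnrichmentResult]:
    """Over-representation of the query in every set of the collection.

    Gene identity is by case-insensitive symbol after whitespace trimming;
    sets are intersected with the background before testing, and query
    symbols outside the background are dropped with a log message.  One
    hypergeometric upper-tail p per set, BH-adjusted across all tested
    sets; a set is significant when adjusted_p < alpha and the overlap has
    at least ``min_overlap`` genes.  Sorted by adjusted p, ties by name.
    """
    background = _normalize(background_genes)
    if not background:
        raise ConfigurationError("empty background gene list")
    query = _normalize(query_genes)
    outside = query - background
    if outside:
        logger.info("dropping %d query genes outside the background", len(outside))
        query &= background
    names = sorted(collection)
    n_total, n_query = len(background), len(query)
    rows = []
    for name in names:
        members = _normalize(collection[name]) & background
        overlap = len(members & query)
        p = hypergeom_overrep(n_total, len(members), n_query, overlap)
        rows.append((name, len(members), overlap, p))
    adjusted = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(
            set_name=name,
            n_set=n_set,
            n_overlap=overlap,
            p_value=p,
            adjusted_p=float(adj),
            significant=bool(adj < alpha and overlap >= min_overlap),
        )
        for (name, n_set, overlap, p), adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.set_name))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "n_set": [r.n_set for r in results],
            "n_overlap": [r.n_overlap for r in results],
            "p": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "significant": [r.significant for r in results],
        }
    )


def aging_overlap_test(
    n_total: int, n_set: int, n_query: int, n_overlap: int
) -> tuple[ContingencyTable, EnrichmentStatResult, float]:
    """Contingency table, Yates chi-squared, and the overlap percentage.

    The percentage is n_overlap / n_query * 100 (share of mutation-bearing
    genes that are in the aging list).
    """
    table = build_contingency(n_total, n_set, n_query, n_overlap)
    result = chisq_yates(table)
    pct = 100.0 * n_overlap / n_query if n_query else float("nan")
    return table, result, pct
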
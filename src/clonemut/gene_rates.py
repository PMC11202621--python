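"""Per-gene mutation counts and rates.

A candidate site is assigned to every gene whose genomic span contains
its position; the per-gene mutation rate ("Frequency") is the mutation
count divided by the gene's span length (end - start + 1), in mutations
per bp. Reported rates are formatted to 3 significant figures in
scientific notation; full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError
from .somatic_filter import CandidateSet
from .variant_io import GeneModel, SiteKey


@dataclass
class MutationRateRecord:
    gene_id: str
    symbol: str
    chrom: str
    length: int
    count: int
    frequency: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigurationError(f"gene {self.gene_id}: non-positive length")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.frequency != self.count / self.length:
            raise ValueError("frequency must equal count/length exactly")

    @property
    def frequency_3sf(self) -> str:
        """Frequency formatted to 3 significant figures, e.g. '3.23e-03'."""
        return f"{self.frequency:.2e}"


def assign_to_genes(
    candidates: CandidateSet, genes: Sequence[GeneModel]
) -> tuple[dict[str, list[SiteKey]], int]:
    """Map gene_id -> candidate sites whose position falls in the gene span.

    A site in several overlapping genes is assigned to each of them.
    Returns the assignment and the count of intergenic candidates.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        # IntervalTree is half-open; [start, end] inclusive -> [start, end+1)
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start, gene.end + 1, gene.gene_id
        )
    assignment: dict[str, list[SiteKey]] = {g.gene_id: [] for g in genes}
    intergenic = 0
    for key, site in candidates.sites.items():
        tree = trees.get(site.chrom)
        hits = tree[site.pos] if tree is not None else set()
        if not hits:
            intergenic += 1
            continue
        for iv in sorted(hits, key=lambda iv: iv.data):
            assignment[iv.data].append(key)
    return assignment, intergenic


def mutation_rates(
    assignment: Mapping[str, Sequence[SiteKey]],
    genes: Sequence[GeneModel],
    min_count: int = 2,
) -> list[MutationRateRecord]:
    """Rate records for genes with >= min_count candidate mutations.

    Sorted by frequency descending, ties broken by symbol for determinism.
    """
    if min_count < 0:
        raise ConfigurationError("min_count must be >= 0")
    by_id = {g.gene_id: g for g in genes}
    records = []
    for gene_id, sites in assignment.items():
        count = len(sites)
        if count < min_count:
            continue
        gene = by_id[gene_id]
        records.append(
            MutationRateRecord(
                gene_id=gene.gene_id,
                symbol=gene.symbol,
                chrom=gene.chrom,
                length=gene.length,
                count=count,
                frequency=count / gene.length,
            )
        )
    records.sort(key=lambda r: (-r.frequency, r.symbol))
    return records


def top_n(records: Sequence[MutationRateRecord], n: int) -> list[MutationRateRecord]:
    """First n records of a rate-sorted list (all records when n exceeds it)."""
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    return list(records[:n])


def rates_frame(records: Sequence[MutationRateRecord]) -> pd.DataFrame:
    """Rate table with columns Gene, Chr, Length, Count, Frequency."""
    return pd.DataFrame(
        {
            "Gene": [r.symbol for r in records],
            "Chr": [r.chrom for r in records],
            "Length": [r.length for r in records],
            "Count": [r.count for r in records],
            "Frequency": [r.frequency_3sf for r in records],
        }
    )
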
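"""Consensus vitamin D target gene selection across filtered DE datasets.

Each dataset is reduced to a gene set by one of three filtering
strategies — every adjusted-p-significant gene, the union of the three
top-N ranking lists (basal activity, fold change, p-value), or an
externally supplied membership list (e.g. a SOM-filtered set).  Genes
present in at least k of the n sets form the consensus; the full Venn
partition over the sets is kept for reporting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .io_model import DERecord, ParameterError

STRATEGY_NAMES = ("unfiltered_significant", "top_n_union", "external_list")


@dataclass(frozen=True)
class FilterStrategy:
    """How one dataset's DE table is reduced to a gene set."""

    name: str
    top_n: int | None = None
    alpha: float | None = None
    list_path: str | None = None

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ParameterError(f"unknown filter strategy {self.name!r}")
        if self.name == "top_n_union" and not self.top_n:
            raise ParameterError("top_n_union strategy requires top_n")
        if self.name == "unfiltered_significant" and self.alpha is None:
            raise ParameterError("unfiltered_significant strategy requires alpha")
        if self.name == "external_list" and not self.list_path:
            raise ParameterError("external_list strategy requires list_path")


@dataclass(frozen=True)
class VennPartition:
    """Disjoint regions of a Venn diagram over up to 8 gene sets.

    Keys are bit-string signatures over the input sets in their given
    order ('1' = member); values are the gene ids exclusive to that
    region.
    """

    region_membership: Mapping[str, frozenset[str]]

    def counts(self) -> dict[str, int]:
        return {sig: len(genes) for sig, genes in sorted(self.region_membership.items())}


def filter_unfiltered_significant(records: Sequence[DERecord], alpha: float) -> set[str]:
    """Genes whose adjusted p-value is below ``alpha``."""
    return {r.gene_id for r in records if r.padj < alpha}


def filter_top_n_union(records: Sequence[DERecord], n: int) -> set[str]:
    """Union of the top-``n`` genes by basal activity, by fold change and
    by significance.

    Basal and log2 fold change rank descending, the (raw) p-value
    ascending; ties at rank ``n`` break lexicographically on gene id so
    the result is order-independent.  When fewer than ``n`` genes exist,
    every gene makes every list.
    """
    if n < 1:
        raise ParameterError("top_n must be >= 1")
    out: set[str] = set()
    for key in (
        lambda r: (-r.basal, r.gene_id),
        lambda r: (-r.log2fc, r.gene_id),
        lambda r: (r.pvalue, r.gene_id),
    ):
        out.update(r.gene_id for r in sorted(records, key=key)[:n])
    return out


def k_of_n_consensus(sets: Sequence[set[str]], k: int) -> set[str]:
    """Genes present in at least ``k`` of the input sets."""
    if not 1 <= k <= len(sets):
        raise ParameterError(f"k={k} out of range for {len(sets)} sets")
    support: Counter[str] = Counter()
    for s in sets:
        support.update(s)
    return {g for g, c in support.items() if c >= k}


def support_counts(sets: Sequence[set[str]]) -> dict[str, int]:
    """Number of sets each gene of the union appears in."""
    support: Counter[str] = Counter()
    for s in sets:
        support.update(s)
    return dict(support)


def venn_partition(sets: Sequence[set[str]]) -> VennPartition:
    """Assign every gene of the union to its exclusive Venn region."""
    if len(sets) > 8:
        raise ParameterError("venn_partition supports at most 8 sets")
    regions: dict[str, set[str]] = {}
    union = set().union(*sets) if sets else set()
    for gene in union:
        sig = "".join("1" if gene in s else "0" for s in sets)
        regions.setdefault(sig, set()).add(gene)
    return VennPartition({sig: frozenset(g) for sig, g in regions.items()})


def apply_strategy(records: Sequence[DERecord], strategy: FilterStrategy) -> set[str]:
    if strategy.name == "unfiltered_significant":
        return filter_unfiltered_significant(records, strategy.alpha)
    if strategy.name == "top_n_union":
        return filter_top_n_union(records, strategy.top_n)
    # external_list: one gene id per line, comments allowed
    genes = set()
    for line in Path(strategy.list_path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line.split("\t")[0])
    return genes


def consensus_targets(
    tables: Mapping[str, Sequence[DERecord]],
    strategies: Mapping[str, FilterStrategy],
    k: int,
) -> tuple[set[str], VennPartition, dict[str, int]]:
    """Filter every dataset, form the k-of-n consensus and the Venn partition.

    Returns ``(consensus genes, partition, per-gene support counts)``;
    dataset order (and hence signature order) follows the ``tables``
    mapping's iteration order.
    """
    missing = set(tables) - set(strategies)
    if missing:
        raise ParameterError(f"no strategy for datasets {sorted(missing)}")
    sets = [apply_strategy(tables[ds], strategies[ds]) for ds in tables]
    return k_of_n_consensus(sets, k), venn_partition(sets), support_counts(sets)
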
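"""Join consensus, epigenome, transcriptome and curation into per-gene
reports and cross-tabulations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_model import (
    CurationRecord,
    EnhancerCall,
    ParameterError,
    TranscriptomeClass,
    report_row,
)


@dataclass(frozen=True)
class IntegratedGeneReport:
    """One gene's joined epigenome + transcriptome + curation record."""

    gene_id: str
    consensus_support: int
    enhancer: EnhancerCall | None
    transcriptome: TranscriptomeClass | None
    curation: CurationRecord | None


@dataclass(frozen=True)
class CrossTab:
    rows: tuple[str, ...]
    cols: tuple[str, ...]
    counts: Mapping[tuple[str, str], int]

    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, row: str, col: str) -> int:
        return self.counts.get((str(row), str(col)), 0)

    def to_dict(self) -> dict:
        return {
            "rows": list(self.rows),
            "cols": list(self.cols),
            "counts": {f"{r}|{c}": n for (r, c), n in sorted(self.counts.items())},
        }


def apply_curation(
    genes: set[str], curation: Sequence[CurationRecord]
) -> tuple[set[str], set[str]]:
    """Keep genes whose curation verdict is ``keep``.

    Returns (kept genes, genes without any curation record).  Uncovered
    genes are retained — absence of curation is not a dismissal — and
    reported with a warning so the caller can flag them as NA.
    """
    verdicts = {c.gene_id: c.verdict for c in curation}
    uncovered = {g for g in genes if g not in verdicts}
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} gene(s) without curation record kept with verdict NA",
            stacklevel=2,
        )
    kept = {g for g in genes if verdicts.get(g, "keep") == "keep"}
    return kept, uncovered


def _unique_by_gene(items: Iterable, what: str) -> dict[str, object]:
    out: dict[str, object] = {}
    for item in items:
        if item.gene_id in out:
            raise ParameterError(f"duplicate gene {item.gene_id!r} in {what}")
        out[item.gene_id] = item
    return out


def build_reports(
    genes: Sequence[str],
    support: Mapping[str, int],
    enhancer_calls: Sequence[EnhancerCall],
    transcriptome: Sequence[TranscriptomeClass],
    curation: Sequence[CurationRecord],
) -> list[IntegratedGeneReport]:
    """One report per gene, joined on gene id.

    ``genes`` fixes the row set and order (typically the curated
    consensus list, sorted).  A gene missing from a stage gets NA fields
    for that stage, with a warning.
    """
    enh = _unique_by_gene(enhancer_calls, "enhancer calls")
    trx = _unique_by_gene(transcriptome, "transcriptome classes")
    cur = _unique_by_gene(curation, "curation records")
    reports = []
    for g in genes:
        for stage, table in (("enhancer", enh), ("transcriptome", trx)):
            if g not in table:
                warnings.warn(f"{g}: no {stage} result, fields set to NA", stacklevel=2)
        reports.append(
            IntegratedGeneReport(
                gene_id=g,
                consensus_support=int(support.get(g, 0)),
                enhancer=enh.get(g),
                transcriptome=trx.get(g),
                curation=cur.get(g),
            )
        )
    return reports


@dataclass(frozen=True)
class AnalysisResult:
    """Everything the end-to-end analysis produces."""

    consensus_genes: set[str]
    venn_counts: dict[str, int]
    support: Mapping[str, int]
    kept_genes: set[str]
    enhancer_calls: Sequence[EnhancerCall]
    transcriptome: Sequence[TranscriptomeClass]
    reports: Sequence[IntegratedGeneReport]


def run_analysis(
    anchors,
    peaks,
    timecourse_profiles,
    curation: Sequence[CurationRecord],
    de_tables,
    strategies,
    cfg,
) -> AnalysisResult:
    """Full pipeline: consensus -> curation -> enhancer profiling ->
    time-course classification -> integrated per-gene reports.

    Tertials are computed within the curated gene set, mirroring the
    within-shortlist categorization of the reference analysis.
    """
    from .consensus import consensus_targets
    from .enhancer_profiling import profile_genes
    from .timecourse import classify_transcriptome

    consensus_set, partition, support = consensus_targets(
        de_tables, strategies, cfg.consensus_k
    )
    kept, _uncovered = apply_curation(consensus_set, curation)
    ordered = sorted(kept)
    anchor_map = {a.gene_id: a for a in anchors}
    calls = profile_genes([anchor_map[g] for g in ordered if g in anchor_map], peaks, cfg)
    profiles = [p for p in timecourse_profiles if p.gene_id in kept]
    classes = classify_transcriptome(profiles, cfg) if len(profiles) >= 3 else []
    reports = build_reports(ordered, support, list(calls.values()), classes, curation)
    return AnalysisResult(
        consensus_genes=consensus_set,
        venn_counts=partition.counts(),
        support=support,
        kept_genes=kept,
        enhancer_calls=list(calls.values()),
        transcriptome=classes,
        reports=reports,
    )


def default_strategies(de_tables, cfg) -> dict:
    """One unfiltered-significance strategy (padj < alpha) per dataset."""
    from .consensus import FilterStrategy

    return {
        ds: FilterStrategy("unfiltered_significant", alpha=cfg.alpha)
        for ds in de_tables
    }


def cross_tab(
    reports: Sequence[IntegratedGeneReport], row_field: str, col_field: str
) -> CrossTab:
    """Contingency counts of two report fields over genes where both are
    defined (NA rows are excluded)."""
    counts: dict[tuple[str, str], int] = {}
    rows: list[str] = []
    cols: list[str] = []
    for r in reports:
        flat = report_row(r)
        if row_field not in flat or col_field not in flat:
            raise ParameterError(f"unknown report field {row_field!r} or {col_field!r}")
        rv, cv = str(flat[row_field]), str(flat[col_field])
        if rv == "NA" or cv == "NA":
            continue
        counts[(rv, cv)] = counts.get((rv, cv), 0) + 1
        if rv not in rows:
            rows.append(rv)
        if cv not in cols:
            cols.append(cv)
    return CrossTab(tuple(sorted(rows)), tuple(sorted(cols)), counts)
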
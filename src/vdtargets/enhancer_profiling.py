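"""Per-gene VDR enhancer architecture from epigenome peak tracks.

For every gene the four peak tracks (VDR ChIP-seq, H3K27ac, H3K4me3,
chromatin accessibility) are queried 1 Mb up- and downstream of the TSS.
A super-enhancer is called when at least three VDR binding sites lie
within a 20 kb stretch, at least one of them is a strong persistent (P)
or transient (T) site, and the H3K27ac mark is continuous across the
whole stretch.  When no such cluster exists, the strong P/T site closest
to the TSS is reported as a single enhancer.  Enhancer and TSS regions
are flagged ligand-dependent when any overlapping peak responds
significantly to 1,25(OH)2D3 in at least one assay, and each gene is
placed in one of four epigenome classes:

    1  super-enhancer, ligand-dependent      3  single enhancer, dependent
    2  super-enhancer, not dependent         4  single enhancer, not dependent
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .io_model import (
    EnhancerCall,
    GeneAnchor,
    ParameterError,
    Peak,
    PipelineConfig,
    RecordError,
    SITE_CLASS_ORDER,
    VDR,
    sort_peaks,
)

Region = tuple[int, int]


@dataclass(frozen=True)
class StitchedCluster:
    """A qualifying group of VDR sites stitched into one super-enhancer."""

    sites: tuple[Peak, ...]
    span: Region  # first-site start to last-site end, half-open
    has_strong_PT: bool
    h3k27ac_continuous: bool


def query_window(peaks: list[Peak], anchor: GeneAnchor, radius: int) -> list[Peak]:
    """All peaks overlapping ``[tss - radius, tss + radius)`` on the
    anchor's chromosome, sorted."""
    if radius <= 0:
        raise ParameterError("radius must be positive")
    on_chrom = [p for p in peaks if p.chrom == anchor.chrom]
    if not on_chrom:
        warnings.warn(f"no peaks on chromosome {anchor.chrom!r}", stacklevel=2)
        return []
    lo = max(0, anchor.tss - radius)
    hi = anchor.tss + radius
    tree = IntervalTree.from_tuples((p.start, p.end, i) for i, p in enumerate(on_chrom))
    hits = [on_chrom[iv.data] for iv in tree.overlap(lo, hi)]
    return sort_peaks(hits)


def _is_strong_pt(p: Peak) -> bool:
    return p.strength == "strong" and p.site_class in ("P", "T")


def assign_strength(vdr_peaks: list[Peak], quantile: float) -> list[Peak]:
    """Label unannotated VDR sites strong/weak by a per-condition score
    quantile; sites with an explicit strength pass through unchanged."""
    if not 0 < quantile < 1:
        raise ParameterError("quantile must be in (0, 1)")
    vdr = [p for p in vdr_peaks if p.assay == VDR]
    thresholds: dict[str, float] = {}
    for cond in {p.condition for p in vdr}:
        scores = [p.score for p in vdr if p.condition == cond]
        thresholds[cond] = float(np.quantile(scores, quantile))
    out = []
    for p in vdr:
        if p.strength is not None:
            out.append(p)
        else:
            label = "strong" if p.score >= thresholds[p.condition] else "weak"
            out.append(
                Peak(
                    chrom=p.chrom,
                    start=p.start,
                    end=p.end,
                    name=p.name,
                    score=p.score,
                    strand=p.strand,
                    assay=p.assay,
                    condition=p.condition,
                    site_class=p.site_class,
                    strength=label,
                    diff_pvalue=p.diff_pvalue,
                )
            )
    return out


def merge_intervals(intervals: list[Region], max_gap: int) -> list[Region]:
    """Union of intervals after bridging gaps of at most ``max_gap`` bp."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def h3k27ac_continuity(span: Region, h3k27ac: list[Peak], max_gap: int) -> bool:
    """True when the gap-merged H3K27ac coverage contains ``span`` entirely."""
    intervals = [(p.start, p.end) for p in h3k27ac if p.assay == "H3K27ac"]
    for s, e in merge_intervals(intervals, max_gap):
        if s <= span[0] and e >= span[1]:
            return True
    return False


def call_super_enhancer(
    vdr_in_window: list[Peak],
    h3k27ac: list[Peak],
    cfg: PipelineConfig,
    tss: int,
) -> StitchedCluster | None:
    """Find the qualifying VDR site cluster nearest the TSS, if any.

    A candidate cluster is the set of VDR sites fully contained in a span
    running from one site's start to another's end, with the span extent
    at most ``se_window_bp``.  Restricting to containment-closed site
    sets loses no calls: any qualifying subset of sites has the same span
    as its containment closure, which also qualifies.  Among qualifying
    spans the one whose midpoint is nearest the TSS wins; ties break on
    (span start, span end).
    """
    sites = sorted(
        (p for p in vdr_in_window if p.assay == VDR), key=lambda p: (p.start, p.end)
    )
    n = len(sites)
    if n < cfg.se_min_sites:
        return None
    starts = [p.start for p in sites]
    ends = [p.end for p in sites]
    candidates: dict[Region, tuple[Peak, ...]] = {}
    for i in range(n):
        for j in range(n):
            if ends[j] <= starts[i] or ends[j] - starts[i] > cfg.se_window_bp:
                continue
            members = [
                p for p in sites if p.start >= starts[i] and p.end <= ends[j]
            ]
            if len(members) < cfg.se_min_sites:
                continue
            span = (min(p.start for p in members), max(p.end for p in members))
            if span in candidates or span[1] - span[0] > cfg.se_window_bp:
                continue
            if not any(_is_strong_pt(p) for p in members):
                continue
            if not h3k27ac_continuity(span, h3k27ac, cfg.h3k27ac_max_gap_bp):
                continue
            candidates[span] = tuple(members)
    if not candidates:
        return None
    best = min(
        candidates,
        key=lambda sp: (abs((sp[0] + sp[1]) / 2.0 - tss), sp[0], sp[1]),
    )
    return StitchedCluster(
        sites=candidates[best],
        span=best,
        has_strong_PT=True,
        h3k27ac_continuous=True,
    )


def select_single_enhancer(vdr_in_window: list[Peak], anchor: GeneAnchor) -> Peak | None:
    """The strong persistent/transient VDR site closest to the TSS.

    Equidistant ties prefer the upstream (lower-coordinate) site, then
    the lower start.  Returns None when no strong P/T site exists.
    """
    eligible = [p for p in vdr_in_window if p.assay == VDR and _is_strong_pt(p)]
    if not eligible:
        return None
    return min(
        eligible,
        key=lambda p: (
            abs(p.midpoint - anchor.tss),
            0 if p.midpoint < anchor.tss else 1,
            p.start,
        ),
    )


def constellation_label(sites: list[Peak] | tuple[Peak, ...]) -> str:
    """Site-class codes joined by '-', ordered P < T < 24 with repeats kept."""
    classes = []
    for p in sites:
        if p.site_class is None:
            raise RecordError(f"VDR site {p.name!r} has no site class")
        classes.append(p.site_class)
    return "-".join(sorted(classes, key=SITE_CLASS_ORDER.__getitem__))


def region_ligand_dependency(region: Region, peaks: list[Peak], alpha: float) -> bool:
    """True when any ligand-condition peak of any assay overlapping the
    region responds significantly (diff_pvalue < alpha) to treatment."""
    lo, hi = region
    for p in peaks:
        if p.condition != "ligand" or p.diff_pvalue is None:
            continue
        if p.start < hi and p.end > lo and p.diff_pvalue < alpha:
            return True
    return False


def distance_to_tss(
    region: tuple[str, int, int], anchor: GeneAnchor, tss_window: int
) -> float:
    """Enhancer-TSS distance in kb (one decimal); 0.0 for regions
    overlapping the TSS window (direct TSS binding)."""
    chrom, start, end = region
    if chrom != anchor.chrom:
        raise ParameterError(
            f"region on {chrom!r} but gene {anchor.gene_id} on {anchor.chrom!r}"
        )
    lo, hi = anchor.tss - tss_window, anchor.tss + tss_window
    if start < hi and end > lo:
        return 0.0
    midpoint = (start + end) / 2.0
    return round(abs(midpoint - anchor.tss) / 1000.0, 1)


def classify_epigenome(call: EnhancerCall) -> int | None:
    """Four-class mapping over (super/single) x (ligand-dependent or not)."""
    if call.kind == "none":
        warnings.warn(f"{call.gene_id}: no enhancer call, class undefined", stacklevel=2)
        return None
    if call.kind == "super":
        return 1 if call.enhancer_ligand_dependent else 2
    return 3 if call.enhancer_ligand_dependent else 4


def profile_gene(
    anchor: GeneAnchor, peaks: list[Peak], cfg: PipelineConfig
) -> EnhancerCall:
    """Full enhancer characterization of one gene.

    ``peaks`` is the combined (all-assay) track; the TSS-region
    dependency is always evaluated, even for genes without an enhancer
    call.
    """
    window = query_window(peaks, anchor, cfg.search_radius_bp)
    vdr = assign_strength([p for p in window if p.assay == VDR], cfg.strength_quantile)
    h3k = [p for p in window if p.assay == "H3K27ac"]
    tss_region = (max(0, anchor.tss - cfg.tss_window_bp), anchor.tss + cfg.tss_window_bp)
    tss_dep = region_ligand_dependency(tss_region, window, cfg.alpha)

    cluster = call_super_enhancer(vdr, h3k, cfg, anchor.tss)
    if cluster is not None:
        kind, members, span = "super", cluster.sites, cluster.span
    else:
        single = select_single_enhancer(vdr, anchor)
        if single is None:
            return EnhancerCall(
                gene_id=anchor.gene_id, kind="none", tss_ligand_dependent=tss_dep
            )
        kind, members, span = "single", (single,), (single.start, single.end)

    enh_dep = region_ligand_dependency(span, window, cfg.alpha)
    region = (anchor.chrom, span[0], span[1])
    call = EnhancerCall(
        gene_id=anchor.gene_id,
        kind=kind,
        member_sites=members,
        region=region,
        constellation=constellation_label(members),
        distance_kb=distance_to_tss(region, anchor, cfg.tss_window_bp),
        enhancer_ligand_dependent=enh_dep,
        tss_ligand_dependent=tss_dep,
        epigenome_class=None,
    )
    return EnhancerCall(
        **{**call.__dict__, "epigenome_class": classify_epigenome(call)}
    )


def profile_genes(
    anchors: list[GeneAnchor], peaks: list[Peak], cfg: PipelineConfig
) -> dict[str, EnhancerCall]:
    return {a.gene_id: profile_gene(a, peaks, cfg) for a in anchors}
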
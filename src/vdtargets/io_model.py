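"""Domain types, file readers/writers and shared configuration.

All genomic coordinates are 0-based, half-open ``[start, end)`` — the BED
convention — both internally and on disk.  Transcription start sites (TSS)
are single 0-based positions.

The on-disk formats are deliberately plain text:

* differential-expression (DE) tables: TSV with DESeq2-style headers,
* peak tracks: BED6 plus five extra columns
  (``assay condition site_class strength diff_pvalue``),
* TSS anchors: 4-column TSV (``gene_id chrom tss strand``) or BED6,
* time courses: TSV with expression at 0/2.5/4/24 h and per-time p-values,
* integrated reports: TSV plus a JSON sidecar carrying the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

VDR = "VDR"
ASSAYS = frozenset({"VDR", "H3K27ac", "H3K4me3", "accessibility"})
CONDITIONS = frozenset({"ligand", "solvent"})
SITE_CLASSES = frozenset({"P", "T", "24"})
STRENGTHS = frozenset({"strong", "weak"})

# VDR temporal occupancy classes ordered as printed in enhancer
# constellations: persistent < transient < 24-h-only.
SITE_CLASS_ORDER = {"P": 0, "T": 1, "24": 2}


class TableFormatError(ValueError):
    """A mandatory column is missing or a file is structurally malformed."""


class RecordError(ValueError):
    """A single record violates a field-level invariant."""


class ParameterError(ValueError):
    """An operation was called with out-of-range parameters."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression statistics in one dataset.

    ``basal`` is the normalized expression of the solvent control (the
    DESeq2 baseMean), ``log2fc`` the 24 h vs control log2 fold change.
    """

    gene_id: str
    dataset_id: str
    basal: float
    log2fc: float
    pvalue: float
    padj: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise RecordError("gene_id must be non-empty")
        if self.basal < 0:
            raise RecordError(f"{self.gene_id}: basal must be >= 0")
        for name in ("pvalue", "padj"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) and not math.isnan(v):
                raise RecordError(f"{self.gene_id}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class GeneAnchor:
    """A gene's TSS position used to center all window queries."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise RecordError(f"{self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise RecordError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class Peak:
    """A genomic interval from one of the four epigenome assays.

    ``site_class`` (persistent / transient / 24-h-only VDR occupancy) and
    ``strength`` are inherited from the upstream VDR ChIP-seq analysis;
    ``diff_pvalue`` is the significance of the peak's response to
    1,25(OH)2D3 treatment, ``None`` when untested (treated as not
    significant).
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    assay: str = VDR
    condition: str = "ligand"
    site_class: str | None = None
    strength: str | None = None
    diff_pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise RecordError(
                f"{self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.assay not in ASSAYS:
            raise RecordError(f"unknown assay {self.assay!r}")
        if self.condition not in CONDITIONS:
            raise RecordError(f"unknown condition {self.condition!r}")
        if self.site_class is not None:
            if self.assay != VDR:
                raise RecordError(
                    f"site_class={self.site_class!r} set on non-VDR assay {self.assay!r}"
                )
            if self.site_class not in SITE_CLASSES:
                raise RecordError(f"unknown site_class {self.site_class!r}")
        if self.strength is not None and self.strength not in STRENGTHS:
            raise RecordError(f"unknown strength {self.strength!r}")
        if self.diff_pvalue is not None and not (0.0 <= self.diff_pvalue <= 1.0):
            raise RecordError(f"diff_pvalue={self.diff_pvalue} outside [0, 1]")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def sort_key(self) -> tuple:
        return (
            self.chrom,
            self.start,
            self.end,
            self.assay,
            self.condition,
            self.name,
            self.site_class or "",
            self.strength or "",
        )


def sort_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    """Sort by (chrom, start, ...); total key makes order input-independent."""
    return sorted(peaks, key=Peak.sort_key)


@dataclass(frozen=True)
class EnhancerCall:
    """Per-gene enhancer architecture derived from the peak tracks.

    ``kind`` distinguishes a super-enhancer (>= 3 VDR sites within the
    stitching window), the closest strong single enhancer, or no call.
    ``constellation`` joins the member site classes, e.g. ``"T-T-24"``.
    ``epigenome_class`` is 1..4 over (super/single) x (ligand-dependent or
    not), ``None`` when ``kind == "none"``.
    """

    gene_id: str
    kind: str  # super | single | none
    member_sites: tuple[Peak, ...] = ()
    region: tuple[str, int, int] | None = None
    constellation: str = ""
    distance_kb: float = float("nan")
    enhancer_ligand_dependent: bool = False
    tss_ligand_dependent: bool = False
    epigenome_class: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("super", "single", "none"):
            raise RecordError(f"unknown enhancer kind {self.kind!r}")
        if self.kind == "super" and len(self.member_sites) < 3:
            raise RecordError(f"{self.gene_id}: super-enhancer needs >= 3 sites")
        if self.kind == "single" and len(self.member_sites) != 1:
            raise RecordError(f"{self.gene_id}: single enhancer needs exactly 1 site")


@dataclass(frozen=True)
class TimecourseProfile:
    """Expression of one gene at 0 / 2.5 / 4 / 24 h with p-values vs basal."""

    gene_id: str
    expr: Mapping[float, float]
    pval: Mapping[float, float]

    TIMES = (0.0, 2.5, 4.0, 24.0)

    def __post_init__(self) -> None:
        missing = [t for t in self.TIMES if t not in self.expr]
        if missing:
            raise RecordError(f"{self.gene_id}: missing time points {missing}")
        if any(v < 0 for v in self.expr.values()):
            raise RecordError(f"{self.gene_id}: negative expression")

    @property
    def fc24(self) -> float:
        """24 h vs basal fold change; inf when basal is zero but 24 h is not."""
        e0, e24 = self.expr[0.0], self.expr[24.0]
        if e0 > 0:
            return e24 / e0
        return float("inf") if e24 > 0 else float("nan")

    @property
    def p24(self) -> float:
        return self.pval[24.0]


@dataclass(frozen=True)
class TranscriptomeClass:
    """Primary/secondary flag, tertials and steepness group for one gene."""

    gene_id: str
    primary: bool
    tertial_basal: str
    tertial_fc: str
    tertial_p: str
    group: int

    def __post_init__(self) -> None:
        for t in (self.tertial_basal, self.tertial_fc, self.tertial_p):
            if t not in ("top", "mid", "low"):
                raise RecordError(f"unknown tertial {t!r}")
        if self.group not in (1, 2, 3):
            raise RecordError(f"group must be 1, 2 or 3, got {self.group}")


VERDICTS = frozenset(
    {"keep", "dismiss_metabolic", "dismiss_non_immune", "dismiss_unknown"}
)
LOCATIONS = frozenset({"plasma_membrane", "secreted", "cytoplasm", "nucleus"})


@dataclass(frozen=True)
class CurationRecord:
    """A literature-curation verdict for one candidate gene."""

    gene_id: str
    verdict: str
    functional_group: str = ""
    location: str | None = None

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise RecordError(f"unknown verdict {self.verdict!r}")
        if self.location is not None and self.location not in LOCATIONS:
            raise RecordError(f"unknown location {self.location!r}")


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline.

    Defaults encode the published thresholds: top-100 ranking lists,
    4-of-5 consensus, p < 0.05 significance, >= 3 VDR sites within 20 kb
    for a super-enhancer, a +-1 Mb search radius around the TSS and a
    0.75 score quantile for labelling unannotated VDR sites "strong".
    ``group_theta_low``/``group_theta_high`` are the late-steepness
    thresholds (log2 of the 4 h -> 24 h expression ratio) separating the
    three transcriptome response groups.
    """

    top_n: int = 100
    consensus_k: int = 4
    alpha: float = 0.05
    se_window_bp: int = 20_000
    se_min_sites: int = 3
    h3k27ac_max_gap_bp: int = 1_000
    tss_window_bp: int = 1_000
    search_radius_bp: int = 1_000_000
    strength_quantile: float = 0.75
    group_theta_low: float = 0.3
    group_theta_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "top_n",
            "consensus_k",
            "alpha",
            "se_window_bp",
            "se_min_sites",
            "h3k27ac_max_gap_bp",
            "tss_window_bp",
            "search_radius_bp",
            "strength_quantile",
            "group_theta_low",
            "group_theta_high",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"config field {name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise TableFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_DE_ALIASES = {
    "gene_id": ("gene_id", "gene", "symbol"),
    "basal": ("basal", "baseMean", "basemean"),
    "log2fc": ("log2fc", "log2FoldChange", "log2foldchange"),
    "pvalue": ("pvalue", "pval", "p_value"),
    "padj": ("padj", "p_adj", "qvalue"),
}


def _resolve_de_columns(
    header: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for canon, aliases in _DE_ALIASES.items():
        if column_map and canon in column_map:
            candidates: tuple[str, ...] = (column_map[canon],)
        else:
            candidates = aliases
        hit = next((c for c in candidates if c in header), None)
        if hit is None:
            raise TableFormatError(
                f"DE table is missing mandatory column {canon!r} "
                f"(accepted headers: {', '.join(candidates)})"
            )
        resolved[canon] = hit
    return resolved


def read_de_table(
    path: str | Path,
    dataset_id: str,
    column_map: Mapping[str, str] | None = None,
) -> list[DERecord]:
    """Read a DESeq2-style TSV into :class:`DERecord` objects.

    Rows with an empty gene id are dropped; a duplicated gene within the
    table raises, because (gene, dataset) must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_de_columns(list(df.columns), column_map)
    records: list[DERecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        gene = row[cols["gene_id"]]
        if gene is None or (isinstance(gene, float) and math.isnan(gene)) or gene == "":
            continue
        gene = str(gene)
        if gene in seen:
            raise RecordError(
                f"{path}: gene {gene!r} duplicated within dataset {dataset_id!r}"
            )
        seen.add(gene)
        stats = {}
        for canon in ("basal", "log2fc", "pvalue", "padj"):
            raw = row[cols[canon]]
            try:
                stats[canon] = float(raw)
            except (TypeError, ValueError) as exc:
                raise RecordError(
                    f"{path} line {idx + 2}: non-numeric {canon} value {raw!r}"
                ) from exc
        records.append(DERecord(gene_id=gene, dataset_id=dataset_id, **stats))
    return records


def write_de_table(records: Sequence[DERecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "baseMean": r.basal,
                "log2FoldChange": r.log2fc,
                "pvalue": r.pvalue,
                "padj": r.padj,
            }
            for r in records
        ],
        columns=["gene_id", "baseMean", "log2FoldChange", "pvalue", "padj"],
    )
    df.to_csv(path, sep="\t", index=False)


_PEAK_NCOL = 11  # BED6 + assay, condition, site_class, strength, diff_pvalue


def read_peaks(path: str | Path) -> list[Peak]:
    """Read a BED6+5 peak track; returns peaks sorted by (chrom, start)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < _PEAK_NCOL:
                raise TableFormatError(
                    f"{path} line {lineno}: expected {_PEAK_NCOL} columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4]) if fields[4] != "." else 0.0
                diff = fields[10]
                peaks.append(
                    Peak(
                        chrom=fields[0],
                        start=start,
                        end=end,
                        name=fields[3],
                        score=score,
                        strand=fields[5],
                        assay=fields[6],
                        condition=fields[7],
                        site_class=None if fields[8] == "NA" else fields[8],
                        strength=None if fields[9] == "NA" else fields[9],
                        diff_pvalue=None if diff == "NA" else float(diff),
                    )
                )
            except (ValueError, RecordError) as exc:
                if isinstance(exc, RecordError):
                    raise RecordError(f"{path} line {lineno}: {exc}") from exc
                raise RecordError(f"{path} line {lineno}: {exc}") from exc
    return sort_peaks(peaks)


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sort_peaks(peaks):
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        repr(p.score) if p.score else "0.0",
                        p.strand,
                        p.assay,
                        p.condition,
                        p.site_class if p.site_class is not None else "NA",
                        p.strength if p.strength is not None else "NA",
                        repr(p.diff_pvalue) if p.diff_pvalue is not None else "NA",
                    ]
                )
                + "\n"
            )


def read_anchors(path: str | Path) -> list[GeneAnchor]:
    """Read TSS anchors from a 4-column TSV (header) or BED6 (no header).

    In BED input the TSS is the strand-aware 5' end of the interval.
    """
    with open(path) as fh:
        first = fh.readline()
    if "gene_id" in first.split():
        df = pd.read_csv(path, sep="\t")
        anchors = [
            GeneAnchor(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
            for r in df.itertuples()
        ]
    else:
        anchors = []
        with open(path) as fh:
            for line in fh:
                f = line.split()
                if not f:
                    continue
                strand = f[5] if len(f) > 5 else "+"
                tss = int(f[1]) if strand == "+" else int(f[2]) - 1
                anchors.append(GeneAnchor(f[3], f[0], tss, strand))
    seen: set[str] = set()
    for a in anchors:
        if a.gene_id in seen:
            raise RecordError(f"{path}: duplicate anchor for gene {a.gene_id!r}")
        seen.add(a.gene_id)
    return anchors


def write_anchors(anchors: Iterable[GeneAnchor], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"gene_id": a.gene_id, "chrom": a.chrom, "tss": a.tss, "strand": a.strand}
            for a in anchors
        ],
        columns=["gene_id", "chrom", "tss", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)


_TC_COLUMNS = ["gene_id", "expr_0", "expr_2.5", "expr_4", "expr_24", "p_2.5", "p_4", "p_24"]


def read_timecourse(path: str | Path) -> list[TimecourseProfile]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TC_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"time-course table missing columns {missing}")
    profiles = []
    for row in df.to_dict("records"):
        profiles.append(
            TimecourseProfile(
                gene_id=str(row["gene_id"]),
                expr={
                    0.0: float(row["expr_0"]),
                    2.5: float(row["expr_2.5"]),
                    4.0: float(row["expr_4"]),
                    24.0: float(row["expr_24"]),
                },
                pval={
                    2.5: float(row["p_2.5"]),
                    4.0: float(row["p_4"]),
                    24.0: float(row["p_24"]),
                },
            )
        )
    return profiles


def write_timecourse(profiles: Iterable[TimecourseProfile], path: str | Path) -> None:
    rows = [
        {
            "gene_id": p.gene_id,
            "expr_0": p.expr[0.0],
            "expr_2.5": p.expr[2.5],
            "expr_4": p.expr[4.0],
            "expr_24": p.expr[24.0],
            "p_2.5": p.pval[2.5],
            "p_4": p.pval[4.0],
            "p_24": p.pval[24.0],
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=_TC_COLUMNS).to_csv(path, sep="\t", index=False)


def read_curation(path: str | Path) -> list[CurationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "gene_id" not in df.columns or "verdict" not in df.columns:
        raise TableFormatError("curation table needs gene_id and verdict columns")
    return [
        CurationRecord(
            gene_id=str(r.gene_id),
            verdict=str(r.verdict),
            functional_group=str(getattr(r, "functional_group", "") or ""),
            location=(str(r.location) or None)
            if "location" in df.columns and getattr(r, "location", "")
            else None,
        )
        for r in df.itertuples()
    ]


def write_curation(records: Iterable[CurationRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "verdict": c.verdict,
            "functional_group": c.functional_group,
            "location": c.location or "",
        }
        for c in records
    ]
    pd.DataFrame(rows, columns=["gene_id", "verdict", "functional_group", "location"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# integrated report I/O
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "gene_id",
    "consensus_support",
    "distance_enhancer_tss_kb",
    "enhancer_constellation",
    "super_enhancer",
    "enhancer_ligand_dependent",
    "tss_ligand_dependent",
    "epigenome_class",
    "primary_target",
    "basal_tertial",
    "fc24_tertial",
    "p24_tertial",
    "transcriptome_group",
    "verdict",
    "functional_group",
    "location",
]


def _yesno(flag: bool) -> str:
    return "yes" if flag else "no"


def report_row(report) -> dict:
    """Flatten an IntegratedGeneReport into the TSV schema."""
    enh = report.enhancer
    trx = report.transcriptome
    cur = report.curation
    return {
        "gene_id": report.gene_id,
        "consensus_support": report.consensus_support,
        "distance_enhancer_tss_kb": (
            "NA"
            if enh is None or math.isnan(enh.distance_kb)
            else f"{enh.distance_kb:.1f}"
        ),
        "enhancer_constellation": enh.constellation if enh else "NA",
        "super_enhancer": _yesno(enh.kind == "super") if enh else "NA",
        "enhancer_ligand_dependent": _yesno(enh.enhancer_ligand_dependent) if enh else "NA",
        "tss_ligand_dependent": _yesno(enh.tss_ligand_dependent) if enh else "NA",
        "epigenome_class": enh.epigenome_class if enh and enh.epigenome_class else "NA",
        "primary_target": _yesno(trx.primary) if trx else "NA",
        "basal_tertial": trx.tertial_basal if trx else "NA",
        "fc24_tertial": trx.tertial_fc if trx else "NA",
        "p24_tertial": trx.tertial_p if trx else "NA",
        "transcriptome_group": trx.group if trx else "NA",
        "verdict": cur.verdict if cur else "NA",
        "functional_group": cur.functional_group if cur else "",
        "location": (cur.location or "") if cur else "",
    }


def write_report(
    records: Sequence,
    path: str | Path,
    config: PipelineConfig | None = None,
    provenance: Mapping[str, str] | None = None,
) -> None:
    """Write the per-gene report TSV plus a JSON sidecar (config, provenance)."""
    path = Path(path)
    rows = [report_row(r) for r in records]
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)
    sidecar = {
        "config": (config or PipelineConfig()).to_dict(),
        "provenance": dict(provenance or {}),
        "n_genes": len(records),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a report TSV back; typed fields keep their printed representation."""
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
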
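"""Classification of the 1,25(OH)2D3 response time course.

Genes are called primary targets when their expression rises
significantly (p < alpha) within 4 h of stimulation, placed into
rank-based tertials (top / mid / low) for basal activity, inducibility
(fold change at 24 h) and sensitivity (p-value at 24 h), and grouped by
the steepness of the late response: with s = log2(expr24 / expr4),

    group 1   s >= theta_high      steep late rise, highly responsive
    group 2   theta_low <= s < theta_high   intermediate increase
    group 3   s < theta_low        no major increase after 4 h

The grouping depends only on expression ratios, never on absolute units.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

from .io_model import (
    ParameterError,
    PipelineConfig,
    TimecourseProfile,
    TranscriptomeClass,
)

_EXPR_FLOOR = 1e-9


def is_primary_target(profile: TimecourseProfile, alpha: float) -> bool:
    """Significant expression increase at 2.5 h or 4 h vs basal."""
    e0 = profile.expr[0.0]
    for t in (2.5, 4.0):
        if t not in profile.expr or t not in profile.pval:
            raise ParameterError(f"{profile.gene_id}: missing {t} h time point")
        if profile.expr[t] > e0 and profile.pval[t] < alpha:
            return True
    return False


def tertile_assign(
    values: Mapping[str, float], higher_is_top: bool = True
) -> dict[str, str]:
    """Rank-based thirds of the analyzed gene set.

    Tertial sizes differ by at most one, with the excess assigned
    top-first; ties break lexicographically on gene id so the labels are
    independent of input order.
    """
    if len(values) < 3:
        raise ParameterError("tertile assignment needs at least 3 genes")
    ranked = sorted(
        values,
        key=lambda g: ((-values[g] if higher_is_top else values[g]), g),
    )
    n = len(ranked)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if rem >= 1 else 0), base + (1 if rem >= 2 else 0), base]
    labels: dict[str, str] = {}
    idx = 0
    for label, size in zip(("top", "mid", "low"), sizes):
        for g in ranked[idx : idx + size]:
            labels[g] = label
        idx += size
    return labels


def late_steepness(profile: TimecourseProfile) -> float:
    """log2 of the 4 h -> 24 h expression ratio; zero expression at 4 h is
    floored to a small positive value (flagged with a warning)."""
    e4, e24 = profile.expr[4.0], profile.expr[24.0]
    if e4 <= 0:
        warnings.warn(
            f"{profile.gene_id}: zero expression at 4 h floored for steepness",
            stacklevel=2,
        )
        e4 = _EXPR_FLOOR
    if e24 <= 0:
        e24 = _EXPR_FLOOR
    return math.log2(e24 / e4)


def steepness_group(profile: TimecourseProfile, cfg: PipelineConfig) -> int:
    """Three-way response grouping on late steepness (see module docstring)."""
    s = late_steepness(profile)
    if s < cfg.group_theta_low:
        return 3
    if s >= cfg.group_theta_high:
        return 1
    return 2


def classify_transcriptome(
    profiles: Sequence[TimecourseProfile], cfg: PipelineConfig
) -> list[TranscriptomeClass]:
    """Primary flag, three tertials and steepness group for every gene."""
    if len(profiles) < 3:
        raise ParameterError("classification needs at least 3 profiles")
    ids = [p.gene_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate gene ids in time-course profiles")
    basal = tertile_assign({p.gene_id: p.expr[0.0] for p in profiles}, True)
    fc = tertile_assign({p.gene_id: p.fc24 for p in profiles}, True)
    # sensitivity: the lowest p-value ranks top
    pv = tertile_assign({p.gene_id: p.p24 for p in profiles}, False)
    return [
        TranscriptomeClass(
            gene_id=p.gene_id,
            primary=is_primary_target(p, cfg.alpha),
            tertial_basal=basal[p.gene_id],
            tertial_fc=fc[p.gene_id],
            tertial_p=pv[p.gene_id],
            group=steepness_group(p, cfg),
        )
        for p in profiles
    ]
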
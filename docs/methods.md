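# Methods

## Scope and model

`vdtargets` operationalizes a three-stage desk analysis of vitamin D
target genes in immune cells. It deliberately starts *downstream* of
primary data processing: differential-expression statistics are DESeq2
outputs, peaks are already-called intervals with upstream annotations
(VDR temporal site class, strength, per-peak treatment-response
p-value), and time-course p-values come from the upstream testing. The
package's contribution is the deterministic decision logic that turns
those inputs into a reproducible per-gene characterization — the part
that was originally done by eye in a genome browser.

Coordinates are 0-based half-open throughout (BED convention); a TSS is
a single 0-based position. Strand is recorded but never affects calls
or distances: enhancer activity in this framework is orientation-free.

## Consensus selection

Each dataset contributes one gene set, produced by one of three
strategies: `unfiltered_significant` (padj < α, default α = 0.05),
`top_n_union` (union of the top-N genes by basal expression descending,
log2 fold change descending, and raw p-value ascending; default
N = 100), or `external_list` for memberships computed elsewhere (e.g. a
self-organizing-map filter, which this package does not re-train). The
top-N semantics are a *union* — a gene strong on several criteria is
counted once, so the set size lies between N and 3N. Ranking by log2
fold change orders identically to ranking by fold change. Ties at rank
N break lexicographically on gene id, making every filter
order-independent. The consensus is membership in ≥ k of n sets
(default k = 4 of 5, with the all-n core reported separately via the
Venn partition). Monotonicity (larger k ⇒ smaller consensus) and
partition conservation (regions are disjoint and cover the union) are
enforced by property tests.

## Enhancer profiling

For each gene all peaks within ±1 Mb of the TSS are collected
(interval-tree query; a brute-force linear scan serves as the test
oracle). VDR sites lacking a strength annotation are labelled strong
when their score reaches the 0.75 quantile of same-condition VDR
scores; annotated strengths always pass through, since strength is an
upstream classification this package cannot re-derive.

**Super-enhancer stitching.** A cluster qualifies when ≥ 3 VDR sites
fit in a span of ≤ 20 kb (first site start to last site end), at least
one member is a strong P or T site, and the H3K27ac track — merged with
a 1 kb gap tolerance, matching browser-visible continuity — covers the
span entirely. The implementation enumerates containment-closed spans
(every site whose interval lies inside the span is a member). This is
exhaustive: any qualifying subset of sites has the same span as its
containment closure, which also qualifies, so closed spans capture
every achievable span. Among qualifying spans, the one whose midpoint
is nearest the TSS is reported, mirroring the one-enhancer-per-gene
convention of the reference analysis; ties break on (start, end). A
dedicated test checks exact agreement with brute-force enumeration of
all site subsets on randomized windows of up to 12 sites.

**Single-enhancer fallback.** When no cluster qualifies, the strong P/T
site with the smallest |midpoint − TSS| is selected; equidistant ties
prefer the upstream site, then the lower start. Weak and 24-h-only
sites never qualify.

**Constellation, distance, dependency, class.** The constellation joins
member site classes ordered P < T < 24 (repeats kept), e.g. `T-T-24`.
Distance is |region midpoint − TSS| in kb, one decimal, and 0.0 when
the region overlaps the TSS window — "direct TSS binding". A region
(enhancer or TSS window) is ligand-dependent when ≥ 1 overlapping
ligand-condition peak of any of the four assays has a response p-value
< α; absent p-values count as not significant (dependency requires
positive evidence). Classes: 1 = super/dependent, 2 = super/not,
3 = single/dependent, 4 = single/not.

## Time-course classification

A gene is a *primary* target when expression rises above basal with
p < α at 2.5 h or 4 h (either early point qualifies). Tertials are
rank-based thirds computed **within the analyzed gene set** (the
reference labels are balanced across the 15-gene shortlist, which is
only possible for within-set ranks); sizes differ by ≤ 1 with the
excess assigned top-first, and ties break on gene id. For sensitivity,
the lowest p-value ranks top.

Response groups measure the steepness of the late expression curve.
With s = log2(expr₂₄/expr₄): group 1 when s ≥ θ_high (default 1.0),
group 3 when s < θ_low (default 0.3, "no major increase after 4 h"),
group 2 between. We considered adding a fold-change floor as a second
condition for group 1 but rejected it: inducibility tertials and
steepness groups are distinct axes in the reference classification
(one group-1 gene has only mid inducibility while a group-2 gene is
top), so any fold-change threshold separating the groups is
inconsistent with the published labels; pure late steepness is the
only monotone single-statistic rule that reproduces them. The rule is
scale-free (depends only on ratios) and monotone in expr₂₄. Zero
expression at 4 h is floored at 1e-9 with a warning.

## Integration and curation

Literature curation (immune relevance, functional group, protein
location) is a **data table, not an algorithm** — the underlying
judgments are subjective literature assessments that cannot be
faithfully automated. Genes with verdict `keep` survive; genes without
any record are kept and flagged, since missing curation is not a
dismissal. The packaged curation fixture covers the named genes of the
reference analysis (15 kept; FBP1 dismissed as metabolic, G0S2 as
non-immune, DENND6B for lack of functional information) and pads the
candidate set with 16 synthetic placeholder candidates (names
`CAND01`–`CAND16`, marked as such) because the remaining dismissed
identities are not on public record — only their count is.

Reports join all stages on gene id (inner on the curated set, NA with
warnings for missing stages) and are written as TSV plus a JSON sidecar
holding the configuration and input checksums; no timestamps, so equal
inputs give byte-identical outputs.

## Synthetic data

The generators are pure functions of (spec, seed).

* `gen_de_tables` plants genes at chosen support counts: a planted gene
  is padj-significant in exactly that many datasets; background genes
  stay below the consensus threshold (configurable
  `background_max_support`, default 0). Expression magnitudes are
  lognormal, fold changes normal — plausible dressing around the
  membership structure, which is the actual ground truth.
* `gen_peakscape` realizes an architecture spec per gene: a 3-site
  cluster of 18 kb extent (super), a lone strong P/T site at the
  specified distance (single), or a weak decoy (none), with H3K27ac
  coverage, TSS marks and accessibility peaks. Significant response
  p-values (0.01) appear exactly where the spec demands dependency,
  0.5 elsewhere — flags, not simulated test statistics, are the ground
  truth. Contradictory specs fail loudly: a ligand-dependent enhancer
  *inside* the TSS window forces a dependent TSS region; an enhancer
  too close to the TSS for its kind is rejected; super specs must have
  exactly three sites, because with more sites a proper sub-cluster can
  legitimately win nearest-to-TSS selection and the planted truth would
  be ambiguous rather than wrong.
* `gen_timecourse` places the 4 h point so the late log-ratio hits a
  group-specific steepness target (1.7 / 0.65 / 0.15 by default,
  comfortably inside the group bands), with p-values encoding the
  primary flag and optional per-point lognormal noise.

The packaged reference bundle uses one pseudo-chromosome per gene with
the TSS at 2 Mb — the published record specifies distances and
constellations, not genomic coordinates, and synthetic coordinates
avoid implying positions that were never stated. Its time-course
values are fixed constants chosen to realize the published tertials,
primary flags and groups; they are abstract normalized expression on a
common scale, as the original units are not specified.

What the synthetic data does *not* emulate: read-level noise, peak
boundary uncertainty, correlated replicates, overlapping genes sharing
an enhancer, or imbalanced tertials. Passing the recovery tests
demonstrates the decision logic is exact on clean inputs, not that the
pipeline is robust to upstream miscalls.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `top_n` | 100 | per-criterion ranking depth |
| `consensus_k` | 4 | minimum dataset support |
| `alpha` | 0.05 | significance for DE, dependency, primary calls |
| `se_window_bp` | 20 000 | max super-enhancer extent |
| `se_min_sites` | 3 | min VDR sites per super-enhancer |
| `h3k27ac_max_gap_bp` | 1 000 | gap tolerance for H3K27ac continuity |
| `tss_window_bp` | 1 000 | TSS window for direct binding / TSS dependency |
| `search_radius_bp` | 1 000 000 | window around the TSS |
| `strength_quantile` | 0.75 | strong/weak threshold for unannotated sites |
| `group_theta_low` / `group_theta_high` | 0.3 / 1.0 | steepness group bounds (log2) |

The reference bundle sets `tss_window_bp = 200`: its gene set contains
both direct TSS binders (distance 0) and an enhancer only 0.5 kb from
the TSS, which a 1 kb window could not distinguish — the original
analysis likewise zoomed in to separate the two cases. The exact width
is not on record; 200 bp is the package's choice and is configurable.

## Numerical and degenerate-input choices

Distances round half-even to one decimal (kb). Quantiles use numpy's
default linear interpolation; a single unannotated site is its own
quantile and hence strong. Empty peak files, empty windows, and genes
with no qualifying site all yield explicit `none` calls rather than
errors; fewer than three genes cannot be tertiled and raise. fc24 with
zero basal is +inf (or NaN at 0/0), and such profiles cannot be ranked
meaningfully — the generators never produce them.

## Known limitations

* Curation and VDR site strength/class are inputs; the pipeline can be
  no better than those upstream judgments.
* Tertials are relative to the analyzed set: adding or removing one
  gene can relabel others.
* The steepness thresholds are calibrated to the packaged reference
  set; other cell systems may need different θ values (config-exposed).
* Genes sharing a physical enhancer (adjacent loci) are profiled
  independently; the shared region is reported for each without
  deduplication.
* One cross-tabulation caveat in the reference data itself: one
  low-responsiveness (group 3) gene does carry a ligand-dependent
  super-enhancer, so response group and enhancer dependency correlate
  strongly but not perfectly.
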
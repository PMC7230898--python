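import itertools

import numpy as np
import pytest

from vdtargets.enhancer_profiling import (
    assign_strength,
    call_super_enhancer,
    classify_epigenome,
    constellation_label,
    distance_to_tss,
    h3k27ac_continuity,
    profile_gene,
    query_window,
    region_ligand_dependency,
    select_single_enhancer,
)
from vdtargets.io_model import (
    EnhancerCall,
    GeneAnchor,
    ParameterError,
    Peak,
    PipelineConfig,
    RecordError,
    sort_peaks,
)
from vdtargets.synthetic_data import gen_peakscape, random_architecture_specs

CFG = PipelineConfig()


def vdr(start, end, cls="T", strength="strong", diff=None, chrom="chr1", score=10.0):
    return Peak(chrom, start, end, f"v{start}", score, ".", "VDR", "ligand", cls, strength, diff)


def k27(start, end, chrom="chr1", diff=None):
    return Peak(chrom, start, end, f"k{start}", 5.0, ".", "H3K27ac", "ligand", None, None, diff)


class TestQueryWindow:
    ANCHOR = GeneAnchor("G", "chr1", 2_000_000)

    def test_peak_near_tss_returned(self):
        peaks = sort_peaks([vdr(2_000_500, 2_000_900)])
        assert query_window(peaks, self.ANCHOR, 1_000_000) == peaks

    def test_peak_beyond_radius_excluded(self):
        peaks = sort_peaks([vdr(3_100_000, 3_100_400)])
        assert query_window(peaks, self.ANCHOR, 1_000_000) == []

    def test_unknown_chromosome_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="chromosome"):
            assert query_window([vdr(1, 5, chrom="chrX")], self.ANCHOR, 1000) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_scan_on_random_peaks(self, seed):
        rng = np.random.default_rng(seed)
        peaks = []
        for i in range(1000):
            chrom = f"chr{rng.integers(1, 4)}"
            s = int(rng.integers(0, 4_000_000))
            peaks.append(vdr(s, s + int(rng.integers(1, 5000)), chrom=chrom))
        peaks = sort_peaks(peaks)
        anchor = GeneAnchor("G", "chr2", int(rng.integers(0, 4_000_000)))
        radius = int(rng.integers(1_000, 1_000_000))
        lo, hi = anchor.tss - radius, anchor.tss + radius
        expected = sort_peaks(
            [p for p in peaks if p.chrom == anchor.chrom and p.start < hi and p.end > lo]
        )
        assert query_window(peaks, anchor, radius) == expected


class TestAssignStrength:
    def test_prelabeled_peaks_pass_through(self):
        peaks = [vdr(0, 10, strength="weak"), vdr(20, 30, strength="strong")]
        assert assign_strength(peaks, 0.75) == peaks

    def test_quantile_threshold_on_unlabeled_scores(self):
        peaks = [vdr(i * 100, i * 100 + 10, strength=None, score=s) for i, s in enumerate([1, 2, 3, 4])]
        labels = [p.strength for p in assign_strength(peaks, 0.75)]
        assert labels == ["weak", "weak", "weak", "strong"]

    def test_single_unlabeled_peak_is_strong(self):
        (out,) = assign_strength([vdr(0, 10, strength=None, score=3.3)], 0.75)
        assert out.strength == "strong"


class TestContinuity:
    def test_single_covering_interval(self):
        assert h3k27ac_continuity((100, 900), [k27(0, 1000)], 1000)

    def test_large_internal_gap_breaks_continuity(self):
        marks = [k27(0, 2000), k27(7000, 12_000)]  # 5 kb gap inside the span
        assert not h3k27ac_continuity((0, 12_000), marks, 1000)
        assert h3k27ac_continuity((0, 12_000), marks, 5000)

    def test_empty_track_is_discontinuous(self):
        assert not h3k27ac_continuity((0, 10), [], 1000)


class TestSuperEnhancer:
    def test_three_sites_within_window_cluster(self):
        sites = [vdr(0, 400, "T"), vdr(8000, 8400, "24", "weak"), vdr(18_000, 18_400, "24", "weak")]
        cluster = call_super_enhancer(sites, [k27(0, 19_000)], CFG, tss=50_000)
        assert cluster is not None
        assert cluster.span == (0, 18_400)
        assert len(cluster.sites) == 3

    def test_extent_beyond_window_gives_no_call(self):
        sites = [vdr(0, 400, "T"), vdr(12_000, 12_400), vdr(25_000, 25_400)]
        assert call_super_enhancer(sites, [k27(0, 26_000)], CFG, tss=0) is None

    def test_no_strong_pt_site_gives_no_call(self):
        sites = [vdr(0, 400, "24", "weak"), vdr(5000, 5400, "T", "weak"), vdr(9000, 9400, "24", "weak")]
        assert call_super_enhancer(sites, [k27(0, 10_000)], CFG, tss=0) is None

    def test_discontinuous_h3k27ac_gives_no_call(self):
        sites = [vdr(0, 400, "P"), vdr(5000, 5400, "24", "weak"), vdr(9000, 9400, "24", "weak")]
        assert call_super_enhancer(sites, [k27(0, 1000)], CFG, tss=0) is None


def _oracle_best_span(sites, h3k, cfg, tss):
    """Exhaustive subset enumeration: the qualifying cluster span whose
    midpoint is nearest the TSS, ties on (start, end)."""
    from vdtargets.enhancer_profiling import _is_strong_pt

    best = None
    for r in range(cfg.se_min_sites, len(sites) + 1):
        for sub in itertools.combinations(sites, r):
            span = (min(p.start for p in sub), max(p.end for p in sub))
            if span[1] - span[0] > cfg.se_window_bp:
                continue
            if not any(_is_strong_pt(p) for p in sub):
                continue
            if not h3k27ac_continuity(span, h3k, cfg.h3k27ac_max_gap_bp):
                continue
            key = (abs((span[0] + span[1]) / 2 - tss), span[0], span[1])
            best = key if best is None or key < best else best
    return best


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_stitching_matches_exhaustive_subset_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(0, 13))
            sites = [
                vdr(
                    s := int(rng.integers(0, 60_000)),
                    s + int(rng.integers(100, 3000)),
                    cls=str(rng.choice(["P", "T", "24"])),
                    strength=str(rng.choice(["strong", "weak"])),
                )
                for _ in range(n)
            ]
            h3k = [
                k27(s := int(rng.integers(0, 60_000)), s + int(rng.integers(500, 30_000)))
                for _ in range(int(rng.integers(0, 6)))
            ]
            tss = int(rng.integers(0, 60_000))
            cluster = call_super_enhancer(sorted(sites, key=lambda p: (p.start, p.end)), h3k, CFG, tss)
            got = (
                None
                if cluster is None
                else (abs((cluster.span[0] + cluster.span[1]) / 2 - tss), *cluster.span)
            )
            assert got == _oracle_best_span(sites, h3k, CFG, tss)


class TestSingleEnhancer:
    ANCHOR = GeneAnchor("G", "chr1", 100_000)

    def test_nearest_strong_pt_site_selected(self):
        near = vdr(96_800, 97_200, "T")  # -3 kb
        far = vdr(109_800, 110_200, "P")  # +10 kb
        assert select_single_enhancer([near, far], self.ANCHOR) == near

    def test_weak_and_24_only_sites_ineligible(self):
        sites = [vdr(99_000, 99_400, "T", "weak"), vdr(101_000, 101_400, "24", "strong")]
        assert select_single_enhancer(sites, self.ANCHOR) is None

    def test_equidistant_tie_prefers_upstream(self):
        up = vdr(94_800, 95_200, "P")
        down = vdr(104_800, 105_200, "T")
        assert select_single_enhancer([down, up], self.ANCHOR) == up


class TestConstellationAndClasses:
    def test_label_ordering_is_input_order_invariant(self):
        sites = [vdr(0, 10, "24", "weak"), vdr(20, 30, "P"), vdr(40, 50, "T")]
        for perm in itertools.permutations(sites):
            assert constellation_label(list(perm)) == "P-T-24"

    def test_repeated_classes_kept(self):
        assert constellation_label([vdr(0, 10, "T"), vdr(20, 30, "24", "weak"), vdr(40, 50, "T")]) == "T-T-24"

    def test_missing_class_is_an_error(self):
        bare = Peak("chr1", 0, 10, assay="VDR")
        with pytest.raises(RecordError):
            constellation_label([bare])

    def test_four_class_mapping(self):
        def call(kind, dep):
            return EnhancerCall(
                "G", kind, member_sites=(vdr(0, 10),) * (3 if kind == "super" else 1),
                enhancer_ligand_dependent=dep,
            )

        assert classify_epigenome(call("super", True)) == 1
        assert classify_epigenome(call("super", False)) == 2
        assert classify_epigenome(call("single", True)) == 3
        assert classify_epigenome(call("single", False)) == 4
        with pytest.warns(UserWarning):
            assert classify_epigenome(EnhancerCall("G", "none")) is None


class TestDependencyAndDistance:
    def test_any_significant_overlapping_peak_suffices(self):
        assert region_ligand_dependency((0, 100), [vdr(50, 150, diff=0.01)], 0.05)
        assert not region_ligand_dependency((0, 100), [vdr(50, 150, diff=0.2)], 0.05)
        assert not region_ligand_dependency((0, 100), [vdr(500, 600, diff=0.001)], 0.05)
        assert not region_ligand_dependency((0, 100), [vdr(50, 150, diff=None)], 0.05)

    def test_distance_zero_inside_tss_window(self):
        anchor = GeneAnchor("G", "chr1", 10_000)
        assert distance_to_tss(("chr1", 9_900, 10_050), anchor, 1000) == 0.0

    def test_midpoint_distance_rounded_to_one_decimal(self):
        anchor = GeneAnchor("G", "chr1", 0)
        assert distance_to_tss(("chr1", 24_800, 25_200), anchor, 1000) == 25.0
        assert distance_to_tss(("chr1", 2_300, 2_700), anchor, 1000) == 2.5

    def test_upstream_downstream_symmetry(self):
        anchor = GeneAnchor("G", "chr1", 500_000)
        down = distance_to_tss(("chr1", 524_800, 525_200), anchor, 1000)
        up = distance_to_tss(("chr1", 474_800, 475_200), anchor, 1000)
        assert down == up

    def test_chromosome_mismatch_is_an_error(self):
        with pytest.raises(ParameterError):
            distance_to_tss(("chr2", 0, 10), GeneAnchor("G", "chr1", 0), 1000)


class TestProfileInvariances:
    def _calls(self, shift=0, strand="+"):
        cfg = PipelineConfig()
        specs = random_architecture_specs(25, seed=3)
        anchors = [
            GeneAnchor(s.gene_id, f"chr_{s.gene_id}", 2_000_000 + shift, strand) for s in specs
        ]
        peaks = gen_peakscape(anchors, specs, cfg, seed=9)
        return [profile_gene(a, peaks, cfg) for a in anchors]

    def test_translation_invariance(self):
        base, shifted = self._calls(0), self._calls(40_000)
        for b, s in zip(base, shifted):
            assert (b.kind, b.constellation, b.distance_kb) == (s.kind, s.constellation, s.distance_kb)
            assert b.enhancer_ligand_dependent == s.enhancer_ligand_dependent
            assert b.epigenome_class == s.epigenome_class

    def test_strand_flip_leaves_calls_unchanged(self):
        plus, minus = self._calls(strand="+"), self._calls(strand="-")
        for p, m in zip(plus, minus):
            assert (p.kind, p.constellation, p.distance_kb) == (m.kind, m.constellation, m.distance_kb)

    def test_super_and_single_calls_are_exclusive(self):
        for call in self._calls():
            if call.kind == "super":
                assert len(call.member_sites) >= 3
            elif call.kind == "single":
                assert len(call.member_sites) == 1
                (site,) = call.member_sites
                assert site.strength == "strong" and site.site_class in ("P", "T")

    def test_gene_with_empty_vdr_track_gets_no_call(self):
        anchor = GeneAnchor("G", "chr1", 2_000_000)
        assert profile_gene(anchor, [k27(1_999_000, 2_001_000)], PipelineConfig()).kind == "none"
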
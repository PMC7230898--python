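import warnings

import pytest

from vdtargets.enhancer_profiling import profile_gene
from vdtargets.io_model import GeneAnchor, ParameterError, PipelineConfig, RecordError
from vdtargets.synthetic_data import (
    ArchitectureSpec,
    DynamicsSpec,
    gen_de_tables,
    gen_peakscape,
    gen_timecourse,
    reference_fixture,
    random_architecture_specs,
    random_dynamics_specs,
    write_bundle,
)
from vdtargets.timecourse import is_primary_target, steepness_group

CFG = PipelineConfig()


class TestDETables:
    def test_planted_support_counts_are_exact(self):
        planted = {"A": 5, "B": 3, "C": 0}
        tables = gen_de_tables(5, 20, planted, seed=1)
        for gene, want in planted.items():
            hits = sum(
                1
                for recs in tables.values()
                for r in recs
                if r.gene_id == gene and r.padj < 0.05
            )
            assert hits == want

    def test_seeded_rerun_is_identical(self):
        a = gen_de_tables(5, 30, {"X": 4}, seed=9)
        b = gen_de_tables(5, 30, {"X": 4}, seed=9)
        assert a == b

    def test_infeasible_plant_rejected(self):
        with pytest.raises(ParameterError):
            gen_de_tables(3, 10, {"A": 4}, seed=0)


class TestPeakscape:
    def test_contradictory_specs_rejected(self):
        anchor = [GeneAnchor("G", "chr_G", 2_000_000)]
        # dependent enhancer inside the TSS window with a non-dependent TSS
        bad = ArchitectureSpec("G", "single", "T", True, False, 0.0)
        with pytest.raises(ParameterError):
            gen_peakscape(anchor, [bad], CFG, seed=0)
        # super-enhancer overlapping the TSS window
        with pytest.raises(ParameterError):
            gen_peakscape(
                anchor, [ArchitectureSpec("G", "super", "P-T-24", True, True, 5.0)], CFG, 0
            )
        # more member sites than the stitching rule can disambiguate
        with pytest.raises(ParameterError):
            gen_peakscape(
                anchor,
                [ArchitectureSpec("G", "super", "P-T-T-24", True, True, 50.0)],
                CFG,
                0,
            )

    def test_invalid_spec_combinations_rejected_at_construction(self):
        with pytest.raises(RecordError):
            ArchitectureSpec("G", "super", "24-24-24", False, False, 50.0)  # no strong P/T
        with pytest.raises(RecordError):
            ArchitectureSpec("G", "single", "24", False, False, 50.0)
        with pytest.raises(RecordError):
            ArchitectureSpec("G", "none", "T", False, False, 0.0)

    def test_planted_architectures_recovered_at_zero_noise(self):
        specs = random_architecture_specs(60, seed=41)
        anchors = [GeneAnchor(s.gene_id, f"chr_{s.gene_id}", 2_000_000) for s in specs]
        peaks = gen_peakscape(anchors, specs, CFG, seed=42)
        for spec, anchor in zip(specs, anchors):
            call = profile_gene(anchor, peaks, CFG)
            assert call.kind == spec.kind
            if spec.kind != "none":
                assert call.constellation == spec.constellation
                assert call.enhancer_ligand_dependent == spec.ligand_dependent
                assert call.tss_ligand_dependent == spec.tss_ligand_dependent
                assert call.distance_kb == pytest.approx(spec.distance_kb, abs=0.05)

    def test_background_decoys_do_not_change_calls(self):
        specs = random_architecture_specs(15, seed=43)
        anchors = [GeneAnchor(s.gene_id, f"chr_{s.gene_id}", 2_000_000) for s in specs]
        clean = gen_peakscape(anchors, specs, CFG, seed=44)
        noisy = gen_peakscape(anchors, specs, CFG, seed=44, n_background_peaks=5)
        assert len(noisy) > len(clean)
        for spec, anchor in zip(specs, anchors):
            assert profile_gene(anchor, noisy, CFG).kind == spec.kind


class TestTimecourseGen:
    def test_group_and_primary_flags_realized(self):
        specs = [
            DynamicsSpec("G3", 3, True, 100.0, 2.0),
            DynamicsSpec("G1", 1, True, 50.0, 10.0),
            DynamicsSpec("SEC", 2, False, 200.0, 3.0),
        ]
        by_gene = {p.gene_id: p for p in gen_timecourse(specs, seed=0)}
        assert steepness_group(by_gene["G3"], CFG) == 3
        assert steepness_group(by_gene["G1"], CFG) == 1
        assert not is_primary_target(by_gene["SEC"], CFG.alpha)

    def test_primary_flag_infeasible_with_tiny_fold_change(self):
        with pytest.raises(ParameterError, match="too low"):
            gen_timecourse([DynamicsSpec("G", 1, True, 100.0, 1.5)], seed=0)

    def test_zero_noise_rerun_identical_and_noise_changes_values(self):
        specs = random_dynamics_specs(10, seed=3)
        assert gen_timecourse(specs, seed=5) == gen_timecourse(specs, seed=5)
        noisy_specs = random_dynamics_specs(10, seed=3, noise_sd=0.3)
        noisy = gen_timecourse(noisy_specs, seed=5)
        assert noisy != gen_timecourse(specs, seed=5)

    def test_recovery_degrades_with_noise(self):
        def accuracy(noise_sd):
            specs = random_dynamics_specs(120, seed=7, noise_sd=noise_sd)
            profiles = gen_timecourse(specs, seed=8)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return sum(
                    steepness_group(p, CFG) == s.group for s, p in zip(specs, profiles)
                ) / len(specs)

        assert accuracy(0.0) == 1.0
        assert accuracy(1.5) < accuracy(0.0)


class TestReferenceFixture:
    def test_fixture_is_byte_stable(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_bundle(reference_fixture(), a)
        write_bundle(reference_fixture(), b)
        files = sorted(p.name for p in a.iterdir())
        assert files == sorted(p.name for p in b.iterdir())
        for name in files:
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_fixture_covers_the_fifteen_key_genes(self, bundle):
        genes = {a.gene_id for a in bundle.anchors}
        assert len(genes) == 15
        assert {p.gene_id for p in bundle.timecourse} == genes
        curated = {c.gene_id for c in bundle.curation}
        assert genes < curated and len(curated) == 34
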
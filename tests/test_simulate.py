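"""Synthetic-fixture generator: determinism, planted truth, structure."""

import json

import numpy as np
import pytest

from riboprof import io
from riboprof.core import extract_sequence
from riboprof.filtering import filter_reads, select_rrna_features
from riboprof.metagene import collect_start_positions, frame_summary, metagene_profile
from riboprof.simulate import (
    SimulationSpec,
    balanced_expression_weights,
    simulate_genome,
    simulate_reads,
    write_dataset,
)


def small_spec(**kwargs) -> SimulationSpec:
    defaults = dict(
        genome_length=4000, n_orfs=4, orf_length_range=(120, 240),
        reads_per_orf=120, seed=7,
    )
    defaults.update(kwargs)
    return SimulationSpec(**defaults)


class TestSpec:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationSpec(read_length_distribution=((28, 0.5), (29, 0.2)))

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationSpec(rrna_fraction=1.0)

    def test_te_length_validated(self):
        with pytest.raises(ValueError):
            SimulationSpec(n_orfs=3, te={"c1": [1.0, 2.0]})


class TestSimulateGenome:
    def test_orfs_start_atg_end_stop(self):
        spec = small_spec()
        genome, orfs, _rrna = simulate_genome(spec)
        for orf in orfs:
            seq = extract_sequence(orf.interval, genome)
            assert seq[:3] == "ATG"
            assert seq[-3:] in ("TAA", "TAG", "TGA")
            assert len(seq) % 3 == 0

    def test_single_orf_spec(self):
        spec = SimulationSpec(
            genome_length=400, circular=False, n_orfs=1,
            orf_length_range=(30, 30), rrna_length=60, seed=1,
        )
        genome, orfs, _ = simulate_genome(spec)
        assert len(orfs) == 1
        assert orfs[0].interval.length == 30
        assert extract_sequence(orfs[0].interval, genome).startswith("ATG")

    def test_circular_forces_origin_spanning_orf(self):
        genome, orfs, _ = simulate_genome(small_spec())
        spanning = [o for o in orfs if o.interval.end > genome.length]
        assert len(spanning) == 1

    def test_same_seed_identical_output_bytes(self, tmp_path):
        spec = small_spec()
        p1 = write_dataset(spec, tmp_path / "a")
        p2 = write_dataset(spec, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_no_same_strand_overlap(self):
        genome, orfs, rrna = simulate_genome(small_spec())
        from riboprof.core import intervals_overlap

        features = orfs + [rrna]
        for i, a in enumerate(features):
            for b in features[i + 1 :]:
                assert not intervals_overlap(a.interval, b.interval, genome)

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="packing"):
            simulate_genome(SimulationSpec(genome_length=300, n_orfs=5))

    def test_wrapped_gff_record_for_origin_orf(self, tmp_path):
        paths = write_dataset(small_spec(), tmp_path)
        wrapped = [
            line
            for line in paths["annotation"].read_text().splitlines()
            if "origin_spanning=true" in line
        ]
        assert len(wrapped) == 1
        cols = wrapped[0].split("\t")
        assert int(cols[4]) < int(cols[3])  # end_gff < start_gff


class TestSimulateReads:
    def test_planted_contamination_counts_exact(self, tmp_path):
        spec = small_spec(library_size=1000, rrna_fraction=0.2, multimap_fraction=0.1)
        paths = write_dataset(spec, tmp_path)
        truth = json.loads(paths["truth"].read_text())
        genomes = io.read_fasta(paths["genome"])
        annotation = io.read_gff3(paths["annotation"], genomes)
        rrna = select_rrna_features(annotation, ["rRNA"])
        for library_id, info in truth["libraries"].items():
            reads = io.read_alignments(paths[library_id], genomes)
            assert len(reads) == info["n_total"] == 1000
            _retained, report = filter_reads(reads, rrna, genomes)
            assert report.removed_multimapped == info["n_multimapped"] == 100
            assert report.removed_rrna == info["n_rrna"] == 200

    def test_retained_per_orf_counts_recovered(self, tmp_path):
        from riboprof.merge import merge_predictions
        from riboprof.quantify import count_reads

        spec = small_spec()
        paths = write_dataset(spec, tmp_path)
        truth = json.loads(paths["truth"].read_text())
        genomes = io.read_fasta(paths["genome"])
        annotation = io.read_gff3(paths["annotation"], genomes)
        cds = [o for o in annotation if o.feature_type == "CDS"]
        rrna = select_rrna_features(annotation, ["rRNA"])
        merged = merge_predictions(cds, [], genomes)
        for library_id, info in truth["libraries"].items():
            reads = io.read_alignments(paths[library_id], genomes)
            retained, _ = filter_reads(reads, rrna, genomes)
            result = count_reads(retained, merged, genomes)
            assert result.counts == info["orf_counts_retained"]
            assert result.ambiguous == 0

    def test_start_enrichment_boosts_frame0(self):
        spec = small_spec(
            start_enrichment=50.0, in_frame_prob=1.0, rrna_fraction=0.0,
            multimap_fraction=0.0, intergenic_range=(130, 170), genome_length=6000,
        )
        rng = np.random.default_rng(spec.seed)
        genome, orfs, rrna = simulate_genome(spec, rng)
        libraries, _truth = simulate_reads(spec, genome, orfs, rrna, rng)
        genomes = {genome.contig_id: genome}
        reads = [r for _q, r in libraries["c1-RIBO-1"]]
        starts, _ = collect_start_positions(orfs, genomes)
        profile = metagene_profile(reads, starts, genomes, read_lengths=range(20, 46))
        frames = frame_summary(profile)
        total = profile.counts.sum(axis=1)
        populated = [l for l, t in zip(profile.read_lengths, total) if t > 0]
        for length in populated:
            assert frames.loc[length, "frame_0"] == 1.0
        # strong start enrichment: offset 0 is the modal coding-side offset
        pooled = profile.counts.sum(axis=0)
        coding = pooled[profile.window_upstream :]
        assert np.argmax(coding) == 0

    def test_planted_te_recovered(self, tmp_path):
        te_values = [0.5, 1.0, 2.0, 4.0]
        spec = small_spec(
            n_orfs=4,
            te={"c1": te_values},
            rna_weights=balanced_expression_weights(te_values),
            reads_per_orf=2000,
            rrna_fraction=0.02,
            multimap_fraction=0.02,
            genome_length=4000,
        )
        paths = write_dataset(spec, tmp_path)
        from riboprof.merge import merge_predictions
        from riboprof.quantify import build_count_matrix, rpkm_matrix, te_table

        genomes = io.read_fasta(paths["genome"])
        annotation = io.read_gff3(paths["annotation"], genomes)
        cds = [o for o in annotation if o.feature_type == "CDS"]
        rrna = select_rrna_features(annotation, ["rRNA"])
        sheet = io.read_sample_sheet(paths["samples"])
        merged = merge_predictions(cds, [], genomes)
        reads_by_library = {}
        for sample in sheet.samples:
            reads = io.read_alignments(tmp_path / sample.path, genomes)
            retained, _ = filter_reads(reads, rrna, genomes)
            reads_by_library[sample.library_id] = retained
        counts, sizes, _ = build_count_matrix(reads_by_library, merged, genomes)
        te = te_table(rpkm_matrix(counts, merged, sizes), sheet)
        for orf_id, planted in zip([o.orf_id for o in cds], te_values):
            assert te.loc[orf_id, "c1"] == pytest.approx(planted, rel=0.10)


class TestBalancedWeights:
    def test_balances_exactly(self):
        te = [0.5, 1.0, 2.0, 4.0]
        w = balanced_expression_weights(te)
        assert sum(wi * ti for wi, ti in zip(w, te)) == pytest.approx(sum(w))
        assert all(wi > 0 for wi in w)

    def test_all_ones_unchanged(self):
        assert balanced_expression_weights([1.0, 1.0]) == [1.0, 1.0]

    def test_unbalanceable_raises(self):
        with pytest.raises(ValueError):
            balanced_expression_weights([2.0, 3.0])
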
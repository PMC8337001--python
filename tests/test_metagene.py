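"""Metagene profiling: offsets, window exclusion, oracle mass, symmetry."""

import numpy as np
import pytest

from riboprof.core import GenomeSequence
from riboprof.metagene import (
    MetageneProfile,
    StartSite,
    collect_start_positions,
    frame_summary,
    metagene_profile,
)

from conftest import make_orf, make_read, oracle_metagene_mass, random_reads


@pytest.fixture
def genomes():
    return {"c": GenomeSequence("c", "A" * 1000, circular=False)}


class TestCollectStartPositions:
    def test_plus_strand_start(self, genomes):
        starts, _ = collect_start_positions([make_orf("g", "c", 100, 400)], genomes)
        assert starts == [StartSite("c", "+", 100)]

    def test_minus_strand_start(self, genomes):
        starts, _ = collect_start_positions([make_orf("g", "c", 100, 400, "-")], genomes)
        assert starts == [StartSite("c", "-", 399)]

    def test_linear_edge_gene_excluded_and_counted(self, genomes):
        starts, n_excluded = collect_start_positions(
            [make_orf("g", "c", 10, 40)], genomes, window_upstream=50
        )
        assert starts == [] and n_excluded == 1

    def test_circular_windows_wrap(self):
        genomes = {"c": GenomeSequence("c", "A" * 1000, circular=True)}
        starts, n_excluded = collect_start_positions(
            [make_orf("g", "c", 10, 40)], genomes, window_upstream=50
        )
        assert starts == [StartSite("c", "+", 10)] and n_excluded == 0

    def test_non_cds_ignored(self, genomes):
        feats = [make_orf("g", "c", 100, 400, feature_type="rRNA")]
        starts, _ = collect_start_positions(feats, genomes)
        assert starts == []


class TestMetageneProfile:
    def test_read_at_start(self, genomes):
        starts = [StartSite("c", "+", 100)]
        reads = [make_read("c", 100, 128, "+")]
        profile = metagene_profile(reads, starts, genomes, read_lengths=[28])
        assert profile.counts[0, profile.window_upstream] == 1
        assert profile.total() == 1

    def test_upstream_offset(self, genomes):
        starts = [StartSite("c", "+", 100)]
        reads = [make_read("c", 85, 113, "+")]
        profile = metagene_profile(reads, starts, genomes, read_lengths=[28])
        assert profile.counts[0, profile.window_upstream - 15] == 1

    def test_minus_strand_mirror_offset(self, genomes):
        starts = [StartSite("c", "-", 399)]
        reads = [make_read("c", 372, 400, "-")]  # 5' end at 399
        profile = metagene_profile(reads, starts, genomes, read_lengths=[28])
        assert profile.counts[0, profile.window_upstream] == 1

    def test_empty_starts_zero_profile(self, genomes):
        profile = metagene_profile([make_read("c", 0, 28, "+")], [], genomes)
        assert profile.total() == 0 and profile.n_genes == 0

    def test_overlapping_windows_count_multiply(self, genomes):
        starts = [StartSite("c", "+", 100), StartSite("c", "+", 110)]
        reads = [make_read("c", 105, 133, "+")]
        profile = metagene_profile(reads, starts, genomes, read_lengths=[28])
        assert profile.total() == 2

    def test_mass_equals_brute_force_incidence(self):
        rng = np.random.default_rng(11)
        for circular in (True, False):
            genome = GenomeSequence("g", "A" * 200, circular=circular)
            genomes = {"g": genome}
            starts = [
                StartSite("g", "+", 30),
                StartSite("g", "-", 120),
                StartSite("g", "+", 180),
            ]
            up, down = 15, 20
            lengths = range(5, 12)
            reads = random_reads(rng, genome, 50, max_len=11)
            if not circular:
                reads = [r for r in reads if r.interval.end <= 200]
            profile = metagene_profile(reads, starts, genomes, up, down, lengths)
            assert profile.total() == oracle_metagene_mass(
                reads, starts, genomes, up, down, lengths
            )

    def test_strand_mirror_symmetry(self):
        rng = np.random.default_rng(5)
        length = 300
        genome = GenomeSequence("g", "A" * length, circular=True)
        genomes = {"g": genome}
        annotation = [
            make_orf("a", "g", 60, 120, "+"),
            make_orf("b", "g", 150, 240, "-"),
            make_orf("o", "g", 280, 320, "+"),  # spans the origin
        ]
        reads = random_reads(rng, genome, 80, max_len=12)
        up, down = 20, 25
        starts, _ = collect_start_positions(annotation, genomes, up, down)
        profile = metagene_profile(reads, starts, genomes, up, down, range(1, 13))

        # reflect genome, reads, annotation through reverse complement
        def mirror_iv(iv):
            from riboprof.core import unwrap_interval
            return unwrap_interval(length - iv.end, length - iv.start,
                                   "-" if iv.strand == "+" else "+", genome)

        m_reads = [make_read("g", *(lambda v: (v.start, v.end))(mirror_iv(r.interval)),
                             mirror_iv(r.interval).strand) for r in reads]
        m_annotation = [
            make_orf(o.orf_id, "g", mirror_iv(o.interval).start,
                     mirror_iv(o.interval).end, mirror_iv(o.interval).strand)
            for o in annotation
        ]
        m_starts, _ = collect_start_positions(m_annotation, genomes, up, down)
        m_profile = metagene_profile(m_reads, m_starts, genomes, up, down, range(1, 13))
        np.testing.assert_array_equal(profile.counts, m_profile.counts)

    def test_planted_periodic_reads_recover_frame0(self, genomes):
        starts = [StartSite("c", "+", 300)]
        reads = [make_read("c", 300 + 3 * k, 328 + 3 * k, "+") for k in range(10)]
        profile = metagene_profile(reads, starts, genomes, read_lengths=[28])
        frames = frame_summary(profile)
        assert frames.loc[28, "frame_0"] == 1.0
        assert frames.loc[28, "frame_1"] == 0.0


class TestFrameSummary:
    def _profile(self, count_map, down=9):
        counts = np.zeros((1, 9 + down))
        for offset, n in count_map.items():
            counts[0, offset + 9] = n
        return MetageneProfile(9, down, [28], counts, n_genes=1)

    def test_pure_frame0(self):
        frames = frame_summary(self._profile({0: 3, 3: 3, 6: 3}))
        assert list(frames.loc[28]) == [1.0, 0.0, 0.0]

    def test_uniform(self):
        frames = frame_summary(self._profile({i: 1 for i in range(9)}))
        assert np.allclose(frames.loc[28], [1 / 3, 1 / 3, 1 / 3])

    def test_mixed(self):
        frames = frame_summary(self._profile({0: 2, 1: 1, 2: 1}))
        assert list(frames.loc[28]) == [0.5, 0.25, 0.25]

    def test_zero_signal_all_zero(self):
        frames = frame_summary(self._profile({}))
        assert list(frames.loc[28]) == [0.0, 0.0, 0.0]

    def test_upstream_signal_ignored(self):
        frames = frame_summary(self._profile({-3: 100, 0: 1}))
        assert list(frames.loc[28]) == [1.0, 0.0, 0.0]

    def test_fractions_sum_to_one_or_zero(self):
        for counts in ({0: 1, 1: 5, 2: 2, 4: 7}, {}):
            frames = frame_summary(self._profile(counts))
            total = frames.loc[28].sum()
            assert total in (0.0, pytest.approx(1.0))


def test_normalized_dataframe_rows_sum_to_one(genomes):
    starts = [StartSite("c", "+", 100)]
    reads = [make_read("c", 100, 128, "+"), make_read("c", 90, 118, "+")]
    profile = metagene_profile(reads, starts, genomes, read_lengths=[27, 28])
    df = profile.to_dataframe(normalized=True)
    assert df.loc[28].sum() == pytest.approx(1.0)
    assert df.loc[27].sum() == 0.0
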
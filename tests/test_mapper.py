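"""Seeding, multi-pass alignment, posteriors, and SAM emission."""

import numpy as np
import pysam
import pytest
import sympy

from conftest import naive_vote_counts, random_genome_string
from probsmap.mapper import (
    MapperConfig,
    align_read,
    candidate_locations,
    map_reads,
    posterior_probabilities,
    write_sam,
)
from probsmap.prob_align import BisulfiteRead
from probsmap.reference_index import (
    ReferenceGenome,
    bs_convert_sequence,
    build_hash,
    build_index,
    reverse_complement,
)


def make_read(id: str, bases: str, q: int = 40) -> BisulfiteRead:
    return BisulfiteRead(id, bases, np.full(len(bases), q))


@pytest.fixture(scope="module")
def planted() -> tuple[ReferenceGenome, str, int]:
    rng = np.random.default_rng(11)
    seq = random_genome_string(rng, 2000)
    start = 700
    return ReferenceGenome([("chr1", seq)]), seq[start : start + 60], start


class TestCandidateLocations:
    def test_unique_locus_all_votes_agree(self, planted):
        genome, read_seq, start = planted
        table = build_hash(genome, k=5, step=1)
        read = make_read("r", read_seq)
        cands = candidate_locations(read, table, "CT", "+", top_n=50)
        assert start in cands

    def test_votes_match_naive_full_scan(self, rng):
        genome = ReferenceGenome([("c", random_genome_string(rng, 500))])
        table = build_hash(genome, k=4, step=1)
        for _ in range(5):
            s = int(rng.integers(0, 460))
            read = make_read("r", genome.sequence[s : s + 30])
            got = candidate_locations(read, table, "CT", "+", top_n=1000)
            conv_read = bs_convert_sequence(read.bases, "CT")
            conv_genome = bs_convert_sequence(genome.sequence, "CT")
            votes = naive_vote_counts(conv_read, conv_genome, 4)
            top2 = sorted(set(votes.values()), reverse=True)[:2]
            expect = sorted(
                (s for s, v in votes.items() if v in top2),
                key=lambda x: (-votes[x], x),
            )
            assert sorted(got) == sorted(expect)

    def test_snp_locus_gets_fewer_votes(self, rng):
        core = random_genome_string(rng, 40)
        variant = "A" + core[1:] if core[0] != "A" else "T" + core[1:]
        filler1 = random_genome_string(rng, 50)
        filler2 = random_genome_string(rng, 50)
        seq = filler1 + core + filler2 + variant + filler1[::-1]
        genome = ReferenceGenome([("c", seq)])
        table = build_hash(genome, k=5, step=1)
        read = make_read("r", core)
        cands = candidate_locations(read, table, "CT", "+", top_n=10)
        exact = 50
        snp = 50 + 40 + 50
        assert cands[0] == exact  # exact locus outranks the SNP locus
        assert snp in cands

    def test_all_n_read_yields_nothing(self, planted):
        genome, _, _ = planted
        table = build_hash(genome, k=5, step=1)
        read = make_read("r", "N" * 30)
        assert candidate_locations(read, table, "CT", "+") == []


class TestPosteriors:
    def test_equal_scores_split_evenly(self):
        assert np.allclose(posterior_probabilities([2.5, 2.5]), [0.5, 0.5])

    def test_log_four_gap(self):
        p = posterior_probabilities([np.log(4.0), 0.0])
        assert np.allclose(p, [0.8, 0.2])

    def test_matches_arbitrary_precision_softmax(self):
        scores = [2.0, 1.0, 0.5]
        exact = [
            float(sympy.exp(s) / sum(sympy.exp(sympy.Float(t, 50)) for t in scores))
            for s in scores
        ]
        assert np.allclose(posterior_probabilities(scores), exact, atol=1e-12)

    def test_large_scores_are_stable(self):
        p = posterior_probabilities([1000.0, 999.0])
        assert np.isfinite(p).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            posterior_probabilities([])
        with pytest.raises(ValueError):
            posterior_probabilities([np.inf, 1.0])


class TestAlignRead:
    def test_fully_methylated_read_unique_locus(self, planted):
        genome, read_seq, start = planted
        index = build_index(genome, k=10)
        hs = align_read(make_read("r", read_seq), genome, index)
        assert hs.passed_threshold
        assert len(hs.hits) == 1
        hit = hs.hits[0]
        assert (hit.chrom, hit.pos, hit.strand) == ("chr1", start + 1, "+")
        assert hit.mode == "CT"
        assert hit.posterior == pytest.approx(1.0)

    def test_unmethylated_top_strand_read(self, planted):
        genome, read_seq, start = planted
        index = build_index(genome, k=10)
        bsr = bs_convert_sequence(read_seq, "CT")  # complete conversion
        hs = align_read(make_read("r", bsr), genome, index)
        best = hs.hits[0]
        assert (best.chrom, best.pos, best.mode, best.strand) == (
            "chr1", start + 1, "CT", "+",
        )

    def test_pcr_strand_read_maps_in_ga_mode(self, planted):
        # complement-of-bottom-strand chemistry shows G->A in genome frame
        genome, read_seq, start = planted
        index = build_index(genome, k=10)
        bsr = bs_convert_sequence(read_seq, "GA")
        hs = align_read(make_read("r", bsr), genome, index)
        best = hs.hits[0]
        assert (best.chrom, best.pos, best.mode, best.strand) == (
            "chr1", start + 1, "GA", "+",
        )

    def test_original_bottom_strand_read(self, planted):
        genome, read_seq, start = planted
        index = build_index(genome, k=10)
        # bottom-strand fragment, bisulfite-converted in its own frame
        bsr = bs_convert_sequence(reverse_complement(read_seq), "CT")
        hs = align_read(make_read("r", bsr), genome, index)
        best = hs.hits[0]
        assert (best.chrom, best.pos, best.strand, best.mode) == (
            "chr1", start + 1, "-", "GA",
        )

    def test_twin_loci_split_posterior(self, rng):
        core = random_genome_string(rng, 50)
        seq = (
            random_genome_string(rng, 60) + core
            + random_genome_string(rng, 60) + core
            + random_genome_string(rng, 60)
        )
        genome = ReferenceGenome([("c", seq)])
        index = build_index(genome, k=10)
        hs = align_read(make_read("r", core), genome, index)
        assert len(hs.hits) == 2
        assert [round(h.posterior, 9) for h in hs.hits] == [0.5, 0.5]
        assert {h.pos for h in hs.hits} == {61, 171}

    def test_posteriors_sum_to_one(self, planted, rng):
        genome, _, _ = planted
        index = build_index(genome, k=10)
        for _ in range(10):
            s = int(rng.integers(0, 1900))
            read_seq = genome.sequence[s : s + 60]
            hs = align_read(make_read("r", read_seq), genome, index)
            if hs.hits:
                assert sum(h.posterior for h in hs.hits) == pytest.approx(1.0, abs=1e-9)

    def test_reverse_complement_flips_strand_same_score(self, planted):
        genome, read_seq, start = planted
        index = build_index(genome, k=10)
        fwd = align_read(make_read("r", read_seq), genome, index)
        rev = align_read(make_read("r", reverse_complement(read_seq)), genome, index)
        assert fwd.hits[0].pos == rev.hits[0].pos
        assert {fwd.hits[0].strand, rev.hits[0].strand} == {"+", "-"}
        assert fwd.hits[0].score == pytest.approx(rev.hits[0].score)

    def test_garbage_read_reported_unmapped(self, planted, rng):
        genome, _, _ = planted
        index = build_index(genome, k=10)
        hs = align_read(make_read("r", "N" * 60), genome, index)
        assert not hs.passed_threshold
        assert hs.hits == []

    def test_planted_read_recovery_rate(self):
        rng = np.random.default_rng(99)
        genome = ReferenceGenome([("c", random_genome_string(rng, 100_000))])
        index = build_index(genome, k=17)
        n, correct = 200, 0
        for i in range(n):
            s = int(rng.integers(0, genome.total_length - 100))
            hs = align_read(make_read(f"r{i}", genome.sequence[s : s + 100]), genome, index)
            if hs.hits and hs.hits[0].pos == s + 1 and hs.hits[0].strand == "+":
                correct += 1
        assert correct / n >= 0.99


class TestSamOutput:
    def _roundtrip(self, hitsets, genome, tmp_path):
        path = tmp_path / "out.sam"
        write_sam(hitsets, genome, path)
        with pysam.AlignmentFile(str(path), "r") as fh:
            return list(fh)

    def test_unique_hit_gets_mapq_60(self, planted, tmp_path):
        genome, read_seq, start = planted
        index = build_index(genome, k=10)
        hs = align_read(make_read("r", read_seq), genome, index)
        (rec,) = self._roundtrip([hs], genome, tmp_path)
        assert rec.mapping_quality == 60
        assert not rec.is_secondary
        assert rec.reference_start == start
        assert rec.cigarstring == "60M"
        assert rec.get_tag("XB") == "C"
        assert rec.get_tag("XP") == pytest.approx(1.0)

    def test_equal_double_hit_mapq_and_secondary_flag(self, rng, tmp_path):
        core = random_genome_string(rng, 50)
        seq = "T" * 60 + core + "A" * 60 + core + "T" * 60
        genome = ReferenceGenome([("c", seq)])
        index = build_index(genome, k=10)
        hs = align_read(make_read("r", core), genome, index)
        recs = self._roundtrip([hs], genome, tmp_path)
        assert len(recs) == 2
        assert [r.is_secondary for r in recs] == [False, True]
        assert all(r.mapping_quality == 3 for r in recs)  # -10*log10(0.5) -> 3
        assert all(r.get_tag("XP") == pytest.approx(0.5) for r in recs)

    def test_unmapped_read_emitted_with_flag(self, planted, tmp_path):
        genome, _, _ = planted
        index = build_index(genome, k=10)
        hs = align_read(make_read("r", "N" * 40), genome, index)
        (rec,) = self._roundtrip([hs], genome, tmp_path)
        assert rec.is_unmapped

    def test_round_trip_preserves_fields(self, planted, tmp_path):
        genome, read_seq, start = planted
        index = build_index(genome, k=10)
        hs = align_read(make_read("r", read_seq), genome, index)
        (rec,) = self._roundtrip([hs], genome, tmp_path)
        hit = hs.hits[0]
        assert rec.reference_name == hit.chrom
        assert rec.reference_start + 1 == hit.pos
        assert rec.cigarstring == hit.cigar
        assert rec.get_tag("XP") == pytest.approx(hit.posterior, abs=1e-6)


class TestMapReadsWorkers:
    def test_worker_count_does_not_change_results(self, planted, tmp_path):
        genome, _, _ = planted
        index = build_index(genome, k=10)
        rng = np.random.default_rng(3)
        reads = []
        for i in range(40):
            s = int(rng.integers(0, 1900))
            reads.append(make_read(f"r{i}", genome.sequence[s : s + 60]))
        one = map_reads(reads, genome, index, workers=1)
        four = map_reads(reads, genome, index, workers=4)
        p1, p4 = tmp_path / "w1.sam", tmp_path / "w4.sam"
        write_sam(one, genome, p1)
        write_sam(four, genome, p4)
        assert p1.read_bytes() == p4.read_bytes()
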
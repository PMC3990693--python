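"""Local aligner correctness, recruitment thresholds, abundance normalization."""

import numpy as np
import pytest

from sagscope import (
    CommunityMember,
    abundance_matrix,
    local_align,
    make_genome,
    make_metagenome,
    recruit,
)
from sagscope.recruitment import InvalidInputError, RecruitHit
from sagscope.synthetic import ReadSet, _mutate_read
from sagscope._seq import revcomp
from conftest import random_dna
from _oracles import gotoh_local_score


class TestLocalAlign:
    def test_exact_substring(self, small_genome):
        read = small_genome.sequence[1000:1250]
        aln = local_align(read, small_genome.sequence)
        assert (aln.score, aln.identity, aln.aln_len, aln.strand) == (250.0, 1.0, 250, "+")
        assert (aln.start, aln.end) == (1000, 1250)

    def test_reverse_complement_same_score_minus_strand(self, small_genome):
        read = revcomp(small_genome.sequence[1000:1250])
        aln = local_align(read, small_genome.sequence)
        assert aln.score == 250.0
        assert aln.strand == "-"
        assert (aln.start, aln.end) == (1000, 1250)

    def test_scattered_substitutions_identity(self, rng):
        contig = random_dna(rng, 2000)
        read = list(contig[500:800])
        pos = rng.choice(300, size=12, replace=False)
        for p in pos:
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        aln = local_align("".join(read), contig, method="exact")
        # ends may be trimmed if a substitution falls at a boundary
        assert aln.identity <= 0.97
        if aln.aln_len == 300:
            assert aln.identity == pytest.approx(288 / 300)

    @pytest.mark.parametrize("seed", range(10))
    def test_score_matches_exhaustive_dp_short_pairs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a = random_dna(rng, int(rng.integers(30, 41)))
            b = random_dna(rng, int(rng.integers(30, 41)))
            expect = max(gotoh_local_score(a, b), gotoh_local_score(revcomp(a), b))
            got = local_align(a, b, method="exact")
            assert (0.0 if got is None else got.score) == expect

    def test_seeded_path_agrees_with_exact_on_real_reads(self, small_genome, rng):
        for _ in range(25):
            s = int(rng.integers(0, len(small_genome.sequence) - 300))
            read = _mutate_read(small_genome.sequence[s : s + 300], 0.05, rng)
            ex = local_align(read, small_genome.sequence, method="exact")
            se = local_align(read, small_genome.sequence, method="seeded")
            assert se is not None
            assert se.score == ex.score
            assert (se.start, se.end, se.identity) == (ex.start, ex.end, ex.identity)

    def test_short_read_rejected(self):
        with pytest.raises(InvalidInputError):
            local_align("ACGT", "ACGTACGT" * 100)


class TestRecruit:
    def _reads_at_divergence(self, genome, n, div, rng, read_len=300):
        reads = []
        for i in range(n):
            s = int(rng.integers(0, len(genome.sequence) - read_len))
            reads.append((f"r{i}", _mutate_read(genome.sequence[s : s + read_len], div, rng)))
        return ReadSet(sample_id="s", depth_m=0, reads=reads)

    def test_identity_boundary(self, rng):
        contig = random_dna(rng, 3000)
        # 250 bp read with 12 substitutions: identity 238/250 = 0.952 -> in
        # 250 bp read with 16 substitutions: identity 234/250 = 0.936 -> out
        def mutated(n_subs, offset):
            read = list(contig[offset : offset + 250])
            for p in np.linspace(20, 230, n_subs).astype(int):
                read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
            return "".join(read)

        from sagscope import Genome

        asm = Genome("t", contig, 0.5)
        rs = ReadSet("s", 0, [("ok", mutated(12, 500)), ("bad", mutated(16, 1500))])
        hits = recruit(rs, asm)
        assert [h.read_id for h in hits] == ["ok"]
        assert hits[0].identity >= 0.95

    def test_one_hit_per_read(self, small_genome, rng):
        rs = self._reads_at_divergence(small_genome, 50, 0.0, rng)
        hits = recruit(rs, small_genome)
        assert len(hits) == len({h.read_id for h in hits}) == 50

    def test_recruitment_fraction_vs_divergence(self, small_genome, rng):
        n = 300
        frac = {}
        for div in (0.02, 0.10):
            rs = self._reads_at_divergence(small_genome, n, div, rng)
            frac[div] = len(recruit(rs, small_genome)) / n
        assert frac[0.02] >= 0.95
        assert frac[0.10] <= 0.05

    def test_empty_assembly_rejected(self, small_genome):
        from sagscope.synthetic import SagAssembly

        empty = SagAssembly("x", "g", [], [], 0, set(), {})
        rs = ReadSet("s", 0, [("r", "ACGT" * 30)])
        with pytest.raises(InvalidInputError):
            recruit(rs, empty)


class TestAbundanceMatrix:
    def test_formula(self):
        am = abundance_matrix({("s1", "t1"): 100}, {"t1": 1_000_000}, {"s1": 10_000})
        assert am.table.loc["t1", "s1"] == pytest.approx(1.0)

    def test_doubling_length_halves_value(self):
        am1 = abundance_matrix({("s1", "t1"): 100}, {"t1": 1_000_000}, {"s1": 10_000})
        am2 = abundance_matrix({("s1", "t1"): 100}, {"t1": 2_000_000}, {"s1": 10_000})
        assert am2.table.loc["t1", "s1"] == pytest.approx(am1.table.loc["t1", "s1"] / 2)

    def test_community_ratio_recovered(self):
        g1 = make_genome(25_000, 0.4, seed=11, genome_id="g1")
        g2 = make_genome(25_000, 0.4, seed=12, genome_id="g2")
        members = [CommunityMember("g1", 0.8), CommunityMember("g2", 0.2)]
        rs = make_metagenome(members, {"g1": g1, "g2": g2}, 1500, (250, 350), seed=13)
        hits = {("s", g.genome_id): recruit(rs, g) for g in (g1, g2)}
        am = abundance_matrix(
            hits, {"g1": 25_000, "g2": 25_000}, {"s": len(rs.reads)}
        )
        n1 = len(hits[("s", "g1")])
        n2 = len(hits[("s", "g2")])
        sd = np.sqrt(1500 * 0.8 * 0.2)
        assert abs(n1 - 1200) <= 3 * sd
        assert am.table.loc["g1", "s"] / am.table.loc["g2", "s"] == pytest.approx(n1 / n2)

    def test_zero_read_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            abundance_matrix({}, {"t": 1000}, {"s": 0})

    def test_unregistered_target_rejected(self):
        with pytest.raises(InvalidInputError):
            abundance_matrix({("s", "t2"): 1}, {"t": 1000}, {"s": 10})
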
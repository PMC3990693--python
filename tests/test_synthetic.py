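"""Generator statistics: GC, divergence, assembly geometry, community
composition, shielding, and determinism."""

import math

import numpy as np
import pytest

from sagscope import (
    CommunityMember,
    make_genome,
    make_metagenome,
    make_occurrence_matrix,
    make_proteome_triplet,
    make_sag_assembly,
    mutate_genome,
    place_family_loci,
)
from sagscope.synthetic import InvalidParameterError


class TestMakeGenome:
    def test_gc_concentrates_on_target(self):
        g = make_genome(10_000, 0.34, seed=1)
        assert 0.31 <= g.gc <= 0.37

    def test_deterministic(self):
        assert make_genome(10_000, 0.34, seed=1).sequence == make_genome(10_000, 0.34, seed=1).sequence

    def test_base_counts_within_binomial_envelope(self):
        # exact binomial: each base has p=0.25, sd = sqrt(n p (1-p))
        g = make_genome(50_000, 0.50, seed=7)
        sd = math.sqrt(50_000 * 0.25 * 0.75)
        for base in "ACGT":
            assert abs(g.sequence.count(base) - 12_500) <= 3 * sd

    @pytest.mark.parametrize("length,gc", [(999, 0.5), (10_000, 0.1), (10_000, 0.9)])
    def test_rejects_out_of_range(self, length, gc):
        with pytest.raises(InvalidParameterError):
            make_genome(length, gc, seed=0)


class TestMutateGenome:
    def test_zero_divergence_is_identity(self, small_genome):
        assert mutate_genome(small_genome, 0.0, seed=5).sequence == small_genome.sequence

    def test_realized_divergence_within_3sd(self):
        g = make_genome(100_000, 0.5, seed=2)
        m = mutate_genome(g, 0.02, seed=3)
        ham = sum(a != b for a, b in zip(g.sequence, m.sequence)) / len(g)
        # binomial 3-sd envelope around 0.02 on 100 kbp
        assert 0.0187 <= ham <= 0.0213

    def test_deterministic_and_length_preserving(self, small_genome):
        m1 = mutate_genome(small_genome, 0.05, seed=9)
        m2 = mutate_genome(small_genome, 0.05, seed=9)
        assert m1.sequence == m2.sequence
        assert len(m1.sequence) == len(small_genome.sequence)


class TestSagAssembly:
    def test_full_single_contig_recovers_genome(self, small_genome):
        loci = place_family_loci(len(small_genome.sequence), [f"f{i}" for i in range(20)], seed=1)
        sag = make_sag_assembly(small_genome, 1.0, 1, loci, seed=4)
        assert sag.contigs[0][1] == small_genome.sequence
        assert sag.detected_families == set(loci)

    def test_assembly_length_matches_completeness(self, small_genome):
        sag = make_sag_assembly(small_genome, 0.5, 10, {}, seed=4)
        frac = sag.assembly_length / len(small_genome.sequence)
        assert 0.49 <= frac <= 0.51
        assert sum(len(s) for _, s in sag.contigs) == sag.assembly_length

    def test_contigs_are_disjoint_genome_substrings(self, small_genome):
        sag = make_sag_assembly(small_genome, 0.3, 8, {}, seed=11)
        prev_end = 0
        for (cid, seq), (s, e) in zip(sag.contigs, sag.contig_origins):
            assert s >= prev_end
            assert small_genome.sequence[s:e] == seq
            prev_end = e

    def test_mean_detected_fraction_tracks_completeness(self, small_genome):
        # Monte-Carlo: 94 point-like loci at completeness 0.5 -> ~50% detected
        fam = [f"m{i}" for i in range(94)]
        loci = place_family_loci(len(small_genome.sequence), fam, locus_len=60, seed=2)
        fracs = [
            len(make_sag_assembly(small_genome, 0.5, 10, loci, seed=s).detected_families) / 94
            for s in range(200)
        ]
        assert 0.45 <= float(np.mean(fracs)) <= 0.55

    def test_too_many_contigs_rejected(self, small_genome):
        with pytest.raises(InvalidParameterError):
            make_sag_assembly(small_genome, 0.0001, 50, {}, seed=0)


class TestMakeMetagenome:
    def _members(self, genome, **kw):
        return [CommunityMember(genome.genome_id, 1.0, **kw)]

    def test_clean_reads_are_exact_substrings_at_zero_divergence(self, small_genome):
        rs = make_metagenome(
            self._members(small_genome), {small_genome.genome_id: small_genome},
            200, (100, 300), seed=1,
        )
        assert len(rs.reads) == 200
        for rid, seq in rs.reads:
            gid, (s, e) = rs.truth[rid]
            assert small_genome.sequence[s:e] == seq

    def test_duplicate_fraction_constructed(self, small_genome):
        rs = make_metagenome(
            self._members(small_genome), {small_genome.genome_id: small_genome},
            1000, (100, 300), junk=(0, 0, 0.1, 0), seed=2,
        )
        seen = set()
        n_dup = 0
        for _, seq in rs.reads:
            if seq in seen:
                n_dup += 1
            seen.add(seq)
        assert n_dup >= 100

    def test_source_counts_follow_abundances(self):
        g1 = make_genome(30_000, 0.4, seed=1, genome_id="g1")
        g2 = make_genome(30_000, 0.4, seed=2, genome_id="g2")
        members = [CommunityMember("g1", 0.8), CommunityMember("g2", 0.2)]
        rs = make_metagenome(members, {"g1": g1, "g2": g2}, 5000, (100, 300), seed=3)
        n1 = sum(1 for v in rs.truth.values() if v[0] == "g1")
        sd = math.sqrt(5000 * 0.8 * 0.2)
        assert abs(n1 - 4000) <= 3 * sd

    def test_shielded_intervals_never_touched(self, small_genome):
        shields = [(1000, 3000), (20_000, 25_000)]
        members = [CommunityMember(small_genome.genome_id, 1.0, 0.02, shields)]
        rs = make_metagenome(
            members, {small_genome.genome_id: small_genome}, 500, (100, 400), seed=4,
        )
        for rid, (gid, (s, e)) in rs.truth.items():
            for ss, se in shields:
                assert not (s < se and ss < e)

    def test_read_count_conserved_with_junk(self, small_genome):
        rs = make_metagenome(
            self._members(small_genome), {small_genome.genome_id: small_genome},
            1000, (100, 300), junk=(0.1, 0.1, 0.1, 0.1), seed=5,
        )
        assert len(rs.reads) == 1000
        kinds = list(rs.kinds.values())
        for kind in ("short", "ambiguous", "duplicate", "low_complexity"):
            assert kinds.count(kind) == 100

    def test_empty_members_rejected(self, small_genome):
        with pytest.raises(InvalidParameterError):
            make_metagenome([], {}, 100, (100, 300), seed=0)


class TestOccurrenceMatrix:
    def test_no_noise_gives_universal_single_copy(self):
        occ = make_occurrence_matrix(50, 94, 30, dropout=0.0, dup_rate=0.0, seed=1)
        sc = occ.copies[:, :94]
        assert (sc == 1).all()

    def test_heavy_dropout_breaks_the_98pct_rule(self):
        from sagscope import derive_cscgs

        occ = make_occurrence_matrix(100, 50, 0, dropout=0.5, dup_rate=0.0, seed=2)
        frac_once = (occ.copies == 1).mean(axis=0)
        assert abs(float(frac_once.mean()) - 0.5) < 0.1
        assert len(derive_cscgs(occ, 0.98)) == 0

    def test_marker_survival_matches_binomial_tail(self):
        # P(a marker stays exactly-once in >= 152 of 155 genomes) when each
        # genome keeps it single-copy w.p. 0.99 (dropout 0.005, dup 0.005)
        from scipy.stats import binom

        p_keep = binom.sf(151, 155, 0.99)
        counts = []
        for s in range(100):
            occ = make_occurrence_matrix(155, 120, 0, dropout=0.005, dup_rate=0.005, seed=s)
            once = (occ.copies == 1).sum(axis=0)
            counts.append(int((once >= 152).sum()))
        expect = 120 * p_keep
        sd = math.sqrt(120 * p_keep * (1 - p_keep) / 100)
        assert abs(float(np.mean(counts)) - expect) <= 3 * sd + 1e-9


class TestProteomeTriplet:
    def test_shared_all_has_homologs_in_both(self):
        from sagscope import protein_align_score

        q, ra, rb, truth = make_proteome_triplet(1, 0, 0, 0, seed=1, n_decoys=0)
        (pid, seq) = q[0]
        assert truth[pid] == "shared_all"
        ident_a = sum(a == b for a, b in zip(seq, ra[0][1])) / len(seq)
        assert ident_a >= 0.70

    def test_unique_proteins_absent_from_references(self):
        from sagscope import bsr

        q, ra, rb, truth = make_proteome_triplet(0, 0, 0, 5, seed=2)
        for rec in bsr(q, ra, rb):
            assert rec.category == "unique"

    def test_truth_covers_query(self):
        q, _, _, truth = make_proteome_triplet(3, 2, 2, 3, seed=3)
        assert set(truth) == {pid for pid, _ in q}
        assert len(q) == 10
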
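"""Synthetic genomes, SAG assemblies, metagenomes, occurrence matrices and
proteomes with the statistical structure the analysis stages assume.

The generators emulate a mesopelagic archaeal single-cell genomics study:
low-GC (~34%) genomes, partial multiple-displacement-amplified assemblies
spanning a wide completeness range, depth-structured community abundances,
population-to-reference nucleotide divergence of a few percent, 454-style
reads of 100-800 bp spiked with short/ambiguous/duplicate/low-complexity
junk, and proteomes partitioned into shared and lineage-specific families.

Everything is a pure function of its arguments including an integer seed,
so all downstream stages are testable against exact generator truth with
no external data. Genomes default to the 50-200 kbp range rather than
megabase scale: every statistic downstream is rate-based and scale-free,
and desk-scale genomes keep full-pipeline runs to minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import DNA_ALPHABET, PROTEIN_ALPHABET, revcomp

_NT = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)


class InvalidParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Genome:
    genome_id: str
    sequence: str
    gc_target: float

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


@dataclass
class CommunityMember:
    """One population in a simulated community.

    ``shielded_intervals`` are 0-based half-open intervals on the genome
    from which no read is ever drawn — the ground truth for genomic-island
    calls (a shielded locus recruits nothing, by construction).
    """

    genome_id: str
    relative_abundance: float
    divergence: float = 0.0
    shielded_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.25:
            raise InvalidParameterError("divergence must be in [0, 0.25]")
        ivs = sorted(self.shielded_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise InvalidParameterError("shielded intervals overlap")
        for s, e in ivs:
            if s < 0 or e <= s:
                raise InvalidParameterError(f"bad shielded interval ({s}, {e})")


@dataclass
class ReadSet:
    """A simulated (or loaded) read sample.

    ``truth`` maps clean read ids to their (source genome, source interval);
    junk reads carry no placement truth. ``kinds`` labels every read as
    clean / short / ambiguous / duplicate / low_complexity, matching the
    attribution order of the QC filters.
    """

    sample_id: str
    depth_m: float
    reads: list[tuple[str, str]]
    truth: dict[str, tuple[str, tuple[int, int]]] | None = None
    kinds: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.reads]
        if len(ids) != len(set(ids)):
            raise InvalidParameterError("read ids must be unique")
        if self.truth is not None and not set(self.truth) <= set(ids):
            raise InvalidParameterError("truth keys must be a subset of read ids")


@dataclass
class SagAssembly:
    """A partial single-cell assembly: disjoint substrings of one genome."""

    sag_id: str
    genome_id: str
    contigs: list[tuple[str, str]]  # (contig_id, sequence)
    contig_origins: list[tuple[int, int]]  # genome interval of each contig
    assembly_length: int
    detected_families: set[str]
    family_contig_loci: dict[str, tuple[str, int, int]]  # family -> contig-relative locus

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]


# ---------------------------------------------------------------------------
# generators


def make_genome(length: int, gc_target: float, seed: int, genome_id: str = "genome") -> Genome:
    """Generate an i.i.d. random genome with P(G) + P(C) = gc_target."""
    if length < 1000:
        raise InvalidParameterError(f"genome length must be >= 1000 bp, got {length}")
    if not 0.2 <= gc_target <= 0.8:
        raise InvalidParameterError(f"gc_target must be in [0.2, 0.8], got {gc_target}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_target) / 2.0
    gc = gc_target / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    seq = _NT[idx].tobytes().decode()
    return Genome(genome_id=genome_id, sequence=seq, gc_target=gc_target)


def mutate_genome(genome: Genome, divergence: float, seed: int, genome_id: str | None = None) -> Genome:
    """Substitution-only mutated copy at the given expected per-base rate."""
    if not 0.0 <= divergence <= 0.25:
        raise InvalidParameterError("divergence must be in [0, 0.25]")
    if divergence == 0:
        return Genome(genome_id or genome.genome_id + "_mut", genome.sequence, genome.gc_target)
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    seq = _mutate_array(arr, divergence, rng)
    return Genome(genome_id or genome.genome_id + "_mut", seq, genome.gc_target)


def _mutate_array(arr: np.ndarray, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with prob ``divergence`` (never to itself)."""
    hit = np.nonzero(rng.random(arr.shape[0]) < divergence)[0]
    if hit.size:
        # map current base to one of the 3 alternatives
        cur = np.searchsorted(_NT, arr[hit])  # _NT is sorted (ACGT)
        offset = rng.integers(1, 4, size=hit.size)
        arr[hit] = _NT[(cur + offset) % 4]
    return arr.tobytes().decode()


def _mutate_read(seq: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    return _mutate_array(arr, divergence, rng)


def place_family_loci(
    genome_length: int,
    family_ids: list[str],
    locus_len: int = 60,
    seed: int = 0,
) -> dict[str, tuple[int, int]]:
    """Place non-overlapping marker loci uniformly along a genome.

    Loci are deliberately short (point-like relative to contigs) so that a
    locus is detected essentially whenever its position falls inside a
    retained contig; longer loci systematically undercount near contig ends.
    """
    n = len(family_ids)
    if n * locus_len * 2 > genome_length:
        raise InvalidParameterError("too many/long loci for genome length")
    rng = np.random.default_rng(seed)
    slot = genome_length // n
    loci: dict[str, tuple[int, int]] = {}
    for i, fam in enumerate(family_ids):
        lo = i * slot
        start = int(rng.integers(lo, lo + slot - locus_len))
        loci[fam] = (start, start + locus_len)
    return loci


def make_sag_assembly(
    genome: Genome,
    completeness: float,
    n_contigs: int,
    family_loci: dict[str, tuple[int, int]],
    seed: int,
    sag_id: str | None = None,
) -> SagAssembly:
    """Sample a partial assembly: ``n_contigs`` disjoint substrings totaling
    ``completeness`` x genome length, with detected families = families whose
    locus lies wholly inside a retained contig."""
    glen = len(genome.sequence)
    if not 0 < completeness <= 1:
        raise InvalidParameterError("completeness must be in (0, 1]")
    if n_contigs < 1:
        raise InvalidParameterError("n_contigs must be >= 1")
    total = int(round(completeness * glen))
    if total < n_contigs:
        raise InvalidParameterError(
            f"completeness x length ({total}) smaller than n_contigs ({n_contigs})"
        )
    rng = np.random.default_rng(seed)
    # contig lengths: positive composition of `total`
    lens = 1 + rng.multinomial(total - n_contigs, [1.0 / n_contigs] * n_contigs)
    # gaps between/around contigs: non-negative composition of the remainder
    gaps = rng.multinomial(glen - total, [1.0 / (n_contigs + 1)] * (n_contigs + 1))
    sag_id = sag_id or f"{genome.genome_id}_sag"
    contigs: list[tuple[str, str]] = []
    origins: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_contigs):
        pos += int(gaps[i])
        start, end = pos, pos + int(lens[i])
        contigs.append((f"{sag_id}_c{i:03d}", genome.sequence[start:end]))
        origins.append((start, end))
        pos = end
    detected: set[str] = set()
    contig_loci: dict[str, tuple[str, int, int]] = {}
    for fam, (fs, fe) in family_loci.items():
        for (cid, _), (cs, ce) in zip(contigs, origins):
            if cs <= fs and fe <= ce:
                detected.add(fam)
                contig_loci[fam] = (cid, fs - cs, fe - cs)
                break
    return SagAssembly(
        sag_id=sag_id,
        genome_id=genome.genome_id,
        contigs=contigs,
        contig_origins=origins,
        assembly_length=int(total),
        detected_families=detected,
        family_contig_loci=contig_loci,
    )


def _overlaps_shield(start: int, end: int, shields: list[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in shields)


def make_metagenome(
    members: list[CommunityMember],
    genomes: dict[str, Genome],
    n_reads: int,
    read_len_range: tuple[int, int] = (100, 800),
    junk: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
    seed: int = 0,
    sample_id: str = "sample",
    depth_m: float = 0.0,
) -> ReadSet:
    """Simulate one metagenome sample.

    Clean reads are drawn from member genomes proportionally to abundance,
    mutated at the member's divergence, and never overlap shielded
    intervals. Junk reads (short <100 bp, ambiguous, exact duplicates of
    earlier clean reads, low-complexity repeats) are appended according to
    the ``junk`` fractions ``(frac_short, frac_ambig, frac_dup,
    frac_lowcomplex)``. Clean reads are guaranteed pairwise distinct under
    the exact/prefix/reverse-complement duplicate relation and to pass the
    trinucleotide-entropy filter at 70, so QC removal counts reconcile
    exactly with the generated junk counts.
    """
    from .qc import entropy_score  # local import: qc depends on ReadSet above

    if not members:
        raise InvalidParameterError("empty member list")
    abunds = np.array([m.relative_abundance for m in members], dtype=float)
    if abs(abunds.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("member abundances must sum to 1")
    if any(f < 0 or f >= 1 for f in junk) or sum(junk) >= 0.5:
        raise InvalidParameterError("junk fractions must each be in [0,1) and sum < 0.5")
    lo, hi = read_len_range
    if not (30 <= lo <= hi <= 2000):
        raise InvalidParameterError("read_len_range must lie within [30, 2000]")
    for m in members:
        glen = len(genomes[m.genome_id].sequence)
        for s, e in m.shielded_intervals:
            if e > glen:
                raise InvalidParameterError("shielded interval outside genome bounds")

    rng = np.random.default_rng(seed)
    frac_short, frac_ambig, frac_dup, frac_lowcomplex = junk
    n_short = int(round(frac_short * n_reads))
    n_ambig = int(round(frac_ambig * n_reads))
    n_dup = int(round(frac_dup * n_reads))
    n_lowc = int(round(frac_lowcomplex * n_reads))
    n_clean = n_reads - n_short - n_ambig - n_dup - n_lowc
    if n_clean <= 0:
        raise InvalidParameterError("junk fractions leave no clean reads")
    clean_lo = max(lo, 100)  # clean reads must pass the 100 bp filter

    reads: list[tuple[str, str]] = []
    truth: dict[str, tuple[str, tuple[int, int]]] = {}
    kinds: dict[str, str] = {}
    seen: set[str] = set()
    rc_seen: set[str] = set()
    prefix_index: dict[str, list[str]] = {}

    def collides(seq: str) -> bool:
        """True if seq would be removed by the exact/prefix/revcomp dedupe."""
        if seq in seen or seq in rc_seen:
            return True
        for r in prefix_index.get(seq[:16], ()):
            if len(seq) <= len(r) and r.startswith(seq):
                return True
        return False

    def register(seq: str) -> None:
        seen.add(seq)
        rc_seen.add(revcomp(seq))
        prefix_index.setdefault(seq[:16], []).append(seq)

    def draw_clean() -> tuple[str, str, tuple[int, int]]:
        for _ in range(2000):
            mi = int(rng.choice(len(members), p=abunds))
            m = members[mi]
            gseq = genomes[m.genome_id].sequence
            rlen = int(rng.integers(clean_lo, hi + 1))
            if rlen > len(gseq):
                rlen = len(gseq)
            start = int(rng.integers(0, len(gseq) - rlen + 1))
            if _overlaps_shield(start, start + rlen, m.shielded_intervals):
                continue
            seq = _mutate_read(gseq[start : start + rlen], m.divergence, rng)
            if collides(seq) or entropy_score(seq) < 70.0:
                continue
            return m.genome_id, seq, (start, start + rlen)
        raise InvalidParameterError(
            "could not place a clean read; shields too dense or genome too repetitive"
        )

    idx = 0

    def emit(seq: str, kind: str, tr: tuple[str, tuple[int, int]] | None = None) -> None:
        nonlocal idx
        rid = f"{sample_id}_r{idx:06d}"
        idx += 1
        reads.append((rid, seq))
        kinds[rid] = kind
        if tr is not None:
            truth[rid] = tr

    clean_seqs: list[str] = []
    for _ in range(n_clean):
        gid, seq, interval = draw_clean()
        register(seq)
        clean_seqs.append(seq)
        emit(seq, "clean", (gid, interval))

    for _ in range(n_short):
        rlen = int(rng.integers(30, 100))
        seq = _NT[rng.choice(4, size=rlen)].tobytes().decode()
        emit(seq, "short")
    for _ in range(n_ambig):
        gid, seq, _ = draw_clean()  # not registered: removed before dedupe
        arr = list(seq)
        n_ns = int(rng.integers(1, 6))
        for p in rng.choice(len(arr), size=min(n_ns, len(arr)), replace=False):
            arr[int(p)] = "N"
        emit("".join(arr), "ambiguous")
    for _ in range(n_dup):
        emit(clean_seqs[int(rng.integers(0, len(clean_seqs)))], "duplicate")
    # motif pool with no two members equal under the exact/prefix/revcomp
    # relation at equal length; per-motif lengths strictly increase so a
    # later read is never a 5' prefix of an earlier one
    motifs = ["A", "C", "AC", "AG", "AT", "CA", "CG", "GA", "TA", "GC"]
    next_len = {m: clean_lo for m in motifs}
    for i in range(n_lowc):
        motif = motifs[i % len(motifs)]
        for _ in range(200):
            rlen = next_len[motif]
            next_len[motif] += 1
            seq = (motif * (rlen // len(motif) + 1))[:rlen]
            if not collides(seq):
                break
        else:  # pragma: no cover - collisions with clean reads are freak events
            raise InvalidParameterError("could not generate a distinct low-complexity read")
        register(seq)
        emit(seq, "low_complexity")

    return ReadSet(sample_id=sample_id, depth_m=depth_m, reads=reads, truth=truth, kinds=kinds)


def make_occurrence_matrix(
    n_genomes: int,
    n_single_copy: int,
    n_accessory: int,
    dropout: float = 0.0,
    dup_rate: float = 0.0,
    seed: int = 0,
):
    """Simulate a genome x gene-family copy-count matrix.

    Single-copy families are present exactly once in every genome except for
    independent dropout (copy 0) and duplication (copy 2) events; accessory
    families are present in a random subset of genomes.
    Returns an :class:`~sagscope.completeness.OccurrenceMatrix`.
    """
    from .completeness import OccurrenceMatrix

    if n_genomes < 10:
        raise InvalidParameterError("need at least 10 genomes")
    rng = np.random.default_rng(seed)
    genome_ids = [f"g{i:03d}" for i in range(n_genomes)]
    sc_ids = [f"SC{i:04d}" for i in range(n_single_copy)]
    acc_ids = [f"ACC{i:04d}" for i in range(n_accessory)]
    sc = np.ones((n_genomes, n_single_copy), dtype=int)
    if n_single_copy:
        drop = rng.random(sc.shape) < dropout
        dup = rng.random(sc.shape) < dup_rate
        sc[dup] = 2
        sc[drop] = 0  # dropout wins when both fire
    acc = np.zeros((n_genomes, n_accessory), dtype=int)
    for j in range(n_accessory):
        prev = rng.uniform(0.05, 0.8)
        present = rng.random(n_genomes) < prev
        acc[present, j] = rng.integers(1, 3, size=int(present.sum()))
    copies = np.hstack([sc, acc]) if n_accessory else sc
    return OccurrenceMatrix(genome_ids=genome_ids, family_ids=sc_ids + acc_ids, copies=copies)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aa = np.frombuffer(PROTEIN_ALPHABET.encode(), dtype=np.uint8)
    return aa[rng.integers(0, len(aa), size=length)].tobytes().decode()


def _mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    aa = PROTEIN_ALPHABET
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < divergence)[0]:
        cur = out[int(i)]
        choices = aa.replace(cur, "")
        out[int(i)] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def make_proteome_triplet(
    n_shared_all: int,
    n_shared_a: int,
    n_shared_b: int,
    n_unique: int,
    seed: int = 0,
    length_range: tuple[int, int] = (120, 240),
    homolog_divergence: float = 0.2,
    n_decoys: int = 5,
):
    """Generate a query proteome plus two reference proteomes with known
    homology structure.

    Shared families get a high-identity (default 80%) homolog in the
    designated reference(s); unique families are random sequences absent
    from both references. Each reference also carries ``n_decoys`` random
    proteins with no query counterpart. Returns
    (query, ref_a, ref_b, truth) where the proteomes are lists of
    (protein_id, sequence) and truth maps query protein id -> category in
    {shared_all, shared_a_only, shared_b_only, unique}.
    """
    total = n_shared_all + n_shared_a + n_shared_b + n_unique
    if min(n_shared_all, n_shared_a, n_shared_b, n_unique) < 0 or total < 1:
        raise InvalidParameterError("counts must be >= 0 with positive total")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    query: list[tuple[str, str]] = []
    ref_a: list[tuple[str, str]] = []
    ref_b: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    plan = (
        [("shared_all", True, True)] * n_shared_all
        + [("shared_a_only", True, False)] * n_shared_a
        + [("shared_b_only", False, True)] * n_shared_b
        + [("unique", False, False)] * n_unique
    )
    for i, (cat, in_a, in_b) in enumerate(plan):
        pid = f"q{i:04d}"
        seq = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        query.append((pid, seq))
        truth[pid] = cat
        if in_a:
            ref_a.append((f"a_{pid}", _mutate_protein(seq, homolog_divergence, rng)))
        if in_b:
            ref_b.append((f"b_{pid}", _mutate_protein(seq, homolog_divergence, rng)))
    for j in range(n_decoys):
        ref_a.append((f"a_decoy{j:03d}", _random_protein(rng, int(rng.integers(lo, hi + 1)))))
        ref_b.append((f"b_decoy{j:03d}", _random_protein(rng, int(rng.integers(lo, hi + 1)))))
    return query, ref_a, ref_b, truth


def make_ssu_clouds(
    n_clouds: int,
    members_per_cloud: list[int],
    sites: list[str],
    seq_len: int = 1200,
    within_divergence: float = 0.003,
    seed: int = 0,
):
    """Generate SSU rRNA-like sequence clouds for phylotype clustering tests.

    ``within_divergence`` is the expected *pairwise* divergence between
    cloud members (well inside a 99% identity radius at the default);
    members are mutated from a common ancestor at half that rate. Distinct
    clouds are unrelated random sequences (~25% background identity).
    Returns a list of (seq_id, sequence, site) and a truth map
    seq_id -> cloud index.
    """
    if len(members_per_cloud) != n_clouds:
        raise InvalidParameterError("members_per_cloud length must equal n_clouds")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, str]] = []
    truth: dict[str, int] = {}
    for c in range(n_clouds):
        anc = _NT[rng.choice(4, size=seq_len)].tobytes().decode()
        for m in range(members_per_cloud[c]):
            sid = f"ssu_c{c}_{m:02d}"
            seq = _mutate_read(anc, within_divergence / 2.0, rng)
            site = sites[int(rng.integers(0, len(sites)))]
            records.append((sid, seq, site))
            truth[sid] = c
    return records, truth
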
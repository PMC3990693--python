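"""Fragment recruitment: align metagenome reads to assemblies and build the
length-normalized genome x metagenome abundance matrix.

Reads (or their reverse complements) are aligned with an optimal local
aligner under match +1 / mismatch -1 and affine gaps (first gap column -2,
each additional column -1), the scoring BLASTN uses for reward 1 /
penalty -1. A read is a *unique recruit* of an assembly when its single
best alignment spans >= 200 columns at >= 95% identity, where identity is
matches / alignment columns with gap columns in the denominator. Abundance
is the percentage of sample reads recruited per Mbp of assembly; each
target recruits independently (no cross-target competition), mirroring
per-genome BLAST runs.

For long contigs a seed step (bit-parallel edit-distance search with
edlib) locates the best-matching region and the optimal aligner is run on
a padded window; the emitted alignment is still produced by the exact
dynamic program, so hits agree with a full-matrix alignment for any read
similar enough to pass the recruitment thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from ._seq import revcomp
from .synthetic import Genome, ReadSet, SagAssembly


class InvalidInputError(ValueError):
    pass


#: contig x read DP cell budget below which the full exact matrix is used
_EXACT_CELL_LIMIT = 2_000_000
_WINDOW_PAD = 60


@dataclass
class LocalAlignment:
    score: float
    start: int  # 0-based half-open on the target/contig
    end: int
    aln_len: int  # alignment columns incl. gap columns
    identity: float  # matches / alignment columns
    strand: str  # "+" or "-"
    matches: int


@dataclass
class RecruitHit:
    read_id: str
    target_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    aln_len: int
    identity: float
    score: float


def _make_aligner(match: int = 1, mismatch: int = -1, gap_open: int = -2, gap_extend: int = -1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_NT_ALIGNER = _make_aligner()


def _score_floor(min_aln_len: int | None, min_identity: float | None) -> float:
    """Lowest possible score of a best alignment that passes the filters:
    an alignment with C >= min_aln_len columns at identity >= id scores at
    least (3*id - 2)*C (each error column costs at most 2). Only useful
    when id > 2/3."""
    if min_aln_len is None or min_identity is None or min_identity <= 2.0 / 3.0:
        return 0.0
    return (3.0 * min_identity - 2.0) * min_aln_len


def _align_window(
    contig: str, read: str, offset: int, strand: str, score_floor: float = 0.0
) -> LocalAlignment | None:
    alns = _NT_ALIGNER.align(contig, read)
    if alns.score <= 0 or alns.score < score_floor:
        return None
    aln = alns[0]
    counts = aln.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    if aln_len == 0:
        return None
    return LocalAlignment(
        score=float(aln.score),
        start=int(aln.coordinates[0][0]) + offset,
        end=int(aln.coordinates[0][-1]) + offset,
        aln_len=int(aln_len),
        identity=counts.identities / aln_len,
        strand=strand,
        matches=int(counts.identities),
    )


def _seeded_on_strand(
    read: str, contig: str, strand: str, max_locs: int = 2, score_floor: float = 0.0
) -> LocalAlignment | None:
    """Locate the best-matching region with a bit-parallel infix edit-
    distance search (edlib), then realign a padded window with the exact
    dynamic program."""
    res = edlib.align(read, contig, mode="HW", task="locations")
    best: LocalAlignment | None = None
    for s, e in (res.get("locations") or [])[:max_locs]:
        lo = max(0, (s or 0) - _WINDOW_PAD)
        hi = min(len(contig), e + 1 + _WINDOW_PAD)
        cand = _align_window(contig[lo:hi], read, lo, strand, score_floor)
        if cand is None:
            continue
        if best is None or cand.score > best.score or (
            cand.score == best.score and cand.start < best.start
        ):
            best = cand
    return best


def _edit_distance(read: str, contig: str) -> int:
    d = edlib.align(read, contig, mode="HW", task="distance")["editDistance"]
    return len(read) if d < 0 else d


def _unreachable_distance(read_len: int, min_aln_len: int, min_identity: float) -> float:
    """Upper bound on the infix edit distance of any read containing a
    local alignment that passes the recruitment filters.

    Such an alignment has C >= min_aln_len columns with at most (1-id)*C
    error columns; aligning the same core and paying <= 1 per remaining
    read base bounds the infix distance by L - (2*id - 1)*C, maximal at
    C = min_aln_len for id > 0.5. A read whose best infix distance exceeds
    this bound on a strand cannot recruit on that strand.
    """
    if min_identity <= 0.5:
        return float("inf")
    return read_len - (2.0 * min_identity - 1.0) * min_aln_len


def local_align(
    read: str,
    contig: str,
    method: str = "auto",
    min_aln_len: int | None = None,
    min_identity: float | None = None,
) -> LocalAlignment | None:
    """Best local alignment of a read or its reverse complement to a contig.

    Returns None when no positive-scoring alignment exists. Ties between
    strands go to "+". ``method`` is "exact" (full DP matrix), "seeded"
    (edlib-located window + exact DP on the better strand) or "auto"
    (exact below a cell budget).

    ``min_aln_len``/``min_identity``, when both given, let the seeded path
    skip reads that provably cannot pass those recruitment thresholds; the
    return value is then None instead of a sub-threshold alignment.
    """
    if len(read) < 30:
        raise InvalidInputError("reads shorter than 30 bp are not alignable here")
    if method not in ("auto", "exact", "seeded"):
        raise InvalidInputError(f"unknown method {method!r}")
    if method == "auto":
        exact = len(read) * len(contig) <= _EXACT_CELL_LIMIT or len(read) > len(contig)
    else:
        exact = method == "exact"
    floor = _score_floor(min_aln_len, min_identity)
    if exact:
        fwd = _align_window(contig, read, 0, "+", floor)
        rev = _align_window(contig, revcomp(read), 0, "-", floor)
        if fwd is None:
            return rev
        if rev is None:
            return fwd
        return rev if rev.score > fwd.score else fwd

    rc = revcomp(read)
    d_fwd = _edit_distance(read, contig)
    d_rev = _edit_distance(rc, contig)
    if min_aln_len is not None and min_identity is not None:
        bound = _unreachable_distance(len(read), min_aln_len, min_identity)
        if min(d_fwd, d_rev) > bound:
            return None
    # the strand with the clearly smaller edit distance holds the best
    # alignment; realign both only when the margin is ambiguous
    margin = max(5, len(read) // 20)
    fwd = rev = None
    if d_fwd <= d_rev + margin:
        fwd = _seeded_on_strand(read, contig, "+", score_floor=floor)
    if d_rev <= d_fwd + margin:
        rev = _seeded_on_strand(rc, contig, "-", score_floor=floor)
    if fwd is None:
        return rev
    if rev is None:
        return fwd
    return rev if rev.score > fwd.score else fwd


def _contigs_of(assembly: Union[SagAssembly, Genome]) -> list[tuple[str, str]]:
    if isinstance(assembly, SagAssembly):
        return assembly.contigs
    return [(assembly.genome_id, assembly.sequence)]


def _target_id_of(assembly: Union[SagAssembly, Genome]) -> str:
    return assembly.sag_id if isinstance(assembly, SagAssembly) else assembly.genome_id


def recruit(
    reads: ReadSet,
    assembly: Union[SagAssembly, Genome],
    min_aln_len: int = 200,
    min_identity: float = 0.95,
    method: str = "auto",
) -> list[RecruitHit]:
    """Recruit reads to one assembly: at most one (best-scoring) hit per
    read, emitted iff alignment length >= ``min_aln_len`` columns and
    identity >= ``min_identity``."""
    contigs = [c for c in _contigs_of(assembly) if c[1]]
    if not contigs:
        raise InvalidInputError("empty assembly")
    target_id = _target_id_of(assembly)
    hits: list[RecruitHit] = []
    for read_id, seq in reads.reads:
        best: LocalAlignment | None = None
        best_contig = ""
        for contig_id, contig_seq in contigs:
            aln = local_align(
                seq, contig_seq, method=method,
                min_aln_len=min_aln_len, min_identity=min_identity,
            )
            if aln is None:
                continue
            if best is None or aln.score > best.score:
                best, best_contig = aln, contig_id
        if best is None:
            continue
        if best.aln_len >= min_aln_len and best.identity >= min_identity:
            hits.append(
                RecruitHit(
                    read_id=read_id,
                    target_id=target_id,
                    contig_id=best_contig,
                    start=best.start,
                    end=best.end,
                    strand=best.strand,
                    aln_len=best.aln_len,
                    identity=best.identity,
                    score=best.score,
                )
            )
    return hits


@dataclass
class AbundanceMatrix:
    """Targets x samples table of percent-of-reads recruited per Mbp."""

    table: pd.DataFrame  # index: target_ids, columns: sample_ids
    n_reads_per_sample: dict[str, int]

    @property
    def target_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.columns)

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy()


def abundance_matrix(
    hits: Mapping[tuple[str, str], Union[int, Sequence[RecruitHit]]],
    assembly_lengths: Mapping[str, int],
    n_reads: Mapping[str, int],
) -> AbundanceMatrix:
    """Build the normalized abundance table.

    value(target, sample) = 100 * n_hits / n_reads(sample)
                                / (assembly_length(target) / 1e6)

    ``hits`` maps (sample_id, target_id) to a hit list or a hit count.
    """
    samples = sorted(n_reads)
    targets = sorted(assembly_lengths)
    for sample, n in n_reads.items():
        if n <= 0:
            raise InvalidInputError(f"sample {sample!r} has zero reads: column undefined")
    for (sample, target) in hits:
        if sample not in n_reads:
            raise InvalidInputError(f"unregistered sample {sample!r}")
        if target not in assembly_lengths:
            raise InvalidInputError(f"unregistered target {target!r}")
    mat = np.zeros((len(targets), len(samples)))
    for (sample, target), h in hits.items():
        count = h if isinstance(h, int) else len(h)
        i, j = targets.index(target), samples.index(sample)
        mat[i, j] = 100.0 * count / n_reads[sample] / (assembly_lengths[target] / 1e6)
    table = pd.DataFrame(mat, index=targets, columns=samples)
    return AbundanceMatrix(table=table, n_reads_per_sample=dict(n_reads))
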
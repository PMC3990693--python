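"""BLAST Score Ratio (BSR) proteome partitioning.

Each query protein is scored against itself and against two reference
proteomes with an optimal local aligner (BLOSUM62, affine gaps: first gap
column -11, each additional -1). The BSR against a reference is the best
raw score over that reference's proteins divided by the query's
self-alignment score, so it lies in [0, 1] with 1 meaning a verbatim
match. Queries with BSR > 0.4 (roughly 30% amino-acid identity) against a
reference are considered homologous to it, which partitions the proteome
into four classes: shared with both references, shared with exactly one,
or unique.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import PROTEIN_ALPHABET

CATEGORIES = ("shared_all", "shared_a_only", "shared_b_only", "unique")


class InvalidResidueError(ValueError):
    pass


class InvalidInputError(ValueError):
    pass


@dataclass
class BsrRecord:
    protein_id: str
    self_score: float
    score_a: float
    score_b: float
    ratio_a: float
    ratio_b: float
    category: str


def _make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_AA_ALIGNER = _make_protein_aligner()
_AA_SET = set(PROTEIN_ALPHABET)


def _check_protein(seq: str, what: str = "protein") -> None:
    if not seq:
        raise InvalidInputError(f"empty {what} sequence")
    bad = set(seq) - _AA_SET
    if bad:
        raise InvalidResidueError(
            f"non-standard residues {sorted(bad)} in {what}; ambiguous residues "
            "(X, B, Z, ...) must be resolved or removed upstream"
        )


def protein_align_score(a: str, b: str) -> float:
    """Optimal local-alignment raw score of two proteins (BLOSUM62, 11/1
    affine gaps). Symmetric in its arguments; 0 when no positive-scoring
    alignment exists."""
    _check_protein(a, "first")
    _check_protein(b, "second")
    return float(max(_AA_ALIGNER.score(a, b), 0.0))


def nonredundant(proteins: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Exact-sequence deduplication, keeping the first occurrence."""
    seen: set[str] = set()
    out = []
    for pid, seq in proteins:
        if seq not in seen:
            seen.add(seq)
            out.append((pid, seq))
    return out


def _best_ratio(seq: str, self_score: float, reference: Sequence[tuple[str, str]]) -> tuple[float, float]:
    best = 0.0
    for _, ref_seq in reference:
        s = protein_align_score(seq, ref_seq)
        if s > best:
            best = s
    return best, max(best / self_score, 0.0)


def bsr(
    query_proteome: Sequence[tuple[str, str]],
    ref_a: Sequence[tuple[str, str]],
    ref_b: Sequence[tuple[str, str]],
    threshold: float = 0.4,
) -> list[BsrRecord]:
    """Score every query protein against both references and classify it.

    A reference counts as homologous when its best score ratio is strictly
    greater than ``threshold``. An empty reference yields all-zero scores
    (every query is then non-homologous to it), not an error.
    """
    if not query_proteome:
        raise InvalidInputError("empty query proteome")
    records: list[BsrRecord] = []
    for pid, seq in query_proteome:
        self_score = protein_align_score(seq, seq)
        if self_score <= 0:
            raise InvalidInputError(f"protein {pid!r} has non-positive self score")
        score_a, ratio_a = _best_ratio(seq, self_score, ref_a)
        score_b, ratio_b = _best_ratio(seq, self_score, ref_b)
        in_a = ratio_a > threshold
        in_b = ratio_b > threshold
        if in_a and in_b:
            category = "shared_all"
        elif in_a:
            category = "shared_a_only"
        elif in_b:
            category = "shared_b_only"
        else:
            category = "unique"
        records.append(
            BsrRecord(
                protein_id=pid,
                self_score=self_score,
                score_a=score_a,
                score_b=score_b,
                ratio_a=ratio_a,
                ratio_b=ratio_b,
                category=category,
            )
        )
    return records


def bsr_summary(records: Sequence[BsrRecord]) -> dict:
    """Category counts and fractions; ``fraction_unique`` is the share of
    query proteins homologous to neither reference."""
    counts = Counter(r.category for r in records)
    total = len(records)
    summary = {
        "n_total": total,
        "counts": {cat: counts.get(cat, 0) for cat in CATEGORIES},
    }
    if total:
        summary["fractions"] = {cat: counts.get(cat, 0) / total for cat in CATEGORIES}
        summary["fraction_unique"] = counts.get("unique", 0) / total
    return summary
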
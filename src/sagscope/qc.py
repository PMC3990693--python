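"""Metagenome read pre-filters applied before fragment recruitment.

Four sequence-level filters, applied in a fixed order so each removed read
is attributed to exactly one rule:

1. minimum length (default 100 bp),
2. ambiguity (any non-A/C/G/T character, e.g. N),
3. duplicate removal (exact copy, exact 5' prefix of a retained read, or
   exact reverse complement of a retained read),
4. low trinucleotide entropy (default threshold 70 on a 0-100 scale).

The entropy score is defined normatively here so results are reproducible
without any external tool: the Shannon entropy (bits) of the distribution
of overlapping 3-mers, rescaled so that a sequence in which all observable
trimer states are equally frequent scores 100 and a homopolymer scores 0.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from ._seq import revcomp
from .synthetic import ReadSet


class InvalidSequenceError(ValueError):
    pass


DUP_CLASSES = frozenset({"exact", "prefix", "revcomp"})
_PREFIX_KEY_LEN = 16


@dataclass
class QcReport:
    """Removal accounting for one filtering pass.

    Counts always reconcile: n_input = n_retained + sum of removals.
    """

    n_input: int = 0
    n_removed_short: int = 0
    n_removed_ambiguous: int = 0
    n_removed_duplicate: int = 0
    n_removed_low_entropy: int = 0
    n_retained: int = 0

    def reconciles(self) -> bool:
        removed = (
            self.n_removed_short
            + self.n_removed_ambiguous
            + self.n_removed_duplicate
            + self.n_removed_low_entropy
        )
        return self.n_input == self.n_retained + removed


def entropy_score(sequence: str) -> float:
    """Trinucleotide entropy of a read on a 0-100 scale.

    score = 100 * H / log2(min(L - 2, 64)) where H is the Shannon entropy
    (bits) of the overlapping 3-mer distribution and L the sequence length.
    A sequence with a single distinct trimer scores 0.

    Raises
    ------
    InvalidSequenceError
        If the sequence is shorter than 3 bp or contains ambiguity codes.
    """
    length = len(sequence)
    if length < 3:
        raise InvalidSequenceError(f"sequence shorter than 3 bp (L={length})")
    if set(sequence) - set("ACGT"):
        raise InvalidSequenceError("ambiguity codes not allowed in entropy_score")
    n_trimers = length - 2
    counts = Counter(sequence[i : i + 3] for i in range(n_trimers))
    h = 0.0
    for c in counts.values():
        p = c / n_trimers
        h -= p * math.log2(p)
    n_states = min(n_trimers, 64)
    if n_states < 2:
        return 0.0
    return 100.0 * h / math.log2(n_states)


def _is_duplicate(
    seq: str,
    exact: set[str],
    rc_of_retained: set[str],
    prefix_index: dict[str, list[str]],
    short_retained: list[str],
    classes: frozenset[str],
) -> bool:
    if "exact" in classes and seq in exact:
        return True
    if "revcomp" in classes and seq in rc_of_retained:
        return True
    if "prefix" in classes:
        if len(seq) >= _PREFIX_KEY_LEN:
            for r in prefix_index.get(seq[:_PREFIX_KEY_LEN], ()):
                if len(seq) <= len(r) and r.startswith(seq):
                    return True
        else:
            # reads shorter than the index key: rare, scan linearly
            for r in short_retained:
                if len(seq) <= len(r) and r.startswith(seq):
                    return True
            for key, rs in prefix_index.items():
                if key.startswith(seq):
                    return True
    return False


def dedupe(
    reads: Sequence[tuple[str, str]],
    classes: Iterable[str] = DUP_CLASSES,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Remove replicate reads, keeping the first occurrence in input order.

    A read is a duplicate of the retained set if it is an exact copy, an
    exact 5' prefix of a retained read, or the exact reverse complement of
    a retained read (classes configurable).

    Returns (retained reads, removed read ids).
    """
    classes = frozenset(classes)
    unknown = classes - DUP_CLASSES
    if unknown:
        raise ValueError(f"unknown duplicate classes: {sorted(unknown)}")
    exact: set[str] = set()
    rc_of_retained: set[str] = set()
    prefix_index: dict[str, list[str]] = {}
    short_retained: list[str] = []
    kept: list[tuple[str, str]] = []
    removed: list[str] = []
    for read_id, seq in reads:
        if _is_duplicate(seq, exact, rc_of_retained, prefix_index, short_retained, classes):
            removed.append(read_id)
            continue
        kept.append((read_id, seq))
        exact.add(seq)
        rc_of_retained.add(revcomp(seq))
        if len(seq) >= _PREFIX_KEY_LEN:
            prefix_index.setdefault(seq[:_PREFIX_KEY_LEN], []).append(seq)
        else:
            short_retained.append(seq)
    return kept, removed


def filter_reads(
    reads: ReadSet,
    min_len: int = 100,
    min_entropy: float = 70.0,
    drop_ambiguous: bool = True,
    dedupe_reads: bool = True,
    dup_classes: Iterable[str] = DUP_CLASSES,
) -> tuple[ReadSet, QcReport]:
    """Apply the pre-recruitment filters in order: length, ambiguity,
    duplicate, entropy.

    Each read is counted under the first rule it fails; retained reads are
    unchanged and in input order. A read is retained by the entropy rule
    when its score is >= ``min_entropy``.
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3 (entropy needs >= 1 trimer)")
    report = QcReport(n_input=len(reads.reads))
    survivors: list[tuple[str, str]] = []
    for read_id, seq in reads.reads:
        if len(seq) < min_len:
            report.n_removed_short += 1
        elif drop_ambiguous and (set(seq) - set("ACGT")):
            report.n_removed_ambiguous += 1
        else:
            survivors.append((read_id, seq))

    if dedupe_reads:
        survivors, dup_ids = dedupe(survivors, classes=dup_classes)
        report.n_removed_duplicate = len(dup_ids)

    if min_entropy is not None and min_entropy > 0:
        kept = []
        for read_id, seq in survivors:
            if entropy_score(seq) >= min_entropy:
                kept.append((read_id, seq))
            else:
                report.n_removed_low_entropy += 1
        survivors = kept

    report.n_retained = len(survivors)
    retained_ids = {rid for rid, _ in survivors}
    truth = None
    if reads.truth is not None:
        truth = {rid: v for rid, v in reads.truth.items() if rid in retained_ids}
    out = replace(reads, reads=survivors, truth=truth)
    return out, report
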
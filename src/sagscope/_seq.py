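"""Small sequence helpers shared across modules."""

from __future__ import annotations

import zlib

NT_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
DNA_ALPHABET = "ACGT"
# standard 20-letter amino-acid alphabet; B/J/O/U/X/Z are rejected upstream
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence (A/C/G/T/N)."""
    return seq.translate(NT_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return not set(seq) - set(DNA_ALPHABET)


def stage_seed(seed: int, name: str) -> int:
    """Fan a global seed out to a stable per-stage seed (< 2**31).

    Uses CRC32 of the stage name so the mapping is reproducible across
    processes and Python versions (unlike the builtin hash).
    """
    return (zlib.crc32(name.encode("utf-8")) ^ (seed * 2654435761)) % (2**31)
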
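"""Conserved single-copy gene (CSCG) derivation and SAG completeness.

A CSCG is a gene family that occurs exactly once in at least a fixed
fraction (default 98%) of a panel of finished reference genomes. The
fraction of such markers detected in a partial single-cell assembly is an
unbiased estimator of genome recovery, and assembly length divided by that
fraction estimates the full genome size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd


class InvalidInputError(ValueError):
    pass


class UndefinedEstimateError(ValueError):
    """Raised when a genome-size estimate is undefined (zero completeness)."""


@dataclass
class OccurrenceMatrix:
    """Genomes x gene-family copy-count matrix."""

    genome_ids: list[str]
    family_ids: list[str]
    copies: np.ndarray  # shape (n_genomes, n_families), non-negative ints

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=int)
        if self.copies.shape != (len(self.genome_ids), len(self.family_ids)):
            raise InvalidInputError("copy matrix shape does not match id lists")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise InvalidInputError("genome ids must be unique")
        if len(set(self.family_ids)) != len(self.family_ids):
            raise InvalidInputError("family ids must be unique")
        if (self.copies < 0).any():
            raise InvalidInputError("copy counts must be non-negative")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.copies, index=self.genome_ids, columns=self.family_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccurrenceMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class CscgSet:
    family_ids: list[str]
    n_source_genomes: int
    threshold: float = 0.98

    def __len__(self) -> int:
        return len(self.family_ids)


@dataclass
class CompletenessEstimate:
    sag_id: str
    n_observed: int
    n_total: int
    completeness: float
    assembly_length: int | None = None
    genome_size_estimate: float | None = None


def derive_cscgs(matrix: OccurrenceMatrix, threshold: float = 0.98) -> CscgSet:
    """Extract families occurring exactly once in >= ceil(threshold * n)
    of the panel genomes.

    The cutoff is a count of genomes, so it is rounded up: with 100 genomes
    and threshold 0.98 a family must be single-copy in at least 98.
    """
    if matrix.copies.size == 0:
        raise InvalidInputError("empty occurrence matrix")
    if matrix.n_genomes < 10:
        raise InvalidInputError("need >= 10 genomes to derive CSCGs")
    if not 0 < threshold <= 1:
        raise InvalidInputError("threshold must be in (0, 1]")
    n = matrix.n_genomes
    # tolerate float representation drift in threshold * n (e.g. 0.9*10)
    cutoff = math.ceil(threshold * n - 1e-9)
    exactly_once = (matrix.copies == 1).sum(axis=0)
    keep = [fam for fam, c in zip(matrix.family_ids, exactly_once) if c >= cutoff]
    return CscgSet(family_ids=keep, n_source_genomes=n, threshold=threshold)


def estimate_completeness(detected_families: Iterable[str], cscgs: CscgSet) -> float:
    """Fraction of marker families detected (presence/absence; extra copies
    count once)."""
    if len(cscgs) == 0:
        raise InvalidInputError("empty CSCG set")
    detected = set(detected_families) & set(cscgs.family_ids)
    return len(detected) / len(cscgs)


def estimate_genome_size(assembly_length: int, completeness: float) -> float:
    """Genome size = assembly length / completeness."""
    if completeness <= 0:
        raise UndefinedEstimateError("completeness is zero: genome size undefined")
    return assembly_length / completeness


def completeness_table(
    detections: dict[str, set[str]],
    cscgs: CscgSet,
    assembly_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-SAG completeness (and genome size, when lengths are given) as a
    tidy table. SAGs with zero detected markers get a missing genome size."""
    rows = []
    for sag_id, fams in detections.items():
        comp = estimate_completeness(fams, cscgs)
        est = CompletenessEstimate(
            sag_id=sag_id,
            n_observed=len(set(fams) & set(cscgs.family_ids)),
            n_total=len(cscgs),
            completeness=comp,
        )
        if assembly_lengths is not None and sag_id in assembly_lengths:
            est.assembly_length = assembly_lengths[sag_id]
            try:
                est.genome_size_estimate = estimate_genome_size(est.assembly_length, comp)
            except UndefinedEstimateError:
                est.genome_size_estimate = None
        rows.append(est.__dict__)
    return pd.DataFrame(rows)
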
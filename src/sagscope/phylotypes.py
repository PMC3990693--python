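"""SSU rRNA phylotype clustering and PCR-screening summary tables.

Phylotypes are >= 99%-identity clusters of SSU rRNA sequences, built by
greedy centroid (representative-linkage) clustering in a deterministic
order: sequences are processed by decreasing length, then lexicographic
id, and each joins the first existing phylotype whose representative it
matches at or above the identity threshold, else founds a new one. This
mirrors standard OTU-picking practice and keeps results reproducible.

Pairwise identity is computed from a global alignment with free terminal
gaps (match +1, mismatch -1, gap -2 per column), so partial-length
amplicons are compared over their overlap; identity is matches / aligned
columns excluding terminal-gap columns, with internal gaps counting as
mismatch columns.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align


class InvalidInputError(ValueError):
    pass


@dataclass
class Phylotype:
    phylotype_id: str
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    site_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ScreenSummary:
    site: str
    depth_m: float | None
    n_sags: int
    genes: dict[str, tuple[int, int]]  # gene -> (n_positive, percent)


def _make_ssu_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free terminal gaps: amplicons of different length compare over overlap
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


_SSU_ALIGNER = _make_ssu_aligner()


def _aligned_core(a: str, b: str) -> tuple[int, int]:
    """(matches, columns) of the aligned core: the best-scoring free-end-gap
    alignment with terminal-gap column runs trimmed."""
    aln = _SSU_ALIGNER.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    n = len(s1)
    i0 = 0
    while i0 < n and (s1[i0] == "-" or s2[i0] == "-"):
        i0 += 1
    i1 = n
    while i1 > i0 and (s1[i1 - 1] == "-" or s2[i1 - 1] == "-"):
        i1 -= 1
    if i1 <= i0:
        return 0, 0
    matches = sum(1 for i in range(i0, i1) if s1[i] == s2[i])
    return matches, i1 - i0


def pairwise_identity(a: str, b: str) -> float:
    """Identity of two SSU sequences over their aligned overlap.

    Terminal-gap columns (leading/trailing runs of gap-containing columns)
    are excluded from the denominator; internal gap columns count as
    non-matching columns. For unrelated sequences the optimal free-end-gap
    alignment overlaps only a short core, so the returned identity is only
    meaningful together with a minimum-overlap requirement (see
    :func:`cluster_phylotypes`).
    """
    if len(a) < 200 or len(b) < 200:
        raise InvalidInputError("sequences must be >= 200 bp")
    matches, cols = _aligned_core(a, b)
    return matches / cols if cols else 0.0


def cluster_phylotypes(
    sequences: list[tuple[str, str, str]],
    threshold: float = 0.99,
    min_overlap_frac: float = 0.5,
) -> list[Phylotype]:
    """Greedy centroid clustering of (id, sequence, site) records at the
    given identity threshold. Every sequence is assigned to exactly one
    phylotype; the founder of each cluster is its representative.

    A sequence joins a phylotype only when its aligned core with the
    representative covers at least ``min_overlap_frac`` of the shorter of
    the two sequences; this blocks the spurious short-core matches that
    free-end-gap alignment produces between unrelated sequences.
    """
    if not sequences:
        raise InvalidInputError("no sequences to cluster")
    ids = [sid for sid, _, _ in sequences]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("sequence ids must be unique")
    ordered = sorted(sequences, key=lambda r: (-len(r[1]), r[0]))
    reps: list[tuple[str, str]] = []  # (rep_id, rep_seq)
    members: list[list[tuple[str, str]]] = []  # (seq_id, site) per phylotype
    for sid, seq, site in ordered:
        for k, (_, rep_seq) in enumerate(reps):
            matches, cols = _aligned_core(seq, rep_seq)
            if cols < min_overlap_frac * min(len(seq), len(rep_seq)):
                continue
            if cols and matches / cols >= threshold:
                members[k].append((sid, site))
                break
        else:
            reps.append((sid, seq))
            members.append([(sid, site)])
    out = []
    for k, (rep_id, _) in enumerate(reps):
        mids = [sid for sid, _ in members[k]]
        counts = Counter(site for _, site in members[k])
        out.append(
            Phylotype(
                phylotype_id=f"PT{k + 1:02d}",
                representative_id=rep_id,
                member_ids=mids,
                site_counts=dict(counts),
            )
        )
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def summarize_screen(detections: pd.DataFrame) -> list[ScreenSummary]:
    """Per-site and pooled-total gene-detection counts and percentages.

    ``detections`` has one row per SAG with columns ``sag_id``, ``site``,
    optionally ``depth_m``, and one boolean column per screened gene.
    Percentages are rounded to the nearest integer, half away from zero.
    The pooled row is returned last with site "Total".
    """
    required = {"sag_id", "site"}
    if not required <= set(detections.columns):
        raise InvalidInputError("detections table needs sag_id and site columns")
    gene_cols = [
        c for c in detections.columns if c not in ("sag_id", "site", "depth_m")
    ]
    if not gene_cols:
        raise InvalidInputError("no gene columns in detections table")
    summaries: list[ScreenSummary] = []

    def one(site: str, depth: float | None, sub: pd.DataFrame) -> ScreenSummary | None:
        n = len(sub)
        if n == 0:
            warnings.warn(f"site {site!r} has no SAGs; skipped", stacklevel=3)
            return None
        genes = {}
        for g in gene_cols:
            pos = int(sub[g].astype(bool).sum())
            genes[g] = (pos, _round_half_away(100.0 * pos / n))
        return ScreenSummary(site=site, depth_m=depth, n_sags=n, genes=genes)

    for site, sub in detections.groupby("site", sort=True):
        depth = None
        if "depth_m" in sub.columns and sub["depth_m"].nunique() == 1:
            depth = float(sub["depth_m"].iloc[0])
        s = one(str(site), depth, sub)
        if s is not None:
            summaries.append(s)
    total = one("Total", None, detections)
    if total is not None:
        summaries.append(total)
    return summaries


def screen_table(summaries: list[ScreenSummary]) -> pd.DataFrame:
    """Flatten screen summaries to a tidy table (one row per site)."""
    rows = []
    for s in summaries:
        row: dict = {"site": s.site, "depth_m": s.depth_m, "n_sags": s.n_sags}
        for g, (pos, pct) in s.genes.items():
            row[f"{g}_n"] = pos
            row[f"{g}_pct"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
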
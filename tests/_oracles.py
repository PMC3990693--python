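"""Independent brute-force oracles used only by the tests.

These are deliberately naive O(n*m) dynamic programs and per-item loops,
kept separate from (and much simpler than) the package implementation so
they can serve as ground truth on small instances.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_local_score(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0):
    """Optimal local alignment score, affine gaps; ``gap_open`` is the
    score of the first gap column, ``gap_extend`` of each additional."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def gotoh_local_score_matrix(a: str, b: str, submat, gap_open=-11.0, gap_extend=-1.0):
    """Local alignment score under a substitution matrix (indexable as
    submat[x, y]); same gap convention as above."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = float(submat[a[i - 1], b[j - 1]])
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def semiglobal_identity(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Global alignment with free terminal gaps (linear gap penalty);
    identity over the aligned core excluding terminal-gap columns."""
    n, m = len(a), len(b)
    S = [[0.0] * (m + 1) for _ in range(n + 1)]  # free leading gaps
    P = [[None] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        P[i][0] = "u"
    for j in range(1, m + 1):
        P[0][j] = "l"
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            options = [
                (S[i - 1][j - 1] + s, "d"),
                (S[i - 1][j] + gap, "u"),
                (S[i][j - 1] + gap, "l"),
            ]
            S[i][j], P[i][j] = max(options, key=lambda t: t[0])
    # free trailing gaps: best over last row/column
    best, end = max(
        [(S[n][j], (n, j)) for j in range(m + 1)] + [(S[i][m], (i, m)) for i in range(n + 1)],
        key=lambda t: t[0],
    )
    i, j = end
    cols = []  # (char_a or None, char_b or None), reversed
    # trailing overhang beyond (i, j) is terminal by construction
    while i > 0 or j > 0:
        move = P[i][j]
        if move == "d":
            cols.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif move == "u":
            cols.append((a[i - 1], None))
            i -= 1
        else:
            cols.append((None, b[j - 1]))
            j -= 1
    cols.reverse()
    lo = 0
    while lo < len(cols) and (cols[lo][0] is None or cols[lo][1] is None):
        lo += 1
    hi = len(cols)
    while hi > lo and (cols[hi - 1][0] is None or cols[hi - 1][1] is None):
        hi -= 1
    core = cols[lo:hi]
    if not core:
        return 0.0
    matches = sum(1 for x, y in core if x is not None and x == y)
    return matches / len(core)


def cscg_families_bruteforce(matrix, threshold=0.98):
    """Per-family loop: family is a CSCG iff the number of genomes with
    copy count exactly 1 is >= the smallest integer >= threshold * n."""
    import math

    n = len(matrix.genome_ids)
    cutoff = math.ceil(threshold * n - 1e-9)
    out = []
    for j, fam in enumerate(matrix.family_ids):
        count = sum(1 for i in range(n) if matrix.copies[i][j] == 1)
        if count >= cutoff:
            out.append(fam)
    return out


def overlap_count_bruteforce(locus_start, locus_end, locus_contig, hits):
    """Per-base scan: a hit overlaps the locus iff they share >= 1 position
    on the same contig."""
    n = 0
    for h in hits:
        if h.contig_id != locus_contig:
            continue
        positions = set(range(h.start, h.end))
        if positions & set(range(locus_start, locus_end)):
            n += 1
    return n
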
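# Methods

This note documents the models and procedures implemented in `sagscope`,
the parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices a maintainer should know about.

## Scope and design

The package reproduces the *analysis logic* of a single-cell + metagenome
comparative genomics study of dark-ocean archaea: estimating how complete
partial single-cell assemblies are, profiling their relatives' abundance
across metagenome depth profiles, partitioning their proteome against two
reference cultures, locating hypervariable (island) loci by absence of
metagenome recruitment, and collapsing SSU rRNA amplicons into
phylotypes. Wet-lab steps, sequencing, assembly, gene calling and
annotation, multiple alignment and tree inference are all upstream of the
package: gene families, coding loci and proteomes enter as annotated
inputs (TSV/BED/FASTA).

All stages run on synthetic communities because the motivating study's
raw data are not desk-scale. Genomes default to 20–100 kbp rather than
the 1.6–2 Mbp of real marine Thaumarchaeota: every statistic in the
pipeline (completeness fractions, recruits per Mbp, score ratios,
category fractions, identity thresholds) is rate-based and scale-free, so
nothing but runtime depends on genome length.

## Synthetic communities

`synthetic` generates, as pure functions of an integer seed:

- **Genomes**: i.i.d. bases with P(G)+P(C) = `gc_target` (default 0.34,
  matching low-GC marine archaea). Realized GC concentrates within ±0.03
  for ≥ 10 kbp by binomial concentration.
- **Population divergence**: substitution-only mutation at a per-base
  rate (0–0.25). No indels, deliberately: recruitment identity then has
  an exact binomial distribution, which the threshold tests use as their
  analytic oracle. Indel robustness is exercised separately in the
  aligner unit tests.
- **SAG assemblies**: `n_contigs` disjoint substrings totalling
  `completeness × genome length` (contig lengths and gaps drawn from
  multinomial compositions). A gene family is *detected* when its locus
  lies wholly inside a retained contig. Marker loci default to 60 bp —
  point-like relative to contigs — because a locus of length ℓ is missed
  whenever it straddles a contig end, biasing detection downward by
  ≈ `n_contigs · ℓ / L`; at ℓ = 60 that bias is negligible.
- **Metagenomes**: reads drawn from members proportionally to abundance,
  lengths uniform in 100–800 bp (454-like), mutated at the member's
  divergence, never overlapping *shielded intervals* (the island ground
  truth). Junk is appended by class: short (< 100 bp), ambiguous (N's),
  exact duplicates of earlier clean reads, and low-complexity repeats.
  Two guarantees make QC truth reconciliation exact rather than
  approximate: clean reads are generated pairwise distinct under the
  exact/5′-prefix/reverse-complement duplicate relation and always pass
  the entropy-70 filter; low-complexity reads use a reverse-complement-
  distinct motif pool with per-motif strictly increasing lengths so a
  later read is never a prefix of an earlier one.
- **Occurrence matrices**: planted single-copy families with independent
  dropout (copy 0) and duplication (copy 2), plus accessory families at
  random prevalence.
- **Proteome triplets**: query families shared with both / one / neither
  reference; homologs at 80% amino-acid identity by default (safely above
  the BSR 0.4 homology radius, far above the random-pair background).
- **SSU clouds**: unrelated random ancestors with members mutated at half
  the nominal `within_divergence`, so that parameter is the expected
  *pairwise* divergence between members.

Truth (read placement, read kind, island loci, proteome categories,
cloud membership) travels in TSV sidecars, never in FASTA headers, so
analysis code cannot read labels.

What the generator does **not** emulate: MDA chimeras and coverage bias,
quality scores (the filters are sequence-level only), repeats and mobile
elements, indel mutation, GC skew, and compositional heterogeneity along
genomes. Passing tests therefore demonstrate correctness of the
*statistics and rules*, not robustness to every artifact of real 454/
Illumina single-cell data.

## Read QC

Filters run in a fixed order — length (< 100 bp), ambiguity, duplicates,
entropy — and each removed read is attributed to the first rule it
fails; the retained set is order-invariant, only the report attribution
depends on rule order. "Replicate/duplicate" means exact copy, exact
5′ prefix of a retained read, or exact reverse complement of a retained
read, keeping the first occurrence; fuzzy (k-mismatch) collapsing is
deliberately not implemented. The entropy score is defined normatively
as `100 · H / log2(min(L−2, 64))` with H the Shannon entropy (bits) of
the overlapping-trimer distribution: a homopolymer scores 0, an
`ACGT`-repeat scores 33.33, a sequence using all 64 trimers equally
scores 100. Random ≥ 200 bp reads pass the default threshold of 70 with
frequency > 0.99. The entropy filter applies to all read sets by default
(`--no-entropy` disables it for non-pyrosequencing data).

## Completeness

`derive_cscgs` keeps families occurring *exactly once* in at least
⌈threshold · n⌉ genomes (threshold 0.98): the cutoff is a genome count,
so it rounds up, and a small epsilon absorbs float representation drift
(0.9 · 10 would otherwise ceil to 10). Marker detection is
presence/absence — extra copies (common MDA artifacts) count once.
Completeness is the detected marker fraction; genome size is
`assembly length / completeness`, the only estimator consistent with the
completeness definition, and is reported as missing (not infinity) at
zero completeness. With 94 markers the estimator's binomial sd is
`sqrt(c(1−c)/94)` ≈ 0.05 at mid-completeness; the Monte-Carlo suites
verify MAE ≤ 0.06 across a 0.1–0.9 grid and median genome-size recovery
within 10% from completeness 0.3 up.

## Fragment recruitment

The aligner is an optimal local (Smith-Waterman) alignment of the read
or its reverse complement, match +1 / mismatch −1, affine gaps scoring
−2 for the first gap column and −1 for each additional column (the
BLASTN 1/−1 weights; no E-values or masking, which desk-scale inputs do
not need). Identity is matches / alignment columns *including* gap
columns; "≥ 200 bp" is alignment length, not read length; one best hit
per read per target; targets recruit independently (no cross-target
competition). Cross-strand score ties go to the + strand.

For contigs beyond a 2M-cell DP budget a seeded path is used: a
bit-parallel infix edit-distance search (edlib) locates the best-matching
region per strand and the exact DP is run on a ±60 bp padded window, so
emitted alignments are still DP-optimal in the located region. When the
recruitment thresholds are supplied, two provably safe skips apply: a
read whose best infix edit distance exceeds `L − (2·id − 1)·minlen`
cannot contain a passing alignment, and a best DP score below
`(3·id − 2)·minlen` cannot belong to one. The strand with the clearly
smaller edit distance is realigned alone; both are realigned when the
margin (5 bp or L/20) is ambiguous. The exact and seeded paths are
cross-checked in the tests, and the exact path is verified against an
independent brute-force Gotoh DP on thousands of short pairs.

Abundance is `100 · hits / reads(sample) / (length(target)/10⁶)` —
percent of (post-QC) sample reads recruited per Mbp of assembly. The
denominator uses post-QC reads, since removed reads are excluded from
all further analysis.

## BSR

Raw local-alignment scores under BLOSUM62 with affine gaps (−11 first
gap column, −1 each additional; the BLASTP-default weights). The ratio
is scale-invariant to the raw-vs-bit choice as long as numerator and
denominator match; raw scores keep it exact (a verbatim reference copy
gives ratio exactly 1.0). Homology is *strictly* greater than 0.4.
Ambiguous residues (X, B, Z…) raise an error rather than being silently
scored; an empty reference yields all-zero scores (valid), not an error.
Exact-sequence deduplication of the query set is provided
(`nonredundant`); clustering-based redundancy removal is out of scope.

## Genomic islands

A locus is an island iff zero filtered recruits overlap it by ≥ 1 bp on
its contig — the strict zero-recruitment reading, chosen to avoid false
positives at the cost of demanding deep outside coverage (≥ 20× gives
exact recovery of shielded loci in simulation; at ~2× in the small demo,
low-coverage loci can also be called, which is the expected behavior of
the conservative rule, not an error). Reads from all samples are pooled
before calling. Enrichment per category uses the one-sided
hypergeometric tail (islands as draws without replacement from the
annotated background) with Benjamini–Hochberg correction across the
categories present; `enriched` means q ≤ 0.05. The hypergeometric test
is discrete and conservative, so the null simulation's raw-p ≤ 0.05
fraction sits well below 0.05.

## Phylotypes and screening tables

Pairwise SSU identity comes from a global alignment with free terminal
gaps (match +1, mismatch −1, gap −2 per column); identity is matches /
columns over the aligned core, excluding terminal-gap column runs, so
partial-length amplicons compare over their overlap and internal gaps
count as mismatch columns. For *unrelated* sequences the score-optimal
free-end-gap alignment degenerates to a short high-identity core, so
clustering additionally requires the core to cover ≥ 50% of the shorter
sequence (`min_overlap_frac`); without this guard unrelated sequences
can tie-break to spuriously high identity. Under co-optimal ties the
reported identity of unrelated pairs may depend on argument order;
scores, and identities of related pairs, are symmetric.

Clustering is greedy centroid: sequences ordered by decreasing length
then id; each joins the first phylotype whose *representative* it
matches at ≥ 99%, else founds one. Greedy schemes are order-dependent
for chained clouds straddling the threshold; the tests assert only on
well-separated clouds, where the partition is permutation-stable.

Screening summaries count per-site and pooled gene detections with
percentages rounded to the nearest integer, half away from zero — the
rounding rule consistent with all six printed percentages of the
two-station survey table the worked example reproduces (40/67 → 60%,
32/67 → 48%, 42/52 → 81%, 32/52 → 62%, 82/119 → 69%, 64/119 → 54%).

## Pipeline

One YAML config drives simulate → qc → completeness → recruit → islands
→ bsr → phylotype → screen. The global seed is fanned out per stage by
CRC32 of the stage name (stable across processes, unlike Python's
builtin hash), so disabling a stage never shifts another stage's random
stream. Config validation rejects unknown keys and out-of-range values
with aggregated messages. The run manifest records a SHA-256 per output
file and wall time per stage; fixed seed ⇒ identical checksums. Default
problem sizes (three 60 kbp genomes, 3 × 3000 reads) complete in a few
minutes on one CPU; the bundled demo uses 30 kbp and 3 × 600 reads.

## Known limitations

- No indel mutation model; realized recruitment identity is purely
  substitution-driven.
- The seeded aligner's strand pre-selection relies on an edit-distance
  margin; contrived reads with near-equal cross-strand distances but
  score-relevant differences would be realigned on both strands (safe),
  at extra cost.
- Greedy phylotype clustering is order-dependent near the threshold by
  construction.
- Island calling has no fractional-coverage relaxation and no
  composition-based (GC/tetranucleotide) detection.
- The enrichment test treats loci as exchangeable; genomic linkage of
  neighboring island loci is ignored.
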
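"""Plain-text readers/writers: FASTA (Biopython), TSV (pandas), BED6.

Truth/metadata tables are always carried as TSV sidecars, never encoded in
FASTA headers, so analysis code cannot accidentally read labels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .islands import CodingLocus


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_bed(loci: Sequence[CodingLocus], path: str | Path) -> None:
    """BED6: chrom, start, end, name (= protein id), score (0), strand."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.contig_id}\t{l.start}\t{l.end}\t{l.protein_id}\t0\t{l.strand}\n")


def read_bed(path: str | Path, categories: dict[str, str] | None = None) -> list[CodingLocus]:
    """Read BED6 coding loci; ``categories`` optionally maps protein id to
    COG category (from the TSV sidecar)."""
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            cat = (categories or {}).get(name, "none")
            loci.append(
                CodingLocus(
                    protein_id=name,
                    contig_id=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    cog_category=cat,
                )
            )
    return loci
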
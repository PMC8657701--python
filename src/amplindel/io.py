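"""File-format helpers: FASTQ/FASTA records and tabular exports."""

from __future__ import annotations

import gzip

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def _open(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> list[tuple[str, str, str]]:
    """(id, sequence, quality) records from a Phred+33 FASTQ file."""
    with _open(path) as fh:
        return [(title.split()[0], seq, qual)
                for title, seq, qual in FastqGeneralIterator(fh)]


def write_fastq(records, path) -> None:
    with _open(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]


def write_fasta(records, path) -> None:
    with _open(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_tsv(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata_tsv(path):
    """Line metadata TSV (line_id, background, generation, parent, cas9)
    into LineMeta records."""
    from .classify import LineMeta
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    metas = []
    for row in df.itertuples(index=False):
        metas.append(LineMeta(
            line_id=row.line_id, background=row.background,
            generation=row.generation,
            parent_id=(row.parent or None) if hasattr(row, "parent") else None,
            cas9=getattr(row, "cas9", "unknown") or "unknown"))
    return metas
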
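"""File formats: FASTA in; count tables, PHYLIP/TSV matrices, JSON out."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kmers import KmerCountVector, KmerIndex, NucleotideSequence
from .stats import DissimilarityMatrix, StatisticKind

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_count_table",
    "write_phylip",
    "read_phylip",
    "write_matrix_tsv",
    "write_json",
]


class NoRecordsError(ValueError):
    """The FASTA input contains no records."""


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file (wrapped lines, case-insensitive)."""
    records = [
        NucleotideSequence(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise NoRecordsError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def write_count_table(
    counts: Iterable[KmerCountVector], path_or_handle: str | Path | TextIO
) -> None:
    """TSV with one row per (sequence, k-mer) with nonzero count."""
    rows = []
    for cv in counts:
        index = KmerIndex(cv.k)
        for rank in np.flatnonzero(cv.counts):
            rows.append(
                {
                    "sequence": cv.source_id,
                    "kmer": index.decode(int(rank)),
                    "rank": int(rank),
                    "count": int(cv.counts[rank]),
                }
            )
    pd.DataFrame(rows, columns=["sequence", "kmer", "rank", "count"]).to_csv(
        path_or_handle, sep="\t", index=False
    )


def _phylip_label(label: str) -> str:
    """PHYLIP labels are exactly 10 characters: truncated or space-padded."""
    return label[:10].ljust(10)


def write_phylip(matrix: DissimilarityMatrix, path_or_handle) -> None:
    """Square PHYLIP distance matrix: N, then one label + N values per row."""
    lines = [f"{len(matrix.labels):5d}"]
    for label, row in zip(matrix.labels, matrix.values):
        vals = "  ".join(f"{v:.6f}" for v in row)
        lines.append(f"{_phylip_label(label)}  {vals}")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        Path(path_or_handle).write_text(text)


def read_phylip(
    path: str | Path, kind: StatisticKind = StatisticKind.D2S, k: int = 0
) -> DissimilarityMatrix:
    """Parse a square PHYLIP distance matrix written by :func:`write_phylip`."""
    lines = Path(path).read_text().strip().splitlines()
    n = int(lines[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        labels.append(line[:10].strip())
        rows.append([float(v) for v in line[10:].split()])
    return DissimilarityMatrix(
        labels=tuple(labels), values=np.array(rows), kind=kind, k=k
    )


def write_matrix_tsv(matrix: DissimilarityMatrix, path_or_handle) -> None:
    """TSV matrix with full labels as header and index."""
    df = pd.DataFrame(
        matrix.values, index=list(matrix.labels), columns=list(matrix.labels)
    )
    df.to_csv(path_or_handle, sep="\t", index_label="id")


def write_json(obj: dict, path_or_handle) -> None:
    if hasattr(path_or_handle, "write"):
        json.dump(obj, path_or_handle, indent=2)
        path_or_handle.write("\n")
    else:
        with open(path_or_handle, "w") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")
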
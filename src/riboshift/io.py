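"""Reading and writing of on-disk formats with explicit coordinate conventions.

All in-memory coordinates are 0-based half-open in transcript space; every
writer/reader converts at the file boundary only (GFF3 is 1-based inclusive,
BED/bedGraph are 0-based half-open).

Containers
----------
Annotation
    ``pandas.DataFrame`` indexed by transcript id with integer columns
    ``orf_start`` (0-based inclusive), ``orf_end`` (0-based exclusive),
    optionally ``tx_length``, and a boolean ``frame_ok`` flag (False when the
    ORF length is not divisible by 3; the record is retained).
Alignments
    ``pandas.DataFrame`` with columns ``transcript_id``, ``five_prime_pos``
    (0-based), ``length`` (nt) and ``multiplicity`` (number of loci the read
    maps to, >= 1).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALIGNMENT_COLUMNS = ["transcript_id", "five_prime_pos", "length", "multiplicity"]

__all__ = [
    "ALIGNMENT_COLUMNS",
    "make_annotation",
    "read_annotation",
    "write_annotation",
    "read_alignments",
    "write_alignments",
    "read_sequences",
    "write_sequences",
    "write_table",
    "read_table",
    "write_bedgraph",
    "read_bedgraph",
]


def make_annotation(records: Iterable[tuple]) -> pd.DataFrame:
    """Build an annotation frame from ``(id, orf_start, orf_end[, tx_length])``."""
    rows = []
    for rec in records:
        tx_id, start, end = rec[0], int(rec[1]), int(rec[2])
        length = int(rec[3]) if len(rec) > 3 else -1
        rows.append((tx_id, start, end, length, (end - start) % 3 == 0))
    df = pd.DataFrame(rows, columns=["transcript_id", "orf_start", "orf_end", "tx_length", "frame_ok"])
    return df.set_index("transcript_id")


def read_annotation(path: str | Path, dialect: str = "GFF3") -> pd.DataFrame:
    """Read ORF annotations from GFF3 (1-based inclusive) or BED (0-based half-open).

    GFF3 coordinates are normalised by ``start - 1``.  ORFs whose length is not
    divisible by 3 raise a warning and are flagged ``frame_ok=False`` but kept.
    A ``##sequence-region`` pragma (GFF3) supplies ``tx_length``; BED files
    leave it at -1 (unknown).
    """
    dialect = dialect.upper()
    if dialect not in {"GFF3", "BED"}:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    rows: list[tuple] = []
    tx_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        tx_lengths[parts[1]] = int(parts[3])
                continue
            fields = line.split("\t")
            try:
                if dialect == "GFF3":
                    if len(fields) < 5:
                        raise ValueError("expected >= 5 GFF3 columns")
                    tx_id = fields[0]
                    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(fields[4])
                else:
                    if len(fields) < 3:
                        raise ValueError("expected >= 3 BED columns")
                    tx_id = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed {dialect} line {lineno}: {exc}") from exc
            if end <= start:
                raise ValueError(f"{path}: malformed {dialect} line {lineno}: end <= start")
            rows.append((tx_id, start, end))
    ann = make_annotation(rows)
    if tx_lengths:
        ann["tx_length"] = ann.index.map(lambda t: tx_lengths.get(t, -1)).astype(int)
    bad = ann.index[~ann["frame_ok"]]
    if len(bad):
        warnings.warn(
            f"{len(bad)} ORF(s) with length not divisible by 3 (e.g. {bad[0]}); retained with frame_ok=False"
        )
    return ann


def write_annotation(annotation: pd.DataFrame, path: str | Path, dialect: str = "GFF3") -> None:
    """Write an annotation frame as GFF3 (CDS features) or BED."""
    dialect = dialect.upper()
    with open(path, "w") as fh:
        if dialect == "GFF3":
            fh.write("##gff-version 3\n")
            for tx_id, row in annotation.iterrows():
                if row.get("tx_length", -1) and row["tx_length"] > 0:
                    fh.write(f"##sequence-region {tx_id} 1 {int(row['tx_length'])}\n")
            for tx_id, row in annotation.iterrows():
                fh.write(
                    f"{tx_id}\triboshift\tCDS\t{int(row['orf_start']) + 1}\t{int(row['orf_end'])}"
                    f"\t.\t+\t0\tID=cds-{tx_id}\n"
                )
        elif dialect == "BED":
            for tx_id, row in annotation.iterrows():
                fh.write(f"{tx_id}\t{int(row['orf_start'])}\t{int(row['orf_end'])}\t{tx_id}\t0\t+\n")
        else:
            raise ValueError(f"unknown annotation dialect: {dialect!r}")


def read_alignments(path: str | Path, max_multiplicity: int = 1) -> pd.DataFrame:
    """Read mapped reads from BED6 in transcript coordinates.

    The BED ``name`` field carries the read length and ``score`` the mapping
    multiplicity.  Records with multiplicity above ``max_multiplicity`` are
    dropped: 1 keeps unique alignments only, 2 additionally retains reads
    mapping to two loci (the paralog-tolerant mode used for differential
    expression).
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["transcript_id", "start", "end", "name", "score", "strand"],
            dtype={"transcript_id": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=ALIGNMENT_COLUMNS).astype(
            {"five_prime_pos": int, "length": int, "multiplicity": int}
        )
    length = df["end"].astype(int) - df["start"].astype(int)
    declared = df["name"].astype(int)
    if not (length == declared).all():
        bad = int((length != declared).idxmax()) + 1
        raise ValueError(f"{path}: record {bad}: name (read length) disagrees with end-start")
    out = pd.DataFrame(
        {
            "transcript_id": df["transcript_id"],
            "five_prime_pos": df["start"].astype(int),
            "length": length,
            "multiplicity": df["score"].astype(int),
        }
    )
    out = out[out["multiplicity"] <= int(max_multiplicity)].reset_index(drop=True)
    return out


def write_alignments(reads: pd.DataFrame, path: str | Path) -> None:
    """Write alignments to BED6 (name = length, score = multiplicity)."""
    with open(path, "w") as fh:
        for tx, pos, length, mult in zip(
            reads["transcript_id"], reads["five_prime_pos"], reads["length"], reads["multiplicity"]
        ):
            fh.write(f"{tx}\t{pos}\t{pos + length}\t{length}\t{mult}\t+\n")


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_sequences(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a TSV with header, stable column order and 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_bedgraph(tracks: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-nt coverage as bedGraph (0-based half-open); zero runs omitted."""
    with open(path, "w") as fh:
        for tx_id in tracks:
            values = np.asarray(tracks[tx_id], dtype=float)
            if values.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [values.size]])
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{tx_id}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str | Path, lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph into dense per-nt arrays of the given transcript lengths."""
    tracks = {tx: np.zeros(n, dtype=float) for tx, n in lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            tx, s, e, v = line.split("\t")
            if tx in tracks:
                tracks[tx][int(s): int(e)] = float(v)
    return tracks
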
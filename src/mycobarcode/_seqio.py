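"""FASTQ/FASTA I/O helpers (Biopython-backed, gzip-aware)."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


@dataclass
class ReadPair:
    """One paired-end read: sequences and ASCII (offset-33) quality strings."""

    read_id: str
    fwd_seq: str
    fwd_qual: str
    rev_seq: str
    rev_qual: str


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return path.open(mode)


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a FASTQ file into (id, seq, qual) tuples (id = first token)."""
    with _open_text(path) as fh:
        return [(title.split()[0], seq, qual) for title, seq, qual in FastqGeneralIterator(fh)]


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> list[ReadPair]:
    """Read synchronized paired FASTQ files; hard error on id/count mismatch."""
    fwd = read_fastq(r1)
    rev = read_fastq(r2)
    if len(fwd) != len(rev):
        raise ValueError(
            f"paired FASTQ files out of sync: {r1} has {len(fwd)} reads, {r2} has {len(rev)}"
        )
    pairs = []
    for (fid, fseq, fq), (rid, rseq, rq) in zip(fwd, rev):
        if fid != rid:
            raise ValueError(f"paired FASTQ id mismatch: {fid!r} vs {rid!r}")
        pairs.append(ReadPair(fid, fseq, fq, rseq, rq))
    return pairs


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write (id, seq, qual) records as FASTQ; returns record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_fastq_pairs(r1: str | Path, r2: str | Path, pairs: Iterable[ReadPair]) -> int:
    n = 0
    with _open_text(r1, "wt") as f1, _open_text(r2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}\n{p.fwd_seq}\n+\n{p.fwd_qual}\n")
            f2.write(f"@{p.read_id}\n{p.rev_seq}\n+\n{p.rev_qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) tuples."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


def qual_to_phred(qual: str) -> list[int]:
    """ASCII offset-33 quality string -> Phred integer list."""
    return [ord(c) - PHRED_OFFSET for c in qual]


def phred_to_qual(phred: Iterable[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in phred)
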
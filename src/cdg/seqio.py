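"""Sequence I/O and overlap merging of read pairs.

FASTA/FASTQ parsing and writing go through Biopython (:mod:`Bio.SeqIO`);
this module adds the light record types the rest of the package uses and an
internal overlap merger that joins paired-end reads whose fragments are
shorter than the summed read length into single long fragments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from cdg._codons import revcomp

__all__ = [
    "SeqRecord", "ReadPair", "ParseError",
    "read_sequences", "read_pairs", "write_fasta", "write_fastq", "merge_pairs",
]


class ParseError(ValueError):
    """A malformed record in a sequence file, naming the offending index."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence with optional Phred qualities.

    ``seq`` is uppercase over {A,C,G,T,N}; ``qual``, when present, is a list
    of Phred scores of the same length.
    """

    id: str
    seq: str
    qual: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


_MATE_SUFFIX = re.compile(r"/[12]$")


def strip_mate_suffix(read_id: str) -> str:
    """Drop a trailing /1 or /2 mate tag from a read id.

    Space-delimited mate tags (Casava 1.8 style) never reach this point:
    ids are already cut at the first whitespace during parsing.
    """
    return _MATE_SUFFIX.sub("", read_id)


@dataclass
class ReadPair:
    """Two mates of one fragment, as sequenced (r2 on the opposite strand)."""

    r1: SeqRecord
    r2: SeqRecord

    def __post_init__(self) -> None:
        if strip_mate_suffix(self.r1.id) != strip_mate_suffix(self.r2.id):
            raise ValueError(
                f"mate ids do not correspond: {self.r1.id!r} vs {self.r2.id!r}"
            )


def _guess_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, format: Optional[str] = None) -> Iterator[SeqRecord]:
    """Stream records from a FASTA or FASTQ file.

    Sequences are uppercased; ids are kept verbatim up to the first
    whitespace. A malformed record raises :class:`ParseError` naming the
    0-based index at which parsing failed. An empty file yields nothing.
    """
    fmt = format or _guess_format(path)
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {fmt!r}")
    parser = SeqIO.parse(str(path), fmt)
    index = 0
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise ParseError(f"{path}: malformed record at index {index}: {exc}") from exc
        qual = rec.letter_annotations.get("phred_quality")
        try:
            yield SeqRecord(rec.id, str(rec.seq).upper(), list(qual) if qual else None)
        except ValueError as exc:
            raise ParseError(f"{path}: malformed record at index {index}: {exc}") from exc
        index += 1


def read_pairs(path1: str | Path, path2: str | Path,
               format: Optional[str] = None) -> Iterator[ReadPair]:
    """Stream mate pairs from two parallel FASTQ/FASTA files."""
    it1, it2 = read_sequences(path1, format), read_sequences(path2, format)
    for r1, r2 in zip(it1, it2, strict=True):
        yield ReadPair(r1, r2)


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 60) -> int:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns.

    Returns the number of records written. ``read_sequences(write_fasta(x))``
    is the identity on (id, seq).
    """
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            if wrap and wrap > 0:
                for i in range(0, len(rec.seq), wrap):
                    fh.write(rec.seq[i:i + wrap] + "\n")
            else:
                fh.write(rec.seq + "\n")
            n += 1
    return n


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    """Write records as Sanger FASTQ (Phred+33); missing quals become Q40."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else [40] * len(rec.seq)
            qline = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qline}\n")
            n += 1
    return n


@dataclass
class MergeResult:
    merged: list[SeqRecord] = field(default_factory=list)
    unmerged: list[ReadPair] = field(default_factory=list)


def _score_overlap(a: str, b: str) -> tuple[int, int]:
    """(matches, mismatches) between equal-length strings; N never matches."""
    matches = mismatches = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            mismatches += 1
        elif x == y:
            matches += 1
        else:
            mismatches += 1
    return matches, mismatches


def merge_pairs(pairs: Iterable[ReadPair], min_overlap: int = 10,
                max_mismatch_rate: float = 0.25) -> MergeResult:
    """Merge overlapping read pairs into single fragments.

    For each pair, r2 is reverse-complemented and every overlap of at least
    ``min_overlap`` bp between the r1 suffix and the rc(r2) prefix is scored.
    The best-scoring overlap (most matching bases; ties broken toward the
    longer overlap) is accepted when its mismatch fraction is at most
    ``max_mismatch_rate``, producing a consensus of length
    ``len(r1) + len(r2) - overlap`` in which disagreements take the
    higher-quality base (r1 on ties or missing qualities). Pairs with no
    acceptable overlap are routed to ``unmerged``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not 0 <= max_mismatch_rate < 0.5:
        raise ValueError("max_mismatch_rate must be in [0, 0.5)")

    out = MergeResult()
    for pair in pairs:
        s1 = pair.r1.seq
        s2 = revcomp(pair.r2.seq)
        q1 = pair.r1.qual
        q2 = pair.r2.qual[::-1] if pair.r2.qual is not None else None
        best = None  # (matches, overlap)
        for olap in range(min(len(s1), len(s2)), min_overlap - 1, -1):
            matches, mismatches = _score_overlap(s1[-olap:], s2[:olap])
            if mismatches / olap <= max_mismatch_rate:
                if best is None or matches > best[0]:
                    best = (matches, olap)
        if best is None:
            out.unmerged.append(pair)
            continue
        olap = best[1]
        head = s1[:-olap] if olap < len(s1) else ""
        tail = s2[olap:]
        consensus = []
        for i in range(olap):
            b1, b2 = s1[len(s1) - olap + i], s2[i]
            if b1 == b2:
                consensus.append(b1)
            else:
                p1 = q1[len(s1) - olap + i] if q1 is not None else None
                p2 = q2[i] if q2 is not None else None
                if p1 is not None and p2 is not None and p2 > p1:
                    consensus.append(b2)
                else:
                    consensus.append(b1)
        merged_seq = head + "".join(consensus) + tail
        out.merged.append(SeqRecord(strip_mate_suffix(pair.r1.id), merged_seq))
    return out
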
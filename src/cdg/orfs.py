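"""Six-frame translation into stop-free, codon-aligned candidate ORFs.

Every input sequence is read in all six frames (three offsets on each
strand). Within each frame, stop codons (TAA/TAG/TGA) split the frame into
maximal stop-free codon runs; runs long enough to matter become candidate
ORFs. An ORF is *strict* when its frame contains no stop codon at all (the
run spans the whole codon-trimmed frame) and *loose* when it covers at
least a configurable fraction (default 80%) of the original sequence.
Strict ORFs seed the self-supervised SVM training set; strict plus loose
ORFs feed the assembly graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

from cdg._codons import STOP_CODONS, revcomp
from cdg.seqio import SeqRecord

__all__ = ["Orf", "FRAMES", "frame_sequences", "extract_orfs", "partition_orfs"]

#: Frame labels: positive frames read the sequence at offsets 0/1/2,
#: negative frames read the reverse complement at offsets 0/1/2.
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class Orf:
    """A stop-free codon-aligned segment of one reading frame.

    ``start`` is the 0-based offset of the segment on the oriented frame
    string (a multiple of 3); ``kind`` is ``strict``, ``loose`` or
    ``other``.
    """

    source_id: str
    frame: int
    start: int
    seq: str
    kind: str

    def __post_init__(self) -> None:
        if len(self.seq) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if self.start % 3 != 0:
            raise ValueError("ORF start must be codon-aligned")

    def __len__(self) -> int:
        return len(self.seq)


def frame_sequences(seq: str) -> list[tuple[int, str]]:
    """The six oriented frame strings of ``seq``, truncated to codons.

    Frames +1/+2/+3 are the sequence at offsets 0/1/2; −1/−2/−3 are the
    reverse complement at offsets 0/1/2. Each frame string is trimmed at
    its 3' end to a multiple of 3, so a frame at offset ``o`` has length
    ``3 * floor((L − o) / 3)``. Sequences shorter than 3 nt have no frames.
    """
    seq = seq.upper()
    if len(seq) < 3:
        return []
    rc = revcomp(seq)
    out = []
    for frame in FRAMES:
        offset = abs(frame) - 1
        oriented = seq if frame > 0 else rc
        sub = oriented[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append((frame, sub))
    return out


def _stop_free_runs(frame_seq: str) -> list[tuple[int, int]]:
    """Half-open codon-aligned intervals between stop codons (stops excluded)."""
    runs = []
    run_start = 0
    for i in range(0, len(frame_seq), 3):
        if frame_seq[i:i + 3] in STOP_CODONS:
            if i > run_start:
                runs.append((run_start, i))
            run_start = i + 3
    if len(frame_seq) > run_start:
        runs.append((run_start, len(frame_seq)))
    return runs


def extract_orfs(record: Union[SeqRecord, str], min_len: int = 27,
                 loose_fraction: float = 0.8, source_id: str = "") -> list[Orf]:
    """All candidate ORFs of a sequence, longest first.

    Codons containing N are treated as non-stop (they never split a run);
    downstream codon-usage counting excludes them instead. Runs shorter
    than ``min_len`` are dropped. ``kind`` is assigned per the module
    docstring, with strict taking precedence over loose.
    """
    if min_len < 3 or min_len % 3 != 0:
        raise ValueError("min_len must be a positive multiple of 3")
    if not 0 < loose_fraction <= 1:
        raise ValueError("loose_fraction must be in (0, 1]")
    if isinstance(record, SeqRecord):
        seq, sid = record.seq, record.id
    else:
        seq, sid = str(record).upper(), source_id
    L = len(seq)
    orfs: list[Orf] = []
    for frame, fseq in frame_sequences(seq):
        runs = _stop_free_runs(fseq)
        whole_frame = len(runs) == 1 and runs[0] == (0, len(fseq)) and len(fseq) > 0
        for start, end in runs:
            length = end - start
            if length < min_len:
                continue
            if whole_frame:
                kind = "strict"
            elif length >= loose_fraction * L:
                kind = "loose"
            else:
                kind = "other"
            orfs.append(Orf(sid, frame, start, fseq[start:end], kind))
    orfs.sort(key=lambda o: (-len(o.seq), abs(o.frame), o.frame < 0, o.start))
    return orfs


def partition_orfs(orfs: Sequence[Orf]) -> tuple[list[Orf], list[Orf]]:
    """Split candidates into (strict, strict ∪ loose).

    The strict set sources the SVM training data; the combined set is the
    SVM test set and the material for the assembly graph.
    """
    strict = [o for o in orfs if o.kind == "strict"]
    graph_set = [o for o in orfs if o.kind in ("strict", "loose")]
    return strict, graph_set
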
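"""Quality statistics for predicted CDSs against a reference gene set.

All metrics operate on :class:`AlignmentRecord` lists, which can come from
a BLAT PSL file (the route for real data) or from the built-in seeded
aligner (exact 15-mer seeds, ungapped X-drop extension), which is adequate
for the near-identical comparisons synthetic tests require.

Metrics follow common practice for transcriptome CDS benchmarking:
*redundancy* (aligned predicted CDSs per reference gene), the ROC point
(sensitivity = fraction of reference genes covered; specificity = fraction
of predictions covered by the reference), *fragment number* (mean number
of predicted CDSs per aligned reference gene, Σ i·pᵢ), *base error rate*
(mismatches / alignment length), the *chimera rate* (predictions > 500 bp
aligning substantially to two or more distinct genes), and ortholog-pair
classification into one-to-one / one-to-many / many-to-one / many-to-many.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from cdg.seqio import SeqRecord, read_sequences

__all__ = [
    "AlignmentRecord", "EvalReport", "parse_psl", "align_records",
    "align_or_load", "filter_alignments", "redundancy", "roc_point",
    "fragment_distribution", "fragment_number", "base_error_rate",
    "chimera_rate", "classify_ortholog_pairs", "evaluate",
]


@dataclass
class AlignmentRecord:
    """One query-vs-reference local alignment (PSL-compatible quantities)."""

    query_id: str
    target_id: str
    identity: float
    query_coverage: float
    target_coverage: float
    mismatches: int
    alignment_length: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]

    def __post_init__(self) -> None:
        for frac in (self.identity, self.query_coverage, self.target_coverage):
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction out of range: {frac}")
        if self.alignment_length < self.mismatches:
            raise ValueError("alignment_length must be >= mismatches")


# -- PSL ingestion --------------------------------------------------------

_PSL_FIELDS = 21


def parse_psl(path: str | Path) -> list[AlignmentRecord]:
    """Read BLAT PSL alignments (header tolerated) into records.

    Identity is matches / (matches + mismatches + query gap bases);
    coverages come from the aligned spans over the sequence sizes.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue
            parts = line.split("\t")
            if len(parts) < _PSL_FIELDS:
                raise ValueError(f"{path}: unparseable PSL line {lineno}: "
                                 f"expected {_PSL_FIELDS} fields, got {len(parts)}")
            try:
                matches, mis = int(parts[0]), int(parts[1])
                q_gap_bases, t_gap_bases = int(parts[5]), int(parts[7])
                q_name, q_size = parts[9], int(parts[10])
                q_start, q_end = int(parts[11]), int(parts[12])
                t_name, t_size = parts[13], int(parts[14])
                t_start, t_end = int(parts[15]), int(parts[16])
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable PSL line {lineno}: {exc}") from exc
            denom = matches + mis + q_gap_bases
            records.append(AlignmentRecord(
                query_id=q_name, target_id=t_name,
                identity=matches / denom if denom else 0.0,
                query_coverage=(q_end - q_start) / q_size,
                target_coverage=(t_end - t_start) / t_size,
                mismatches=mis,
                alignment_length=matches + mis + q_gap_bases + t_gap_bases,
                query_span=(q_start, q_end),
                target_span=(t_start, t_end),
            ))
    return records


# -- built-in aligner ------------------------------------------------------

_SEED_LEN = 15
_XDROP = 10


def _xdrop_extend(q: str, t: str, qs: int, qe: int, d: int) -> tuple[int, int]:
    """Extend [qs, qe) on diagonal d (t position = q position + d) ungapped."""
    # right
    score = best = 0
    best_qe = qe
    i = qe
    while i < len(q) and i + d < len(t):
        score += 1 if q[i] == t[i + d] else -2
        i += 1
        if score > best:
            best, best_qe = score, i
        elif best - score > _XDROP:
            break
    # left
    score = best = 0
    best_qs = qs
    i = qs - 1
    while i >= 0 and i + d >= 0:
        score += 1 if q[i] == t[i + d] else -2
        if score > best:
            best, best_qs = score, i
        elif best - score > _XDROP:
            break
        i -= 1
    return best_qs, best_qe


def align_records(predicted: Sequence[SeqRecord], reference: Sequence[SeqRecord],
                  seed_len: int = _SEED_LEN) -> list[AlignmentRecord]:
    """Seed-and-extend alignment of predictions against references.

    Exact ``seed_len``-mers anchor diagonals; each diagonal cluster is
    extended without gaps under an X-drop rule. Substitution-only test
    data needs no gapped extension; indel-bearing real alignments should
    come from BLAT via :func:`parse_psl` instead.
    """
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)  # kmer -> (ref_i, pos)
    for ri, ref in enumerate(reference):
        s = ref.seq
        for i in range(0, len(s) - seed_len + 1):
            index[s[i:i + seed_len]].append((ri, i))
    records = []
    for q in predicted:
        qs_seq = q.seq
        hits: dict[tuple[int, int], list[int]] = defaultdict(list)  # (ref, diag) -> qpos
        for i in range(0, len(qs_seq) - seed_len + 1):
            for ri, tpos in index.get(qs_seq[i:i + seed_len], ()):
                hits[(ri, tpos - i)].append(i)
        # merge nearby diagonals per reference (tolerates nothing fancy;
        # substitution-only data stays on one diagonal)
        for (ri, d), qposs in sorted(hits.items()):
            ref = reference[ri]
            qs0, qe0 = min(qposs), max(qposs) + seed_len
            qs1, qe1 = _xdrop_extend(qs_seq, ref.seq, qs0, qe0, d)
            seg_q = qs_seq[qs1:qe1]
            seg_t = ref.seq[qs1 + d:qe1 + d]
            matches = sum(1 for a, b in zip(seg_q, seg_t) if a == b)
            alen = qe1 - qs1
            if alen < seed_len:
                continue
            records.append(AlignmentRecord(
                query_id=q.id, target_id=ref.id,
                identity=matches / alen,
                query_coverage=alen / len(qs_seq),
                target_coverage=alen / len(ref.seq),
                mismatches=alen - matches,
                alignment_length=alen,
                query_span=(qs1, qe1),
                target_span=(qs1 + d, qe1 + d),
            ))
    # collapse duplicate diagonal clusters: same query/target/span
    unique = {}
    for rec in records:
        key = (rec.query_id, rec.target_id, rec.query_span, rec.target_span)
        unique[key] = rec
    return list(unique.values())


def _as_records(source: Union[str, Path, Sequence[SeqRecord]]) -> list[SeqRecord]:
    if isinstance(source, (str, Path)):
        return list(read_sequences(source))
    return list(source)


def align_or_load(predicted, reference, psl: Optional[str | Path] = None,
                  ) -> list[AlignmentRecord]:
    """Alignments from a PSL file when given, else the built-in aligner."""
    if psl is not None:
        return parse_psl(psl)
    return align_records(_as_records(predicted), _as_records(reference))


# -- filters and metrics ---------------------------------------------------

def filter_alignments(records: Iterable[AlignmentRecord],
                      min_identity: float = 0.90, min_qcov: float = 0.90,
                      min_tcov: float = 0.90) -> list[AlignmentRecord]:
    """Keep alignments strictly above all three thresholds, best per pair.

    The comparisons are strict (an identity of exactly 0.90 is rejected);
    one record per (query, target) survives — highest identity, then
    longest alignment.
    """
    for thr in (min_identity, min_qcov, min_tcov):
        if not 0 < thr <= 1:
            raise ValueError("thresholds must be in (0, 1]")
    best: dict[tuple[str, str], AlignmentRecord] = {}
    for rec in records:
        if not (rec.identity > min_identity and rec.query_coverage > min_qcov
                and rec.target_coverage > min_tcov):
            continue
        key = (rec.query_id, rec.target_id)
        cur = best.get(key)
        if cur is None or (rec.identity, rec.alignment_length) > (cur.identity, cur.alignment_length):
            best[key] = rec
    return list(best.values())


def redundancy(records: Iterable[AlignmentRecord], n_reference: int,
               per_link: bool = False) -> float:
    """Aligned predicted CDSs divided by the reference gene count.

    ``per_link=True`` counts every surviving (query, target) link instead
    of distinct queries; the two coincide whenever each query survives
    against a single gene.
    """
    if n_reference < 1:
        raise ValueError("n_reference must be >= 1")
    records = list(records)
    if per_link:
        return len({(r.query_id, r.target_id) for r in records}) / n_reference
    return len({r.query_id for r in records}) / n_reference


def roc_point(records: Iterable[AlignmentRecord], predicted_ids: Sequence[str],
              reference_ids: Sequence[str]) -> tuple[float, float]:
    """(sensitivity, specificity) of CDS recognition.

    Sensitivity (TPR) is the fraction of reference genes with at least one
    surviving alignment; specificity (1−FPR) is the fraction of predicted
    CDSs with at least one surviving alignment.
    """
    if not predicted_ids or not reference_ids:
        raise ValueError("predicted and reference sets must be non-empty")
    records = list(records)
    covered = {r.target_id for r in records} & set(reference_ids)
    aligned = {r.query_id for r in records} & set(predicted_ids)
    return len(covered) / len(set(reference_ids)), len(aligned) / len(set(predicted_ids))


def fragment_distribution(records: Iterable[AlignmentRecord]) -> dict[int, float]:
    """pᵢ: fraction of aligned-to reference genes with exactly i aligned CDSs."""
    per_gene: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        per_gene[rec.target_id].add(rec.query_id)
    if not per_gene:
        return {}
    counts = defaultdict(int)
    for queries in per_gene.values():
        counts[len(queries)] += 1
    total = len(per_gene)
    return {i: c / total for i, c in sorted(counts.items())}


def fragment_number(records: Iterable[AlignmentRecord]) -> float:
    """Mean number of predicted CDSs per aligned reference gene: Σ i·pᵢ."""
    dist = fragment_distribution(records)
    if not dist:
        raise ValueError("no reference gene has an aligned CDS")
    return sum(i * p for i, p in dist.items())


def base_error_rate(records: Iterable[AlignmentRecord], pooled: bool = False) -> float:
    """Mismatches over alignment length, averaged per record.

    ``pooled=True`` instead divides total mismatches by total aligned
    bases.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one alignment record")
    if pooled:
        total = sum(r.alignment_length for r in records)
        return sum(r.mismatches for r in records) / total if total else 0.0
    return sum(r.mismatches / r.alignment_length for r in records) / len(records)


def _span_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def chimera_rate(records: Iterable[AlignmentRecord],
                 query_lengths: dict[str, int],
                 min_cds_bp: int = 500, min_frac: float = 0.30,
                 ) -> tuple[float, list[str]]:
    """Fraction of large predicted CDSs assembled from two or more genes.

    A predicted CDS longer than ``min_cds_bp`` is chimeric when
    alignments to at least two distinct reference genes each span at least
    ``min_frac`` of the CDS and occupy distinct query regions (pairwise
    span overlap below 50% of the shorter span — the same stretch aligned
    to two homologs does not count). The rate denominator is every
    predicted CDS longer than ``min_cds_bp``. Operates on unfiltered
    alignments.
    """
    eligible = {q for q, L in query_lengths.items() if L > min_cds_bp}
    if not eligible:
        return 0.0, []
    spans: dict[str, dict[str, tuple[int, int]]] = defaultdict(dict)  # q -> gene -> span
    for rec in records:
        q = rec.query_id
        if q not in eligible:
            continue
        span = rec.query_span
        if span[1] - span[0] < min_frac * query_lengths[q]:
            continue
        cur = spans[q].get(rec.target_id)
        if cur is None or span[1] - span[0] > cur[1] - cur[0]:
            spans[q][rec.target_id] = span
    chimeric = []
    for q, per_gene in spans.items():
        gspans = list(per_gene.values())
        found = False
        for i in range(len(gspans)):
            for j in range(i + 1, len(gspans)):
                shorter = min(gspans[i][1] - gspans[i][0], gspans[j][1] - gspans[j][0])
                if _span_overlap(gspans[i], gspans[j]) < 0.5 * shorter:
                    found = True
        if found:
            chimeric.append(q)
    return len(chimeric) / len(eligible), sorted(chimeric)


def classify_ortholog_pairs(alignments_a: Iterable[AlignmentRecord],
                            alignments_b: Iterable[AlignmentRecord],
                            pairs: Sequence[tuple[str, str]],
                            min_identity: float = 0.95,
                            min_qcov: float = 0.50, min_tcov: float = 0.50,
                            min_codons: int = 250) -> dict[str, int]:
    """Classify one-to-one reference ortholog pairs by predicted multiplicity.

    Alignments on each side are filtered (identity, coverages strictly
    above the thresholds; aligned length strictly above ``min_codons``
    codons, i.e. alignment_length/3). For each (refA, refB) pair the
    surviving predicted queries per side are counted: (1,1) one-to-one,
    (1,>1) one-to-many, (>1,1) many-to-one, (>1,>1) many-to-many; a zero
    on either side makes the pair unaligned.
    """
    ids_a = [a for a, _ in pairs]
    ids_b = [b for _, b in pairs]
    if len(set(ids_a)) != len(ids_a) or len(set(ids_b)) != len(ids_b):
        raise ValueError("duplicate reference ids in ortholog pairs")

    def surviving(records: Iterable[AlignmentRecord]) -> dict[str, set[str]]:
        per_ref: dict[str, set[str]] = defaultdict(set)
        for rec in records:
            if (rec.identity > min_identity and rec.query_coverage > min_qcov
                    and rec.target_coverage > min_tcov
                    and rec.alignment_length / 3 > min_codons):
                per_ref[rec.target_id].add(rec.query_id)
        return per_ref

    by_a = surviving(alignments_a)
    by_b = surviving(alignments_b)
    counts = {"one-to-one": 0, "one-to-many": 0, "many-to-one": 0,
              "many-to-many": 0, "unaligned": 0}
    for ra, rb in pairs:
        na, nb = len(by_a.get(ra, ())), len(by_b.get(rb, ()))
        if na == 0 or nb == 0:
            counts["unaligned"] += 1
        elif na == 1 and nb == 1:
            counts["one-to-one"] += 1
        elif na == 1:
            counts["one-to-many"] += 1
        elif nb == 1:
            counts["many-to-one"] += 1
        else:
            counts["many-to-many"] += 1
    return counts


@dataclass
class EvalReport:
    """Bundle of CDS-quality metrics for one prediction set."""

    redundancy: float
    sensitivity: float
    specificity: float
    fragment_number: Optional[float]
    base_error_rate: Optional[float]
    chimera_rate: float
    n_predicted: int
    n_reference: int
    fragment_pi: dict[int, float]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for name in ("redundancy", "sensitivity", "specificity",
                         "fragment_number", "base_error_rate", "chimera_rate",
                         "n_predicted", "n_reference"):
                value = getattr(self, name)
                fh.write(f"{name}\t{'' if value is None else value}\n")


def evaluate(predicted, reference, psl: Optional[str | Path] = None,
             min_identity: float = 0.90, min_qcov: float = 0.90,
             min_tcov: float = 0.90) -> EvalReport:
    """End-to-end evaluation of predicted CDSs against a reference set."""
    pred = _as_records(predicted)
    ref = _as_records(reference)
    raw = align_or_load(pred, ref, psl=psl)
    kept = filter_alignments(raw, min_identity, min_qcov, min_tcov)
    sens, spec = roc_point(kept, [r.id for r in pred], [r.id for r in ref]) \
        if pred and ref else (0.0, 0.0)
    frag = fragment_number(kept) if kept else None
    err = base_error_rate(kept) if kept else None
    chim, _ = chimera_rate(raw, {r.id: len(r.seq) for r in pred})
    return EvalReport(
        redundancy=redundancy(kept, len(ref)),
        sensitivity=sens, specificity=spec,
        fragment_number=frag, base_error_rate=err, chimera_rate=chim,
        n_predicted=len(pred), n_reference=len(ref),
        fragment_pi=fragment_distribution(kept),
    )
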
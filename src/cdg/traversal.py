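"""Landmark-guided traversal: from a noisy graph to full-length CDSs.

The SVM keeps only high-confidence ORFs, so a graph built from rORFs alone
would be fragmented. Instead, the assembly graph is built from *all*
candidate ORFs (complete but noisy), and the rORFs are mapped onto it:
graph nodes that are also rORF k-mers become *landmarks*. A depth-first
search starts at every landmark and follows out-edges until it reaches
another landmark (success), a dead end, or a depth cap; successful
landmark-to-landmark segments are chained through shared endpoints into
maximal paths and spelled into CDSs. In *strict* mode every node on a
path must itself be a landmark, trading sensitivity for precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from cdg.graph import CodonGraph, build_codon_graph
from cdg.orfs import Orf, extract_orfs, partition_orfs
from cdg.seqio import SeqRecord
from cdg.svm import TrainingError, build_training_sets, filter_orfs, train_svm

__all__ = ["Cds", "map_landmarks", "connect_landmarks", "emit_cds", "assemble"]


@dataclass
class Cds:
    """An assembled coding sequence with its provenance."""

    id: str
    seq: str
    path_len: int
    landmark_orf_ids: list[str] = field(default_factory=list)
    mode: str = "default"

    def __len__(self) -> int:
        return len(self.seq)


def map_landmarks(graph: CodonGraph, rorfs: Sequence[Orf],
                  ) -> tuple[set[str], dict[str, set[str]]]:
    """Landmark nodes of the graph plus per-node supporting rORF ids.

    A landmark is a graph node that equals a k-mer (codon step) of some
    rORF; rORF k-mers absent from the graph are ignored, and a node shared
    by several rORFs records every supporting id.
    """
    k, step = graph.k, graph.step
    landmarks: set[str] = set()
    support: dict[str, set[str]] = {}
    for orf in rorfs:
        seq = orf.seq
        for i in range(0, len(seq) - k + 1, step):
            kmer = seq[i:i + k]
            if kmer in graph.g:
                landmarks.add(kmer)
                support.setdefault(kmer, set()).add(orf.source_id)
    return landmarks, support


def _dfs_segments(graph: CodonGraph, start: str, landmarks: set[str],
                  max_depth: int, strict: bool) -> list[list[str]]:
    """All landmark-terminated out-paths from one landmark."""
    g = graph.g

    def children(node: str) -> list[str]:
        succ = [(-g[node][v]["mult"], v) for v in g.successors(node)]
        return [v for _, v in sorted(succ)]

    segments: list[list[str]] = []
    path = [start]
    on_path = {start}
    stack = [iter(children(start))]
    while stack:
        try:
            v = next(stack[-1])
        except StopIteration:
            stack.pop()
            on_path.discard(path.pop())
            continue
        if v in on_path:
            continue
        if v in landmarks:
            segments.append(path + [v])  # halt this branch at the landmark
            continue
        if strict:
            continue  # non-landmark nodes are off-limits in strict mode
        if len(path) >= max_depth:
            continue
        path.append(v)
        on_path.add(v)
        stack.append(iter(children(v)))
    return segments


def _extend_ends(graph: CodonGraph, path: list[str]) -> list[str]:
    """Prolong a path through unambiguous edges beyond its landmarks.

    The decision threshold of the ORF filter is conservative, so the
    terminal stretch of a coding path often carries no landmark even
    though the graph continues without any ambiguity. Walking on while
    the local structure stays linear (out-degree 1 into in-degree 1, and
    symmetrically backwards) recovers those residual codons without ever
    taking a branching decision.
    """
    g = graph.g
    on_path = set(path)
    tail = path[-1]
    while g.out_degree(tail) == 1:
        (nxt,) = g.successors(tail)
        if nxt in on_path or g.in_degree(nxt) != 1:
            break
        path.append(nxt)
        on_path.add(nxt)
        tail = nxt
    head = path[0]
    prefix: list[str] = []
    while g.in_degree(head) == 1:
        (prv,) = g.predecessors(head)
        if prv in on_path or g.out_degree(prv) != 1:
            break
        prefix.append(prv)
        on_path.add(prv)
        head = prv
    return prefix[::-1] + path


def connect_landmarks(graph: CodonGraph, landmarks: set[str],
                      max_depth: int = 5000, mode: str = "default",
                      extend_ends: bool = True) -> list[list[str]]:
    """Chain landmark-to-landmark DFS segments into maximal node paths.

    Segments are accepted greedily, longest first, with each landmark
    serving as the source of at most one accepted segment and the sink of
    at most one (this is what chains segments into maximal paths without
    combinatorial blowup). Accepted segments sharing endpoints concatenate;
    segments displaced by the greedy choice are still emitted as standalone
    paths so that genuine forks yield one path per branch. Unless
    ``extend_ends`` is off, finished paths are finally prolonged through
    unambiguous edges past their terminal landmarks (see
    :func:`_extend_ends`).
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if mode not in ("default", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    strict = mode == "strict"
    segments: list[list[str]] = []
    for lm in sorted(landmarks):
        if lm in graph.g:
            segments.extend(_dfs_segments(graph, lm, landmarks, max_depth, strict))
    segments.sort(key=lambda p: (-len(p), p[0], p[-1]))

    next_seg: dict[str, list[str]] = {}
    has_in: set[str] = set()
    standalone: list[list[str]] = []
    for seg in segments:
        u, v = seg[0], seg[-1]
        if u not in next_seg and v not in has_in and u != v:
            next_seg[u] = seg
            has_in.add(v)
        else:
            standalone.append(seg)

    chains: list[list[str]] = []
    consumed: set[int] = set()
    for u in sorted(next_seg):
        if u in has_in:
            continue  # not a chain start
        chain = list(next_seg[u])
        consumed.add(id(next_seg[u]))
        seen = {u}
        while chain[-1] in next_seg and chain[-1] not in seen:
            seen.add(chain[-1])
            seg = next_seg[chain[-1]]
            consumed.add(id(seg))
            chain.extend(seg[1:])
        chains.append(chain)
    # accepted segments inside cycles (no start node) are emitted as-is
    for u, seg in sorted(next_seg.items()):
        if id(seg) not in consumed:
            chains.append(seg)
    paths = chains + standalone
    if extend_ends:
        paths = [_extend_ends(graph, list(p)) for p in paths]
    return paths


def emit_cds(paths: Sequence[Sequence[str]], k: int, step: int = 3,
             support: Optional[dict[str, set[str]]] = None,
             mode: str = "default") -> list[Cds]:
    """Spell node paths into CDSs, dropping exact-substring duplicates.

    Output is sorted by length descending with stable ids; when one
    spelled sequence is a substring of another, only the container is
    kept.
    """
    spelled = []
    for path in paths:
        seq = path[0] + "".join(n[-step:] for n in path[1:])
        spelled.append((seq, list(path)))
    spelled.sort(key=lambda t: (-len(t[0]), t[0]))
    kept: list[tuple[str, list[str]]] = []
    for seq, path in spelled:
        if any(seq in other for other, _ in kept):
            continue
        kept.append((seq, path))
    out = []
    for i, (seq, path) in enumerate(kept, start=1):
        ids: set[str] = set()
        if support:
            for node in path:
                ids |= support.get(node, set())
        out.append(Cds(id=f"cds_{i:05d}", seq=seq, path_len=len(path),
                       landmark_orf_ids=sorted(ids), mode=mode))
    return out


@dataclass
class AssemblyResult:
    cds: list[Cds]
    manifest: dict

    def __iter__(self):
        return iter(self.cds)


def assemble(records: Iterable[SeqRecord], *, k: int = 27, min_orf: int = 27,
             loose_fraction: float = 0.8, min_contig_bp: int = 1000,
             tip_bp: Optional[int] = None, bubble_identity: float = 0.95,
             mode: str = "default", target_specificity: float = 0.95,
             max_depth: int = 5000, seed: int = 0, svm_window: Optional[int] = 150,
             min_class: int = 20) -> AssemblyResult:
    """End-to-end CDS construction from reads (or transcripts).

    Stages: six-frame translation → strict/loose partition → SVM training
    on graph-derived sets and filtration into rORFs → codon graph over all
    candidate ORFs → tip trimming + bubble merging → landmark mapping →
    DFS connection → CDS emission. Returns the CDS list plus a manifest of
    per-stage counts.

    If no SVM training set can be assembled (too few long contigs), the
    positive-contig threshold is halved once; if training is still
    impossible every candidate ORF is kept as an rORF and the manifest
    flags the run (``svm: skipped``).
    """
    manifest: dict = {"parameters": {
        "k": k, "min_orf": min_orf, "loose_fraction": loose_fraction,
        "min_contig_bp": min_contig_bp, "tip_bp": tip_bp or 2 * k,
        "bubble_identity": bubble_identity, "mode": mode,
        "target_specificity": target_specificity, "max_depth": max_depth,
        "seed": seed, "svm_window": svm_window,
    }}

    all_orfs: list[Orf] = []
    n_records = 0
    for rec in records:
        n_records += 1
        all_orfs.extend(extract_orfs(rec, min_len=min_orf, loose_fraction=loose_fraction))
    strict, candidates = partition_orfs(all_orfs)
    manifest["translate"] = {"records": n_records, "orfs": len(all_orfs),
                             "strict": len(strict), "candidates": len(candidates)}

    model = None
    svm_note = "trained"
    for contig_floor in (min_contig_bp, max(min_contig_bp // 2, 2 * k)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pos, neg = build_training_sets(strict, k=k, min_contig_bp=contig_floor,
                                           min_orf_len=min_orf)
        try:
            model = train_svm(pos, neg, target_specificity=target_specificity,
                              seed=seed, window=svm_window, min_class=min_class)
            break
        except TrainingError:
            model = None
            svm_note = f"retry at min_contig_bp={contig_floor}"
    if model is not None:
        rorfs, _ = filter_orfs(model, candidates)
        manifest["svm"] = {"status": "trained", "n_pos": model.n_pos,
                           "n_neg": model.n_neg,
                           "holdout_accuracy": model.holdout_accuracy,
                           "rorfs": len(rorfs)}
    else:
        warnings.warn("SVM training set too small; keeping all candidate ORFs as rORFs")
        rorfs = list(candidates)
        manifest["svm"] = {"status": "skipped", "note": svm_note, "rorfs": len(rorfs)}

    graph = build_codon_graph(candidates, k)
    n0, e0 = graph.counts()
    tips, bubbles = graph.simplify(max_tip_bp=tip_bp, min_identity=bubble_identity)
    n1, e1 = graph.counts()
    manifest["graph"] = {"nodes": n0, "edges": e0, "tips_trimmed": tips,
                         "bubbles_merged": bubbles,
                         "nodes_simplified": n1, "edges_simplified": e1}

    landmarks, support = map_landmarks(graph, rorfs)
    paths = connect_landmarks(graph, landmarks, max_depth=max_depth, mode=mode)
    cds = emit_cds(paths, k, step=graph.step, support=support, mode=mode)
    manifest["traverse"] = {"landmarks": len(landmarks), "paths": len(paths),
                            "cds": len(cds)}
    return AssemblyResult(cds=cds, manifest=manifest)
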
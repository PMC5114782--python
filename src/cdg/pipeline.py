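"""File-based orchestration of the four-stage pipeline with a run manifest.

The library's :func:`cdg.traversal.assemble` does the work in memory; this
module wraps it for batch use: read inputs, optionally merge pairs, write
the intermediate artifacts (orfs.fa, rorfs.fa, graph.gfa, cds.fa) and a
JSON manifest recording parameters, seeds and per-stage counts so a run
can be reproduced or resumed by inspection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from cdg import __version__
from cdg.graph import build_codon_graph
from cdg.orfs import extract_orfs, partition_orfs
from cdg.seqio import SeqRecord, read_pairs, read_sequences, merge_pairs, write_fasta
from cdg.svm import TrainingError, build_training_sets, filter_orfs, train_svm
from cdg.traversal import connect_landmarks, emit_cds, map_landmarks

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated, serializable parameters of one pipeline run."""

    input: str
    input2: Optional[str] = None  # second mate file triggers pair merging
    outdir: str = "cdg_out"
    k: int = 27
    min_orf: int = 27
    loose_fraction: float = 0.8
    min_contig_bp: int = 1000
    tip_bp: Optional[int] = None  # default 2k
    bubble_identity: float = 0.95
    mode: str = "default"
    target_specificity: float = 0.95
    max_depth: int = 5000
    seed: int = 0
    svm_window: Optional[int] = 150
    min_overlap: int = 10
    max_mismatch_rate: float = 0.25
    write_intermediates: bool = True

    def __post_init__(self) -> None:
        if self.k % 3 != 0 or not 6 <= self.k <= 63:
            raise ValueError(f"k must be a multiple of 3 in [6, 63], got {self.k}")
        if self.min_orf % 3 != 0 or self.min_orf < 3:
            raise ValueError("min_orf must be a positive multiple of 3")
        if not 0 < self.loose_fraction <= 1:
            raise ValueError("loose_fraction must be in (0, 1]")
        if not 0 < self.bubble_identity <= 1:
            raise ValueError("bubble_identity must be in (0, 1]")
        if self.mode not in ("default", "strict"):
            raise ValueError(f"mode must be default or strict, got {self.mode!r}")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


def run_pipeline(config: PipelineConfig) -> tuple[Path, dict]:
    """Execute translate → filter → graph → traverse, writing artifacts.

    Returns (path to cds.fa, manifest dict). The manifest is also written
    as ``manifest.json`` in the output directory. Re-running with the same
    inputs and config reproduces identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    # ---- input (optionally merging pairs)
    if config.input2:
        result = merge_pairs(read_pairs(config.input, config.input2),
                             min_overlap=config.min_overlap,
                             max_mismatch_rate=config.max_mismatch_rate)
        records = list(result.merged)
        for pair in result.unmerged:  # unmerged mates enter as single reads
            records.extend([pair.r1, pair.r2])
        manifest["stages"]["merge"] = {"merged": len(result.merged),
                                       "unmerged_pairs": len(result.unmerged)}
    else:
        records = list(read_sequences(config.input))
    if not records:
        warnings.warn(f"no input sequences in {config.input}; writing empty output")

    # ---- stage 1: six-frame translation
    all_orfs = []
    for rec in records:
        all_orfs.extend(extract_orfs(rec, min_len=config.min_orf,
                                     loose_fraction=config.loose_fraction))
    strict, candidates = partition_orfs(all_orfs)
    manifest["stages"]["translate"] = {
        "records": len(records), "orfs": len(all_orfs),
        "strict": len(strict), "candidates": len(candidates)}
    if config.write_intermediates:
        write_fasta((SeqRecord(f"{o.source_id}|{o.frame:+d}|{o.start}|{o.kind}", o.seq)
                     for o in all_orfs), outdir / "orfs.fa")

    # ---- stage 2: SVM filtration
    model = None
    for contig_floor in (config.min_contig_bp, max(config.min_contig_bp // 2, 2 * config.k)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pos, neg = build_training_sets(strict, k=config.k,
                                           min_contig_bp=contig_floor,
                                           min_orf_len=config.min_orf)
        try:
            model = train_svm(pos, neg, target_specificity=config.target_specificity,
                              seed=config.seed, window=config.svm_window)
            break
        except TrainingError:
            model = None
    if model is not None:
        rorfs, _ = filter_orfs(model, candidates)
        manifest["stages"]["svm"] = {
            "status": "trained", "n_pos": model.n_pos, "n_neg": model.n_neg,
            "holdout_accuracy": round(model.holdout_accuracy, 4), "rorfs": len(rorfs)}
    else:
        if candidates:
            warnings.warn("SVM training set too small; keeping all candidate ORFs")
        rorfs = list(candidates)
        manifest["stages"]["svm"] = {"status": "skipped", "rorfs": len(rorfs)}
    if config.write_intermediates:
        write_fasta((SeqRecord(f"{o.source_id}|{o.frame:+d}|{o.start}|{o.kind}", o.seq)
                     for o in rorfs), outdir / "rorfs.fa")

    # ---- stage 3: graph construction + simplification
    graph = build_codon_graph(candidates, config.k)
    n0, e0 = graph.counts()
    tips, bubbles = graph.simplify(max_tip_bp=config.tip_bp,
                                   min_identity=config.bubble_identity)
    n1, e1 = graph.counts()
    manifest["stages"]["graph"] = {
        "nodes": n0, "edges": e0, "tips_trimmed": tips, "bubbles_merged": bubbles,
        "nodes_simplified": n1, "edges_simplified": e1}
    if config.write_intermediates:
        graph.export_gfa(outdir / "graph.gfa")

    # ---- stage 4: traversal
    landmarks, support = map_landmarks(graph, rorfs)
    paths = connect_landmarks(graph, landmarks, max_depth=config.max_depth,
                              mode=config.mode)
    cds = emit_cds(paths, config.k, step=graph.step, support=support, mode=config.mode)
    manifest["stages"]["traverse"] = {"landmarks": len(landmarks),
                                      "paths": len(paths), "cds": len(cds)}

    cds_path = outdir / "cds.fa"
    write_fasta((SeqRecord(f"{c.id} length={len(c)} path_len={c.path_len} mode={c.mode}",
                           c.seq) for c in cds), cds_path)
    with open(outdir / "provenance.tsv", "w") as fh:
        fh.write("cds_id\tsupporting_rorf_sources\n")
        for c in cds:
            fh.write(f"{c.id}\t{','.join(c.landmark_orf_ids)}\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return cds_path, manifest
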
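"""Self-supervised SVM filtration of candidate ORFs.

True coding sequence carries a species-specific codon-usage signature that
wrong-frame translations lack. The filter exploits this without any
external training data: strict ORFs (whole-frame, stop-free) are threaded
into a codon-based de Bruijn graph, and the long unitig contigs (default
≥ 1 kb) that emerge are taken as the positive class — they are long
precisely because many independent reads agree on the frame. The negative
class is built from the other five reading frames of each positive contig.
An RBF-kernel SVM over 64-dimensional codon-usage-frequency vectors is
trained on these sets (gamma scaled to the feature variance: frequency
vectors live on the unit simplex, where squared distances are of order
1/L, so a fixed small gamma would make the kernel nearly constant), with its decision threshold calibrated on a held-out
split to favour specificity; candidates scoring above threshold become
reliable ORFs (rORFs) which later guide graph traversal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from cdg._codons import CODONS
from cdg.graph import build_codon_graph
from cdg.orfs import Orf, frame_sequences, _stop_free_runs

__all__ = [
    "codon_usage_features", "build_training_sets", "train_svm", "filter_orfs",
    "SvmModel", "TrainingError", "NoPositiveContigs",
]

_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

MODEL_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Raised when a class does not meet the example-count floor."""


class NoPositiveContigs(UserWarning):
    """No unitig contig reached the positive-set length threshold."""


def codon_usage_features(seq: str) -> np.ndarray:
    """64-entry codon-usage-frequency vector of a codon-aligned sequence.

    Codons containing N are excluded from both numerator and denominator;
    if every codon contains an N the vector is all zeros. Entries sum to 1
    otherwise.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    vec = np.zeros(64)
    seq = seq.upper()
    for i in range(0, len(seq), 3):
        idx = _CODON_INDEX.get(seq[i:i + 3])
        if idx is not None:
            vec[idx] += 1
    total = vec.sum()
    return vec / total if total else vec


def build_training_sets(strict_orfs: Sequence[Orf], k: int = 27,
                        min_contig_bp: int = 1000, min_orf_len: int = 27,
                        ) -> tuple[list[str], list[str]]:
    """Derive (positives, negatives) from strict ORFs via the codon graph.

    Positives: unitig contigs of the strict-ORF codon graph spelling at
    least ``min_contig_bp``. Negatives: for each positive contig, the
    longest stop-free run (≥ ``min_orf_len``) of each of its five alternate
    reading frames. Warns (:class:`NoPositiveContigs`) when no contig
    reaches the threshold.
    """
    if min_contig_bp < k:
        raise ValueError("min_contig_bp must be at least k")
    graph = build_codon_graph(strict_orfs, k)
    positives = sorted((u for u in graph.unitigs() if len(u) >= min_contig_bp),
                       key=lambda s: (-len(s), s))
    negatives: list[str] = []
    for contig in positives:
        for frame, fseq in frame_sequences(contig):
            if frame == 1:
                continue  # the contig's own frame
            runs = [(e - s, s, e) for s, e in _stop_free_runs(fseq)]
            runs = [r for r in runs if r[0] >= min_orf_len]
            if runs:
                length, s, e = max(runs)
                negatives.append(fseq[s:e])
    if not positives:
        warnings.warn("no unitig contig reached min_contig_bp; positive set empty",
                      NoPositiveContigs)
    return positives, negatives


def _tile(seqs: Sequence[str], window: int) -> list[str]:
    """Codon-aligned non-overlapping windows; sequences < window are kept whole."""
    window -= window % 3
    out = []
    for s in seqs:
        if len(s) <= window:
            out.append(s)
            continue
        for i in range(0, len(s) - window + 1, window):
            out.append(s[i:i + window])
    return out


@dataclass
class SvmModel:
    """A fitted codon-usage classifier plus its decision threshold.

    Scores strictly above ``threshold`` are called positive (coding). The
    model records its training conditions so a fit is reproducible from
    (data, hyperparameters, seed).
    """

    clf: SVC
    threshold: float
    n_pos: int
    n_neg: int
    seed: int
    target_specificity: float
    holdout_accuracy: float
    holdout_sensitivity: float
    holdout_specificity: float
    separable: bool
    format_version: int = MODEL_FORMAT_VERSION
    hyperparams: dict = field(default_factory=dict)

    def decision_scores(self, seqs: Sequence[str]) -> np.ndarray:
        if len(seqs) == 0:
            return np.zeros(0)
        X = np.vstack([codon_usage_features(s) for s in seqs])
        return self.clf.decision_function(X)

    def predict(self, seqs: Sequence[str]) -> np.ndarray:
        """Boolean coding calls (score > threshold)."""
        return self.decision_scores(seqs) > self.threshold

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": self.format_version, "model": self}, path)

    @staticmethod
    def load(path: str | Path) -> "SvmModel":
        payload = joblib.load(path)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model file version in {path}")
        return payload["model"]


def train_svm(positives: Sequence[str], negatives: Sequence[str], *,
              C: float = 1.0, gamma="scale",
              target_specificity: float = 0.95, holdout: float = 0.2,
              seed: int = 0, min_class: int = 20,
              window: Optional[int] = None) -> SvmModel:
    """Fit the codon-usage SVM and calibrate its decision threshold.

    ``window``, when given, tiles the training sequences into codon-aligned
    windows of that many bases first, matching classifier training length
    to the read-scale ORFs it will score. Sequences are canonically sorted
    before splitting so that input order cannot influence the fit.

    Threshold calibration is cross-validated: out-of-fold decision scores
    are computed for every example (``1/holdout`` stratified folds), and
    the threshold is set at the ``target_specificity`` quantile of the
    out-of-fold negative scores — a specificity-first operating point with
    far lower variance than a single split, which matters for the small
    training sets self-supervised construction yields. The reported
    held-out metrics are the out-of-fold ones; the returned classifier is
    refit on all the data.
    """
    pos = sorted(_tile(positives, window)) if window else sorted(positives)
    neg = sorted(_tile(negatives, window)) if window else sorted(negatives)
    if len(pos) < min_class or len(neg) < min_class:
        raise TrainingError(
            f"need >= {min_class} examples per class, got {len(pos)} positive "
            f"and {len(neg)} negative")
    X = np.vstack([codon_usage_features(s) for s in pos + neg])
    y = np.array([1] * len(pos) + [0] * len(neg))
    clf = SVC(kernel="rbf", C=C, gamma=gamma, class_weight="balanced",
              random_state=seed)
    n_folds = max(2, round(1 / holdout))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof_scores = cross_val_predict(clf, X, y, cv=cv, method="decision_function")
    neg_scores = oof_scores[y == 0]
    pos_scores = oof_scores[y == 1]
    # 'higher' interpolation keeps the calibration conservative
    threshold = float(np.quantile(neg_scores, target_specificity, method="higher"))
    calls = oof_scores > threshold
    accuracy = float(np.mean(calls == (y == 1)))
    sensitivity = float(np.mean(pos_scores > threshold))
    specificity = float(np.mean(neg_scores <= threshold))
    clf.fit(X, y)
    separable = accuracy >= 0.6
    if not separable:
        warnings.warn(f"threshold calibration: classes look non-separable "
                      f"(held-out accuracy {accuracy:.2f})")
    return SvmModel(
        clf=clf, threshold=threshold, n_pos=len(pos), n_neg=len(neg),
        seed=seed, target_specificity=target_specificity,
        holdout_accuracy=accuracy, holdout_sensitivity=sensitivity,
        holdout_specificity=specificity, separable=separable,
        hyperparams={"kernel": "rbf", "C": C, "gamma": gamma,
                     "class_weight": "balanced", "window": window},
    )


def filter_orfs(model: SvmModel, orfs: Sequence[Orf]) -> tuple[list[Orf], list[Orf]]:
    """Partition candidate ORFs into (rORFs, rejected), preserving order."""
    if not orfs:
        return [], []
    calls = model.predict([o.seq for o in orfs])
    rorfs = [o for o, c in zip(orfs, calls) if c]
    rejected = [o for o, c in zip(orfs, calls) if not c]
    return rorfs, rejected
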
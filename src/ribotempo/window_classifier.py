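"""Fast/slow position labeling and the window-size sweep classifier.

Positions are labeled slow from pooled normalized footprint counts
under one of three cutoffs (median, mean, 90th percentile). A logistic
model over windowed codon-count features is then scored by stratified
5-fold cross-validation across window sizes 1-21 plus the special
(-5, +3) window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .cub_models import Window, window_offsets
from .genetics import CODON_INDEX, SENSE_CODONS
from .orfeome_io import CodingSequence
from .rfp_processing import RfpTrack

logger = logging.getLogger(__name__)

CUTOFF_MODES = ("median", "mean", "p90")


@dataclass(frozen=True)
class ClassifierConfig:
    cutoff_mode: str = "median"
    folds: int = 5
    seed: int = 0
    C: float = 1.0
    tol: float = 1e-4
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.cutoff_mode not in CUTOFF_MODES:
            raise ValueError(f"unknown cutoff mode: {self.cutoff_mode}")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class MetricsRow:
    """Cross-validated slow-class metrics for one window."""

    window: Window
    cutoff_mode: str
    precision: float
    recall: float
    f1: float
    fold_precision: list[float] = field(default_factory=list)
    fold_recall: list[float] = field(default_factory=list)
    fold_f1: list[float] = field(default_factory=list)


def slow_cutoff(values: np.ndarray, mode: str) -> float:
    """Cutoff value for one labeling mode over pooled counts."""
    if mode == "median":
        return float(np.median(values))
    if mode == "mean":
        return float(np.mean(values))
    if mode == "p90":
        return float(np.quantile(values, 0.9))
    raise ValueError(f"unknown cutoff mode: {mode}")


def label_positions(
    tracks: Mapping[str, RfpTrack], mode: str
) -> tuple[dict[str, np.ndarray], float]:
    """Binary slow labels per retained position, pooled cutoff.

    median/mean modes label slow strictly above the cutoff; p90 labels
    slow at or above the 90th-percentile boundary so the top 10% forms
    the slow class.
    """
    pooled = np.concatenate([t.retained_counts for t in tracks.values()])
    cutoff = slow_cutoff(pooled, mode)
    labels: dict[str, np.ndarray] = {}
    for gene_id, track in tracks.items():
        retained = track.retained_counts
        if mode == "p90":
            labels[gene_id] = retained >= cutoff
        else:
            labels[gene_id] = retained > cutoff
    return labels, cutoff


def window_features(
    seq: CodingSequence, position: int, window: Window
) -> np.ndarray:
    """61-length codon count vector over the window around ``position``."""
    codons = seq.sense_codons
    lo = position - window.left
    hi = position + window.right + 1
    if lo < 0 or hi > len(codons):
        raise IndexError(
            f"{seq.gene_id}: window {window} out of bounds at position {position}"
        )
    vec = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for codon in codons[lo:hi]:
        vec[CODON_INDEX[codon]] += 1
    return vec


def collect_positions(
    tracks: Mapping[str, RfpTrack],
    seqs: Mapping[str, CodingSequence],
    max_half_window: int = 10,
) -> list[tuple[str, int]]:
    """(gene, position) pairs usable for every window size up to
    2*max_half_window + 1."""
    positions: list[tuple[str, int]] = []
    for gene_id, track in tracks.items():
        seq = seqs[gene_id]
        n_sense = len(seq.sense_codons)
        for pos in track.retained_positions:
            if pos - max_half_window >= 0 and pos + max_half_window < n_sense:
                positions.append((gene_id, int(pos)))
    return positions


def feature_matrix(
    seqs: Mapping[str, CodingSequence],
    positions: Sequence[tuple[str, int]],
    window: Window,
) -> np.ndarray:
    """Stack window_features for all positions; vectorized per gene."""
    n_codons = len(SENSE_CODONS)
    X = np.zeros((len(positions), n_codons), dtype=np.int64)
    # per-gene cumulative one-hot so each row is a range-sum
    cumsums: dict[str, np.ndarray] = {}
    for i, (gene_id, pos) in enumerate(positions):
        if gene_id not in cumsums:
            codons = seqs[gene_id].sense_codons
            onehot = np.zeros((len(codons) + 1, n_codons), dtype=np.int64)
            for j, c in enumerate(codons):
                onehot[j + 1, CODON_INDEX[c]] = 1
            cumsums[gene_id] = np.cumsum(onehot, axis=0)
        cs = cumsums[gene_id]
        X[i] = cs[pos + window.right + 1] - cs[pos - window.left]
    return X


def label_vector(
    tracks: Mapping[str, RfpTrack],
    labels: Mapping[str, np.ndarray],
    positions: Sequence[tuple[str, int]],
) -> np.ndarray:
    """Align pooled per-gene labels with a position list."""
    y = np.zeros(len(positions), dtype=np.int64)
    offsets = {g: int(t.trim) for g, t in tracks.items()}
    for i, (gene_id, pos) in enumerate(positions):
        y[i] = bool(labels[gene_id][pos - offsets[gene_id]])
    return y


def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per sample)."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(f"a class has fewer than {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.full(len(y), -1, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def crossval_metrics(
    X: np.ndarray,
    y: np.ndarray,
    fold_assignment: np.ndarray,
    config: ClassifierConfig,
    window: Window,
) -> MetricsRow:
    """Class-balanced logistic regression, slow-class precision/recall/F1
    averaged over folds."""
    row = MetricsRow(window=window, cutoff_mode=config.cutoff_mode,
                     precision=0.0, recall=0.0, f1=0.0)
    for fold in range(config.folds):
        test = fold_assignment == fold
        train = ~test
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {fold} is single-class")
        model = LogisticRegression(
            class_weight="balanced",
            C=config.C,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        p, r, f1, _ = precision_recall_fscore_support(
            y[test], pred, labels=[1], average=None, zero_division=0
        )
        row.fold_precision.append(float(p[0]))
        row.fold_recall.append(float(r[0]))
        row.fold_f1.append(float(f1[0]))
    row.precision = float(np.mean(row.fold_precision))
    row.recall = float(np.mean(row.fold_recall))
    row.f1 = float(np.mean(row.fold_f1))
    return row


def sweep_windows(
    tracks: Mapping[str, RfpTrack],
    seqs: Mapping[str, CodingSequence],
    cutoff_modes: Iterable[str] = CUTOFF_MODES,
    sizes: Iterable[int] = range(1, 22),
    include_special: bool = True,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Metrics table over window sizes for each cutoff instance.

    The fold partition is computed once per cutoff instance and reused
    across all windows.
    """
    windows = [window_offsets(s) for s in sizes]
    if include_special:
        windows.append(window_offsets(convention="special"))
    positions = collect_positions(tracks, seqs)
    rows = []
    for mode in cutoff_modes:
        config = ClassifierConfig(cutoff_mode=mode, folds=folds, seed=seed)
        labels, _ = label_positions(tracks, mode)
        y = label_vector(tracks, labels, positions)
        folds_assignment = stratified_folds(y, folds, seed)
        for window in windows:
            X = feature_matrix(seqs, positions, window)
            m = crossval_metrics(X, y, folds_assignment, config, window)
            rows.append(
                {
                    "cutoff": mode,
                    "left": window.left,
                    "right": window.right,
                    "size": window.size,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
            )
            logger.info("cutoff=%s window=%s f1=%.3f", mode, window, m.f1)
    return pd.DataFrame(rows)
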
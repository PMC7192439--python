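"""Sliding-window tempo tracks and slow-position calling.

Five models are supported, all producing a per-codon score where lower
values imply slower predicted translation:

* ``orfeome_minmax`` / ``highphi_minmax`` — windowed %MinMax over a
  codon usage table,
* ``cai`` / ``highphi_cai`` / ``tai`` — windowed geometric mean of
  adaptiveness weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .genetics import SENSE_CODONS, SINGLETON_CODONS
from .orfeome_io import AdaptivenessWeights, CodingSequence, CodonUsageTable

logger = logging.getLogger(__name__)

MODEL_NAMES = ("orfeome_minmax", "highphi_minmax", "cai", "highphi_cai", "tai")

DEFAULT_SLOW_QUANTILE = 0.10


@dataclass(frozen=True)
class Window:
    """Asymmetric codon window around the A-site.

    ``left`` codons upstream, the A-site itself, and ``right`` codons
    downstream; size = left + right + 1.
    """

    left: int
    right: int

    def __post_init__(self) -> None:
        if self.left < 0 or self.right < 0:
            raise ValueError("window offsets must be nonnegative")

    @property
    def size(self) -> int:
        return self.left + self.right + 1

    def __str__(self) -> str:  # e.g. "(-5,+4)"
        return f"(-{self.left},+{self.right})"


def window_offsets(size: int | None = None, convention: str = "centered") -> Window:
    """Build a window by size.

    ``centered``: the A-site sits at the center; for even sizes the
    latter of the two possible middle positions is chosen, so size 10
    gives (-5, +4). ``special`` ignores ``size`` and returns the
    (-5, +3) window.
    """
    if convention == "special":
        return Window(5, 3)
    if convention != "centered":
        raise ValueError(f"unknown window convention: {convention}")
    if size is None or size < 1:
        raise ValueError("window size must be >= 1")
    left = size // 2
    return Window(left, size - left - 1)


#: Default analysis window, (-5, +4).
DEFAULT_WINDOW = window_offsets(10)


@dataclass
class ModelTrack:
    """Per-codon model scores for one gene; NaN marks undefined positions."""

    gene_id: str
    model_name: str
    scores: np.ndarray
    window: Window

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.scores)


@dataclass
class SlowCallset:
    """Bottom-q slow calls pooled across genes for one model."""

    model_name: str
    q: float
    threshold: float
    #: gene_id -> boolean array aligned with the model track's scores
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    #: gene_id -> defined-score mask
    defined: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_defined(self) -> int:
        return int(sum(m.sum() for m in self.defined.values()))

    @property
    def n_slow(self) -> int:
        return int(sum(m.sum() for m in self.labels.values()))


def _window_means(values: np.ndarray, window: Window) -> np.ndarray:
    """Mean of ``values`` over each full window; NaN where the window
    overhangs the sequence."""
    n = len(values)
    out = np.full(n, np.nan)
    size = window.size
    if n < size:
        return out
    csum = np.concatenate(([0.0], np.cumsum(values)))
    starts = np.arange(0, n - size + 1)
    means = (csum[starts + size] - csum[starts]) / size
    out[window.left : n - window.right] = means
    return out


def minmax_track(
    seq: CodingSequence,
    table: CodonUsageTable,
    window: Window = DEFAULT_WINDOW,
    model_name: str = "minmax",
) -> ModelTrack:
    """Windowed %MinMax score in [-100, 100].

    For each position with a full window, the actual mean within-family
    frequency of the window's codons is compared with the window's
    maximal, minimal, and average possible synonymous usage. Windows
    where the actual usage exceeds the average scale against the
    maximum, otherwise against the minimum. A fully degenerate window
    (all single-codon families) scores 0.
    """
    codons = seq.sense_codons
    n = len(codons)
    if n < window.size:
        logger.warning(
            "%s: length %d < window size %d; all scores undefined",
            seq.gene_id,
            n,
            window.size,
        )
        return ModelTrack(seq.gene_id, model_name, np.full(n, np.nan), window)
    stats = np.array([table.family_stats(c) for c in codons])
    x_act = _window_means(stats[:, 0], window)
    x_max = _window_means(stats[:, 1], window)
    x_min = _window_means(stats[:, 2], window)
    x_avg = _window_means(stats[:, 3], window)
    scores = np.full(n, np.nan)
    ok = ~np.isnan(x_act)
    den_hi = x_max - x_avg
    hi = ok & (x_act >= x_avg) & (den_hi > 0)
    degenerate = ok & (x_act >= x_avg) & (den_hi <= 0)
    lo = ok & (x_act < x_avg)  # implies x_avg - x_min > 0
    scores[hi] = 100.0 * (x_act[hi] - x_avg[hi]) / den_hi[hi]
    scores[degenerate] = 0.0
    scores[lo] = -100.0 * (x_avg[lo] - x_act[lo]) / (x_avg[lo] - x_min[lo])
    np.clip(scores, -100.0, 100.0, out=scores)  # guard float overshoot
    return ModelTrack(seq.gene_id, model_name, scores, window)


def geomean_track(
    seq: CodingSequence,
    weights: AdaptivenessWeights,
    window: Window = DEFAULT_WINDOW,
    exclude_singletons: bool = True,
    model_name: str = "geomean",
) -> ModelTrack:
    """Windowed geometric mean of adaptiveness weights.

    ATG/TGG (single-codon families) are skipped by default, per the
    usual CAI convention; a window consisting only of skipped codons is
    undefined.
    """
    codons = seq.sense_codons
    n = len(codons)
    scores = np.full(n, np.nan)
    if n < window.size:
        logger.warning(
            "%s: length %d < window size %d; all scores undefined",
            seq.gene_id,
            n,
            window.size,
        )
        return ModelTrack(seq.gene_id, model_name, scores, window)
    logw = np.array([math.log(weights.w[c]) for c in codons])
    if exclude_singletons:
        incl = np.array([c not in SINGLETON_CODONS for c in codons], dtype=float)
    else:
        incl = np.ones(n)
    size = window.size
    csum_w = np.concatenate(([0.0], np.cumsum(logw * incl)))
    csum_n = np.concatenate(([0.0], np.cumsum(incl)))
    starts = np.arange(0, n - size + 1)
    tot = csum_w[starts + size] - csum_w[starts]
    cnt = csum_n[starts + size] - csum_n[starts]
    vals = np.full(len(starts), np.nan)
    nz = cnt > 0
    vals[nz] = np.exp(tot[nz] / cnt[nz])
    if not nz.all():
        logger.warning("%s: %d windows with no scorable codons", seq.gene_id, int((~nz).sum()))
    scores[window.left : n - window.right] = vals
    return ModelTrack(seq.gene_id, model_name, scores, window)


def build_all_tracks(
    orfeome: Iterable[CodingSequence],
    tables: Mapping[str, CodonUsageTable],
    weights: Mapping[str, AdaptivenessWeights],
    window: Window = DEFAULT_WINDOW,
) -> dict[str, dict[str, ModelTrack]]:
    """Score every gene under all five models.

    ``tables`` must provide 'orfeome' and 'high_phi'; ``weights`` must
    provide 'cai', 'highphi_cai', and 'tai'. Returns
    model_name -> gene_id -> ModelTrack.
    """
    for key in ("orfeome", "high_phi"):
        if key not in tables:
            raise KeyError(f"missing codon usage table: {key}")
    for key in ("cai", "highphi_cai", "tai"):
        if key not in weights:
            raise KeyError(f"missing adaptiveness weights: {key}")
    orfeome = list(orfeome)
    out: dict[str, dict[str, ModelTrack]] = {m: {} for m in MODEL_NAMES}
    for cds in orfeome:
        out["orfeome_minmax"][cds.gene_id] = minmax_track(
            cds, tables["orfeome"], window, model_name="orfeome_minmax"
        )
        out["highphi_minmax"][cds.gene_id] = minmax_track(
            cds, tables["high_phi"], window, model_name="highphi_minmax"
        )
        for model, wkey in (("cai", "cai"), ("highphi_cai", "highphi_cai"), ("tai", "tai")):
            out[model][cds.gene_id] = geomean_track(
                cds, weights[wkey], window, model_name=model
            )
    return out


def call_slow(
    tracks: Iterable[ModelTrack],
    q: float = DEFAULT_SLOW_QUANTILE,
    model_name: str | None = None,
) -> SlowCallset:
    """Label the bottom-q fraction of pooled defined scores as slow.

    The threshold is the inclusive empirical q-quantile over all defined
    scores pooled across genes; ties at the threshold are all labeled
    slow.
    """
    tracks = list(tracks)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if model_name is None:
        model_name = tracks[0].model_name if tracks else "unknown"
    pooled = np.concatenate([t.scores[t.defined] for t in tracks]) if tracks else np.array([])
    if pooled.size == 0:
        raise ValueError("no defined scores to threshold")
    if np.min(pooled) == np.max(pooled):
        logger.warning("all %d pooled scores identical; every position called slow", pooled.size)
    threshold = float(np.quantile(pooled, q))
    callset = SlowCallset(model_name=model_name, q=q, threshold=threshold)
    for t in tracks:
        defined = t.defined
        callset.defined[t.gene_id] = defined
        callset.labels[t.gene_id] = defined & (t.scores <= threshold)
    return callset
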
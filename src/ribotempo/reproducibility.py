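"""Cross-experiment agreement of footprint tracks.

Per-gene Pearson correlations for genes passing filters in both
datasets, averaged per dataset pair, plus rank-sum comparisons of the
pair-average distributions between experimental-condition groups
(CHX-frozen vs not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
from scipy import stats

from .rfp_processing import RfpTrack

logger = logging.getLogger(__name__)


@dataclass
class PairCorrelation:
    dataset_a: str
    dataset_b: str
    per_gene_r: dict[str, float]

    @property
    def n_genes(self) -> int:
        return len(self.per_gene_r)

    @property
    def mean_r(self) -> float:
        if not self.per_gene_r:
            return float("nan")
        return float(np.mean(list(self.per_gene_r.values())))


def per_gene_pearson(a: RfpTrack, b: RfpTrack) -> float | None:
    """Pearson r over the shared retained span; None if either vector
    is constant (logged) — such genes are excluded from averages."""
    if a.gene_id != b.gene_id:
        raise ValueError(f"gene mismatch: {a.gene_id} vs {b.gene_id}")
    x, y = a.retained_counts, b.retained_counts
    if len(x) != len(y):
        raise ValueError(
            f"{a.gene_id}: retained span length mismatch ({len(x)} vs {len(y)})"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("%s: constant vector, correlation undefined", a.gene_id)
        return None
    return float(stats.pearsonr(x, y).statistic)


def pair_correlation(
    tracks_a: Mapping[str, RfpTrack],
    tracks_b: Mapping[str, RfpTrack],
    name_a: str,
    name_b: str,
) -> PairCorrelation:
    """Average per-gene correlation over genes present in both datasets.

    Genes whose retained spans differ in length (annotation drift) are
    excluded, logged.
    """
    shared = sorted(set(tracks_a) & set(tracks_b))
    per_gene: dict[str, float] = {}
    n_drift = 0
    for gene_id in shared:
        a, b = tracks_a[gene_id], tracks_b[gene_id]
        if len(a.retained_counts) != len(b.retained_counts):
            n_drift += 1
            continue
        r = per_gene_pearson(a, b)
        if r is not None:
            per_gene[gene_id] = r
    if n_drift:
        logger.info("%s vs %s: %d genes excluded (span drift)", name_a, name_b, n_drift)
    return PairCorrelation(dataset_a=name_a, dataset_b=name_b, per_gene_r=per_gene)


def pair_matrix(
    datasets: Mapping[str, Mapping[str, RfpTrack]],
) -> dict[tuple[str, str], PairCorrelation]:
    """All unordered dataset pairs; cell (a, b) is stored under the
    sorted key and is identical to (b, a)."""
    names = sorted(datasets)
    if len(names) < 2:
        raise ValueError("need at least two datasets")
    out: dict[tuple[str, str], PairCorrelation] = {}
    for a, b in combinations(names, 2):
        pc = pair_correlation(datasets[a], datasets[b], a, b)
        if pc.n_genes == 0:
            logger.warning("%s vs %s: no shared genes", a, b)
        out[(a, b)] = pc
    return out


def _ranksum_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def group_difference(
    matrix: Mapping[tuple[str, str], PairCorrelation],
    labels: Mapping[str, str],
    alpha: float = 0.05,
) -> dict[tuple[str, str], float]:
    """Pairwise rank-sum tests among within-group and cross-group
    pair-average correlation distributions.

    ``labels`` maps dataset name to a group label (e.g. 'CHX' /
    'nonCHX'). Distributions with fewer than 2 values are omitted
    (logged). Returns p-values keyed by distribution-name pairs.
    """
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError("exactly two groups expected")
    g1, g2 = groups
    dists: dict[str, list[float]] = {
        f"within_{g1}": [],
        f"within_{g2}": [],
        "cross": [],
    }
    for (a, b), pc in matrix.items():
        if np.isnan(pc.mean_r):
            continue
        la, lb = labels[a], labels[b]
        if la == lb:
            dists[f"within_{la}"].append(pc.mean_r)
        else:
            dists["cross"].append(pc.mean_r)
    usable = {k: np.asarray(v) for k, v in dists.items() if len(v) >= 2}
    for k in dists:
        if k not in usable:
            logger.warning("distribution %s has <2 values, omitted", k)
    out: dict[tuple[str, str], float] = {}
    for ka, kb in combinations(sorted(usable), 2):
        out[(ka, kb)] = _ranksum_two_sided(usable[ka], usable[kb])
    return out
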
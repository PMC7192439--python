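"""Model/footprint association statistics.

Per gene, normalized counts are split into model-slow and non-slow bins
and compared with a one-tailed Wilcoxon rank-sum test (slow
stochastically greater). Per-gene p-values are aggregated with Fisher's
combined probability test, over three gene partitions, with a
count-shuffling null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cub_models import SlowCallset
from .rfp_processing import RfpTrack, density_rank

logger = logging.getLogger(__name__)

MIN_BIN = 30
P_FLOOR = 1e-300
PARTITIONS = ("all", "dense500", "intersect")


@dataclass
class GeneBins:
    """Normalized counts routed by the model's slow calls."""

    gene_id: str
    slow_counts: np.ndarray
    nonslow_counts: np.ndarray
    min_bin: int = MIN_BIN

    @property
    def eligible(self) -> bool:
        return (
            len(self.slow_counts) >= self.min_bin
            and len(self.nonslow_counts) >= self.min_bin
        )


@dataclass
class CombinedResult:
    model_name: str
    partition: str
    n_genes: int
    chi2: float
    df: int
    p_combined: float


def make_bins(
    track: RfpTrack, slow: SlowCallset, min_bin: int = MIN_BIN
) -> GeneBins:
    """Split a gene's retained normalized counts by slow label.

    Retained positions without a defined model score are dropped.
    """
    labels = slow.labels.get(track.gene_id)
    defined = slow.defined.get(track.gene_id)
    if labels is None or defined is None:
        raise KeyError(f"{track.gene_id}: no slow calls for this gene")
    counts = track.retained_counts
    positions = track.retained_positions
    in_model = positions < len(labels)
    if not in_model.all():
        raise ValueError(
            f"{track.gene_id}: track positions extend past model track"
        )
    pos_defined = defined[positions]
    pos_slow = labels[positions]
    use = pos_defined
    return GeneBins(
        gene_id=track.gene_id,
        slow_counts=counts[use & pos_slow],
        nonslow_counts=counts[use & ~pos_slow],
        min_bin=min_bin,
    )


def wilcoxon_slow_greater(
    bins: GeneBins, method: str = "auto"
) -> float:
    """One-tailed rank-sum p-value for slow counts stochastically greater.

    ``auto`` uses the exact distribution for small tie-free bins and the
    tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    x, y = bins.slow_counts, bins.nonslow_counts
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"{bins.gene_id}: empty bin")
    pooled = np.concatenate([x, y])
    if np.min(pooled) == np.max(pooled):
        logger.warning("%s: constant counts, p = 0.5", bins.gene_id)
        return 0.5
    if method == "auto":
        small = max(len(x), len(y)) < MIN_BIN
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


def fisher_combine(pvalues: Sequence[float], model_name: str = "", partition: str = "") -> CombinedResult:
    """Fisher's method: chi2 = -2 Σ ln p with 2k degrees of freedom.

    Inputs are floored at 1e-300 before the log so the statistic stays
    finite; a combined p that underflows is reported as 0.0 (i.e.,
    below 2e-308).
    """
    pvalues = list(pvalues)
    if not pvalues:
        raise ValueError("no p-values to combine")
    floored = np.maximum(np.asarray(pvalues, dtype=float), P_FLOOR)
    chi2 = float(-2.0 * np.sum(np.log(floored)))
    df = 2 * len(pvalues)
    p = float(stats.chi2.sf(chi2, df))
    return CombinedResult(
        model_name=model_name,
        partition=partition,
        n_genes=len(pvalues),
        chi2=chi2,
        df=df,
        p_combined=p,
    )


def _eligible_genes(
    tracks: Mapping[str, RfpTrack],
    callset: SlowCallset,
    min_bin: int,
    genes: Iterable[str] | None = None,
) -> dict[str, GeneBins]:
    out: dict[str, GeneBins] = {}
    gene_ids = tracks.keys() if genes is None else genes
    for gene_id in gene_ids:
        track = tracks[gene_id]
        if gene_id not in callset.labels:
            continue
        bins = make_bins(track, callset, min_bin)
        if bins.eligible:
            out[gene_id] = bins
    return out


def run_partition(
    tracks: Mapping[str, RfpTrack],
    callsets: Mapping[str, SlowCallset],
    model_name: str,
    partition: str,
    min_bin: int = MIN_BIN,
    dense_n: int = 500,
    raw_tracks: Mapping[str, RfpTrack] | None = None,
) -> CombinedResult:
    """Combined p-value for one model on one gene partition.

    ``all``: every filtered gene eligible for this model. ``dense500``:
    the ``dense_n`` highest-density genes, pruned to eligible ones
    (density ranking uses ``raw_tracks`` — trimmed, unnormalized — when
    provided, else the normalized tracks). ``intersect``: genes
    eligible under every model in ``callsets``.
    """
    if partition not in PARTITIONS:
        raise ValueError(f"unknown partition: {partition}")
    callset = callsets[model_name]
    if partition == "all":
        bins = _eligible_genes(tracks, callset, min_bin)
    elif partition == "dense500":
        rank_source = raw_tracks if raw_tracks is not None else tracks
        top = density_rank(rank_source.values())[:dense_n]
        top = [g for g in top if g in tracks]
        bins = _eligible_genes(tracks, callset, min_bin, genes=top)
    else:  # intersect
        genes = None
        for cs in callsets.values():
            eligible = set(_eligible_genes(tracks, cs, min_bin))
            genes = eligible if genes is None else genes & eligible
        bins = _eligible_genes(tracks, callset, min_bin, genes=sorted(genes or ()))
    if not bins:
        raise ValueError(f"empty partition {partition} for model {model_name}")
    pvals = [wilcoxon_slow_greater(b) for b in bins.values()]
    return fisher_combine(pvals, model_name=model_name, partition=partition)


def intersect_genes(
    tracks: Mapping[str, RfpTrack],
    callsets: Mapping[str, SlowCallset],
    min_bin: int = MIN_BIN,
) -> list[str]:
    """Genes eligible under every model."""
    genes: set[str] | None = None
    for cs in callsets.values():
        eligible = set(_eligible_genes(tracks, cs, min_bin))
        genes = eligible if genes is None else genes & eligible
    return sorted(genes or ())


def _ranksum_p_greater(
    rank_sums: np.ndarray, n1: int, n2: int, tie_term: float
) -> np.ndarray:
    """Vectorized tie-corrected normal approximation with continuity
    correction, matching the asymptotic one-tailed rank-sum test."""
    n = n1 + n2
    u1 = rank_sums - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return np.full_like(rank_sums, 0.5, dtype=float)
    z = (u1 - mean - 0.5) / np.sqrt(var)
    return stats.norm.sf(z)


def shuffle_null(
    tracks: Mapping[str, RfpTrack],
    callsets: Mapping[str, SlowCallset],
    model_name: str,
    genes: Sequence[str],
    iters: int = 100,
    seed: int = 0,
    min_bin: int = MIN_BIN,
    identity: bool = False,
) -> float:
    """Average combined p over ``iters`` random within-gene count shuffles.

    Shuffling a gene's retained counts while keeping the slow mask fixed
    is equivalent to drawing the slow bin's ranks as a uniform random
    subset, so each iteration only resamples rank sums. ``identity``
    forces the unshuffled assignment (useful for verification).
    """
    rng = np.random.default_rng(seed)
    callset = callsets[model_name]
    combined = np.zeros(iters)
    per_gene_p = np.zeros((len(genes), iters))
    for gi, gene_id in enumerate(genes):
        bins = make_bins(tracks[gene_id], callset, min_bin)
        if not bins.eligible:
            raise ValueError(f"{gene_id}: ineligible gene in shuffle set")
        pooled = np.concatenate([bins.slow_counts, bins.nonslow_counts])
        if np.min(pooled) == np.max(pooled):
            per_gene_p[gi, :] = 0.5
            continue
        ranks = stats.rankdata(pooled)
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        n1 = len(bins.slow_counts)
        rank_sums = np.empty(iters)
        for it in range(iters):
            if identity:
                idx = np.arange(n1)
            else:
                idx = rng.choice(len(pooled), size=n1, replace=False)
            rank_sums[it] = ranks[idx].sum()
        per_gene_p[gi, :] = _ranksum_p_greater(
            rank_sums, n1, len(bins.nonslow_counts), tie_term
        )
    for it in range(iters):
        combined[it] = fisher_combine(per_gene_p[:, it]).p_combined
    return float(np.mean(combined))
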
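"""A-site codon enrichment at high-occupancy positions.

Positions are pooled across genes and split at the 90th percentile of
normalized counts; each sense codon's representation in the top split
is tested against the bottom split with Fisher's exact test at a
Bonferroni-corrected threshold. Codons significant in enough datasets
form the consensus lists, which are then scored against each codon
usage measure via the deviation from uniform synonymous usage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genetics import SENSE_CODONS, CODON_TO_AA, family_size, is_stop
from .orfeome_io import CodingSequence, CodonUsageTable, uniform_expectation
from .rfp_processing import RfpTrack

logger = logging.getLogger(__name__)

#: Bonferroni-corrected significance threshold over the 61 sense codons.
BONFERRONI_ALPHA = 0.05 / 61

DEFAULT_TOP_FRACTION = 0.10


@dataclass
class OccupancySplit:
    """Pooled positions split into top-occupancy and bottom sets."""

    top_fraction: float
    threshold: float
    top_positions: list[tuple[str, int]]
    bottom_positions: list[tuple[str, int]]

    @property
    def n_total(self) -> int:
        return len(self.top_positions) + len(self.bottom_positions)


@dataclass
class EnrichmentResult:
    codon: str
    table: tuple[tuple[int, int], tuple[int, int]]  # [[top_c, top_other], [bot_c, bot_other]]
    odds_ratio: float
    direction: str  # 'over' | 'under'
    p: float
    significant: bool


@dataclass(frozen=True)
class ConsensusConfig:
    n_datasets: int = 14
    min_datasets: int = 10
    alpha: float = BONFERRONI_ALPHA

    def __post_init__(self) -> None:
        if self.min_datasets > self.n_datasets:
            raise ValueError("min_datasets cannot exceed n_datasets")


@dataclass
class DeviationScore:
    codon: str
    measure_name: str
    deviation: float


def split_occupancy(
    tracks: Mapping[str, RfpTrack],
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> OccupancySplit:
    """Rank pooled retained positions by normalized count; the top
    fraction (boundary ties included) versus the rest."""
    genes: list[str] = []
    positions: list[int] = []
    values: list[float] = []
    for gene_id, track in tracks.items():
        for pos, val in zip(track.retained_positions, track.retained_counts):
            genes.append(gene_id)
            positions.append(int(pos))
            values.append(float(val))
    vals = np.asarray(values)
    if vals.size == 0:
        raise ValueError("no positions to split")
    if np.min(vals) == np.max(vals):
        raise ValueError("all pooled counts identical; occupancy split undefined")
    threshold = float(np.quantile(vals, 1.0 - top_fraction))
    top_mask = vals >= threshold
    top = [(g, p) for g, p, m in zip(genes, positions, top_mask) if m]
    bottom = [(g, p) for g, p, m in zip(genes, positions, top_mask) if not m]
    return OccupancySplit(
        top_fraction=top_fraction,
        threshold=threshold,
        top_positions=top,
        bottom_positions=bottom,
    )


def _codon_counts(
    positions: Iterable[tuple[str, int]],
    seqs: Mapping[str, CodingSequence],
) -> np.ndarray:
    counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    for gene_id, pos in positions:
        codon = seqs[gene_id].sense_codons[pos]
        counts[index[codon]] += 1
    return counts


def codon_enrichment(
    split: OccupancySplit,
    seqs: Mapping[str, CodingSequence],
    alpha: float = BONFERRONI_ALPHA,
    alternative: str = "two-sided",
) -> list[EnrichmentResult]:
    """Fisher's exact test per sense codon, top vs bottom occupancy.

    The A-site codon of a position is the codon at that position. The
    direction is read off the sample odds ratio.
    """
    top_counts = _codon_counts(split.top_positions, seqs)
    bot_counts = _codon_counts(split.bottom_positions, seqs)
    n_top = int(top_counts.sum())
    n_bot = int(bot_counts.sum())
    results: list[EnrichmentResult] = []
    for i, codon in enumerate(SENSE_CODONS):
        a, c = int(top_counts[i]), int(bot_counts[i])
        b, d = n_top - a, n_bot - c
        if a + c == 0:
            logger.info("%s: absent from all positions", codon)
            results.append(
                EnrichmentResult(codon, ((0, b), (0, d)), 1.0, "over", 1.0, False)
            )
            continue
        table = [[a, b], [c, d]]
        res = stats.fisher_exact(table, alternative=alternative)
        # direction from the sample odds ratio a*d vs b*c
        over = a * d > b * c
        results.append(
            EnrichmentResult(
                codon=codon,
                table=((a, b), (c, d)),
                odds_ratio=float(res.statistic),
                direction="over" if over else "under",
                p=float(res.pvalue),
                significant=bool(res.pvalue < alpha),
            )
        )
    return results


def consensus(
    per_dataset: Sequence[Sequence[EnrichmentResult]],
    config: ConsensusConfig = ConsensusConfig(),
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Codons significant-and-over (resp. under) in at least
    ``min_datasets`` datasets, with the enriched fraction per codon.

    Returns (over_list, under_list) of (codon, fraction) sorted by
    descending fraction then codon.
    """
    if not per_dataset:
        raise ValueError("no datasets")
    n = len(per_dataset)
    over_counts: dict[str, int] = {c: 0 for c in SENSE_CODONS}
    under_counts: dict[str, int] = {c: 0 for c in SENSE_CODONS}
    for results in per_dataset:
        for r in results:
            if r.significant and r.direction == "over":
                over_counts[r.codon] += 1
            elif r.significant and r.direction == "under":
                under_counts[r.codon] += 1

    def _listed(counts: dict[str, int]) -> list[tuple[str, float]]:
        hits = [
            (c, counts[c] / n)
            for c in SENSE_CODONS
            if counts[c] >= config.min_datasets
        ]
        return sorted(hits, key=lambda t: (-t[1], t[0]))

    return _listed(over_counts), _listed(under_counts)


def deviation_score(
    codons: Sequence[str], table: CodonUsageTable
) -> tuple[list[DeviationScore], float]:
    """Per-codon deviation freq - 1/n_syn under one usage measure, plus
    the total over the input codon list."""
    scores: list[DeviationScore] = []
    for codon in codons:
        if is_stop(codon):
            raise ValueError(f"{codon} is a stop codon")
        dev = table.freq[codon] - uniform_expectation(codon)
        scores.append(
            DeviationScore(codon=codon, measure_name=table.measure_name, deviation=dev)
        )
    total = float(sum(s.deviation for s in scores))
    return scores, total


def table_from_deviations(
    deviations: Mapping[str, float], measure_name: str
) -> CodonUsageTable:
    """Reconstruct a usage table from per-codon deviation scores.

    Listed codons get freq = deviation + 1/n_syn; the remaining
    probability mass in each family is spread uniformly over unlisted
    codons, and untouched families stay uniform.
    """
    freq: dict[str, float] = {}
    from .genetics import FAMILIES

    for fam in FAMILIES.values():
        listed = [c for c in fam if c in deviations]
        unlisted = [c for c in fam if c not in deviations]
        for c in listed:
            freq[c] = deviations[c] + 1.0 / len(fam)
        remaining = 1.0 - sum(freq[c] for c in listed)
        if unlisted:
            for c in unlisted:
                freq[c] = remaining / len(unlisted)
        elif abs(remaining) > 1e-9:
            raise ValueError(
                f"{measure_name}: family {fam} deviations inconsistent "
                f"(residual mass {remaining:.3g})"
            )
    return CodonUsageTable(measure_name=measure_name, freq=freq)


def load_reference_overenriched():
    """Bundled reference rows for the ten consensus over-enriched codons:
    enriched fraction plus published deviation scores under the four
    usage measures."""
    import importlib.resources as resources

    import pandas as pd

    with resources.files("ribotempo.data").joinpath(
        "consensus_overenriched.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def deviation_table(
    codons: Sequence[str],
    fractions: Mapping[str, float],
    tables: Mapping[str, CodonUsageTable],
):
    """Long-format rows mirroring the consensus/deviation export:
    codon, aa, enriched fraction, one deviation column per measure."""
    import pandas as pd

    rows = []
    per_measure = {
        name: dict(zip(codons, (s.deviation for s in deviation_score(codons, t)[0])))
        for name, t in tables.items()
    }
    for codon in codons:
        row = {
            "codon": codon,
            "aa": CODON_TO_AA[codon],
            "frac_enriched": fractions.get(codon, float("nan")),
        }
        for name in tables:
            row[f"dev_{name}"] = per_measure[name][codon]
        rows.append(row)
    total_row = {"codon": "TOTAL", "aa": "", "frac_enriched": float("nan")}
    for name in tables:
        total_row[f"dev_{name}"] = float(sum(per_measure[name].values()))
    rows.append(total_row)
    return pd.DataFrame(rows)
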
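"""Footprint-count track construction, filtering, and normalization.

Tracks carry one (possibly fractional) count per codon position. End
trimming marks positions excluded from all downstream analysis; quality
filters and per-gene mean normalization operate on the retained span
only. Genomic per-nucleotide coverage (bedGraph) can be folded into
per-codon tracks given a CDS annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QualityThresholds:
    """End trimming plus the two strict-inequality gene filters."""

    trim: int = 20
    min_net: float = 200.0
    min_nonzero: int = 100

    def __post_init__(self) -> None:
        if self.trim < 0 or self.min_net < 0 or self.min_nonzero < 0:
            raise ValueError("thresholds must be nonnegative")


DEFAULT_THRESHOLDS = QualityThresholds()


@dataclass(frozen=True)
class RfpTrack:
    """Per-codon footprint counts for one gene.

    ``counts`` always spans the full gene; ``trim`` codons at each end
    are excluded from analysis. ``normalized`` means the retained-span
    mean is 1.
    """

    gene_id: str
    counts: np.ndarray
    trim: int = 0
    normalized: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError(f"{self.gene_id}: negative counts")

    @property
    def n_codons(self) -> int:
        return len(self.counts)

    @property
    def retained_positions(self) -> np.ndarray:
        return np.arange(self.trim, self.n_codons - self.trim)

    @property
    def retained_counts(self) -> np.ndarray:
        return np.asarray(self.counts)[self.trim : self.n_codons - self.trim]

    @property
    def density(self) -> float:
        """Average count per retained codon position."""
        return float(np.mean(self.retained_counts))


def trim_track(track: RfpTrack, trim: int = 20) -> RfpTrack | None:
    """Mark ``trim`` codons at each end as excluded.

    Returns None (and logs) when the gene has no retained positions
    left.
    """
    if track.n_codons <= 2 * trim:
        logger.info("%s: length %d <= 2*%d, excluded", track.gene_id, track.n_codons, trim)
        return None
    return replace(track, trim=trim)


def passes_filters(track: RfpTrack, thresholds: QualityThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Strictly-greater net-count and nonzero-position filters on the
    retained span."""
    retained = track.retained_counts
    return bool(
        retained.sum() > thresholds.min_net
        and np.count_nonzero(retained) > thresholds.min_nonzero
    )


def normalize_track(track: RfpTrack) -> RfpTrack:
    """Divide counts by the mean count over the retained span."""
    if track.normalized:
        return track
    mean = track.retained_counts.mean()
    if mean <= 0:
        raise ValueError(f"{track.gene_id}: zero mean count, cannot normalize")
    return replace(track, counts=np.asarray(track.counts) / mean, normalized=True)


def preprocess_tracks(
    tracks: Iterable[RfpTrack],
    thresholds: QualityThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, RfpTrack]:
    """Trim, filter, and normalize; returns surviving tracks by gene id."""
    out: dict[str, RfpTrack] = {}
    n_in = 0
    for track in tracks:
        n_in += 1
        trimmed = trim_track(track, thresholds.trim)
        if trimmed is None or not passes_filters(trimmed, thresholds):
            continue
        out[trimmed.gene_id] = normalize_track(trimmed)
    logger.info("preprocess: %d/%d genes retained", len(out), n_in)
    return out


def density_rank(tracks: Iterable[RfpTrack]) -> list[str]:
    """Gene ids sorted by descending mean retained count; ties broken
    lexicographically. Expects trimmed, unnormalized tracks."""
    return [
        t.gene_id
        for t in sorted(tracks, key=lambda t: (-t.density, t.gene_id))
    ]


def assign_multimapped(
    read_weight: float,
    target_genes: Sequence[str],
    fpkm: Mapping[str, float],
) -> dict[str, float]:
    """Apportion a multimapped read's weight FPKM-proportionally.

    Returns an empty dict (and logs) when every target has zero FPKM.
    """
    vals = np.array([fpkm.get(g, 0.0) for g in target_genes], dtype=float)
    total = vals.sum()
    if total <= 0:
        logger.warning("read dropped: all-zero FPKM among %s", list(target_genes))
        return {}
    return {g: read_weight * v / total for g, v in zip(target_genes, vals)}


# ---------------------------------------------------------------------------
# bedGraph coverage -> per-codon tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CdsPart:
    """One genomic CDS interval, 0-based half-open, stranded."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"{self.gene_id}: bad interval {self.start}-{self.end}")


def read_bed6(path: str | Path) -> list[CdsPart]:
    """Read a BED6 CDS annotation (0-based half-open, UCSC dialect)."""
    parts: list[CdsPart] = []
    with Path(path).open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{i}: expected >=6 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            parts.append(CdsPart(name, chrom, int(start), int(end), strand))
    return parts


def _read_bedgraph(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with Path(path).open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{i}: malformed bedGraph line")
            try:
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: malformed bedGraph line") from exc
            if end <= start:
                raise ValueError(f"{path}:{i}: empty/negative interval")
            by_chrom.setdefault(chrom, []).append((start, end, value))
    return by_chrom


def bedgraph_to_tracks(
    bedgraph_path: str | Path,
    annotation: Iterable[CdsPart],
    source: str = "",
) -> dict[str, RfpTrack]:
    """Fold per-nucleotide coverage into per-codon count tracks.

    Coverage values are taken per nucleotide and summed in triplets
    along the coding frame; minus-strand genes are read 3'->5' in
    genomic coordinates. Genes with no coverage get all-zero tracks;
    genes whose CDS length is not a multiple of 3 are skipped (logged).
    """
    coverage = _read_bedgraph(bedgraph_path)
    by_gene: dict[str, list[CdsPart]] = {}
    for part in annotation:
        by_gene.setdefault(part.gene_id, []).append(part)

    tracks: dict[str, RfpTrack] = {}
    for gene_id, parts in by_gene.items():
        strands = {p.strand for p in parts}
        chroms = {p.chrom for p in parts}
        if len(strands) > 1 or len(chroms) > 1:
            logger.warning("%s: inconsistent strand/chrom, skipped", gene_id)
            continue
        parts = sorted(parts, key=lambda p: p.start)
        length = sum(p.end - p.start for p in parts)
        if length % 3 != 0:
            logger.warning("%s: CDS length %d not multiple of 3, skipped", gene_id, length)
            continue
        per_nt = np.zeros(length)
        offset = 0
        chrom_cov = coverage.get(parts[0].chrom, [])
        for part in parts:
            for start, end, value in chrom_cov:
                lo = max(start, part.start)
                hi = min(end, part.end)
                if lo < hi:
                    per_nt[offset + lo - part.start : offset + hi - part.start] += value
            offset += part.end - part.start
        if parts[0].strand == "-":
            per_nt = per_nt[::-1]
        codon_counts = per_nt.reshape(-1, 3).sum(axis=1)
        tracks[gene_id] = RfpTrack(gene_id=gene_id, counts=codon_counts, source=source)
    return tracks


# ---------------------------------------------------------------------------
# Track TSV IO: `gene_id<TAB>pos<TAB>count`
# ---------------------------------------------------------------------------

def write_tracks_tsv(tracks: Iterable[RfpTrack], path: str | Path) -> None:
    rows = []
    for t in tracks:
        for pos, count in enumerate(np.asarray(t.counts)):
            rows.append((t.gene_id, pos, count))
    pd.DataFrame(rows, columns=["gene_id", "pos", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_tracks_tsv(path: str | Path, source: str = "") -> dict[str, RfpTrack]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    expected = {"gene_id", "pos", "count"}
    if not expected <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    tracks: dict[str, RfpTrack] = {}
    for gene_id, group in df.groupby("gene_id", sort=True):
        n = int(group["pos"].max()) + 1
        counts = np.zeros(n)
        counts[group["pos"].to_numpy()] = group["count"].to_numpy()
        tracks[str(gene_id)] = RfpTrack(gene_id=str(gene_id), counts=counts, source=source)
    return tracks
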
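"""Coding-sequence input, gene matching, and codon-usage measures.

This module owns the four per-codon usage measures used by the tempo
models: genome-wide family frequencies, high-expression ("High-Phi")
frequencies derived from ROC-SEMPPR mutation/selection parameters,
CAI-style relative adaptiveness weights, and externally supplied
tAI-style weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .genetics import (
    CODON_TO_AA,
    FAMILIES,
    FAMILY_OF,
    SENSE_CODONS,
    VALID_BASES,
    family_size,
    is_stop,
)

logger = logging.getLogger(__name__)

#: Expression level used for the high-expression codon usage prediction.
DEFAULT_PHI = 5.623

#: Default floor applied to zero adaptiveness weights so windowed
#: geometric means stay finite.
DEFAULT_WEIGHT_FLOOR = 0.01


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding sequence split into codons."""

    gene_id: str
    codons: tuple[str, ...]

    @property
    def length_nt(self) -> int:
        return 3 * len(self.codons)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """Codons with a terminal stop (if present) stripped."""
        if self.codons and is_stop(self.codons[-1]):
            return self.codons[:-1]
        return self.codons


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene footprint count vector, one value per codon position."""

    gene_id: str
    counts: np.ndarray

    @property
    def length_nt(self) -> int:
        return 3 * len(self.counts)


@dataclass
class CodonUsageTable:
    """Relative frequency of each sense codon within its synonymous family."""

    measure_name: str
    freq: dict[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in SENSE_CODONS if c not in self.freq]
        if missing:
            raise ValueError(
                f"{self.measure_name}: missing frequencies for {missing[:5]}..."
            )
        for aa, fam in FAMILIES.items():
            total = sum(self.freq[c] for c in fam)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"{self.measure_name}: family {aa} sums to {total!r}, not 1"
                )

    def family_stats(self, codon: str) -> tuple[float, float, float, float]:
        """(freq, family max, family min, family mean) for ``codon``."""
        fam = FAMILY_OF[codon]
        vals = [self.freq[c] for c in fam]
        return self.freq[codon], max(vals), min(vals), sum(vals) / len(vals)


@dataclass(frozen=True)
class RocSemprParams:
    """ROC-SEMPPR mutation (ΔM) and selection (Δη) parameters plus φ."""

    delta_M: Mapping[str, float]
    delta_eta: Mapping[str, float]
    phi: float = DEFAULT_PHI

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        for c in SENSE_CODONS:
            if c not in self.delta_M or c not in self.delta_eta:
                raise ValueError(f"missing ROC-SEMPPR parameters for codon {c}")


@dataclass(frozen=True)
class AdaptivenessWeights:
    """Per-codon multiplicative weights in (0, 1] for geometric-mean scores."""

    weight_name: str
    w: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [c for c, v in self.w.items() if not 0 < v <= 1]
        if bad:
            raise ValueError(f"{self.weight_name}: weights outside (0,1]: {bad[:5]}")
        missing = [c for c in SENSE_CODONS if c not in self.w]
        if missing:
            raise ValueError(f"{self.weight_name}: missing weights for {missing[:5]}")


@dataclass
class MatchResult:
    """Outcome of pairing count records with coding sequences."""

    matched: dict[str, tuple[GeneRecord, CodingSequence]]
    no_name: list[str] = field(default_factory=list)
    length_mismatch: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def _validate_cds(gene_id: str, seq: str) -> CodingSequence | str:
    """Return a CodingSequence or a rejection reason string."""
    seq = seq.upper()
    if len(seq) % 3 != 0:
        return "length not multiple of 3"
    if not set(seq) <= VALID_BASES:
        return "non-ACGT characters"
    codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
    if not codons:
        return "empty sequence"
    for codon in codons[:-1]:
        if is_stop(codon):
            return "internal stop codon"
    return CodingSequence(gene_id=gene_id, codons=codons)


def read_orfeome(path: str | Path) -> list[CodingSequence]:
    """Read and validate an in-frame CDS FASTA.

    Records violating the CDS invariants (length, alphabet, internal
    stops) are skipped with a logged reason. Raises if the file cannot
    be read or yields zero valid records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            logger.warning("%s: duplicate record id, skipped", rec.id)
            continue
        seen.add(rec.id)
        result = _validate_cds(rec.id, str(rec.seq))
        if isinstance(result, str):
            logger.warning("%s: skipped (%s)", rec.id, result)
            continue
        out.append(result)
    if not out:
        raise ValueError(f"{path}: no valid coding sequences")
    return out


def match_gene_records(
    records: Iterable[GeneRecord], orfeome: Iterable[CodingSequence]
) -> MatchResult:
    """Pair count records with coding sequences by name AND length.

    A pair is retained only when the gene id exists in the ORFeome and
    the nucleotide lengths agree exactly; everything else is dropped
    and tallied by reason.
    """
    by_id = {cds.gene_id: cds for cds in orfeome}
    result = MatchResult(matched={})
    for rec in records:
        cds = by_id.get(rec.gene_id)
        if cds is None:
            result.no_name.append(rec.gene_id)
        elif cds.length_nt != rec.length_nt:
            result.length_mismatch.append(rec.gene_id)
        else:
            result.matched[rec.gene_id] = (rec, cds)
    logger.info(
        "matched %d records; dropped %d (no name match), %d (length mismatch)",
        len(result.matched),
        len(result.no_name),
        len(result.length_mismatch),
    )
    return result


def codon_family_frequencies(
    orfeome: Iterable[CodingSequence], measure_name: str = "orfeome"
) -> CodonUsageTable:
    """Within-family relative codon frequencies over an ORFeome.

    Terminal stop codons are excluded from the tally. A family with no
    occurrences at all receives uniform frequencies (logged).
    """
    counts = {c: 0 for c in SENSE_CODONS}
    n_seq = 0
    for cds in orfeome:
        n_seq += 1
        for codon in cds.sense_codons:
            counts[codon] += 1
    if n_seq == 0:
        raise ValueError("empty ORFeome")
    freq: dict[str, float] = {}
    for aa, fam in FAMILIES.items():
        total = sum(counts[c] for c in fam)
        if total == 0:
            logger.warning("family %s absent from ORFeome; using uniform", aa)
            for c in fam:
                freq[c] = 1.0 / len(fam)
        else:
            for c in fam:
                freq[c] = counts[c] / total
    return CodonUsageTable(measure_name=measure_name, freq=freq)


def high_phi_frequencies(
    params: RocSemprParams, measure_name: str = "high_phi"
) -> CodonUsageTable:
    """Within-family codon frequencies at expression level φ.

    freq(c) ∝ exp(−ΔM_c − Δη_c · φ), normalized within each synonymous
    family. The family maximum exponent is subtracted before
    exponentiating to guard against overflow.
    """
    freq: dict[str, float] = {}
    for fam in FAMILIES.values():
        expo = {
            c: -params.delta_M[c] - params.delta_eta[c] * params.phi for c in fam
        }
        peak = max(expo.values())
        raw = {c: math.exp(expo[c] - peak) for c in fam}
        total = sum(raw.values())
        for c in fam:
            freq[c] = raw[c] / total
    return CodonUsageTable(measure_name=measure_name, freq=freq)


def relative_adaptiveness(
    table: CodonUsageTable,
    floor: float = DEFAULT_WEIGHT_FLOOR,
    weight_name: str | None = None,
) -> AdaptivenessWeights:
    """CAI-style weights: each codon's frequency over its family maximum.

    Values below ``floor`` are replaced by ``floor`` so windowed
    geometric means stay finite; single-codon families get w = 1.
    """
    if not 0 < floor <= 0.1:
        raise ValueError("floor must be in (0, 0.1]")
    w: dict[str, float] = {}
    for fam in FAMILIES.values():
        peak = max(table.freq[c] for c in fam)
        for c in fam:
            if len(fam) == 1:
                w[c] = 1.0
            else:
                w[c] = max(table.freq[c] / peak, floor)
    name = weight_name or f"{table.measure_name}_cai"
    return AdaptivenessWeights(weight_name=name, w=w)


def uniform_expectation(codon: str) -> float:
    """Expected within-family frequency if synonymous codons were used
    uniformly at random: 1 / family size."""
    if is_stop(codon):
        raise ValueError(f"{codon} is a stop codon")
    return 1.0 / family_size(codon)


# ---------------------------------------------------------------------------
# TSV plumbing: `codon<TAB>value` parameter tables
# ---------------------------------------------------------------------------

def write_codon_values(values: Mapping[str, float], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("codon\tvalue\n")
        for codon in SENSE_CODONS:
            if codon in values:
                fh.write(f"{codon}\t{values[codon]:.10g}\n")


def read_codon_values(path: str | Path) -> dict[str, float]:
    values: dict[str, float] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.lower().startswith("codon"):
            raise ValueError(f"{path}: expected 'codon<TAB>value' header")
        for i, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            codon, value = line.split("\t")
            codon = codon.upper()
            if codon not in CODON_TO_AA:
                raise ValueError(f"{path}:{i}: not a sense codon: {codon}")
            values[codon] = float(value)
    return values


def read_usage_table(path: str | Path, measure_name: str) -> CodonUsageTable:
    return CodonUsageTable(measure_name=measure_name, freq=read_codon_values(path))


def read_weights(path: str | Path, weight_name: str) -> AdaptivenessWeights:
    return AdaptivenessWeights(weight_name=weight_name, w=read_codon_values(path))


def read_rocsemppr(path: str | Path, phi: float = DEFAULT_PHI) -> RocSemprParams:
    """Read a `codon<TAB>delta_m<TAB>delta_eta` TSV."""
    dm: dict[str, float] = {}
    de: dict[str, float] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.lower() for h in header] != ["codon", "delta_m", "delta_eta"]:
            raise ValueError(f"{path}: expected codon/delta_m/delta_eta header")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            codon, m, eta = line.split("\t")
            dm[codon.upper()] = float(m)
            de[codon.upper()] = float(eta)
    return RocSemprParams(delta_M=dm, delta_eta=de, phi=phi)
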
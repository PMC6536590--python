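"""Domain containers for genomes, annotations, coverage and intervals.

All coordinates are 0-based half-open on the forward strand. File-format
conventions (GFF3 1-based inclusive, BED/bedGraph 0-based half-open) are
converted at the I/O boundary (:mod:`chapmap.io`) so that no other module
ever needs to reason about the convention of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Contig",
    "GeneFeature",
    "RegionInterval",
    "GenomeAnnotation",
    "CoverageTrack",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass
class Contig:
    """A chromosome or plasmid: identifier, sequence and topology."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid characters {sorted(bad)!r} in sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene locus, keyed by locus tag (e.g. ``cg3315``).

    ``start``/``end`` are 0-based half-open regardless of strand; the
    transcription start in reading orientation is ``start`` for ``+`` genes
    and ``end - 1`` for ``-`` genes.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval ({self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def oriented_start(self) -> int:
        """Coordinate of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class RegionInterval:
    """A named genomic interval, e.g. a prophage element."""

    contig_id: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"region {self.name!r}: start must be < end")


@dataclass
class GenomeAnnotation:
    """Contigs plus gene features plus named regions of interest."""

    contigs: list[Contig] = field(default_factory=list)
    genes: list[GeneFeature] = field(default_factory=list)
    regions: dict[str, RegionInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_id = {c.id: c for c in self.contigs}
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in annotation")
            seen.add(g.gene_id)
            contig = by_id.get(g.contig_id)
            if contig is None:
                raise ValueError(
                    f"gene {g.gene_id} references unknown contig {g.contig_id!r}"
                )
            if g.end > contig.length:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of contig {g.contig_id}"
                )
        for region in self.regions.values():
            contig = by_id.get(region.contig_id)
            if contig is None:
                raise ValueError(
                    f"region {region.name!r} references unknown contig"
                )
            if region.end > contig.length:
                raise ValueError(f"region {region.name!r} exceeds contig bounds")

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    def gene(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes}


@dataclass
class CoverageTrack:
    """Dense per-base sequencing coverage over one contig."""

    contig_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be a 1-D array")
        if np.any(self.values < 0):
            raise ValueError(f"coverage track {self.contig_id}: negative values")

    @property
    def length(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if self.length else 0.0
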
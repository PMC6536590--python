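"""Assignment of binding peaks to candidate target promoters.

A peak is assigned to a gene when its summit falls inside a promoter
window around the gene's transcription start, measured in the gene's
reading orientation (default: 500 bp upstream to 100 bp downstream).
Summits shared by two divergently transcribed gene starts produce two
assignments, both flagged, since either promoter (or both) may be the
functional target — a common situation for regulators whose own gene
lies divergent to a target operon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .model import GenomeAnnotation, RegionInterval
from .peaks import Peak, PeakSet

__all__ = [
    "PromoterRule",
    "PeakAssignment",
    "assign_peaks_to_genes",
    "tally_region",
    "autoregulation_check",
    "read_operon_map",
    "assignments_table",
]


@dataclass(frozen=True)
class PromoterRule:
    """Promoter window, in bp relative to the oriented gene start."""

    upstream_bp: int = 500
    downstream_bp: int = 100

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be non-negative")
        if self.upstream_bp + self.downstream_bp == 0:
            raise ValueError("promoter window must be non-empty")


@dataclass
class PeakAssignment:
    """One peak-to-gene call; ``offset_bp`` < 0 means upstream of the start."""

    peak: Peak
    gene_id: str
    offset_bp: int = 0
    relation: str = ""  # upstream | overlapping_start | divergent_shared | ""


def _oriented_offset(summit: int, start: int, end: int, strand: str) -> int:
    """Signed distance from the oriented gene start to the summit."""
    return summit - start if strand == "+" else (end - 1) - summit


def assign_peaks_to_genes(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    rule: PromoterRule = PromoterRule(),
    operon_map: Mapping[str, str] | None = None,
) -> list[PeakAssignment]:
    """Assign each peak summit to promoter windows of nearby genes.

    Returns one assignment per (peak, gene) pair the summit qualifies
    for; peaks matching no window are retained with an empty ``gene_id``.
    When two hit genes are divergently oriented, both assignments are
    flagged ``divergent_shared``. With an operon map, assignments to
    non-leader operon members are re-pointed to the operon leader.
    """
    out: list[PeakAssignment] = []
    for p in peaks:
        hits: list[PeakAssignment] = []
        for g in annotation.genes:
            if g.contig_id != p.contig_id:
                continue
            off = _oriented_offset(p.summit, g.start, g.end, g.strand)
            if -rule.upstream_bp <= off < rule.downstream_bp:
                relation = "upstream" if off < 0 else "overlapping_start"
                hits.append(PeakAssignment(peak=p, gene_id=g.gene_id,
                                           offset_bp=off, relation=relation))
        strands = {annotation.gene(h.gene_id).strand for h in hits}
        if len(hits) >= 2 and strands == {"+", "-"}:
            for h in hits:
                h.relation = "divergent_shared"
        if not hits:
            hits = [PeakAssignment(peak=p, gene_id="")]
        out.extend(hits)
    if operon_map:
        for h in out:
            if h.gene_id and h.gene_id in operon_map:
                h.gene_id = operon_map[h.gene_id]
    return out


def tally_region(peaks: PeakSet, region: RegionInterval) -> int:
    """Number of peaks whose summit lies in [region.start, region.end)."""
    return sum(
        1
        for p in peaks
        if p.contig_id == region.contig_id and region.start <= p.summit < region.end
    )


def autoregulation_check(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    regulator_gene_id: str,
    rule: PromoterRule = PromoterRule(),
    operon_map: Mapping[str, str] | None = None,
) -> tuple[bool, PeakAssignment | None]:
    """Does any peak sit in the regulator's own promoter?

    With an operon map the check targets the regulator's operon leader,
    since an autoregulatory site upstream of the leader controls the
    whole operon.
    """
    if regulator_gene_id not in annotation.gene_ids:
        raise KeyError(f"regulator gene {regulator_gene_id!r} not in annotation")
    target = regulator_gene_id
    if operon_map and regulator_gene_id in operon_map:
        target = operon_map[regulator_gene_id]
    for a in assign_peaks_to_genes(peaks, annotation, rule, operon_map):
        if a.gene_id == target:
            return True, a
    return False, None


def read_operon_map(path) -> dict[str, str]:
    """Two-column tabular text: gene_id <tab> operon_leader_gene_id."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, leader = line.split()[:2]
            mapping[gene] = leader
    return mapping


def assignments_table(
    assignments: Iterable[PeakAssignment], peaks: PeakSet
) -> pd.DataFrame:
    """Tabular regulon table (peak name, gene, offset, relation, fold)."""
    names = {id(p): f"peak_{i}" for i, p in enumerate(peaks, 1)}
    rows = [
        {
            "peak": names.get(id(a.peak), "peak_?"),
            "contig": a.peak.contig_id,
            "summit": a.peak.summit,
            "gene_id": a.gene_id,
            "offset_bp": a.offset_bp if a.gene_id else "",
            "relation": a.relation,
            "fold_over_mean": round(a.peak.fold_over_mean, 4),
        }
        for a in assignments
    ]
    return pd.DataFrame(
        rows,
        columns=["peak", "contig", "summit", "gene_id", "offset_bp",
                 "relation", "fold_over_mean"],
    )
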
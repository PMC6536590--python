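"""Readers and writers for the standard flat-file formats.

GFF3 is 1-based inclusive and is converted to the package's internal
0-based half-open convention on read (and back on write); BED and bedGraph
are already 0-based half-open and pass through unchanged.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence, TYPE_CHECKING

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import Contig, CoverageTrack, GeneFeature, RegionInterval

if TYPE_CHECKING:  # pragma: no cover
    from .peaks import PeakSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed_regions",
    "write_peaks_bed",
    "read_peaks_bed",
    "extract_sequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike, circular: bool = False) -> list[Contig]:
    """Read a FASTA file into :class:`Contig` objects (sequences uppercased).

    ``circular`` applies to every record; chromosome topology is not part
    of the FASTA format, so it is declared by the caller (config).
    """
    contigs = [
        Contig(id=rec.id, sequence=str(rec.seq), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gff3(path: str | os.PathLike) -> list[GeneFeature]:
    """Read gene/CDS features from GFF3, converting to 0-based half-open.

    The gene key is the ``locus_tag`` attribute when present, else ``ID``.
    When a locus has both a ``gene`` and a ``CDS`` feature the ``gene``
    feature wins; duplicate keys across distinct loci are an error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneFeature] = {}
    from_gene_feature: dict[str, bool] = {}
    for ftype in ("gene", "CDS"):
        for feat in db.features_of_type(ftype, order_by="start"):
            locus = feat.attributes.get("locus_tag", [None])[0]
            if locus is None:
                locus = feat.attributes.get("ID", [None])[0]
            if locus is None:
                raise ValueError(
                    f"{path}: feature at {feat.seqid}:{feat.start}-{feat.end} "
                    "has neither locus_tag nor ID"
                )
            # gffutils appends _1, _2 ... for duplicated IDs; strip only
            # when we took the ID attribute, never the locus_tag.
            if feat.end < feat.start:
                raise ValueError(f"{path}: feature {locus} has end < start")
            gf = GeneFeature(
                gene_id=locus,
                contig_id=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                product=feat.attributes.get("product", [""])[0],
            )
            if locus in genes:
                if ftype == "CDS" and from_gene_feature[locus]:
                    continue  # CDS nested inside an already-read gene
                raise ValueError(f"{path}: duplicate gene_id {locus!r}")
            genes[locus] = gf
            from_gene_feature[locus] = ftype == "gene"
    return list(genes.values())


def write_gff3(genes: Sequence[GeneFeature], path: str | os.PathLike) -> None:
    """Write gene features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig_id}\tchapmap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_bedgraph(
    path: str | os.PathLike, contigs: Sequence[Contig]
) -> dict[str, CoverageTrack]:
    """Densify a bedGraph into one per-base vector per contig.

    Uncovered bases are zero. Overlapping intervals, intervals beyond the
    contig end and negative values are errors; intervals for unknown
    contigs are errors too.
    """
    lengths = {c.id: c.length for c in contigs}
    dense = {cid: np.zeros(n) for cid, n in lengths.items()}
    covered = {cid: np.zeros(n, dtype=bool) for cid, n in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            cid, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if cid not in lengths:
                raise ValueError(f"{path}:{lineno}: unknown contig {cid!r}")
            if not (0 <= start < end <= lengths[cid]):
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) outside contig "
                    f"{cid} (length {lengths[cid]})"
                )
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage {value}")
            if covered[cid][start:end].any():
                raise ValueError(f"{path}:{lineno}: overlapping bedGraph intervals")
            dense[cid][start:end] = value
            covered[cid][start:end] = True
    return {cid: CoverageTrack(contig_id=cid, values=v) for cid, v in dense.items()}


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike, mode: str = "w") -> None:
    """Write a dense track as run-length-encoded bedGraph (zeros omitted)."""
    v = track.values
    with open(path, mode) as fh:
        if v.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [v.size]))
        for s, e in zip(starts, ends):
            if v[s] != 0:
                fh.write(f"{track.contig_id}\t{s}\t{e}\t{v[s]:g}\n")


def read_bed_regions(path: str | os.PathLike) -> list[RegionInterval]:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            name = fields[3] if len(fields) > 3 else f"region_{lineno}"
            regions.append(
                RegionInterval(
                    contig_id=fields[0], start=int(fields[1]), end=int(fields[2]), name=name
                )
            )
    return regions


def write_peaks_bed(
    peaks: "PeakSet",
    path: str | os.PathLike,
    summit_path: str | os.PathLike | None = None,
) -> None:
    """Write called peaks as BED6 plus a companion summit table.

    BED score is the fold-over-mean rounded to 2 decimals; the summit table
    lists peak name, summit coordinate and maximal smoothed coverage.
    """
    if summit_path is None:
        summit_path = str(path) + ".summits.tsv"
    with open(path, "w") as bed, open(summit_path, "w") as tab:
        tab.write("peak\tcontig\tsummit\tmax_smoothed\tfold_over_mean\ttruncated\n")
        for i, p in enumerate(peaks.peaks, 1):
            name = f"peak_{i}"
            bed.write(
                f"{p.contig_id}\t{p.start}\t{p.end}\t{name}\t"
                f"{p.fold_over_mean:.2f}\t.\n"
            )
            tab.write(
                f"{name}\t{p.contig_id}\t{p.summit}\t{p.max_smoothed:.4f}\t"
                f"{p.fold_over_mean:.4f}\t{int(p.truncated)}\n"
            )


def read_peaks_bed(
    path: str | os.PathLike, summit_path: str | os.PathLike | None = None
):
    """Reconstruct a PeakSet from a BED6 file and its summit table."""
    from .peaks import Peak, PeakSet

    if summit_path is None:
        summit_path = str(path) + ".summits.tsv"
    summits: dict[str, tuple[int, float, float, bool]] = {}
    with open(summit_path) as fh:
        header = fh.readline()
        for line in fh:
            name, _contig, summit, max_sm, fold, trunc = line.rstrip("\n").split("\t")
            summits[name] = (int(summit), float(max_sm), float(fold), bool(int(trunc)))
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, name, _score, _strand = line.split()[:6]
            summit, max_sm, fold, trunc = summits[name]
            peaks.append(
                Peak(
                    contig_id=contig, start=int(start), end=int(end),
                    summit=summit, max_smoothed=max_sm, fold_over_mean=fold,
                    truncated=trunc,
                )
            )
    gm = peaks[0].max_smoothed / peaks[0].fold_over_mean if peaks else 0.0
    return PeakSet(peaks=peaks, genome_mean=gm)


def extract_sequence(
    contig: Contig, start: int, end: int, circular_wrap: bool = False
) -> str:
    """Subsequence of ``contig`` over [start, end), optionally wrapping.

    On a linear contig coordinates must lie within bounds; with
    ``circular_wrap`` they are taken modulo the contig length, so windows
    spanning the origin come back joined.
    """
    if start >= end:
        raise ValueError(f"empty or inverted interval ({start}, {end})")
    n = contig.length
    if not circular_wrap:
        if start < 0 or end > n:
            raise ValueError(
                f"interval ({start}, {end}) out of bounds for linear contig "
                f"{contig.id} (length {n})"
            )
        return contig.sequence[start:end]
    if end - start > n:
        raise ValueError("window longer than the circular contig")
    s = start % n
    e = s + (end - start)
    if e <= n:
        return contig.sequence[s:e]
    return contig.sequence[s:] + contig.sequence[: e - n]
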
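"""Binding-region detection from coverage tracks.

The procedure: smooth raw per-base coverage with a rolling mean on a fixed
step grid (defaults: 50 bp window, 10 bp step), mark grid windows whose
smoothed value exceeds a fold of the genome-wide mean raw coverage
(default 3x), merge nearby supra-threshold runs into peaks, locate each
peak's summit, and extract the 100-bp sequence window centred on it
(50 bp up- and downstream of the coverage maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import extract_sequence
from .model import Contig, CoverageTrack

__all__ = [
    "SmoothingParams",
    "SmoothedTrack",
    "PeakCallParams",
    "Peak",
    "PeakSet",
    "rolling_mean",
    "genome_mean",
    "call_peaks",
    "extract_peak_windows",
]


@dataclass(frozen=True)
class SmoothingParams:
    """Rolling-mean window and step, in bp."""

    window_bp: int = 50
    step_bp: int = 10

    def __post_init__(self) -> None:
        if not (self.window_bp >= self.step_bp >= 1):
            raise ValueError("require window_bp >= step_bp >= 1")


@dataclass
class SmoothedTrack:
    """Rolling-mean coverage sampled at fixed window centres."""

    contig_id: str
    positions: np.ndarray  # window-centre coordinates, strictly increasing
    values: np.ndarray
    params: SmoothingParams
    contig_length: int
    circular: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != self.values.size:
            raise ValueError("positions and values must have equal length")
        if self.positions.size > 1:
            d = np.diff(self.positions)
            if not np.all(d == self.params.step_bp):
                raise ValueError("window centres must be spaced step_bp apart")


@dataclass(frozen=True)
class PeakCallParams:
    """Thresholding and segmentation parameters.

    ``fold_threshold``: smoothed coverage must exceed this multiple of the
    genome-wide mean. ``merge_gap_bp``: supra-threshold runs whose window
    centres are at most this far apart are merged. ``min_windows``: runs
    with fewer supra-threshold windows are discarded as noise.
    """

    fold_threshold: float = 3.0
    merge_gap_bp: int = 50
    min_windows: int = 2

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.merge_gap_bp < 0 or self.min_windows < 1:
            raise ValueError("merge_gap_bp >= 0 and min_windows >= 1 required")


@dataclass
class Peak:
    """One contiguous supra-threshold binding region."""

    contig_id: str
    start: int
    end: int
    summit: int
    max_smoothed: float
    fold_over_mean: float
    window_seq: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie within the peak span")


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)
    genome_mean: float = 0.0

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def rolling_mean(
    track: CoverageTrack,
    params: SmoothingParams = SmoothingParams(),
    circular: bool = False,
) -> SmoothedTrack:
    """Rolling-mean smoothing on a fixed step grid.

    Window k starts at ``k * step_bp`` and covers ``window_bp`` bases; its
    centre coordinate is ``start + window_bp // 2``. The final windows are
    truncated at the contig end on a linear contig, or wrap on a circular
    one.
    """
    v = track.values
    n = v.size
    w, s = params.window_bp, params.step_bp
    half = w // 2
    if n < w:
        raise ValueError(f"contig {track.contig_id} shorter than the smoothing window")
    csum = np.concatenate(([0.0], np.cumsum(v)))
    if circular:
        # full-length windows that wrap past the origin
        starts = np.arange(0, n, s)
        ends = starts + w
        wrap = ends > n
        sums = np.where(
            wrap,
            (csum[n] - csum[starts]) + csum[np.minimum(np.maximum(ends - n, 0), n)],
            csum[np.minimum(ends, n)] - csum[starts],
        )
        means = sums / w
    else:
        # trailing windows truncate at the contig end; windows whose centre
        # would fall past the end are dropped
        starts = np.arange(0, n - half, s)
        ends = np.minimum(starts + w, n)
        means = (csum[ends] - csum[starts]) / (ends - starts)
    centres = starts + half
    return SmoothedTrack(
        contig_id=track.contig_id,
        positions=centres,
        values=means,
        params=params,
        contig_length=n,
        circular=circular,
    )


def genome_mean(tracks: Sequence[CoverageTrack]) -> float:
    """Length-weighted mean raw coverage over all contigs."""
    if not tracks:
        raise ValueError("at least one coverage track required")
    total = sum(float(t.values.sum()) for t in tracks)
    bases = sum(t.length for t in tracks)
    return total / bases


def call_peaks(
    smoothed: SmoothedTrack,
    genome_mean: float,
    params: PeakCallParams = PeakCallParams(),
) -> PeakSet:
    """Segment supra-threshold windows into peaks.

    Steps: (1) mark windows with smoothed value strictly above
    ``fold_threshold * genome_mean``; (2) group runs of consecutive marked
    windows, merging runs whose flanking marked centres are at most
    ``merge_gap_bp`` apart; (3) drop groups with fewer than ``min_windows``
    marked windows; (4) peak span runs from the first marked window's start
    to the last marked window's end; (5) the summit is the marked centre
    with the maximal smoothed value (ties to the smaller coordinate).
    """
    if genome_mean <= 0:
        raise ValueError("genome mean coverage must be positive (all-zero genome?)")
    thr = params.fold_threshold * genome_mean
    w = smoothed.params.window_bp
    half = w // 2
    marked = np.flatnonzero(smoothed.values > thr)
    peaks: list[Peak] = []
    if marked.size:
        pos = smoothed.positions[marked]
        # split where the bp gap between successive marked centres exceeds
        # both one grid step (run break) and merge_gap_bp (no re-merge)
        gaps = np.diff(pos)
        brk = np.flatnonzero(
            (gaps > smoothed.params.step_bp) & (gaps > params.merge_gap_bp)
        )
        groups = np.split(np.arange(marked.size), brk + 1)
        for grp in groups:
            if grp.size < params.min_windows:
                continue
            idx = marked[grp]
            first_c, last_c = smoothed.positions[idx[0]], smoothed.positions[idx[-1]]
            start = first_c - half
            end = last_c - half + w
            if not smoothed.circular:
                end = min(end, smoothed.contig_length)
            best = idx[np.argmax(smoothed.values[idx])]  # argmax ties -> smallest
            peaks.append(
                Peak(
                    contig_id=smoothed.contig_id,
                    start=int(start),
                    end=int(end),
                    summit=int(smoothed.positions[best]),
                    max_smoothed=float(smoothed.values[best]),
                    fold_over_mean=float(smoothed.values[best] / genome_mean),
                )
            )
    return PeakSet(peaks=peaks, genome_mean=genome_mean)


def extract_peak_windows(
    peaks: PeakSet, contigs: Sequence[Contig], flank_bp: int = 50
) -> PeakSet:
    """Fill each peak's summit-centred sequence window (in place).

    The window is [summit - flank_bp, summit + flank_bp), i.e. 100 bp at
    the default flank. On a linear contig windows are clipped at the
    bounds and the peak is flagged ``truncated``; circular contigs wrap.
    """
    by_id = {c.id: c for c in contigs}
    for p in peaks:
        contig = by_id[p.contig_id]
        lo, hi = p.summit - flank_bp, p.summit + flank_bp
        if contig.circular:
            p.window_seq = extract_sequence(contig, lo, hi, circular_wrap=True)
        else:
            clo, chi = max(lo, 0), min(hi, contig.length)
            p.truncated = (clo, chi) != (lo, hi)
            p.window_seq = extract_sequence(contig, clo, chi)
    return peaks
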
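import numpy as np
import pytest

from chapmap.model import Contig, CoverageTrack
from chapmap.peaks import (
    PeakCallParams,
    SmoothingParams,
    call_peaks,
    extract_peak_windows,
    genome_mean,
    rolling_mean,
)

# --- independent loop-based oracles ---------------------------------------

def oracle_rolling_mean(values, window, step):
    """Per-window means by explicit looping (linear contig)."""
    n = len(values)
    half = window // 2
    positions, means = [], []
    start = 0
    while start + half < n:
        end = min(start + window, n)
        chunk = values[start:end]
        positions.append(start + half)
        means.append(sum(chunk) / len(chunk))
        start += step
    return np.array(positions), np.array(means)


def oracle_segment(positions, values, threshold, step, merge_gap, min_windows,
                   window, contig_length):
    """Threshold-scan segmentation by explicit looping."""
    half = window // 2
    marked = [i for i, v in enumerate(values) if v > threshold]
    groups = []
    for i in marked:
        if groups and positions[i] - positions[groups[-1][-1]] <= max(step, merge_gap):
            groups[-1].append(i)
        else:
            groups.append([i])
    peaks = []
    for grp in groups:
        if len(grp) < min_windows:
            continue
        start = positions[grp[0]] - half
        end = min(positions[grp[-1]] - half + window, contig_length)
        best = max(grp, key=lambda i: (values[i], -positions[i]))
        peaks.append((start, end, positions[best], values[best]))
    return peaks


# --- rolling_mean ----------------------------------------------------------

def test_rolling_mean_constant_track():
    track = CoverageTrack("chr", np.full(500, 20.0))
    sm = rolling_mean(track)
    assert np.all(sm.values == 20.0)


def test_rolling_mean_single_spike():
    v = np.zeros(500)
    v[250] = 50.0
    sm = rolling_mean(track := CoverageTrack("chr", v), SmoothingParams(50, 10))
    containing = (sm.positions - 25 <= 250) & (250 < sm.positions - 25 + 50)
    assert np.all(sm.values[containing] == 1.0)
    assert np.all(sm.values[~containing] == 0.0)


def test_rolling_mean_matches_loop_oracle_exactly():
    rng = np.random.default_rng(1)
    v = rng.poisson(20, size=10_000).astype(float)
    sm = rolling_mean(CoverageTrack("chr", v), SmoothingParams(50, 10))
    pos, means = oracle_rolling_mean(v, 50, 10)
    assert np.array_equal(sm.positions, pos)
    assert np.array_equal(sm.values, means)


def test_rolling_mean_short_contig_errors():
    with pytest.raises(ValueError):
        rolling_mean(CoverageTrack("chr", np.ones(10)), SmoothingParams(50, 10))


def test_rolling_mean_circular_wraps():
    v = np.zeros(1000)
    v[:5] = 100.0  # mass at the origin is seen by windows spanning the wrap
    sm = rolling_mean(CoverageTrack("chr", v), SmoothingParams(50, 10),
                      circular=True)
    assert sm.positions.size == 100
    last = sm.values[-1]  # window [990, 1040) wraps onto [0, 40)
    assert last == pytest.approx(500 / 50)


# --- genome_mean -----------------------------------------------------------

def test_genome_mean_single_track():
    assert genome_mean([CoverageTrack("c", np.array([1.0, 2.0, 3.0]))]) == 2.0


def test_genome_mean_is_length_weighted():
    t1 = CoverageTrack("a", np.full(10, 4.0))
    t2 = CoverageTrack("b", np.full(30, 8.0))
    assert genome_mean([t1, t2]) == 7.0


def test_zero_genome_mean_blocks_peak_calling():
    track = CoverageTrack("chr", np.zeros(1000))
    sm = rolling_mean(track)
    assert genome_mean([track]) == 0.0
    with pytest.raises(ValueError):
        call_peaks(sm, 0.0)


# --- call_peaks ------------------------------------------------------------

def test_constant_track_has_no_peaks():
    track = CoverageTrack("chr", np.full(2000, 20.0))
    ps = call_peaks(rolling_mean(track), 20.0)
    assert len(ps) == 0


def test_rectangular_region_matches_segmentation_oracle():
    v = np.full(50_000, 20.0)
    v[10_000:10_200] = 200.0
    sm = rolling_mean(CoverageTrack("chr", v))
    gm = genome_mean([CoverageTrack("chr", v)])
    params = PeakCallParams()
    ps = call_peaks(sm, gm, params)
    expected = oracle_segment(
        sm.positions, sm.values, params.fold_threshold * gm,
        sm.params.step_bp, params.merge_gap_bp, params.min_windows,
        sm.params.window_bp, 50_000,
    )
    assert len(ps) == len(expected) == 1
    p, (start, end, summit, maxv) = ps.peaks[0], expected[0]
    assert (p.start, p.end, p.summit, p.max_smoothed) == (start, end, summit, maxv)


def test_fold_threshold_monotonicity():
    rng = np.random.default_rng(3)
    v = rng.poisson(20, size=30_000).astype(float)
    for c in rng.integers(1000, 29_000, size=6):
        v[c : c + 150] += rng.integers(100, 400)
    track = CoverageTrack("chr", v)
    gm = genome_mean([track])
    sm = rolling_mean(track)
    at3 = call_peaks(sm, gm, PeakCallParams(fold_threshold=3))
    at5 = call_peaks(sm, gm, PeakCallParams(fold_threshold=5))
    assert len(at5) <= len(at3)
    span = lambda ps: sum(p.end - p.start for p in ps)
    assert span(at5) <= span(at3)


def test_every_peak_exceeds_fold_threshold():
    rng = np.random.default_rng(4)
    v = rng.poisson(20, size=20_000).astype(float)
    v[5000:5100] += 300
    track = CoverageTrack("chr", v)
    gm = genome_mean([track])
    ps = call_peaks(rolling_mean(track), gm)
    assert len(ps) >= 1
    assert all(p.fold_over_mean > 3.0 for p in ps)


def test_random_tracks_match_oracles_exactly():
    """Smoothing and segmentation equal loop-based oracles on random tracks."""
    rng = np.random.default_rng(5)
    params = PeakCallParams()
    sp = SmoothingParams()
    for _ in range(20):
        n = int(rng.integers(1000, 20_000))
        v = rng.poisson(20, size=n).astype(float)
        for c in rng.integers(0, n - 200, size=3):
            v[c : c + int(rng.integers(20, 200))] += int(rng.integers(50, 300))
        track = CoverageTrack("chr", v)
        sm = rolling_mean(track, sp)
        pos, means = oracle_rolling_mean(v, sp.window_bp, sp.step_bp)
        assert np.array_equal(sm.positions, pos)
        assert np.array_equal(sm.values, means)
        gm = genome_mean([track])
        ps = call_peaks(sm, gm, params)
        expected = oracle_segment(
            sm.positions, sm.values, params.fold_threshold * gm, sp.step_bp,
            params.merge_gap_bp, params.min_windows, sp.window_bp, n,
        )
        got = [(p.start, p.end, p.summit, p.max_smoothed) for p in ps]
        assert got == expected


# --- window extraction -----------------------------------------------------

def _contig(n=2000, circular=False):
    rng = np.random.default_rng(7)
    return Contig(id="chr", sequence="".join(rng.choice(list("ACGT"), size=n)),
                  circular=circular)


def _peakset(summit, contig_len=2000):
    from chapmap.peaks import Peak, PeakSet

    return PeakSet(
        peaks=[Peak("chr", max(summit - 100, 0), min(summit + 100, contig_len),
                    summit, 100.0, 5.0)],
        genome_mean=20.0,
    )


def test_window_is_100bp_centred_on_summit():
    contig = _contig()
    ps = extract_peak_windows(_peakset(1000), [contig])
    p = ps.peaks[0]
    assert len(p.window_seq) == 100
    assert p.window_seq == contig.sequence[950:1050]
    assert p.window_seq[50] == contig.sequence[1000]
    assert not p.truncated


def test_window_truncated_near_linear_end():
    contig = _contig()
    ps = extract_peak_windows(_peakset(30), [contig])
    p = ps.peaks[0]
    assert p.truncated
    assert p.window_seq == contig.sequence[0:80]


def test_window_wraps_on_circular_contig():
    contig = _contig(n=1000, circular=True)
    ps = extract_peak_windows(_peakset(10, contig_len=1000), [contig])
    p = ps.peaks[0]
    assert len(p.window_seq) == 100
    assert p.window_seq == contig.sequence[960:] + contig.sequence[:60]
    assert not p.truncated
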
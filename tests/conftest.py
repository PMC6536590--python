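import numpy as np
import pytest

from chapmap import (
    PeakSet,
    call_peaks,
    extract_peak_windows,
    genome_mean,
    rolling_mean,
)
from chapmap.simulate import (
    plant_sites,
    simulate_coverage,
    simulate_expression,
    simulate_genome,
)


@pytest.fixture(scope="session")
def mini_dataset():
    """A small simulated dataset (60 kb, 40 genes, 8 planted sites)."""
    contig, annotation = simulate_genome(
        length_bp=60_000, n_genes=40, seed=100
    )
    contig, truth = plant_sites(contig, annotation, n_sites=8, seed=101)
    annotation.contigs = [contig]
    track = simulate_coverage(contig, truth, seed=102)
    return contig, annotation, truth, track


@pytest.fixture(scope="session")
def default_dataset():
    """A default-scale dataset (500 kb, 300 genes, 30 sites) with peaks called."""
    contig, annotation = simulate_genome(seed=11)
    contig, truth = plant_sites(contig, annotation, seed=12)
    annotation.contigs = [contig]
    track = simulate_coverage(contig, truth, seed=13)
    expression = simulate_expression(annotation, truth, seed=14)
    gm = genome_mean([track])
    peaks = call_peaks(rolling_mean(track), gm)
    extract_peak_windows(peaks, [contig])
    return {
        "contig": contig,
        "annotation": annotation,
        "truth": truth,
        "track": track,
        "expression": expression,
        "genome_mean": gm,
        "peaks": peaks,
    }


def match_sites(peaks: PeakSet, centers, tol_bp: int = 200):
    """Greedy summit-to-planted-centre matching; returns (recall, precision, errors)."""
    centers = np.asarray(centers)
    errors = []
    matched = 0
    for c in centers:
        if len(peaks):
            d = min(abs(p.summit - c) for p in peaks)
            if d <= tol_bp:
                matched += 1
                errors.append(d)
    recall = matched / len(centers) if len(centers) else float("nan")
    if len(peaks):
        precision = sum(
            1 for p in peaks if np.min(np.abs(centers - p.summit)) <= tol_bp
        ) / len(peaks)
    else:
        precision = float("nan")
    return recall, precision, np.array(errors)
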
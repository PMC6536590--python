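"""Synthetic genomes, binding sites, coverage, expression and flow data.

Every generator is a pure function of its parameters and a seed, and
records the planted ground truth so that each pipeline stage can be
scored against what was actually put in: site coordinates for the peak
caller, the planting consensus for the motif finder, per-gene expression
effects for target classification, and the true induced fraction for the
flow-cytometry gate.

The coverage model is a fragment-pileup approximation: Poisson counts
around a base rate, with Gaussian-shaped enrichment centred on each
planted site (the pipeline consumes coverage tracks, not reads). The
default consensus is an 18-bp AT-rich perfect palindrome, the operator
shape typical of homodimeric MarR-family regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import FlowSample
from .io import reverse_complement
from .model import Contig, CoverageTrack, GeneFeature, GenomeAnnotation, RegionInterval
from .motif import PWM, _BASE_INDEX, _encode

__all__ = [
    "DEFAULT_CONSENSUS",
    "PlantedSite",
    "SyntheticTruth",
    "CoverageSimParams",
    "simulate_genome",
    "plant_sites",
    "simulate_coverage",
    "simulate_expression",
    "simulate_flow",
]

# 18-bp AT-rich palindrome (16/18 A or T); equal to its reverse complement
DEFAULT_CONSENSUS = "TTGTAATATATATTACAA"
assert DEFAULT_CONSENSUS == reverse_complement(DEFAULT_CONSENSUS)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSite:
    contig_id: str
    center: int
    strand: str
    sequence: str
    gene_id: str = ""  # intended target gene; "" for intergenic decoys


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset: the acceptance oracle."""

    planted_sites: list[PlantedSite] = field(default_factory=list)
    motif: PWM | None = None
    consensus: str = ""
    site_to_gene: dict[int, str] = field(default_factory=dict)
    expression_effects: dict[str, float] = field(default_factory=dict)
    induced_fraction_true: float = float("nan")
    rng_seed: int = 0

    def sites_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contig": s.contig_id,
                    "center": s.center,
                    "strand": s.strand,
                    "sequence": s.sequence,
                    "gene_id": s.gene_id,
                }
                for s in self.planted_sites
            ],
            columns=["contig", "center", "strand", "sequence", "gene_id"],
        )

    def effects_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.expression_effects.items()),
            columns=["gene_id", "true_log2_effect"],
        )


@dataclass(frozen=True)
class CoverageSimParams:
    """Background rate, site enrichment and enrichment spread."""

    background_lambda: float = 20.0
    enrichment_fold: float = 10.0
    site_sd_bp: float = 60.0

    def __post_init__(self) -> None:
        if min(self.background_lambda, self.enrichment_fold, self.site_sd_bp) <= 0:
            raise ValueError("all coverage simulation parameters must be positive")


def simulate_genome(
    length_bp: int = 500_000,
    gc_fraction: float = 0.54,
    n_genes: int = 300,
    mean_gene_bp: int = 1000,
    intergenic_bp: int = 400,
    seed: int = 0,
    contig_id: str = "chr",
    circular: bool = False,
    prophage_fraction: float = 0.1,
) -> tuple[Contig, GenomeAnnotation]:
    """An i.i.d. random chromosome with regularly laid-out genes.

    Genes are placed head-to-tail with fixed intergenic spacing; strands
    follow a repeating ``- + + -`` block pattern so that divergent,
    tandem and convergent gene pairs all occur. A central slice of the
    chromosome (default 10%) is recorded as a named ``prophage`` region,
    standing in for a resident prophage element. Deterministic per seed.
    """
    if n_genes * (mean_gene_bp + intergenic_bp) > length_bp:
        raise ValueError(
            "infeasible layout: n_genes * (mean_gene_bp + intergenic_bp) "
            "exceeds length_bp"
        )
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = "".join(rng.choice(_BASES, size=length_bp, p=p))
    contig = Contig(id=contig_id, sequence=seq, circular=circular)

    strand_pattern = "-++-"
    genes = []
    cursor = intergenic_bp
    for i in range(n_genes):
        glen = int(rng.integers(int(0.7 * mean_gene_bp), int(1.3 * mean_gene_bp) + 1))
        start, end = cursor, cursor + glen
        genes.append(
            GeneFeature(
                gene_id=f"cg{i + 1:04d}",
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand_pattern[i % 4],
                product="hypothetical protein",
            )
        )
        cursor = end + intergenic_bp
    regions = {}
    if prophage_fraction > 0:
        mid = length_bp // 2
        half_span = int(length_bp * prophage_fraction / 2)
        regions["prophage"] = RegionInterval(
            contig_id=contig_id, start=mid - half_span, end=mid + half_span,
            name="prophage",
        )
    annotation = GenomeAnnotation(contigs=[contig], genes=genes, regions=regions)
    return contig, annotation


def _mutation_pwm(consensus: str, mutation_rate: float) -> PWM:
    """The PWM implied by the per-base mutation model used for planting."""
    w = len(consensus)
    probs = np.full((w, 4), mutation_rate / 3)
    probs[np.arange(w), _encode(consensus)] = 1 - mutation_rate
    return PWM(probs)


def plant_sites(
    contig: Contig,
    annotation: GenomeAnnotation,
    consensus: str = DEFAULT_CONSENSUS,
    n_sites: int = 30,
    promoter_fraction: float = 0.8,
    mutation_rate: float = 0.1,
    seed: int = 0,
    ensure_genes: tuple[str, ...] = (),
    min_separation_bp: int = 800,
) -> tuple[Contig, SyntheticTruth]:
    """Overwrite motif instances into the genome and record the truth.

    ``round(promoter_fraction * n_sites)`` sites are centred 50-300 bp
    upstream of distinct gene starts (in reading orientation, so they
    fall in the promoter) and recorded with their intended target gene;
    the remainder are placed at other positions, at least 500 bp away
    from every gene start, as intergenic/orphan sites. Each planted
    instance mutates every base independently with ``mutation_rate``.
    Site centres are kept at least ``min_separation_bp`` apart so that
    each site produces its own resolvable coverage peak.
    ``ensure_genes`` forces specific genes (e.g. the regulator itself,
    for autoregulation) to receive a promoter site.
    """
    w = len(consensus)
    half = w // 2
    n_prom = round(promoter_fraction * n_sites)
    genes = [g for g in annotation.genes if g.contig_id == contig.id]
    eligible = []
    for g in genes:
        # need the whole site inside the contig
        if g.strand == "+" and g.start - 300 - half >= 0:
            eligible.append(g)
        elif g.strand == "-" and (g.end - 1) + 300 + half < contig.length:
            eligible.append(g)
    for gid in ensure_genes:
        if gid not in {g.gene_id for g in eligible}:
            raise ValueError(f"ensure_genes: {gid!r} has no eligible promoter")
    if len(eligible) < n_prom:
        raise ValueError(
            f"only {len(eligible)} eligible promoters for {n_prom} promoter sites"
        )
    rng = np.random.default_rng(seed)
    forced = [g for g in eligible if g.gene_id in set(ensure_genes)]
    pool = [g for g in eligible if g.gene_id not in set(ensure_genes)]
    order = list(rng.permutation(len(pool)))

    seq = np.array(list(contig.sequence))
    centres: list[int] = []
    sites: list[PlantedSite] = []

    def separated(center: int) -> bool:
        return all(abs(center - c) >= min_separation_bp for c in centres)

    def place(center: int, gene_id: str) -> None:
        lo = center - half
        hi = lo + w
        instance = list(consensus)
        for i in range(w):
            if rng.random() < mutation_rate:
                alternatives = [b for b in "ACGT" if b != instance[i]]
                instance[i] = alternatives[rng.integers(3)]
        strand = "+" if rng.random() < 0.5 else "-"
        written = "".join(instance) if strand == "+" else reverse_complement(
            "".join(instance)
        )
        seq[lo:hi] = list(written)
        centres.append(center)
        sites.append(
            PlantedSite(contig_id=contig.id, center=center, strand=strand,
                        sequence=written, gene_id=gene_id)
        )

    def promoter_center(g: GeneFeature) -> int | None:
        for _ in range(100):
            u = int(rng.integers(-300, -49))  # oriented offset in [-300, -50]
            center = g.start + u if g.strand == "+" else (g.end - 1) - u
            if separated(center):
                return center
        return None

    placed_prom = 0
    for g in forced:
        center = promoter_center(g)
        if center is None:
            raise ValueError(f"cannot place a separated site for {g.gene_id}")
        place(center, g.gene_id)
        placed_prom += 1
    for i in order:
        if placed_prom == n_prom:
            break
        center = promoter_center(pool[i])
        if center is not None:
            place(center, pool[i].gene_id)
            placed_prom += 1
    if placed_prom < n_prom:
        raise ValueError("could not place the requested number of promoter sites")

    # orphan sites: keep clear of all promoter windows and planted sites
    starts = np.array([g.oriented_start for g in genes]) if genes else np.array([])
    n_orphan = n_sites - n_prom
    tries = 0
    while n_orphan > 0:
        tries += 1
        if tries > 10000 * n_sites:
            raise ValueError("could not place orphan sites without overlap")
        center = int(rng.integers(half + 1, contig.length - half - 1))
        if starts.size and np.min(np.abs(starts - center)) < 500:
            continue
        if not separated(center):
            continue
        place(center, "")
        n_orphan -= 1

    truth = SyntheticTruth(
        planted_sites=sites,
        motif=_mutation_pwm(consensus, mutation_rate),
        consensus=consensus,
        site_to_gene={i: s.gene_id for i, s in enumerate(sites) if s.gene_id},
        rng_seed=seed,
    )
    new_contig = Contig(id=contig.id, sequence="".join(seq), circular=contig.circular)
    return new_contig, truth


def simulate_coverage(
    contig: Contig,
    truth: SyntheticTruth,
    params: CoverageSimParams = CoverageSimParams(),
    seed: int = 0,
) -> CoverageTrack:
    """Poisson coverage with Gaussian enrichment at every planted site.

    lambda(b) = background * (1 + sum_sites (fold - 1) *
    exp(-(b - center)^2 / (2 sd^2))), so the rate at a site centre is
    ~ background * fold.
    """
    n = contig.length
    lam = np.full(n, params.background_lambda)
    sd = params.site_sd_bp
    reach = int(np.ceil(4 * sd))
    for s in truth.planted_sites:
        if s.contig_id != contig.id:
            continue
        lo, hi = max(0, s.center - reach), min(n, s.center + reach + 1)
        d = np.arange(lo, hi) - s.center
        lam[lo:hi] += (
            params.background_lambda
            * (params.enrichment_fold - 1)
            * np.exp(-(d.astype(float) ** 2) / (2 * sd * sd))
        )
    rng = np.random.default_rng(seed)
    return CoverageTrack(contig_id=contig.id, values=rng.poisson(lam).astype(float))


def simulate_expression(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    n_replicates: int = 4,
    noise_sd: float = 0.3,
    effect_log2: float = -2.8,
    off_target_fraction: float = 0.05,
    off_target_effect: float = 2.8,
    baseline_log2_mean: float = 10.0,
    baseline_log2_sd: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-condition replicate intensity table with known per-gene effects.

    Bound target genes get a true log2 effect of ``effect_log2``
    (repression-dominant by default: overexpressing the regulator lowers
    its targets ~7-fold); a small fraction of the remaining genes get an
    off-target effect of random sign, emulating indirect responses; all
    other genes are null. Per replicate, the perturbed/control intensity
    ratio is 2^(effect + N(0, noise_sd^2)), so the MA statistics recover
    the planted effect exactly as noise_sd -> 0. Updates
    ``truth.expression_effects`` in place.
    """
    rng = np.random.default_rng(seed)
    targets = set(truth.site_to_gene.values())
    effects: dict[str, float] = {}
    others = [g.gene_id for g in annotation.genes if g.gene_id not in targets]
    n_off = round(off_target_fraction * len(others))
    off_idx = set(rng.choice(len(others), size=n_off, replace=False)) if n_off else set()
    for gid in targets:
        effects[gid] = effect_log2
    for i, gid in enumerate(others):
        if i in off_idx:
            effects[gid] = off_target_effect * (1 if rng.random() < 0.5 else -1)
        else:
            effects[gid] = 0.0
    rows = []
    for g in annotation.genes:
        eff = effects[g.gene_id]
        baseline = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd)
        m = eff + rng.normal(0.0, noise_sd, size=n_replicates)
        row = {"gene_id": g.gene_id}
        for r in range(n_replicates):
            row[f"ctrl_{r + 1}"] = baseline
            row[f"pert_{r + 1}"] = baseline * 2.0 ** m[r]
        rows.append(row)
    truth.expression_effects = effects
    return pd.DataFrame(rows)


def simulate_flow(
    n_events: int = 100_000,
    induced_fraction: float = 0.2,
    off_mean_log: float = 2.0,
    on_mean_log: float = 4.0,
    sd_log: float = 0.25,
    seed: int = 0,
) -> tuple[FlowSample, FlowSample]:
    """(sample, uninduced negative control) fluorescence event vectors.

    Events are log10-normal; the sample is a two-component mixture with
    exactly ``round(induced_fraction * n_events)`` induced events.
    """
    if not (0 <= induced_fraction <= 1):
        raise ValueError("induced_fraction must be in [0, 1]")
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng(seed)
    control = 10.0 ** rng.normal(off_mean_log, sd_log, size=n_events)
    n_on = round(induced_fraction * n_events)
    off = 10.0 ** rng.normal(off_mean_log, sd_log, size=n_events - n_on)
    on = 10.0 ** rng.normal(on_mean_log, sd_log, size=n_on)
    mixed = np.concatenate((off, on))
    rng.shuffle(mixed)
    return FlowSample(events=mixed), FlowSample(events=control)
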
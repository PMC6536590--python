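# Methods

This note specifies the statistical models and numerical choices behind
`chapmap`. All parameters below are package defaults and can be
overridden via the YAML config or function arguments.

## 1. Peak calling

**Input.** A non-negative per-base coverage track per contig (dense;
bedGraph input is densified with zeros for uncovered bases) and the
contig sequences.

**Smoothing.** Rolling mean with window `window_bp = 50` and step
`step_bp = 10`. Window start positions are `0, s, 2s, …`; on linear
contigs only windows whose centre `start + w//2` lies inside the contig
are kept (the last window may be truncated to the contig end); on
circular contigs every window wraps and is full-length. Implementation
uses a cumulative sum, which is exact in float64 for integer-valued
counts — the test suite asserts bit-identity against a naive loop.

**Thresholding.** `fold_threshold = 3` times the genome-wide mean raw
coverage (length-weighted across contigs). The factor 3 is a
conventional enrichment cutoff for high-enrichment affinity
purification data; with ~10× enrichment over background it separates
signal from Poisson background by a wide margin.

**Segmentation.** Marked window centres are merged into one peak while
consecutive centres are at most `max(step_bp, merge_gap_bp = 50)` bp
apart; groups with fewer than `min_windows = 2` windows are discarded
(suppresses single-window noise excursions). The peak span is
`[first_centre − w//2, last_centre − w//2 + w)`, clipped to the contig
on linear contigs. The **summit** is the marked centre with maximal
smoothed value (ties → smallest coordinate).

**Summit windows.** `flank_bp = 50` gives 100-bp windows
`[summit − 50, summit + 50)`. On linear contigs windows are clipped and
flagged `truncated`; on circular contigs they wrap. 100 bp comfortably
contains an 18-bp site given the observed summit accuracy (median error
~3 bp on synthetic data at default conditions).

## 2. Promoter assignment

For a peak summit and a gene on strand `+`/`−`, the oriented offset is
`t = summit − start` or `t = (end − 1) − summit` respectively (0-based,
half-open gene coordinates). The peak is assigned to the gene iff
`−upstream_bp ≤ t < downstream_bp` with `upstream_bp = 500`,
`downstream_bp = 100` — a window wide enough for bacterial promoters
and leaderless starts, narrow enough to keep most assignments unique.
When one summit lands in range of genes on both strands the assignments
are flagged `divergent_shared`. An optional operon map re-points
assignments from internal operon members to the operon leader.
Unassigned peaks are retained with an empty `gene_id` ("orphan" peaks,
e.g. inside prophage-like regions).

## 3. Motif discovery (ZOOPS-EM)

**Model.** Each 100-bp window contains zero or one motif occurrence of
fixed width `width = 18` on either strand (ZOOPS). Background is a
0-order model estimated from the input windows (+1 pseudocount).
Latent variables: presence (prior γ, shared across windows) and, given
presence, a uniform choice among all `2·(L − w + 1)` strand/offset
placements.

**EM.** The E-step computes placement posteriors in log space
(`scipy.special.logsumexp`). The M-step re-estimates γ and the position
weight matrix (PWM) from expected counts with a Dirichlet pseudocount
of 0.5 per cell (MAP-EM). With `symmetric = True` (default) the
expected count matrix is averaged with its reverse complement before
normalisation — a valid constrained M-step, so the penalised objective
(data log-likelihood + Dirichlet log-prior) is non-decreasing; the
fitted `objective_trace_` is asserted monotone to 1e−9 in the tests.
Symmetry is on by default because homodimeric bacterial repressors bind
palindromes; it halves the effective parameter count and removes the
strand ambiguity of the solution.

**Restarts and convergence.** `n_seeds = 10` random restarts, each
seeded from a sampled w-mer (symmetrised); the restart with the best
data log-likelihood wins. Iteration stops at relative objective change
`tol = 1e−6` or `max_iter = 200`. Reported per-window hits are the MAP
placement when the posterior presence probability exceeds ½.

**Deviation from spaced-dyad seeding.** Classical motif discovery tools
seed EM from spaced palindromic dyads; we seed from sampled w-mers,
which is simpler and sufficient at these site counts (recovery is
validated against planted truth). A known degeneracy remains: motifs
with repetitive cores (e.g. `(AT)_n`) admit phase-shifted solutions of
near-equal likelihood, so recovered PWMs should be compared to
references allowing a small alignment offset.

**PWM statistics.** Information content `Σ p log2(p/q)` (uniform
background by default), AT-content (mean `p(A)+p(T)` per column), and
palindromicity `1 − ‖P − rc(P)‖₁ / (2·width)` which is 1 exactly for
self-reverse-complement matrices.

## 4. Expression integration

Per gene with replicate intensity pairs (pert, ctrl): per-replicate
log-ratios `m_r = log2(pert_r/ctrl_r)`, summary `M = mean(m_r)`,
`A = (mean log2 pert + mean log2 ctrl)/2`, and a two-sided one-sample
t-test of `m_r` against 0 (`scipy.stats.ttest_1samp`). Conventions:
fewer than 2 replicates → p = NaN, flag `p_undefined`; zero variance →
p = 0 if the mean is non-zero else p = 1, flag `zero_variance`.
Optional Benjamini–Hochberg correction (`statsmodels`). A gene is
differentially expressed iff `|M| ≥ log2(fold_cutoff = 5)` and
`p < p_cutoff = 0.05`. Classes: `direct_repressed` / `direct_activated`
(bound and DE, by sign of M), `bound_unchanged`, `unbound_DE`, `none`.

**RT-qPCR.** `ΔCt = Ct_sample − Ct_control`; relative expression
`2^−ΔCt` (assumes 100 % amplification efficiency).

**Flow-cytometry gating.** The gate is the `quantile = 0.995` quantile
(numpy linear interpolation) of the uninduced control sample; the
induced fraction is the proportion of sample events strictly above the
gate. By construction ~0.5 % of a null sample exceeds the gate, so a
true induced fraction f reports ≈ `f + (1 − f)·0.005`.

## 5. Synthetic data generator

The generator emulates, at the level of summary statistics, a ChAP-Seq
+ transcriptomics study of a single-contig bacterial genome:

* **Genome** (`simulate_genome`): `length_bp = 500000`, i.i.d. bases at
  `gc_fraction = 0.54`; `n_genes = 300` genes of length U[700, 1300] bp
  with 400-bp intergenic gaps, strand pattern `-++-` repeated (creates
  divergent and convergent pairs and shared intergenic regions); a
  central region covering 10 % of the genome is annotated
  `prophage`-like for region tallies.
* **Sites** (`plant_sites`): `n_sites = 30` instances of the 18-bp
  self-reverse-complement consensus `TTGTAATATATATTACAA` with per-base
  mutation rate 0.1 and random strand. `promoter_fraction = 0.8` of
  sites (24) are placed at oriented offsets U[−300, −50] upstream of
  distinct genes; the rest (6) are orphans ≥ 500 bp from any oriented
  gene start. All sites are ≥ 800 bp apart so adjacent peaks never
  merge.
* **Coverage** (`simulate_coverage`): per-base Poisson with rate
  `λ_b = λ0·(1 + (E−1)·exp(−d²/2σ²))`, `λ0 = background_lambda = 20`,
  `E = enrichment_fold = 10`, `σ = site_sd_bp = 60` (d = distance to the
  nearest site centre; contributions beyond 4σ are dropped).
* **Expression** (`simulate_expression`): promoter-site target genes get
  a true effect of `effect_log2 = −2.8` (≈ 7-fold repression, i.e. the
  TF perturbation de-represses/changes them beyond the 5-fold cutoff);
  `off_target_fraction = 0.05` of the remaining genes get ±2.8 with
  random sign; `n_replicates = 4` per-replicate ratios are the true
  effect + N(0, `noise_sd = 0.3`); control intensities are log-normal,
  perturbed intensities are `ctrl · 2^{m_r}`.
* **Flow** (`simulate_flow`): 100 000 events per sample; log10-normal
  fluorescence with an induced subpopulation shifted ~10× and exactly
  `round(f·n)` induced events.

**What it does not emulate:** read-level artefacts (mappability, GC
bias, duplicates, fragment-size effects), transcription units beyond a
user-supplied operon map, dye-swap or array-specific noise structure,
and cell-to-cell expression autocorrelation. Conclusions about those
aspects cannot be drawn from this generator.

## 6. Determinism and numerics

All randomness flows through `numpy.random.default_rng(seed)`; the CLI
derives stage seeds `base, base+1, base+2, base+3` for genome, site
planting, coverage and expression. Floats are written with `%.6g`, so
identical configs and seeds yield byte-identical output files. EM is
computed in log space throughout; rolling means use cumulative sums
(exact for integer counts).

## 7. Limitations

* The fold-over-mean threshold assumes a roughly stationary background;
  strong copy-number structure would need a local background model.
* ZOOPS assumes at most one site per 100-bp window; tandem sites within
  one window are collapsed.
* The t-test with n = 4 replicates has limited power at the 5-fold
  cutoff for noisy genes; the package reports flags rather than hiding
  undefined cases.
* The generator's planted effects are homogeneous (−2.8 log2); graded
  regulon responses are not modelled.
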
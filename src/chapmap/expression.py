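"""Differential-expression statistics and regulon classification.

Joins per-gene expression changes under regulator overexpression with
binding information to call direct targets. The differential-expression
rule is deliberately simple: a gene is DE when its mean log2 ratio
exceeds log2(fold_cutoff) in magnitude and a per-gene two-sided
one-sample t-test of the replicate log2 ratios gives p below p_cutoff,
with no multiple-testing correction by default (a Benjamini-Hochberg
switch is available). Also houses the qRT-PCR ddCt-style relative-change
calculation and quantile gating of reporter fluorescence against an
uninduced negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionRecord",
    "DECriteria",
    "TargetCall",
    "QPCRMeasurement",
    "FlowSample",
    "compute_ma",
    "replicate_pvalue",
    "records_from_table",
    "classify_targets",
    "qpcr_relative_change",
    "gate_induced_fraction",
]


@dataclass
class ExpressionRecord:
    """Per-gene M (log2 ratio), A (mean log2 intensity) and p-value."""

    gene_id: str
    M: float
    A: float = float("nan")
    p_value: float = float("nan")
    n_replicates: int = 1
    flag: str = ""  # "", "p_undefined", "zero_variance"


@dataclass(frozen=True)
class DECriteria:
    """Fold-change and significance cutoffs for calling a gene DE."""

    fold_cutoff: float = 5.0
    p_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if self.fold_cutoff <= 1:
            raise ValueError("fold_cutoff must be > 1")
        if not (0 < self.p_cutoff < 1):
            raise ValueError("p_cutoff must be in (0, 1)")


@dataclass
class TargetCall:
    gene_id: str
    bound: bool
    M: float
    p_value: float
    target_class: str  # direct_repressed | direct_activated | bound_unchanged | unbound_DE | none


@dataclass
class QPCRMeasurement:
    """Relative transcriptional change from threshold cycles: 2^-(dCt)."""

    gene_id: str
    ct_sample: float
    ct_control: float
    delta_ct: float = field(init=False)
    relative_change: float = field(init=False)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ct_sample) and np.isfinite(self.ct_control)):
            raise ValueError("Ct values must be finite")
        self.delta_ct = self.ct_sample - self.ct_control
        self.relative_change = 2.0 ** (-self.delta_ct)


@dataclass
class FlowSample:
    """Per-event fluorescence values from one flow-cytometry sample."""

    events: np.ndarray

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.size == 0:
            raise ValueError("flow sample must contain at least one event")

    @property
    def n_events(self) -> int:
        return self.events.size


def compute_ma(
    intensities_perturbed: Sequence[float],
    intensities_control: Sequence[float],
) -> tuple[float, float, np.ndarray]:
    """Per-gene M and A from paired two-channel replicate intensities.

    Returns (M, A, per-replicate log2 ratios); M is the mean of the
    per-replicate log2 ratios, A the mean log2 intensity over both
    channels and all replicates.
    """
    pert = np.asarray(intensities_perturbed, dtype=float)
    ctrl = np.asarray(intensities_control, dtype=float)
    if pert.shape != ctrl.shape or pert.size == 0:
        raise ValueError("need equal, non-empty paired replicate intensities")
    if np.any(pert <= 0) or np.any(ctrl <= 0):
        raise ValueError("intensities must be strictly positive")
    m = np.log2(pert / ctrl)
    a = float(np.concatenate((np.log2(pert), np.log2(ctrl))).mean())
    return float(m.mean()), a, m


def replicate_pvalue(m_values: Sequence[float]) -> tuple[float, str]:
    """Two-sided one-sample t-test of replicate log2 ratios against 0.

    Returns (p, flag). Fewer than two replicates gives an undefined p
    (NaN, flagged); zero replicate variance gives p = 0 for a nonzero
    mean and p = 1 for an all-zero vector, both flagged, by convention.
    """
    m = np.asarray(m_values, dtype=float)
    if m.size < 2:
        return float("nan"), "p_undefined"
    if np.ptp(m) == 0.0:
        if m[0] == 0.0:
            return 1.0, "zero_variance"
        return 0.0, "zero_variance"
    t = stats.ttest_1samp(m, 0.0)
    return float(t.pvalue), ""


def records_from_table(
    table: pd.DataFrame,
    pert_prefix: str = "pert_",
    ctrl_prefix: str = "ctrl_",
    gene_col: str = "gene_id",
) -> list[ExpressionRecord]:
    """Build per-gene records from a wide table of replicate intensities."""
    pert_cols = sorted(c for c in table.columns if c.startswith(pert_prefix))
    ctrl_cols = sorted(c for c in table.columns if c.startswith(ctrl_prefix))
    if len(pert_cols) != len(ctrl_cols) or not pert_cols:
        raise ValueError("paired perturbed/control replicate columns required")
    records = []
    for row in table.itertuples(index=False):
        d = row._asdict()
        M, A, m = compute_ma([d[c] for c in pert_cols], [d[c] for c in ctrl_cols])
        p, flag = replicate_pvalue(m)
        records.append(
            ExpressionRecord(
                gene_id=d[gene_col], M=M, A=A, p_value=p,
                n_replicates=len(pert_cols), flag=flag,
            )
        )
    return records


def classify_targets(
    records: Iterable[ExpressionRecord],
    bound_genes: set[str],
    criteria: DECriteria = DECriteria(),
    bh_correct: bool = False,
) -> list[TargetCall]:
    """Join binding with differential expression into target classes.

    DE means |M| >= log2(fold_cutoff) and p < p_cutoff. A bound DE gene
    is a direct target: ``direct_repressed`` when its mRNA drops under
    regulator overexpression (M < 0), ``direct_activated`` when it rises.
    Bound genes that do not respond are ``bound_unchanged``; unbound DE
    genes (``unbound_DE``) are candidate indirect effects.
    """
    records = list(records)
    seen: set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene_id {r.gene_id!r}")
        seen.add(r.gene_id)
    pvals = np.array([r.p_value for r in records])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        finite = np.isfinite(pvals)
        adj = pvals.copy()
        if finite.any():
            adj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        pvals = adj
    m_cut = np.log2(criteria.fold_cutoff)
    calls = []
    for r, p in zip(records, pvals):
        de = abs(r.M) >= m_cut and np.isfinite(p) and p < criteria.p_cutoff
        bound = r.gene_id in bound_genes
        if bound and de:
            cls = "direct_repressed" if r.M < 0 else "direct_activated"
        elif bound:
            cls = "bound_unchanged"
        elif de:
            cls = "unbound_DE"
        else:
            cls = "none"
        calls.append(
            TargetCall(gene_id=r.gene_id, bound=bound, M=r.M,
                       p_value=float(p), target_class=cls)
        )
    return calls


def qpcr_relative_change(
    ct_sample: float, ct_control: float, gene_id: str = ""
) -> QPCRMeasurement:
    """Relative transcriptional change 2^-(Ct_sample - Ct_control)."""
    return QPCRMeasurement(gene_id=gene_id, ct_sample=ct_sample, ct_control=ct_control)


def gate_induced_fraction(
    sample: FlowSample,
    negative_control: FlowSample,
    quantile: float = 0.995,
) -> float:
    """Fraction of sample events above a negative-control quantile gate.

    The gate threshold is the given quantile of the uninduced negative
    control's fluorescence (linear interpolation between order
    statistics); events strictly above it count as induced.
    """
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    threshold = float(np.quantile(negative_control.events, quantile))
    return float(np.mean(sample.events > threshold))
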
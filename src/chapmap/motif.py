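"""Position-weight-matrix motif model and a ZOOPS-EM motif finder.

The finder assumes each peak window carries zero or one occurrence of a
shared operator motif on either strand (the "zero or one occurrence per
sequence" model). Because MarR-family regulators bind as homodimers to
(near-)palindromic operators, the finder can constrain the PWM to be
reverse-complement symmetric, in which case the expected letter counts
are pooled with their reverse complement after every M-step — the exact
maximiser of the expected complete-data objective over symmetric
matrices, so the EM ascent property is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

__all__ = [
    "PWM",
    "MotifHit",
    "pwm_from_sites",
    "information_content",
    "at_content",
    "palindromicity",
    "zoops_em",
    "ZoopsMotifFinder",
    "scan_width",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
# complement permutation of the (A, C, G, T) columns
_COMP = np.array([3, 2, 1, 0])


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGT character {exc}") from None


@dataclass
class PWM:
    """Per-position base probabilities of a motif, rows over (A, C, G, T)."""

    probs: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be a width x 4 matrix")
        if np.any(self.probs < 0):
            raise ValueError("PWM entries must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1][:, _COMP], pseudocount=self.pseudocount)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def to_meme(self, name: str = "MOTIF_1") -> str:
        """MEME minimal motif format text block."""
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "strands: + -",
            "",
            "Background letter frequencies",
            "A 0.25 C 0.25 G 0.25 T 0.25",
            "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width} nsites= 20 E= 0",
        ]
        for row in self.probs:
            lines.append(" ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


@dataclass
class MotifHit:
    """Best motif occurrence in one input window."""

    seq_index: int
    offset: int
    strand: str  # '+' or '-'
    score_bits: float  # log2 odds of the site under the PWM vs background


def pwm_from_sites(sites: list[str], pseudocount: float = 0.5) -> PWM:
    """Build a PWM from aligned equal-length sites by letter counting."""
    if not sites:
        raise ValueError("at least one site required")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("all sites must have equal length")
    counts = np.zeros((width, 4))
    for s in sites:
        enc = _encode(s)
        counts[np.arange(width), enc] += 1
    probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return PWM(probs, pseudocount=pseudocount)


def information_content(
    pwm: PWM, background: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Per-column information content (bits) and its total.

    IC_i = sum_b p_ib * log2(p_ib / q_b), with the 0*log(0) = 0 convention.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if np.any(background <= 0):
        raise ValueError("background frequencies must be strictly positive")
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / background), 0.0)
    per_col = terms.sum(axis=1)
    return per_col, float(per_col.sum())


def at_content(pwm: PWM) -> float:
    """Mean over columns of p(A) + p(T)."""
    return float((pwm.probs[:, 0] + pwm.probs[:, 3]).mean())


def palindromicity(pwm: PWM) -> float:
    """1 minus half the mean L1 distance to the reverse-complement PWM.

    1.0 for a perfectly reverse-complement-symmetric matrix, 0.0 for a
    matrix maximally far from its reverse complement (e.g. all-A vs all-T).
    """
    rc = pwm.reverse_complement().probs
    return float(1.0 - np.abs(pwm.probs - rc).sum() / (2 * pwm.width))


def _symmetrize_counts(counts: np.ndarray) -> np.ndarray:
    return 0.5 * (counts + counts[::-1][:, _COMP])


class ZoopsMotifFinder:
    """Zero-or-one-occurrence-per-sequence EM motif discovery.

    Parameters
    ----------
    width : motif width in bp.
    symmetric : constrain the PWM to reverse-complement symmetry
        (palindromic operator model).
    n_seeds : number of random restarts; each restart is seeded from a
        w-mer sampled from the input windows. The restart with the best
        final data log-likelihood wins.
    pseudocount : Dirichlet pseudocount added per letter in the M-step.

    Fitted attributes
    -----------------
    pwm_ : the recovered :class:`PWM`.
    hits_ : list of :class:`MotifHit` or ``None`` per window (maximum
        posterior; ``None`` when "no occurrence" has the highest posterior).
    gamma_ : fitted prior probability that a window contains the motif.
    log_likelihood_ : final data log-likelihood of the winning restart.
    objective_trace_ : per-iteration penalized objective (log-likelihood
        plus the Dirichlet pseudocount prior term) of the winning restart;
        non-decreasing by construction of the EM updates.
    """

    def __init__(
        self,
        width: int = 18,
        symmetric: bool = True,
        max_iter: int = 200,
        tol: float = 1e-6,
        n_seeds: int = 10,
        pseudocount: float = 0.5,
        rng_seed: int = 0,
    ) -> None:
        self.width = width
        self.symmetric = symmetric
        self.max_iter = max_iter
        self.tol = tol
        self.n_seeds = n_seeds
        self.pseudocount = pseudocount
        self.rng_seed = rng_seed

    # -- internals ---------------------------------------------------------

    def _background(self, encoded: list[np.ndarray]) -> np.ndarray:
        counts = np.bincount(np.concatenate(encoded), minlength=4).astype(float)
        counts += 1.0  # keep all four letters representable
        return counts / counts.sum()

    def _seed_pwm(self, encoded: list[np.ndarray], rng: np.random.Generator) -> np.ndarray:
        w = self.width
        si = rng.integers(len(encoded))
        x = encoded[si]
        off = rng.integers(len(x) - w + 1)
        probs = np.full((w, 4), 0.1)
        probs[np.arange(w), x[off : off + w]] = 0.7
        if self.symmetric:
            probs = 0.5 * (probs + probs[::-1][:, _COMP])
        return probs / probs.sum(axis=1, keepdims=True)

    def _run_em(
        self, encoded: list[np.ndarray], views, bg: np.ndarray, probs: np.ndarray
    ):
        w = self.width
        log_bg = np.log(bg)
        gamma = 0.5
        trace: list[float] = []
        data_ll = -np.inf
        cols = np.arange(w)
        for _ in range(self.max_iter):
            log_p = np.log(probs)
            # E-step: posterior over (offset, strand, absent) per window
            counts = np.zeros((w, 4))
            presence = 0.0
            data_ll = 0.0
            for V, V_rc in views:
                m = V.shape[0]
                r_plus = (log_p[cols, V] - log_bg[V]).sum(axis=1)
                r_minus = (log_p[cols, V_rc] - log_bg[V_rc]).sum(axis=1)
                r = np.concatenate((r_plus, r_minus))
                log_terms = np.concatenate(
                    ([np.log1p(-gamma)], np.log(gamma / (2 * m)) + r)
                )
                norm = logsumexp(log_terms)
                data_ll += norm  # the window's background log-prob factors out
                q = np.exp(log_terms - norm)
                presence += 1.0 - q[0]
                q_plus, q_minus = q[1 : m + 1], q[m + 1 :]
                for b in range(4):
                    counts[:, b] += (q_plus[:, None] * (V == b)).sum(axis=0)
                    counts[:, b] += (q_minus[:, None] * (V_rc == b)).sum(axis=0)
            data_ll += self._window_log_bg
            if self.symmetric:
                counts = _symmetrize_counts(counts)
            prior = self.pseudocount * np.log(probs).sum()
            trace.append(data_ll + prior)
            if len(trace) > 1 and trace[-1] - trace[-2] < self.tol:
                break
            # M-step (stop here on the final iteration so that the returned
            # parameters are the ones the trace and posteriors refer to)
            new_probs = counts + self.pseudocount
            new_probs /= new_probs.sum(axis=1, keepdims=True)
            probs = new_probs
            gamma = min(max(presence / len(encoded), 1e-9), 1 - 1e-9)
        return probs, gamma, data_ll, trace

    # -- API ---------------------------------------------------------------

    def fit(self, windows: list[str]) -> "ZoopsMotifFinder":
        if len(windows) < 2:
            raise ValueError("at least two windows are required")
        encoded = [_encode(s) for s in windows]
        if min(len(x) for x in encoded) < self.width:
            raise ValueError("motif width exceeds the shortest window")
        w = self.width
        views = []
        for x in encoded:
            V = sliding_window_view(x, w)
            # site read on the minus strand: reverse complement of the w-mer
            V_rc = (3 - V)[:, ::-1]
            views.append((V, V_rc))
        bg = self._background(encoded)
        log_bg = np.log(bg)
        self._window_log_bg = float(sum(log_bg[x].sum() for x in encoded))
        rng = np.random.default_rng(self.rng_seed)
        best = None
        for _ in range(self.n_seeds):
            probs0 = self._seed_pwm(encoded, rng)
            result = self._run_em(encoded, views, bg, probs0)
            if best is None or result[2] > best[2]:
                best = result
        probs, gamma, data_ll, trace = best
        self.pwm_ = PWM(probs, pseudocount=self.pseudocount)
        self.gamma_ = float(gamma)
        self.log_likelihood_ = float(data_ll)
        self.objective_trace_ = np.array(trace)
        self.background_ = bg
        self.hits_ = self._extract_hits(encoded, views, np.log(probs), log_bg, gamma)
        return self

    def _extract_hits(self, encoded, views, log_p, log_bg, gamma):
        hits: list[MotifHit | None] = []
        cols = np.arange(self.width)
        for i, (x, (V, V_rc)) in enumerate(zip(encoded, views)):
            m = V.shape[0]
            r_plus = (log_p[cols, V] - log_bg[V]).sum(axis=1)
            r_minus = (log_p[cols, V_rc] - log_bg[V_rc]).sum(axis=1)
            r = np.concatenate((r_plus, r_minus))
            log_terms = np.concatenate(
                ([np.log1p(-gamma)], np.log(gamma / (2 * m)) + r)
            )
            k = int(np.argmax(log_terms))
            if k == 0:
                hits.append(None)
                continue
            k -= 1
            strand = "+" if k < m else "-"
            off = k if k < m else k - m
            score = float(r[k] / np.log(2))
            hits.append(MotifHit(seq_index=i, offset=int(off), strand=strand,
                                 score_bits=score))
        return hits


def zoops_em(
    windows: list[str],
    width: int = 18,
    symmetric: bool = True,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_seeds: int = 10,
    rng_seed: int = 0,
) -> tuple[PWM, list[MotifHit | None]]:
    """Functional wrapper over :class:`ZoopsMotifFinder`."""
    finder = ZoopsMotifFinder(
        width=width,
        symmetric=symmetric,
        max_iter=max_iter,
        tol=tol,
        n_seeds=n_seeds,
        rng_seed=rng_seed,
    ).fit(windows)
    return finder.pwm_, finder.hits_


def scan_width(
    windows: list[str],
    widths: range = range(14, 23, 2),
    rng_seed: int = 0,
    **kwargs,
) -> tuple[int, dict[int, float]]:
    """Pick the motif width maximising total IC per free parameter.

    Returns the chosen width and the per-width score table. A light
    wrapper around repeated :func:`zoops_em` runs; intended for
    exploratory use rather than the default pipeline.
    """
    scores: dict[int, float] = {}
    for w in widths:
        pwm, _ = zoops_em(windows, width=w, rng_seed=rng_seed, **kwargs)
        _, total = information_content(pwm)
        scores[w] = total / w
    best = max(scores, key=lambda w: (scores[w], -w))
    return best, scores
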
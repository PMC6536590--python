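import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chapmap.io import reverse_complement
from chapmap.motif import (
    PWM,
    ZoopsMotifFinder,
    at_content,
    information_content,
    palindromicity,
    pwm_from_sites,
    zoops_em,
)

# --- PWM construction ------------------------------------------------------

def test_pwm_from_sites_counting():
    pwm = pwm_from_sites(["AT", "AT"], pseudocount=0)
    assert np.array_equal(pwm.probs[0], [1, 0, 0, 0])
    assert np.array_equal(pwm.probs[1], [0, 0, 0, 1])


def test_pwm_from_sites_pseudocount_formula():
    pwm = pwm_from_sites(["A"], pseudocount=0.5)
    assert pwm.probs[0] == pytest.approx([1.5 / 3, 0.5 / 3, 0.5 / 3, 0.5 / 3])


def test_pwm_from_sites_matches_counting_oracle():
    rng = np.random.default_rng(0)
    sites = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(20)]
    pwm = pwm_from_sites(sites, pseudocount=0.5)
    for i in range(12):
        for b, base in enumerate("ACGT"):
            count = sum(s[i] == base for s in sites)
            assert pwm.probs[i, b] == pytest.approx((count + 0.5) / (20 + 2.0))


def test_pwm_from_sites_invalid_inputs():
    with pytest.raises(ValueError):
        pwm_from_sites([])
    with pytest.raises(ValueError):
        pwm_from_sites(["AT", "ATT"])


# --- information content, AT content, palindromicity ----------------------

def test_information_content_closed_forms():
    degenerate = PWM(np.array([[1.0, 0, 0, 0]]))
    per_col, total = information_content(degenerate)
    assert per_col[0] == pytest.approx(2.0) and total == pytest.approx(2.0)
    uniform = PWM(np.full((1, 4), 0.25))
    assert information_content(uniform)[1] == pytest.approx(0.0)
    half = PWM(np.array([[0.5, 0, 0, 0.5]]))
    assert information_content(half)[1] == pytest.approx(1.0)


def test_information_content_zero_background_errors():
    with pytest.raises(ValueError):
        information_content(PWM(np.full((1, 4), 0.25)), background=[0.5, 0.5, 0, 0])


def test_at_content_closed_forms():
    assert at_content(PWM(np.tile([0.5, 0, 0, 0.5], (4, 1)))) == pytest.approx(1.0)
    assert at_content(PWM(np.full((4, 4), 0.25))) == pytest.approx(0.5)


def test_palindromicity_extremes():
    # a self-reverse-complement matrix scores exactly 1
    sym = PWM(np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7]]))
    assert palindromicity(sym) == pytest.approx(1.0)
    # all-A consensus of width 2: reverse complement is all-T
    all_a = PWM(np.array([[1.0, 0, 0, 0], [1.0, 0, 0, 0]]))
    assert palindromicity(all_a) == pytest.approx(0.0)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_palindromicity_bounded_and_matches_recomputation(seed):
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(4), size=6)
    pwm = PWM(probs)
    score = palindromicity(pwm)
    assert 0.0 <= score <= 1.0
    # direct recomputation from the definition
    rc = probs[::-1][:, [3, 2, 1, 0]]
    assert score == pytest.approx(1 - np.abs(probs - rc).sum() / 12)


def test_ic_after_construction_matches_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(50):
        n_sites = int(rng.integers(2, 20))
        sites = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(n_sites)]
        pwm = pwm_from_sites(sites)
        _, total = information_content(pwm)
        brute = sum(
            p * np.log2(p / 0.25)
            for row in pwm.probs
            for p in row
            if p > 0
        )
        assert total == pytest.approx(brute)


# --- ZOOPS-EM --------------------------------------------------------------

PLANTED = "TTGTAATATATATTACAA"  # AT-rich palindrome


def _windows_with_planted(n=20, length=98, mutation=0.0, seed=7):
    rng = np.random.default_rng(seed)
    w = len(PLANTED)
    windows, offsets = [], []
    for _ in range(n):
        bg = "".join(rng.choice(list("ACGT"), size=length, p=[0.23, 0.27, 0.27, 0.23]))
        site = list(PLANTED)
        for i in range(w):
            if rng.random() < mutation:
                site[i] = rng.choice([b for b in "ACGT" if b != site[i]])
        site = "".join(site)
        if rng.random() < 0.5:
            site = reverse_complement(site)
        off = int(rng.integers(0, length - w + 1))
        windows.append(bg[:off] + site + bg[off + w:])
        offsets.append(off)
    return windows, offsets


def test_zoops_em_recovers_planted_consensus_and_offsets():
    windows, offsets = _windows_with_planted(seed=7)
    pwm, hits = zoops_em(windows, rng_seed=7)
    assert pwm.consensus == PLANTED
    correct = sum(
        h is not None and h.offset == off for h, off in zip(hits, offsets)
    )
    assert correct >= 18


def test_zoops_em_random_windows_have_lower_ic():
    planted, _ = _windows_with_planted(seed=7)
    rng = np.random.default_rng(8)
    random_windows = [
        "".join(rng.choice(list("ACGT"), size=98)) for _ in range(20)
    ]
    _, ic_planted = information_content(zoops_em(planted, rng_seed=1)[0])
    _, ic_random = information_content(zoops_em(random_windows, rng_seed=1)[0])
    assert ic_random < ic_planted


def test_zoops_em_symmetric_output_is_palindromic():
    windows, _ = _windows_with_planted(mutation=0.15, seed=3)
    pwm, _ = zoops_em(windows, symmetric=True, rng_seed=3)
    assert palindromicity(pwm) >= 0.999


def test_zoops_em_objective_nondecreasing_every_seed():
    windows, _ = _windows_with_planted(mutation=0.1, seed=5)
    for seed in range(3):
        finder = ZoopsMotifFinder(n_seeds=2, rng_seed=seed).fit(windows)
        diffs = np.diff(finder.objective_trace_)
        assert np.all(diffs >= -1e-9)


def test_zoops_em_input_validation():
    with pytest.raises(ValueError):
        zoops_em(["ACGTACGTACGTACGTACGTAC"])  # one window
    with pytest.raises(ValueError):
        zoops_em(["ACGT", "ACGT"], width=18)  # width > window length


def _shift_tolerant_distance(a, b, max_shift=3):
    """Min mean per-column Euclidean distance over small alignment offsets.

    The AT-repeat core of the planted palindrome makes phase-shifted
    alignments near-degenerate in likelihood, so motif comparison must
    allow an offset (as standard PWM comparison tools do).
    """
    best = np.inf
    for s in range(-max_shift, max_shift + 1):
        lo, hi = max(0, s), min(len(a), len(b) + s)
        d = np.linalg.norm(a[lo:hi] - b[lo - s:hi - s], axis=1).mean()
        best = min(best, d)
    return best


def test_zoops_em_motif_recovery_distance():
    """Mean per-column distance between recovered and planted PWM stays small."""
    dists = []
    for rep in range(5):
        windows, _ = _windows_with_planted(n=60, mutation=0.1, seed=100 + rep)
        pwm, _ = zoops_em(windows, rng_seed=rep, n_seeds=5)
        planted = np.full((18, 4), 0.1 / 3)
        from chapmap.motif import _encode

        planted[np.arange(18), _encode(PLANTED)] = 0.9
        dists.append(_shift_tolerant_distance(pwm.probs, planted))
    assert np.mean(dists) <= 0.15
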
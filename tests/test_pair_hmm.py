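import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from almask import pair_hmm as ph
from almask.substitution import SUPPORTED_PAM, pam_matrix

from .oracles import enumerate_paths


@pytest.mark.parametrize("pam", SUPPORTED_PAM)
def test_default_params_invariants(pam):
    p = ph.default_params(pam)
    rows = p.trans.sum(axis=1) + p.end
    assert np.allclose(rows, 1.0, atol=1e-12)
    core = p.match_emission[:20, :20]
    assert abs(core.sum() - 1.0) < 1e-9
    assert np.allclose(core, core.T)
    assert abs(p.gap_emission[:20].sum() - 1.0) < 1e-9
    assert np.all(p.trans >= 0) and np.all(core >= 0)
    assert abs(p.start.sum() - 1.0) < 1e-9


def test_unsupported_pam_distance():
    with pytest.raises(ValueError, match="unsupported PAM"):
        ph.default_params(97)


def test_pam_semigroup():
    """Applying the 1-PAM matrix 250 times equals the direct PAM250 matrix."""
    p250 = np.linalg.matrix_power(pam_matrix(1), 250)
    assert np.abs(p250 - pam_matrix(250)).max() < 1e-6


def test_match_emission_diagonal_dominant_at_pam120(params120):
    core = params120.match_emission[:20, :20]
    for a in range(20):
        off = (core[a].sum() - core[a, a]) / 19.0
        assert core[a, a] > off


def test_forward_equals_backward(params120):
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.integers(0, 20, size=5).astype(np.int64)
        b = rng.integers(0, 20, size=5).astype(np.int64)
        lf, _ = ph.forward(a, b, params120)
        lb, _ = ph.backward(a, b, params120)
        assert abs(lf - lb) < 1e-9


def test_forward_symmetric_in_arguments(params120):
    lf1, _ = ph.forward("ACDEF", "WYV", params120)
    lf2, _ = ph.forward("WYV", "ACDEF", params120)
    assert lf1 == pytest.approx(lf2, abs=1e-10)


def test_forward_matches_enumeration(params120):
    for a, b in [("A", "A"), ("A", "C"), ("ACD", "WYVF")]:
        ea, eb = ph.encode(a), ph.encode(b)
        total, _ = enumerate_paths(ea, eb, params120)
        lf, _ = ph.forward(a, b, params120)
        assert lf == pytest.approx(np.log(total), abs=1e-9)


def test_empty_sequence_rejected(params120):
    with pytest.raises(ValueError):
        ph.forward("", "ACD", params120)
    with pytest.raises(ValueError):
        ph.pair_posteriors("ACD", "", params120)


def test_posteriors_identical_pair_diagonal_dominant(params120):
    post = ph.pair_posteriors("ACDEFGHI", "ACDEFGHI", params120)
    for k in range(8):
        assert post.probs[k, k] > 0.9
        off = np.delete(post.probs[k], k)
        assert off.max() < post.probs[k, k]


def test_posterior_single_residue_pair_is_match_only(params120):
    """With no X<->Y transition there is no non-match path emitting one
    residue of each sequence, so the single-cell posterior is exactly 1."""
    ea = ph.encode("A")
    eb = ph.encode("C")
    total, match = enumerate_paths(ea, eb, params120)
    assert match[(0, 0)] == pytest.approx(total)
    post = ph.pair_posteriors("A", "C", params120)
    assert post.probs[0, 0] == pytest.approx(1.0, abs=1e-12)


def test_posterior_symmetry_under_pair_swap(params120):
    rng = np.random.default_rng(1)
    for _ in range(5):
        a = rng.integers(0, 20, size=6).astype(np.int64)
        b = rng.integers(0, 20, size=9).astype(np.int64)
        pab = ph.pair_posteriors(a, b, params120).probs
        pba = ph.pair_posteriors(b, a, params120).probs
        assert np.allclose(pab, pba.T, atol=1e-12)


def test_posterior_row_sums_bounded(params120):
    rng = np.random.default_rng(2)
    for _ in range(5):
        a = rng.integers(0, 20, size=30).astype(np.int64)
        b = rng.integers(0, 20, size=25).astype(np.int64)
        probs = ph.pair_posteriors(a, b, params120).probs
        assert probs.min() >= 0.0
        assert probs.sum(axis=1).max() <= 1.0 + 1e-9
        assert probs.sum(axis=0).max() <= 1.0 + 1e-9


def test_substitution_never_increases_match_posterior(params120):
    base = "AAAAAAAA"
    p0 = ph.pair_posteriors(base, base, params120).probs
    for pos in (0, 3, 7):
        for repl in "WCD":
            mutated = base[:pos] + repl + base[pos + 1:]
            p1 = ph.pair_posteriors(base, mutated, params120).probs
            assert p1[pos, pos] <= p0[pos, pos] + 1e-12


def test_occupancy_plus_diagonal_jumps_is_one(params120):
    """Each path crosses anti-diagonal d through one cell unless a match
    move jumps it; occupancy plus jump mass must be exactly 1."""
    a, b = "ACDE", "WYF"
    lf, F = ph.forward(a, b, params120)
    _, B = ph.backward(a, b, params120)
    occ = np.exp(F + B - lf)  # (5, m+1, n+1) posterior state occupancy
    m, n = len(a), len(b)
    for d in range(1, m + n):
        tot = 0.0
        for i in range(m + 1):
            j = d - i
            if 0 <= j <= n:
                tot += occ[:, i, j].sum()
        # match moves entering (i, j) jump over anti-diagonal i + j - 1
        for i in range(1, m + 1):
            j = d + 1 - i
            if 1 <= j <= n:
                tot += occ[0, i, j]
        assert tot == pytest.approx(1.0, abs=1e-9)


def test_long_sequences_stay_finite(params120):
    rng = np.random.default_rng(3)
    a = rng.integers(0, 20, size=1500).astype(np.int64)
    b = rng.integers(0, 20, size=1400).astype(np.int64)
    post = ph.pair_posteriors(a, b, params120)
    assert np.isfinite(post.log_prob)
    assert np.isfinite(post.probs).all()
    assert post.probs.sum(axis=1).max() <= 1.0 + 1e-9


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    st.lists(st.integers(0, 3), min_size=1, max_size=4),
    st.lists(st.integers(0, 3), min_size=1, max_size=4),
)
def test_posteriors_match_enumeration_reduced_alphabet(params4, sa, sb):
    a = np.array(sa, dtype=np.int64)
    b = np.array(sb, dtype=np.int64)
    total, match = enumerate_paths(a, b, params4)
    post = ph.pair_posteriors(a, b, params4)
    assert post.log_prob == pytest.approx(np.log(total), abs=1e-9)
    for (x, y), mass in match.items():
        assert post.probs[x, y] == pytest.approx(mass / total, abs=1e-9)


def test_encode_rejects_gap_and_unknown():
    with pytest.raises(ValueError):
        ph.encode("AC-D")
    with pytest.raises(ValueError):
        ph.encode("ACJD")
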
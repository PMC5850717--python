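"""Unit tests for the folded-similarity measure, θ estimators, β, D, and HWE."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betasel import core_stats as cs
from betasel.core_stats import (
    BetaScore,
    WindowSpectrum,
    beta_folded,
    beta_unfolded,
    beta_variable_n,
    fold,
    fold_spectrum,
    hwe_exact_test,
    max_fold_diff,
    similarity,
    similarity_weights,
    tajimas_d,
    theta_beta,
    theta_beta_folded,
    theta_watterson,
)

# ---------------------------------------------------------------------------
# similarity


@pytest.mark.parametrize(
    "count,n,expected",
    [(75, 100, 25), (50, 100, 50), (10, 100, 10), (0, 10, 0), (10, 10, 0)],
)
def test_fold(count, n, expected):
    assert fold(count, n) == expected


def test_fold_domain_error():
    with pytest.raises(ValueError):
        fold(-1, 100)
    with pytest.raises(ValueError):
        fold(101, 100)


@pytest.mark.parametrize(
    "core_folded,n,expected", [(50, 100, 50), (25, 100, 25), (10, 100, 40)]
)
def test_max_fold_diff(core_folded, n, expected):
    assert max_fold_diff(core_folded, n) == expected


def test_max_fold_diff_odd_n_is_fractional():
    # n/2 stays a real number for odd n
    assert max_fold_diff(1, 5) == pytest.approx(1.5)


def test_max_fold_diff_domain_error():
    with pytest.raises(ValueError):
        max_fold_diff(51, 100)


@pytest.mark.parametrize(
    "core,site,n,p,expected",
    [
        (50, 100, 100, 1.0, None),  # filled below: site must be polymorphic
        (50, 50, 100, 2.0, 1.0),
        (50, 50, 100, 7.0, 1.0),
        (10, 50, 100, 2.0, 0.0),  # maximum folded difference (m = 40)
        (10, 50, 100, 1.0, 0.0),
        (50, 25, 100, 2.0, 0.25),  # ((50-25)/50)^2
        (50, 75, 100, 2.0, 0.25),  # symmetric in folding
    ],
)
def test_similarity_values(core, site, n, p, expected):
    if expected is None:
        with pytest.raises(ValueError):
            similarity(core, site, n, p)
    else:
        assert similarity(core, site, n, p) == pytest.approx(expected, abs=1e-12)


def test_similarity_symmetric_in_allele_labels():
    # flipping derived/ancestral of either site leaves d unchanged
    for core, site in [(30, 44), (70, 44), (30, 56), (70, 56)]:
        assert similarity(core, site, 100, 2.0) == pytest.approx(
            similarity(30, 44, 100, 2.0)
        )


@given(
    n=st.integers(4, 200),
    data=st.data(),
    p=st.floats(0.5, 5.0),
)
@settings(max_examples=200, deadline=None)
def test_similarity_bounds_property(n, data, p):
    core = data.draw(st.integers(1, n - 1))
    site = data.draw(st.integers(1, n - 1))
    d = similarity(core, site, n, p)
    assert 0.0 <= d <= 1.0
    g0, gi = fold(core, n), fold(site, n)
    if g0 == gi:
        assert d == 1.0
    if abs(g0 - gi) == max_fold_diff(g0, n):
        assert d == 0.0


def test_similarity_weights_match_scalar():
    n, core, p = 37, 12, 2.5
    d = similarity_weights(core, n, p)
    for i in range(1, n):
        assert d[i - 1] == pytest.approx(similarity(core, i, n, p))


# ---------------------------------------------------------------------------
# spectra and θ estimators


def test_window_spectrum_validation():
    with pytest.raises(ValueError):
        WindowSpectrum(n=4, counts=np.array([1, 2]))  # wrong length
    with pytest.raises(ValueError):
        WindowSpectrum(n=4, counts=np.array([1, -1, 0]))
    with pytest.raises(ValueError):
        WindowSpectrum.from_derived_counts([0], 4)  # monomorphic class


def _watterson_oracle(counts, n):
    """Exact-rational Watterson estimator, independent of the package path."""
    s = int(sum(counts))
    a = sum(Fraction(1, i) for i in range(1, n))
    return float(Fraction(s) / a) if s else 0.0


@pytest.mark.parametrize(
    "n,counts_map,expected",
    [
        (4, {1: 2, 2: 1}, 18 / 11),
        (4, {}, 0.0),
        (2, {1: 5}, 5.0),
    ],
)
def test_theta_watterson_examples(n, counts_map, expected):
    counts = np.zeros(n - 1, dtype=int)
    for i, c in counts_map.items():
        counts[i - 1] = c
    spec = WindowSpectrum(n=n, counts=counts)
    assert theta_watterson(spec) == pytest.approx(expected, abs=1e-9)


def test_theta_watterson_random_spectra_vs_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(2, 120))
        counts = rng.integers(0, 5, size=n - 1)
        spec = WindowSpectrum(n=n, counts=counts)
        assert theta_watterson(spec) == pytest.approx(
            _watterson_oracle(counts, n), abs=1e-12
        )


@pytest.mark.parametrize(
    "counts_map,expected",
    [
        ({1: 1, 2: 1}, 1.5),  # (1*0.25*1 + 2*1*1) / 1.5
        ({2: 2}, 4.0 / 1.5),
        ({}, 0.0),
    ],
)
def test_theta_beta_small_window(counts_map, expected):
    # n=4, core count 2, p=2: d = (0.25, 1, 0.25), sum 1.5
    counts = np.zeros(3, dtype=int)
    for i, c in counts_map.items():
        counts[i - 1] = c
    spec = WindowSpectrum(n=4, counts=counts, core_count=2)
    assert theta_beta(spec, 2.0) == pytest.approx(expected, abs=1e-9)


def test_theta_beta_linear_in_spectrum(rng):
    """Adding one SNP at class j moves θ̂_β by exactly j·d_j / Σ d_k."""
    n, core, p = 60, 21, 2.0
    d = similarity_weights(core, n, p)
    for _ in range(20):
        counts = rng.integers(0, 4, size=n - 1)
        if counts.sum() == 0:
            counts[n // 2] = 1
        j = int(rng.integers(1, n))
        bumped = counts.copy()
        bumped[j - 1] += 1
        t0 = theta_beta(WindowSpectrum(n=n, counts=counts, core_count=core), p)
        t1 = theta_beta(WindowSpectrum(n=n, counts=bumped, core_count=core), p)
        assert t1 - t0 == pytest.approx(j * d[j - 1] / d.sum(), abs=1e-9)


def test_beta_unfolded_composition():
    spec = WindowSpectrum.from_derived_counts([1, 2], 4, core_count=2)
    sc = beta_unfolded(spec, 2.0, position=77)
    assert sc.theta_beta == pytest.approx(1.5, abs=1e-9)
    assert sc.theta_w == pytest.approx(12 / 11, abs=1e-9)
    assert sc.beta == pytest.approx(1.5 - 12 / 11, abs=1e-9)
    assert sc.beta == sc.theta_beta - sc.theta_w  # exact identity
    assert sc.position == 77 and sc.n_window_snps == 2
    assert sc.folded_freq == pytest.approx(0.5)


def test_beta_max_distance_window_is_minus_watterson():
    # core folded 10 (m=40); every window SNP at folded 50 -> all d weights 0
    spec = WindowSpectrum.from_derived_counts([50, 50, 50], 100, core_count=10)
    sc = beta_unfolded(spec, 2.0)
    assert sc.theta_beta == 0.0
    assert sc.beta == pytest.approx(-theta_watterson(spec))


def test_beta_empty_window_is_missing():
    spec = WindowSpectrum.from_derived_counts([], 100, core_count=50)
    sc = beta_unfolded(spec, 2.0)
    assert sc.is_missing and math.isnan(sc.beta)
    assert sc.n_window_snps == 0


def test_beta_order_invariant(rng):
    counts = list(rng.integers(1, 99, size=30))
    a = beta_unfolded(
        WindowSpectrum.from_derived_counts(counts, 100, core_count=40), 2.0
    )
    rng.shuffle(counts)
    b = beta_unfolded(
        WindowSpectrum.from_derived_counts(counts, 100, core_count=40), 2.0
    )
    assert a.beta == b.beta


# ---------------------------------------------------------------------------
# folded β


def test_beta_folded_worked_example():
    # n=4, core folded 2, S*={2:1}: θ*₂ = 2, weights (0.25, 1) -> 1.6
    spec = WindowSpectrum.from_derived_counts([2], 4, core_count=2)
    sc = beta_folded(4, fold_spectrum(spec), 2, 2.0)
    assert sc.theta_beta == pytest.approx(1.6, abs=1e-9)
    assert sc.theta_w == pytest.approx(6 / 11, abs=1e-9)


def test_fold_spectrum_collapses_classes():
    spec = WindowSpectrum.from_derived_counts([1, 1, 3, 2, 2], 4)
    # folded: class1 <- S1 + S3 = 2 + 1; class2 <- S2 = 2
    assert fold_spectrum(spec).tolist() == [3, 2]


@given(
    st.integers(4, 60),
    st.data(),
)
@settings(max_examples=100, deadline=None)
def test_beta_folded_invariant_under_relabeling(n, data):
    """Flipping derived/ancestral on any subset of sites leaves folded β fixed."""
    k = data.draw(st.integers(1, 12))
    counts = data.draw(
        st.lists(st.integers(1, n - 1), min_size=k, max_size=k)
    )
    flip = data.draw(st.lists(st.booleans(), min_size=k, max_size=k))
    core = data.draw(st.integers(1, n - 1))
    flipped = [n - c if f else c for c, f in zip(counts, flip)]
    a = WindowSpectrum.from_derived_counts(counts, n, core_count=core)
    b = WindowSpectrum.from_derived_counts(flipped, n, core_count=core)
    s_a = beta_folded(n, fold_spectrum(a), fold(core, n), 2.0)
    s_b = beta_folded(n, fold_spectrum(b), fold(core, n), 2.0)
    assert s_a.beta == pytest.approx(s_b.beta, abs=1e-12)


def test_beta_folded_empty_window_missing():
    sc = beta_folded(100, np.zeros(50, dtype=int), 25, 2.0)
    assert sc.is_missing


# ---------------------------------------------------------------------------
# variable sample sizes


def test_beta_variable_n_reduces_to_uniform():
    counts = [10, 40, 55, 70]
    n = 100
    uniform = beta_unfolded(
        WindowSpectrum.from_derived_counts(counts, n, core_count=50), 2.0
    )
    var = beta_variable_n(50, n, counts, [n] * len(counts), 2.0)
    assert var.beta == pytest.approx(uniform.beta, abs=1e-12)


def test_beta_variable_n_mixed_sizes_runs():
    sc = beta_variable_n(50, 100, [30, 18], [80, 40], 2.0)
    assert not math.isnan(sc.beta)


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_oracle(counts_map, n):
    """Tajima's D from first principles with exact rationals until the sqrt."""
    s = sum(counts_map.values())
    pi = sum(
        Fraction(2 * i * (n - i) * c, n * (n - 1)) for i, c in counts_map.items()
    )
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return float(pi - s / a1) / math.sqrt(float(var))


def test_tajimas_d_zero_when_pi_equals_watterson():
    # n=4: 8 singletons + 3 doubletons gives π = S/a1 exactly
    spec = WindowSpectrum.from_derived_counts([1] * 8 + [2] * 3, 4)
    assert tajimas_d(spec) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "n,counts_map",
    [(4, {2: 3}), (4, {1: 5, 3: 2}), (20, {1: 4, 10: 3, 19: 1})],
)
def test_tajimas_d_matches_first_principles_oracle(n, counts_map):
    counts = np.zeros(n - 1, dtype=int)
    for i, c in counts_map.items():
        counts[i - 1] = c
    spec = WindowSpectrum(n=n, counts=counts)
    assert tajimas_d(spec) == pytest.approx(_tajima_oracle(counts_map, n), abs=1e-10)


def test_tajimas_d_empty_window_missing():
    assert math.isnan(tajimas_d(WindowSpectrum.from_derived_counts([], 10)))


def test_tajimas_d_rejects_tiny_samples():
    with pytest.raises(ValueError):
        tajimas_d(WindowSpectrum.from_derived_counts([1], 3))


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test


def _hwe_oracle(a, b, c):
    """Exact-rational enumeration of the conditional het distribution."""
    n = a + b + c
    na = min(2 * a + b, 2 * c + b)

    def weight(h):
        n0 = (na - h) // 2
        n1 = (2 * n - na - h) // 2
        return Fraction(
            2**h * math.factorial(n),
            math.factorial(h) * math.factorial(n0) * math.factorial(n1),
        )

    hets = list(range(na % 2, na + 1, 2))
    ws = {h: weight(h) for h in hets}
    z = sum(ws.values())
    p_obs = ws[b] / z
    p_excess = sum(w for h, w in ws.items() if h >= b) / z
    p_two = sum(w for h, w in ws.items() if w / z <= p_obs) / z
    return float(p_excess), float(p_two)


def test_hwe_monomorphic_sample():
    res = hwe_exact_test(10, 0, 0)
    assert res.p_het_excess == 1.0 and res.p_two_sided == 1.0


def test_hwe_two_hets_of_two():
    # 2 diploids, 2 of each allele: P(het>=2) = 4/6
    res = hwe_exact_test(0, 2, 0)
    assert res.p_het_excess == pytest.approx(2 / 3, abs=1e-12)


def test_hwe_balanced_100_sample():
    res = hwe_exact_test(25, 50, 25)
    exp_excess, exp_two = _hwe_oracle(25, 50, 25)
    assert res.p_het_excess == pytest.approx(exp_excess, rel=1e-9)
    assert res.p_two_sided == pytest.approx(exp_two, rel=1e-9)


def test_hwe_rejects_empty_input():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_matches_enumeration_oracle_exhaustively():
    """All genotype triples with up to 20 diploids agree with the oracle."""
    for n in range(1, 21):
        for a in range(n + 1):
            for b in range(n - a + 1):
                c = n - a - b
                res = hwe_exact_test(a, b, c)
                exp_excess, exp_two = _hwe_oracle(a, b, c)
                assert res.p_het_excess == pytest.approx(exp_excess, rel=1e-8)
                assert res.p_two_sided == pytest.approx(exp_two, rel=1e-8)
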
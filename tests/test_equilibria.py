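"""Cardano solver, discriminant trichotomy, eigenvalues and stability."""

import numpy as np
import pytest

from memhr import ModelParams, DriveParams
from memhr.equilibria import (cubic_coefficients, cardano_discriminant,
                              solve_equilibria, characteristic_coeffs,
                              eigenvalues_at, classify_stability,
                              equilibrium_track, stability_intervals,
                              DegenerateCubicError)


def bisection_roots(cubic, lo=None, hi=None, n=40001, tol=1e-12):
    """Brute-force oracle: bracket sign changes of P on a fine grid, bisect.

    The grid spans the Cauchy root bound, so every real root is bracketed.
    """
    A, B, C, D = cubic
    if lo is None:
        bound = 1.0 + max(abs(B), abs(C), abs(D)) / abs(A)
        lo, hi = -bound, bound

    def P(x):
        return ((A * x + B) * x + C) * x + D

    xs = np.linspace(lo, hi, n)
    vals = P(xs)
    roots = []
    for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
        a, b = xs[i], xs[i + 1]
        for _ in range(100):
            m = 0.5 * (a + b)
            if P(a) * P(m) <= 0:
                b = m
            else:
                a = m
            if b - a < tol:
                break
        roots.append(0.5 * (a + b))
    for x in xs[np.abs(vals) < 1e-14]:  # exact grid hits
        if not any(abs(x - r) < 1e-6 for r in roots):
            roots.append(float(x))
    return sorted(roots)


@pytest.mark.parametrize("k, I, expected", [
    (1.0, 2.0, (-0.99, -2.0, 0.0, 3.0)),
    (0.0, 0.0, (-1.0, -2.0, 0.0, 1.0)),
])
def test_cubic_coefficients(k, I, expected):
    cubic, degenerate = cubic_coefficients(k, I)
    assert cubic == pytest.approx(expected)
    assert not degenerate


def test_cubic_degenerates_at_k_100():
    cubic, degenerate = cubic_coefficients(100.0, 0.7)
    assert cubic[0] == 0.0 and degenerate
    with pytest.raises(DegenerateCubicError):
        cardano_discriminant(cubic)


def test_depressed_coefficients_match_specialized_forms():
    """General p, q reduce to the model-specific closed forms."""
    for k in (-7.0, 0.0, 1.0, 50.0):
        for I in (-2.0, 0.0, 1.3):
            A = 0.01 * k - 1.0
            rep = cardano_discriminant(cubic_coefficients(k, I)[0])
            assert rep.p == pytest.approx(-4.0 / (3.0 * A * A), rel=1e-12)
            q_expected = (I + 1.0) / A - 16.0 / (27.0 * A ** 3)
            assert rep.q == pytest.approx(q_expected, rel=1e-12)


def test_discriminant_trichotomy():
    one = cardano_discriminant(cubic_coefficients(1.0, 2.0)[0])
    assert one.delta > 0 and one.n_real_roots == 1
    three = cardano_discriminant(cubic_coefficients(1.0, -0.9)[0])
    assert three.delta < 0 and three.n_real_roots == 3
    boundary = cardano_discriminant((1.0, 0.0, 0.0, 0.0))  # p = q = 0
    assert boundary.n_real_roots == 2


def test_root_count_matches_bisection_oracle():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        k = rng.uniform(-20, 99)
        I = rng.uniform(-3, 3)
        cubic, _ = cubic_coefficients(k, I)
        rep = cardano_discriminant(cubic)
        oracle = bisection_roots(cubic)
        if rep.n_real_roots == 2:
            assert len(oracle) in (1, 2, 3)  # double root: grid may miss it
        else:
            assert rep.n_real_roots == len(oracle), (k, I)


def test_cardano_roots_match_bisection_oracle():
    rng = np.random.default_rng(11)
    worst = 0.0
    for _ in range(1000):
        k = rng.uniform(-20, 99)
        I = rng.uniform(-3, 3)
        cubic, _ = cubic_coefficients(k, I)
        etas = sorted(r.eta for r in solve_equilibria(k, I))
        oracle = bisection_roots(cubic)
        assert len(etas) >= len(oracle)
        for r_o in oracle:
            worst = max(worst, min(abs(r_o - e) for e in etas))
    assert worst <= 1e-8


def test_solved_roots_have_tiny_residual():
    for k, I in [(1.0, 2.0), (1.0, -0.9), (-7.0, 0.0), (35.0, 1.5)]:
        A, B, C, D = cubic_coefficients(k, I)[0]
        for rep in solve_equilibria(k, I):
            e = rep.eta
            assert abs(((A * e + B) * e + C) * e + D) <= 1e-12 * max(1, e * e)


def test_known_roots():
    # I = +2: single equilibrium near (1, -4, 1)
    reps = solve_equilibria(1.0, 2.0)
    assert len(reps) == 1
    assert reps[0].eta == pytest.approx(1.0, abs=2e-3)
    assert reps[0].point[1] == pytest.approx(-4.0, abs=2e-2)
    # I = -2: single equilibrium near -2.22
    reps = solve_equilibria(1.0, -2.0)
    assert len(reps) == 1
    assert reps[0].eta == pytest.approx(-2.22, abs=5e-3)


def test_degenerate_quadratic_path():
    reps = solve_equilibria(100.0, 1.0)  # -2 eta^2 + 2 = 0
    assert sorted(r.eta for r in reps) == pytest.approx([-1.0, 1.0])
    assert solve_equilibria(100.0, -3.0) == []  # no real roots


@pytest.mark.parametrize("eta, k, expected_m1", [
    (1.0, 1.0, -1.01),
    (0.0, 13.0, 2.0),
])
def test_characteristic_coeff_values(eta, k, expected_m1):
    m1, m2, m3 = characteristic_coeffs(eta, k)
    assert m1 == pytest.approx(expected_m1, abs=1e-12)
    if eta == 0.0:
        assert (m1, m2, m3) == pytest.approx((2.0, 1.0, 0.0), abs=1e-12)


def test_characteristic_identity_m2():
    """(lambda + 1) divides the characteristic polynomial: m2 = m1 + m3 - 1."""
    rng = np.random.default_rng(3)
    for _ in range(300):
        eta = rng.uniform(-5, 5)
        k = rng.uniform(-20, 100)
        m1, m2, m3 = characteristic_coeffs(eta, k)
        assert m2 - (m1 + m3 - 1.0) == pytest.approx(0.0, abs=1e-9 * max(1, abs(m2)))


def test_eigenvalues_match_dense_solver():
    from memhr.model import jacobian
    rng = np.random.default_rng(5)
    for _ in range(100):
        eta = rng.uniform(-4, 4)
        k = rng.uniform(-20, 100)
        eigs = np.array(eigenvalues_at(eta, k))
        dense = np.linalg.eigvals(jacobian(eta, ModelParams(k=k)))
        dense = sorted(dense, key=lambda z: (-z.real, -z.imag))
        np.testing.assert_allclose(eigs, dense, atol=1e-7)
        assert min(abs(e - (-1)) for e in eigs) < 1e-9


def test_table_eigenvalue_rows():
    l1, l2, l3 = eigenvalues_at(1.0, 1.0)
    assert l1.real == pytest.approx(1.005, abs=5e-4)
    assert abs(l1.imag) == pytest.approx(2.4413, abs=5e-5)
    assert l3 == pytest.approx(-1.0, abs=1e-9)
    eigs = eigenvalues_at(-2.22, 1.0)
    reals = sorted(e.real for e in eigs)
    assert reals[0] == pytest.approx(-28.8564, abs=5e-5)
    assert reals[2] == pytest.approx(-0.1995, abs=5e-5)


def test_stability_rule():
    assert classify_stability(eigenvalues_at(1.0, 1.0)) == "unstable"
    assert classify_stability(eigenvalues_at(-2.02, 1.0)) == "stable"
    # marginal eigenvalue counts as not-stable under the strict rule
    assert classify_stability((-1.0, -1.0, 0.0)) == "unstable"


@pytest.fixture(scope="module")
def track():
    drive = DriveParams(A1=1.0, f1=0.05, A2=1.0, f2=0.05)
    return equilibrium_track(ModelParams(k=1.0), drive,
                             np.linspace(5.0, 25.0, 801))


class TestEquilibriumTrack:
    def test_row_stabilities(self, track):
        at5 = track[np.isclose(track.t, 5.0)]
        assert set(at5.stability) == {"unstable"}
        at15 = track[np.isclose(track.t, 15.0)]
        assert set(at15.stability) == {"stable"}

    def test_single_root_branch_stable_window(self, track):
        """The unique-equilibrium branch is stable only inside ~(11.64, 18.34)."""
        counts = track.groupby("t").size()
        single = counts[counts == 1].index
        sub = track[track.t.isin(single)]
        stable_ts = sub[sub.stability == "stable"].t
        assert stable_ts.min() == pytest.approx(11.67, abs=0.1)
        assert stable_ts.max() == pytest.approx(18.33, abs=0.1)
        unstable_ts = sub[sub.stability == "unstable"].t
        assert (unstable_ts < 11.6).any() and (unstable_ts > 18.4).any()

    def test_stability_consistent_with_eigenvalue_signs(self, track):
        re_max = track[["re_l1", "re_l2", "re_l3"]].max(axis=1)
        expect = np.where(re_max < -1e-9, "stable", "unstable")
        assert (expect == track.stability).all()

    def test_intervals_helper(self, track):
        ivs = stability_intervals(track)
        assert len(ivs) == 1
        lo, hi = ivs[0]
        assert 9.5 < lo < 12.0 and 18.0 < hi < 21.0
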
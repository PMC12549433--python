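"""Cycle bases, reversibility criteria, and the theta / theta0 fields."""

import numpy as np
import pytest

import qsdwkb as q
from qsdwkb.reversibility import (
    ThetaField,
    check_cycle_condition,
    check_irrotational,
    check_solvability,
    full_report,
    integer_cycle_basis,
    interior_samples,
)

from conftest import competition_two_group


def test_cycle_basis_birth_death_empty(logistic_k2):
    assert integer_cycle_basis(logistic_k2.model.jumps).empty


def test_cycle_basis_one_dimensional_empty():
    assert integer_cycle_basis(((1,), (-1,))).empty


def test_cycle_basis_competition_single_cycle():
    jumps = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))
    basis = integer_cycle_basis(jumps)
    assert len(basis.vectors) == 1
    A = np.array(basis.reps, dtype=int)
    assert np.array_equal(basis.vectors[0] @ A, np.zeros(2, dtype=int))


def test_cycle_condition_discriminates_movement_balance(two_group):
    """PASS iff lam1 nu1 = lam2 nu2 (printed parameters satisfy 1*2 = 2*1)."""
    Y = interior_samples(two_group.model, 32, seed=1)
    assert check_cycle_condition(two_group.model, Y).status == "PASS"

    bad = q.make_two_group(mu=2.9, kappa=0.1, lam1=1.0, lam2=2.0,
                           nu1=3.0, nu2=1.0)
    v = check_cycle_condition(bad.model, interior_samples(bad.model, 32, 1))
    assert v.status == "FAIL"
    # the cycle sum is the constant ln(lam2 nu2 / lam1 nu1)
    assert v.worst_residual == pytest.approx(abs(np.log(2.0 / 3.0)), rel=1e-10)


def test_cycle_condition_competition_constants():
    """Competition family passes iff a1 a4 a5 = a2 a3 a6."""
    ok = competition_two_group(a5=1.0, a6=2.0)      # 1*2*1 = 1*1*2
    bad = competition_two_group(a5=1.0, a6=3.0)
    Y = interior_samples(ok.model, 32, seed=2)
    assert check_cycle_condition(ok.model, Y).status == "PASS"
    assert check_cycle_condition(bad.model, Y).status == "FAIL"


def test_theta_vanishes_at_equilibrium(two_group, two_group_wkb):
    th, resid = q.solve_theta(two_group.model, two_group_wkb.y_star)
    assert np.allclose(th, 0.0, atol=1e-9)
    assert resid < 1e-9


def test_theta_equals_log_death_birth_ratio_for_birth_death(logistic_k2):
    m = logistic_k2.model
    y = np.array([0.4, 0.9])
    th, resid = q.solve_theta(m, y)
    s = y.sum()
    h = [np.log(y[i] * (0.5 + s) / (1.0 * s)) for i in range(2)]
    assert np.allclose(th, h, rtol=1e-12)
    assert resid < 1e-12


def test_theta_closed_forms_competition():
    """theta components follow the explicit log-ratio forms; residual
    vanishes exactly when the cycle constants balance."""
    built = competition_two_group(a5=1.0, a6=2.0)
    mu, kappa, lam1, lam2 = 2.9, 0.1, 1.0, 2.0
    y = np.array([0.3, 0.5])
    th, resid = q.solve_theta(built.model, y)
    s = y.sum()
    th1 = np.log(y[0] * (mu + kappa * s) / (lam1 * s))
    th2 = np.log(y[1] * (mu + kappa * s) / (lam2 * s))
    assert th == pytest.approx([th1, th2], rel=1e-10)
    assert resid < 1e-10


def test_theta_residual_zero_iff_cycle_condition(two_group):
    """Least-squares residual vanishes at interior samples exactly when the
    cycle condition holds (both sides of the lam1 nu1 = lam2 nu2 boundary)."""
    good = two_group.model
    bad = q.make_two_group(mu=2.9, kappa=0.1, lam1=1.0, lam2=2.0,
                           nu1=3.0, nu2=1.0).model
    Y = interior_samples(good, 16, seed=3)
    fg, fb = ThetaField(good), ThetaField(bad)
    _, rg = fg.theta_batch(Y)
    _, rb = fb.theta_batch(Y)
    assert np.max(rg) < 1e-10
    assert np.min(rb) > 1e-3


def test_theta_solution_satisfies_every_equation(two_group):
    """Plug-back: l^T theta equals the log rate ratio for every jump."""
    m = two_group.model
    f = ThetaField(m)
    Y = interior_samples(m, 8, seed=4)
    TH, _ = f.theta_batch(Y)
    for l in m.jumps:
        neg = tuple(-v for v in l)
        rhs = np.log(m.rate_batch(neg, Y) / m.rate_batch(l, Y))
        lhs = TH @ np.asarray(l, dtype=float)
        assert np.allclose(lhs, rhs, atol=1e-10)


def test_theta0_birth_death_closed_form(logistic_k2):
    m = logistic_k2.model
    y = np.array([0.6, 0.8])
    th0, resid = q.solve_theta0(m, y)
    # independent oracle: (1/2) d/dy_i ln(beta_{+e_i} beta_{-e_i}) by central
    # differences of the explicit log rate product
    lam, mu, kappa = 1.0, 0.5, 1.0
    h = 1e-6
    expected = [0.0, 0.0]
    for i in range(2):
        def logprod(z):
            zz = np.asarray(z)
            ssum = zz.sum()
            return (np.log(lam * ssum)
                    + np.log(zz[i] * (mu + kappa * ssum)))
        hi, lo = y.copy(), y.copy()
        hi[i] += h
        lo[i] -= h
        expected[i] = 0.5 * (logprod(hi) - logprod(lo)) / (2 * h)
    assert th0 == pytest.approx(expected, rel=1e-5)
    assert resid < 1e-10


def test_theta0_solvable_iff_b3d3_constant():
    ok = competition_two_group()                     # b3 = d3 = 1
    bad = q.make_competition(
        [1.0, 1.0, 1.0, 2.0, 1.0, 2.0],
        b0=[0, 1], b1=[1], b2=[1], b3=[1, 0.2],
        c0=[1], c1=[1], c2=[1],
        d0=[2.9, 0.1], d1=[0, 1], d2=[0, 1], d3=[1, 0.1],
    )
    Y = interior_samples(ok.model, 16, seed=5)
    assert check_solvability(ThetaField(ok.model), "theta0", Y).status == "PASS"
    assert check_solvability(ThetaField(bad.model), "theta0", Y).status == "FAIL"


def test_one_dimensional_theta0_always_solvable(logistic_k1):
    Y = interior_samples(logistic_k1.model, 8, seed=6)
    v = check_solvability(ThetaField(logistic_k1.model), "theta0", Y)
    assert v.status == "VACUOUS"


def test_irrotationality_two_group_and_sis(two_group, sis2):
    for built in (two_group, sis2):
        Y = interior_samples(built.model, 16, seed=7)
        assert check_irrotational(built.model, "theta", Y).passed
        assert check_irrotational(built.model, "theta0", Y).passed


def test_full_report_applicability(two_group, two_group_nu0, logistic_k2, sis2):
    rep = full_report(two_group.model, 24, seed=0)
    assert rep.correction_ok and not rep.prefactor_ok  # not birth-death

    rep0 = full_report(two_group_nu0.model, 24, seed=0)
    assert rep0.prefactor_ok

    for built in (logistic_k2, sis2):
        rep = full_report(built.model, 24, seed=0)
        assert rep.prefactor_ok
        assert rep.bd_origin_rates.status == "PASS"
        assert rep.bd_equal_births.status == "PASS"


def test_theta_derivative_matches_sigma(two_group, two_group_wkb):
    """d theta / dy at y* equals the Sigma built by the WKB layer."""
    f = ThetaField(two_group.model)
    y = two_group_wkb.y_star
    k = 2
    M = np.empty((k, k))
    for j in range(k):
        h = 1e-6
        hi, lo = y.copy(), y.copy()
        hi[j] += h
        lo[j] -= h
        vals, _ = f.theta_batch(np.stack([hi, lo]))
        M[:, j] = (vals[0] - vals[1]) / (2 * h)
    assert np.allclose(M, two_group_wkb.sigma(), atol=1e-6)
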
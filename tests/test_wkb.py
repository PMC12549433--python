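"""The action V, correction V0, Sigma, and the QSD approximations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qsdwkb as q
from qsdwkb.errors import Divergence, DomainError
from qsdwkb.wkb import PathSpec


def test_potential_zero_at_equilibrium(two_group_wkb):
    assert two_group_wkb.potential(two_group_wkb.y_star) == pytest.approx(0.0, abs=1e-12)


def test_potential_positive_away_from_equilibrium(two_group_wkb):
    rng = np.random.default_rng(0)
    for _ in range(10):
        y = rng.uniform(0.05, 1.2, size=2)
        if np.allclose(y, two_group_wkb.y_star, atol=1e-2):
            continue
        assert two_group_wkb.potential(y) > 0.0


def test_gradient_of_potential_vanishes_at_mode(two_group_wkb):
    w = two_group_wkb
    h = 1e-6
    for j in range(2):
        hi, lo = w.y_star.copy(), w.y_star.copy()
        hi[j] += h
        lo[j] -= h
        g = (w.potential(hi) - w.potential(lo)) / (2 * h)
        assert abs(g) < 1e-6


def test_potential_matches_printed_closed_form(two_group, two_group_wkb):
    ref = two_group.reference
    grid = np.linspace(0.08, 1.1, 6)
    for y1 in grid:
        for y2 in grid:
            V = two_group_wkb.potential(np.array([y1, y2]))
            assert V == pytest.approx(ref.potential((y1, y2)), rel=1e-8, abs=1e-10)


def test_action_at_origin_closed_form(two_group, two_group_wkb):
    # (lam1+lam2-mu)/kappa + (mu/kappa) ln(mu/(lam1+lam2))
    A = two_group_wkb.log_tau_leading()
    assert A == pytest.approx(two_group.reference.action(), rel=1e-9)


def test_action_logistic_closed_form(logistic_k1, logistic_k1_wkb):
    assert logistic_k1_wkb.log_tau_leading() == pytest.approx(
        logistic_k1.reference.action(), rel=1e-9
    )


def test_action_sis_closed_form(sis2):
    w = q.WKB(sis2.model)
    assert w.log_tau_leading() == pytest.approx(sis2.reference.action(), rel=1e-8)


@settings(max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=10 ** 6))
def test_path_independence(two_group_wkb, draw_seed):
    """V agrees along the straight segment and random two-leg paths."""
    w = two_group_wkb
    rng = np.random.default_rng(draw_seed)
    y = rng.uniform(0.08, 1.2, size=2)
    direct = w.potential(y)
    for _ in range(3):
        mid = rng.uniform(0.05, 1.3, size=2)
        via = w.potential(y, path=PathSpec([mid, y]))
        assert via == pytest.approx(direct, abs=1e-6)


def test_potential_batch_matches_adaptive(two_group_wkb):
    rng = np.random.default_rng(3)
    Y = rng.uniform(0.1, 1.0, size=(12, 2))
    V_fast = two_group_wkb.potential_batch(Y)
    V_slow = np.array([two_group_wkb.potential(y) for y in Y])
    assert np.allclose(V_fast, V_slow, atol=1e-9)


def test_correction_zero_at_equilibrium(two_group_wkb):
    assert two_group_wkb.correction(two_group_wkb.y_star) == pytest.approx(0.0, abs=1e-12)


def test_correction_decomposition_independence(two_group_wkb):
    """V0 is independent of the jump decomposition of y - y*."""
    w = two_group_wkb
    y = np.array([0.6, 0.4])
    default = w.correction(y)
    # reversed coordinate order
    d2 = [(y[1] - w.y_star[1], (0, 1)), (y[0] - w.y_star[0], (1, 0))]
    # a three-leg decomposition using the movement jump e_1 - e_2
    c = 0.1
    d3 = [(y[0] - w.y_star[0] - c, (1, 0)), (c, (1, -1)),
          (y[1] - w.y_star[1] + c, (0, 1))]
    assert w.correction(y, d2) == pytest.approx(default, abs=1e-10)
    assert w.correction(y, d3) == pytest.approx(default, abs=1e-10)


def test_correction_diverges_on_boundary(two_group_wkb):
    with pytest.raises((Divergence, DomainError)):
        two_group_wkb.correction(np.array([0.0, 0.5]))


def test_correction_reproduces_nested_product_birth_death(two_group_nu0_wkb):
    """exp(-V0) equals the nested rate-product square root of the explicit
    birth-death QSD formula."""
    w = two_group_nu0_wkb
    m = w.model
    y = np.array([0.5, 0.8])
    v0 = w.correction(y)
    prod = 1.0
    for i in range(2):
        num_pt = np.concatenate([y[:i], w.y_star[i:]])
        den_pt = np.concatenate([y[:i + 1], w.y_star[i + 1:]])
        e = tuple(1 if j == i else 0 for j in range(2))
        ne = tuple(-v for v in e)
        num = m.rate(e, num_pt) * m.rate(ne, num_pt)
        den = m.rate(e, den_pt) * m.rate(ne, den_pt)
        prod *= num / den
    assert np.exp(-v0) == pytest.approx(np.sqrt(prod), rel=1e-10)


def test_sigma_symmetric_and_matches_closed_form(two_group, two_group_wkb):
    S = two_group_wkb.sigma()
    assert np.allclose(S, S.T)
    assert np.allclose(S, two_group.reference.sigma(), atol=2e-7)
    assert np.linalg.det(S) == pytest.approx(
        two_group.reference.det_sigma(), rel=1e-7
    )


def test_sigma_inverse_solves_lyapunov_equation(two_group_wkb):
    """J Sigma^-1 + Sigma^-1 J^T + G = 0 at the stable equilibrium."""
    w = two_group_wkb
    S = w.sigma()
    Sinv = np.linalg.inv(S)
    J = w.drift_jacobian_at_star()
    G = w.diffusion_matrix()
    resid = J @ Sinv + Sinv @ J.T + G
    assert np.max(np.abs(resid)) < 1e-8 * np.max(np.abs(G))
    # Sigma^-1 positive definite
    assert np.all(np.linalg.eigvalsh(Sinv) > 0)


def test_hessian_of_potential_equals_sigma(two_group_wkb):
    w = two_group_wkb
    h = 1e-4
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            pts = []
            for si in (1, -1):
                for sj in (1, -1):
                    y = w.y_star.copy()
                    y[i] += si * h
                    y[j] += sj * h
                    pts.append(si * sj * w.potential(y))
            H[i, j] = sum(pts) / (4 * h * h)
    assert np.allclose(H, w.sigma(), atol=1e-5)


def test_rates_balance_at_equilibrium(two_group, two_group_wkb):
    """beta_l(y*) = beta_{-l}(y*) for every jump (detailed balance at the
    interior equilibrium)."""
    m = two_group.model
    y = two_group_wkb.y_star
    for l in m.jumps:
        neg = tuple(-v for v in l)
        assert m.rate(l, y) == pytest.approx(m.rate(neg, y), rel=1e-10)


def test_qsd_at_mode_equals_prefactor(two_group_wkb):
    w = two_group_wkb
    N = 90  # N y* = (30, 60) is a lattice point: V = V0 = 0 exactly
    x = np.rint(N * w.y_star).astype(int)
    assert w.wkb_qsd(N, x) == pytest.approx(w.prefactor(N), rel=1e-9)


def test_qsd_matches_printed_formula(two_group, two_group_wkb):
    N = 100
    rng = np.random.default_rng(8)
    X = rng.integers(8, 120, size=(40, 2))
    lw = two_group_wkb.log_wkb_qsd_batch(N, X)
    ref = np.array([two_group.reference.qsd(N, x) for x in X])
    assert np.allclose(np.exp(lw), ref, rtol=1e-8)


def test_qsd_mass_near_one_outside_boundary_layer(two_group_wkb):
    """The WKB mass over a generous interior grid, excluding the boundary
    layer (where the correction diverges), is close to 1 at N=100."""
    w = two_group_wkb
    N = 100
    caps = np.ceil(3 * N * w.y_star).astype(int)
    g1, g2 = np.meshgrid(np.arange(1, caps[0] + 1), np.arange(1, caps[1] + 1),
                         indexing="ij")
    X = np.column_stack([g1.ravel(), g2.ravel()])
    X = X[np.all(X >= N * w.boundary_layer(N), axis=1)]
    mass = float(np.exp(w.log_wkb_qsd_batch(N, X)).sum())
    assert 0.95 < mass < 1.05


def test_gaussian_agrees_with_wkb_near_mode(two_group_wkb):
    """Within |x - N y*| = O(sqrt(N)) the two approximations agree to first
    order: the log-mass gap is small and shrinks as N grows."""
    w = two_group_wkb
    rng = np.random.default_rng(9)
    gaps = []
    for N in (400, 1600):
        x0 = np.rint(N * w.y_star)
        r = int(np.sqrt(N) / 2)
        X = x0 + rng.integers(-r, r + 1, size=(30, 2))
        lw = w.log_wkb_qsd_batch(N, X)
        lg = w.log_gaussian_qsd_batch(N, X)
        gaps.append(float(np.max(np.abs(lw - lg))))
    assert gaps[0] < 0.2
    assert gaps[1] < gaps[0]
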
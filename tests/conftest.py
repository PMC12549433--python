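import numpy as np
import pytest

import qsdwkb as q

# printed parameter set used throughout the two-group illustrations
TWO_GROUP_PARAMS = dict(mu=2.9, kappa=0.1, lam1=1.0, lam2=2.0, nu1=2.0, nu2=1.0)


@pytest.fixture(scope="session")
def two_group():
    """Two-group movement model at the printed parameters."""
    return q.make_two_group(**TWO_GROUP_PARAMS)


@pytest.fixture(scope="session")
def two_group_nu0():
    """Two-group model without movement (pure birth-death, lam1 != lam2)."""
    return q.make_two_group(mu=2.9, kappa=0.1, lam1=1.0, lam2=2.0,
                            nu1=0.0, nu2=0.0)


@pytest.fixture(scope="session")
def logistic_k1():
    """One-type linear-birth/quadratic-death model in its asymptotic regime."""
    return q.make_logistic(k=1, lam=3.0, mu=1.0, kappa=4.0)


@pytest.fixture(scope="session")
def logistic_k2():
    return q.make_logistic(k=2, lam=1.0, mu=0.5, kappa=1.0)


@pytest.fixture(scope="session")
def sis2():
    """Two-group SIS model with heterogeneous susceptibilities."""
    return q.make_sis(beta=2.0, mu=[0.8, 1.2], alpha=[1.0, 1.5], f=[0.5, 0.5])


@pytest.fixture(scope="session")
def two_group_wkb(two_group):
    eq = q.find_equilibria(two_group.model)
    return q.WKB(two_group.model, equilibrium=eq)


@pytest.fixture(scope="session")
def two_group_nu0_wkb(two_group_nu0):
    eq = q.find_equilibria(two_group_nu0.model)
    return q.WKB(two_group_nu0.model, equilibrium=eq)


@pytest.fixture(scope="session")
def logistic_k1_wkb(logistic_k1):
    eq = q.find_equilibria(logistic_k1.model)
    return q.WKB(logistic_k1.model, equilibrium=eq)


def competition_two_group(a5=1.0, a6=2.0):
    """The two-group movement model expressed in the competition-family
    factorisation (a2=lam1, a4=lam2, a5=nu2, a6=nu1, d0(u)=mu+kappa*u)."""
    return q.make_competition(
        [1.0, 1.0, 1.0, 2.0, a5, a6],
        b0=[0, 1], b1=[1], b2=[1], b3=[1],
        c0=[1], c1=[1], c2=[1],
        d0=[2.9, 0.1], d1=[0, 1], d2=[0, 1], d3=[1],
    )
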
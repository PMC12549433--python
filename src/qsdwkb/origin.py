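"""Near-origin linearisation of multitype birth-death processes.

Close to the origin the process is approximated by a linear multitype
birth-death process in which a type-j individual produces type-i offspring
at rate ``b_ij`` and type-i individuals die at per-capita rate ``d_i``, the
constants being one-sided derivatives of the rate functions at 0.  When the
birth rates satisfy ``b_ij = b_ii`` (each type reproduces at a rate
proportional to total population regardless of composition), the linearised
balance equation has an explicit solution ``u~_x`` involving the unique
positive root ``D`` of ``sum_i b_ii / (D + d_i) = 1``.  Matching ``u~``
against the WKB body of the quasistationary distribution fixes its
normalisation ``Lambda`` and yields the full Eyring-Kramers-type asymptotics

    tau^(N) ~ (Lambda D)^(-1),

i.e. an explicit prefactor multiplying ``exp(N V(0))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .errors import (
    CriteriaViolation,
    DomainError,
    NotBirthDeath,
    Subcritical,
)
from .process import PopulationProcess
from .wkb import WKB

#: relative tolerance for the equal-birth-rates condition b_ij = b_ii
EQUAL_BIRTHS_TOL = 1e-8


@dataclass
class OriginLinearisation:
    """Linear birth-death approximation of the process at the origin.

    ``b[i, j]`` is the rate at which a type-j individual produces type-i
    offspring; ``d[i]`` the per-capita death rate of type i.  ``D`` (set by
    :func:`solve_D`) is the decay-rate root of the linear process; ``Lambda``
    the WKB-matched normaliser of the near-origin solution.
    """

    b: np.ndarray
    d: np.ndarray
    D: Optional[float] = None
    Lambda: Optional[float] = None

    @property
    def k(self) -> int:
        return len(self.d)

    @property
    def supercritical(self) -> bool:
        return float(np.sum(np.diag(self.b) / self.d)) > 1.0

    @property
    def origin_rates_ok(self) -> bool:
        """d_i > 0 and every row of b has a positive entry."""
        return bool(np.all(self.d > 0.0) and np.all(np.max(self.b, axis=1) > 0.0))

    @property
    def equal_births(self) -> bool:
        """b_ij = b_ii for all j (required for the explicit u~)."""
        scale = max(float(np.max(np.abs(self.b))), 1e-300)
        return bool(
            np.max(np.abs(self.b - np.diag(self.b)[:, None])) < EQUAL_BIRTHS_TOL * scale
        )


def linearise_origin(model: PopulationProcess) -> OriginLinearisation:
    """One-sided derivatives of the birth/death rates at the origin.

    Requires the multitype birth-death jump set; verifies that the death rate
    of type i has no cross-derivative at the origin (a structural consequence
    of the boundary assumptions).
    """
    if not model.is_birth_death:
        raise NotBirthDeath(
            f"{model.name}: origin linearisation requires jumps {{±e_i}}"
        )
    k = model.k
    zero = np.zeros(k)
    b = np.empty((k, k))
    d = np.empty(k)
    for i in range(k):
        e = tuple(1 if j == i else 0 for j in range(k))
        ne = tuple(-v for v in e)
        b[i] = model.rate_gradient(e, zero)
        gd = model.rate_gradient(ne, zero)
        d[i] = gd[i]
        cross = np.delete(gd, i)
        if np.any(np.abs(cross) > 1e-6 * (1.0 + abs(d[i]))):
            raise CriteriaViolation(
                f"{model.name}: death rate for type {i} has a nonzero "
                f"cross-derivative at the origin ({cross})"
            )
    return OriginLinearisation(b=b, d=d)


def solve_D(lin: OriginLinearisation) -> float:
    """Unique positive root of ``sum_i b_ii / (D + d_i) = 1``.

    Exists iff the linearised process is supercritical,
    ``sum_i b_ii / d_i > 1``; solved by bracketing and Brent's method on
    ``(0, sum_i b_ii)``.
    """
    if not lin.origin_rates_ok:
        raise Subcritical(
            "origin linearisation violates d_i > 0 / positive birth rows"
        )
    if not lin.supercritical:
        raise Subcritical(
            f"sum b_ii/d_i = {float(np.sum(np.diag(lin.b) / lin.d)):.6g} <= 1: "
            "no positive root"
        )
    bii = np.diag(lin.b)

    def g(D):
        return float(np.sum(bii / (D + lin.d))) - 1.0

    hi = float(np.sum(bii))
    # g(0+) > 0 by supercriticality; g(sum b_ii) < 0 since each term < b_ii/hi
    D = optimize.brentq(g, 1e-300, hi, xtol=1e-15, rtol=1e-14)
    lin.D = float(D)
    return lin.D


def log_u_tilde(lin: OriginLinearisation, x) -> float:
    """Log of the unnormalised near-origin weight ``u~_x / Lambda``.

    Computed entirely in log-space (log-gamma for the multinomial factor and
    ``expm1`` for the difference of the two death-rate products) so that
    large ``|x|`` neither overflows nor cancels catastrophically.
    """
    x = np.asarray(x, dtype=int)
    if np.any(x < 0) or not np.any(x):
        raise DomainError("u~ is defined for nonzero nonnegative states only")
    if lin.D is None:
        solve_D(lin)
    s = int(np.sum(x))
    bii = np.diag(lin.b)
    out = -np.log(s) + gammaln(s + 1) - float(np.sum(gammaln(x + 1)))
    out += float(np.sum(x * np.log(bii)))
    a = -float(np.sum(x * np.log(lin.d)))          # log prod d_i^{-x_i}
    c = -float(np.sum(x * np.log(lin.D + lin.d)))  # log prod (D+d_i)^{-x_i}
    # a > c strictly since D > 0, so the bracket is positive
    out += a + np.log(-np.expm1(c - a))
    return out


def u_tilde(lin: OriginLinearisation, x) -> float:
    """Unnormalised near-origin weight (``Lambda`` excluded); always > 0."""
    return float(np.exp(log_u_tilde(lin, x)))


def _partial_equilibrium_points(y_star: np.ndarray):
    """Points (0,...,0, y*_i, ..., y*_k) for i = 1..k+1 (coordinate order)."""
    k = len(y_star)
    pts = []
    for i in range(k + 1):
        p = y_star.copy()
        p[:i] = 0.0
        pts.append(p)
    return pts  # pts[i] has zeros in the first i coordinates


def log_lambda(model: PopulationProcess, N: int, wkb: WKB,
               lin: OriginLinearisation) -> float:
    """Log of the matched normaliser ``Lambda`` of the near-origin solution.

    Combines ``det Sigma``, products of birth/death rates at the partial
    equilibria ``(0,...,0, y*_i,...,y*_k)``, the one-sided death-rate
    derivatives at ``(0,...,0, y*_{i+1},...,y*_k)``, the last-coordinate
    birth coefficient ``b_kk``, and ``exp(-N V(0))``.
    """
    k = model.k
    y_star = wkb.y_star
    pts = _partial_equilibrium_points(y_star)
    det = float(np.linalg.det(wkb.sigma()))
    if det <= 0.0:
        raise CriteriaViolation(f"det Sigma = {det} not positive")
    log_num = np.log(N * det / (2.0 * np.pi))
    for i in range(k):
        e = tuple(1 if j == i else 0 for j in range(k))
        ne = tuple(-v for v in e)
        p = pts[i]       # zeros in first i coords: (0,..,0, y*_{i+1..k}) shifted
        be = model.rate(e, p)
        bd = model.rate(ne, p)
        if be <= 0.0 or bd <= 0.0:
            raise CriteriaViolation(
                f"rate product vanishes at partial equilibrium {p}"
            )
        log_num += np.log(be) + np.log(bd)
    log_den = np.log(np.diag(lin.b)[k - 1])  # b_kk
    for i in range(k):
        e = tuple(1 if j == i else 0 for j in range(k))
        ne = tuple(-v for v in e)
        q = pts[i + 1]   # zeros in first i+1 coords
        dd = model.rate_gradient(ne, q)[i]
        if dd <= 0.0:
            raise CriteriaViolation(
                f"one-sided death derivative non-positive at {q}"
            )
        log_den += np.log(dd)
        if i < k - 1:
            be = model.rate(e, q)
            if be <= 0.0:
                raise CriteriaViolation(f"birth rate vanishes at {q}")
            log_den += np.log(be)
    A = wkb.log_tau_leading()
    return 0.5 * (log_num - log_den) - N * A


def tau_full(model: PopulationProcess, N: int, wkb: Optional[WKB] = None,
             check: bool = True) -> float:
    """Full WKB approximation ``tau = 1 / (Lambda D)`` of the mean time from
    quasistationarity to extinction (multitype birth-death only).

    With ``check=True`` (default) the cheap structural conditions — the
    birth-death jump set, positive origin rates with supercriticality, and
    equal birth rates ``b_ij = b_ii`` — are verified and a violation raises
    :class:`~qsdwkb.errors.CriteriaViolation`; the irrotationality criteria
    are assumed (check them via :func:`qsdwkb.reversibility.full_report`).
    """
    lin = linearise_origin(model)
    if check:
        if not lin.origin_rates_ok or not lin.supercritical:
            raise Subcritical(
                f"{model.name}: origin linearisation not supercritical"
            )
        if not lin.equal_births:
            raise CriteriaViolation(
                f"{model.name}: b_ij = b_ii fails; the explicit prefactor "
                "requires equal birth rates"
            )
    if wkb is None:
        wkb = WKB(model)
    D = solve_D(lin)
    lam = log_lambda(model, N, wkb, lin)
    lin.Lambda = float(np.exp(lam))
    return float(np.exp(-lam) / D)


def log_tau_full(model: PopulationProcess, N: int,
                 wkb: Optional[WKB] = None, check: bool = True) -> float:
    """``ln tau`` from the full prefactor formula (overflow-safe for large N)."""
    lin = linearise_origin(model)
    if check and (not lin.origin_rates_ok or not lin.supercritical):
        raise Subcritical(f"{model.name}: not supercritical at the origin")
    if check and not lin.equal_births:
        raise CriteriaViolation(f"{model.name}: b_ij = b_ii fails")
    if wkb is None:
        wkb = WKB(model)
    D = solve_D(lin)
    return -log_lambda(model, N, wkb, lin) - float(np.log(D))
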
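"""Asymptotic Kolmogorov reversibility criteria and the fields theta, theta0.

The quasistationary WKB machinery applies when asymptotic analogues of
Kolmogorov's cycle criterion hold.  Writing one representative ``l`` per
``±l`` pair, the criteria are:

* cycle condition — for every integer combination with ``sum a_i l_i = 0``,
  ``sum a_i ln(beta_{-l_i}(y) / beta_{l_i}(y)) = 0`` on the interior
  (guarantees the overdetermined system ``l^T theta = ln(beta_{-l}/beta_l)``
  is consistent);
* irrotationality of ``theta`` — its derivative matrix is symmetric, so
  ``theta`` is a gradient and the action ``V`` exists;
* the analogous pair for the subleading field ``theta0`` with right-hand
  sides ``(1/2) l^T d/dy ln(beta_{-l} beta_l)``.

For multitype birth-death jump sets the cycle conditions are vacuous and the
criteria reduce to symmetry of the derivative matrices of the closed-form
fields ``h`` and ``h0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import sympy
from scipy.stats import qmc

from .errors import ModelError, NumericError, QsdwkbError
from .process import PopulationProcess, _default_guess

#: default relative tolerance for a criterion PASS
CRITERIA_TOL = 1e-8

PASS, FAIL, VACUOUS = "PASS", "FAIL", "VACUOUS"


def representatives(jumps: Sequence[tuple]) -> list[tuple]:
    """One canonical representative per ±pair (first nonzero entry positive)."""
    reps = []
    seen = set()
    for l in sorted(jumps):
        neg = tuple(-v for v in l)
        if l in seen or neg in seen:
            continue
        seen.add(l)
        first = next(v for v in l if v != 0)
        reps.append(l if first > 0 else neg)
    return reps


@dataclass
class CycleBasis:
    """Integer basis of {a : sum_i a_i l_i = 0} over the jump representatives."""

    reps: list[tuple]
    vectors: list[np.ndarray]

    @property
    def empty(self) -> bool:
        return len(self.vectors) == 0


def integer_cycle_basis(jumps: Sequence[tuple]) -> CycleBasis:
    """Integer nullspace basis of the representative jump matrix.

    An empty basis means the cycle conditions hold vacuously (e.g. any
    multitype birth-death jump set, where the number of ±pairs equals the
    rank k).
    """
    reps = representatives(jumps)
    A = sympy.Matrix([list(l) for l in reps]).T  # k x n, columns are jumps
    basis = []
    for v in A.nullspace():
        denoms = [sympy.fraction(sympy.nsimplify(c))[1] for c in v]
        scale = sympy.lcm([sympy.Integer(d) for d in denoms]) if denoms else 1
        w = [sympy.Integer(c * scale) for c in v]
        g = sympy.gcd([c for c in w if c != 0]) or 1
        basis.append(np.array([int(c / g) for c in w], dtype=int))
    return CycleBasis(reps=reps, vectors=basis)


def _log_ratio(model: PopulationProcess, l, Y: np.ndarray) -> np.ndarray:
    """ln(beta_{-l}(Y) / beta_l(Y)) for interior points Y of shape (m, k)."""
    neg = tuple(-v for v in l)
    num = model.rate_batch(neg, Y)
    den = model.rate_batch(l, Y)
    if np.any(num <= 0.0) or np.any(den <= 0.0):
        raise QsdwkbError(
            f"rate for jump {l} vanishes at an interior sample point "
            "(violates interior positivity)"
        )
    return np.log(num) - np.log(den)


@dataclass
class Verdict:
    status: str
    worst_residual: float = 0.0
    witness: Optional[np.ndarray] = None

    @property
    def passed(self) -> bool:
        return self.status in (PASS, VACUOUS)


def check_cycle_condition(
    model: PopulationProcess,
    sample_points: np.ndarray,
    tol: float = CRITERIA_TOL,
    basis: Optional[CycleBasis] = None,
) -> Verdict:
    """Leading-order cycle condition on a basis of integer jump cycles.

    By linearity of the log-ratio sums it suffices to check a basis of the
    integer nullspace rather than all finite integer combinations.
    """
    if basis is None:
        basis = integer_cycle_basis(model.jumps)
    if basis.empty:
        return Verdict(VACUOUS)
    Y = np.atleast_2d(np.asarray(sample_points, dtype=float))
    logs = np.stack([_log_ratio(model, l, Y) for l in basis.reps])  # (n, m)
    worst, witness = 0.0, None
    for a in basis.vectors:
        vals = a @ logs
        i = int(np.argmax(np.abs(vals)))
        if abs(vals[i]) > worst:
            worst, witness = abs(vals[i]), Y[i]
    return Verdict(PASS if worst < tol else FAIL, worst, witness)


class ThetaField:
    """Evaluators for the fields theta(y) and theta0(y).

    ``theta(y)`` solves the overdetermined system
    ``l^T theta = ln(beta_{-l}(y)/beta_l(y))`` over one representative per
    ±pair, in the least-squares sense; ``theta0(y)`` solves the analogous
    system with right-hand sides ``(1/2) l^T d/dy ln(beta_{-l} beta_l)``.
    Residual norms of the solves are recorded at each evaluation: they vanish
    (to tolerance) exactly when the corresponding consistency criterion holds.
    """

    def __init__(self, model: PopulationProcess):
        self.model = model
        self.reps = representatives(model.jumps)
        self.A = np.array(self.reps, dtype=float)  # (n, k)
        if np.linalg.matrix_rank(self.A) < model.k:
            raise ModelError("jump set must span R^k for theta to be defined")
        self.pinv = np.linalg.pinv(self.A)  # (k, n)
        self.last_theta_residual: float = 0.0
        self.last_theta0_residual: float = 0.0

    # -- theta ---------------------------------------------------------------

    def theta_batch(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """theta at points Y of shape (m, k); returns (theta (m,k), residuals)."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        R = np.stack([_log_ratio(self.model, l, Y) for l in self.reps])  # (n, m)
        TH = self.pinv @ R  # (k, m)
        resid = np.max(np.abs(self.A @ TH - R), axis=0)
        return TH.T, resid

    def theta(self, y) -> np.ndarray:
        th, r = self.theta_batch(np.asarray(y, dtype=float)[None, :])
        self.last_theta_residual = float(r[0])
        return th[0]

    # -- theta0 --------------------------------------------------------------

    def _theta0_rhs(self, Y: np.ndarray) -> np.ndarray:
        """(1/2) l^T grad ln(beta_{-l} beta_l) for each representative l."""
        rows = []
        for l in self.reps:
            neg = tuple(-v for v in l)
            gl = self.model.rate_gradient_batch(l, Y)
            gn = self.model.rate_gradient_batch(neg, Y)
            bl = self.model.rate_batch(l, Y)[:, None]
            bn = self.model.rate_batch(neg, Y)[:, None]
            grad_log = gl / bl + gn / bn  # (m, k)
            rows.append(0.5 * (grad_log @ np.asarray(l, dtype=float)))
        return np.stack(rows)  # (n, m)

    def theta0_batch(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        R = self._theta0_rhs(Y)
        TH = self.pinv @ R
        resid = np.max(np.abs(self.A @ TH - R), axis=0)
        return TH.T, resid

    def theta0(self, y) -> np.ndarray:
        th, r = self.theta0_batch(np.asarray(y, dtype=float)[None, :])
        self.last_theta0_residual = float(r[0])
        return th[0]


def solve_theta(model: PopulationProcess, y) -> tuple[np.ndarray, float]:
    """theta(y) with the least-squares residual of the solve."""
    f = ThetaField(model)
    th = f.theta(y)
    return th, f.last_theta_residual


def solve_theta0(model: PopulationProcess, y) -> tuple[np.ndarray, float]:
    """theta0(y) with the least-squares residual of the solve."""
    f = ThetaField(model)
    th = f.theta0(y)
    return th, f.last_theta0_residual


def check_solvability(
    field: ThetaField, which: str, sample_points: np.ndarray,
    tol: float = CRITERIA_TOL,
) -> Verdict:
    """Consistency of the overdetermined system for theta or theta0.

    A square system (one ±pair per dimension) is vacuously consistent.
    """
    Y = np.atleast_2d(np.asarray(sample_points, dtype=float))
    if len(field.reps) == field.model.k:
        return Verdict(VACUOUS)
    if which == "theta":
        _, resid = field.theta_batch(Y)
    else:
        _, resid = field.theta0_batch(Y)
    i = int(np.argmax(resid))
    worst = float(resid[i])
    return Verdict(PASS if worst < tol else FAIL, worst, Y[i])


def check_irrotational(
    model: PopulationProcess,
    which: str,
    sample_points: np.ndarray,
    tol: float = 1e-6,
    boundary_cutoff: float = 1e-3,
) -> Verdict:
    """Symmetry of the derivative matrix of theta (or theta0) at samples.

    Implements the parallelogram-loop criteria: the field is the gradient of
    a scalar potential iff its derivative matrix is symmetric.  Points closer
    to the boundary than ``boundary_cutoff`` (relative to the box side) are
    skipped.  Differentiation is central finite differences.
    """
    field = ThetaField(model)
    fn = field.theta_batch if which == "theta" else field.theta0_batch
    Y = np.atleast_2d(np.asarray(sample_points, dtype=float))
    ub = model.upper_bounds()
    span = np.where(np.isfinite(ub), ub, 2.0 * _default_guess(model))
    keep = np.all((Y > boundary_cutoff * span) &
                  (Y < span - boundary_cutoff * span), axis=1)
    Y = Y[keep]
    if Y.shape[0] == 0:
        raise NumericError("all sample points too close to the boundary")
    worst, witness = 0.0, None
    k = model.k
    for y in Y:
        M = np.empty((k, k))
        for j in range(k):
            h = 1e-6 * (1.0 + abs(y[j]))
            hi, lo = y.copy(), y.copy()
            hi[j] += h
            lo[j] -= h
            vals, _ = fn(np.stack([hi, lo]))
            M[:, j] = (vals[0] - vals[1]) / (2.0 * h)
        asym = float(np.max(np.abs(M - M.T)) / (1.0 + np.max(np.abs(M))))
        if asym > worst:
            worst, witness = asym, y
    return Verdict(PASS if worst < tol else FAIL, worst, witness)


@dataclass
class CriteriaReport:
    """Per-condition verdicts and the WKB results they enable.

    ``cycle`` / ``theta_consistent`` — consistency of the theta system;
    ``theta_irrotational`` — theta is a gradient field;
    ``cycle0`` / ``theta0_consistent`` — consistency of the theta0 system;
    ``theta0_irrotational`` — theta0 is a gradient field.
    Birth-death specialisations (origin rates, b_ij = b_ii) are reported only
    for jump sets {±e_i}.
    """

    model_name: str
    cycle: Verdict
    theta_consistent: Verdict
    theta_irrotational: Verdict
    cycle0: Verdict
    theta0_consistent: Verdict
    theta0_irrotational: Verdict
    bd_origin_rates: Optional[Verdict] = None  # condition on d_i, b_ij at 0
    bd_equal_births: Optional[Verdict] = None  # b_ij = b_ii
    sample_points: Optional[np.ndarray] = None

    @property
    def leading_order_ok(self) -> bool:
        """V(y) and the leading extinction-time exponent are available."""
        return (self.cycle.passed and self.theta_consistent.passed
                and self.theta_irrotational.passed)

    @property
    def correction_ok(self) -> bool:
        """V0(y) and the full WKB quasistationary approximation are available."""
        return (self.leading_order_ok and self.cycle0.passed
                and self.theta0_consistent.passed
                and self.theta0_irrotational.passed)

    @property
    def prefactor_ok(self) -> bool:
        """The full extinction-time prefactor (birth-death only) is available."""
        return (self.correction_ok
                and self.bd_origin_rates is not None
                and self.bd_origin_rates.passed
                and self.bd_equal_births is not None
                and self.bd_equal_births.passed)

    def applicable_results(self) -> list[str]:
        out = []
        if self.leading_order_ok:
            out.append("leading-order extinction exponent")
        if self.correction_ok:
            out.append("WKB quasistationary distribution")
        if self.prefactor_ok:
            out.append("full extinction-time prefactor")
        return out

    def as_dict(self) -> dict:
        def v(x):
            if x is None:
                return None
            return {"status": x.status, "worst_residual": x.worst_residual}

        return {
            "model": self.model_name,
            "cycle": v(self.cycle),
            "theta_consistent": v(self.theta_consistent),
            "theta_irrotational": v(self.theta_irrotational),
            "cycle0": v(self.cycle0),
            "theta0_consistent": v(self.theta0_consistent),
            "theta0_irrotational": v(self.theta0_irrotational),
            "bd_origin_rates": v(self.bd_origin_rates),
            "bd_equal_births": v(self.bd_equal_births),
            "applicable": self.applicable_results(),
        }


def interior_samples(
    model: PopulationProcess, n: int = 64, seed: int = 0, inset: float = 0.01
) -> np.ndarray:
    """Scrambled low-discrepancy interior sample of the continuous space.

    Unbounded models are sampled in the box [0, 2] per coordinate (around the
    all-ones default scale); box models in their own box, inset by ``inset``
    of each side.
    """
    ub = model.upper_bounds()
    span = np.where(np.isfinite(ub), ub, 2.0 * _default_guess(model))
    sampler = qmc.Sobol(d=model.k, scramble=True, seed=seed)
    U = sampler.random_base2(max(int(np.ceil(np.log2(max(n, 1)))), 0))[:n]
    return (inset + (1.0 - 2.0 * inset) * U) * span


def check_cycle0_condition(
    model: PopulationProcess,
    sample_points: np.ndarray,
    tol: float = CRITERIA_TOL,
    basis: Optional[CycleBasis] = None,
) -> Verdict:
    """Second-order cycle condition: cycles annihilate the theta0 right-hand
    sides (equivalently the theta0 system is consistent)."""
    if basis is None:
        basis = integer_cycle_basis(model.jumps)
    if basis.empty:
        return Verdict(VACUOUS)
    field = ThetaField(model)
    Y = np.atleast_2d(np.asarray(sample_points, dtype=float))
    R = field._theta0_rhs(Y)  # (n, m)
    worst, witness = 0.0, None
    for a in basis.vectors:
        vals = a @ R
        i = int(np.argmax(np.abs(vals)))
        if abs(vals[i]) > worst:
            worst, witness = abs(vals[i]), Y[i]
    return Verdict(PASS if worst < tol else FAIL, worst, witness)


def full_report(
    model: PopulationProcess, n_samples: int = 64, seed: int = 0,
    tol: float = CRITERIA_TOL,
) -> CriteriaReport:
    """Evaluate all applicable reversibility criteria on a seeded sample."""
    Y = interior_samples(model, n_samples, seed)
    basis = integer_cycle_basis(model.jumps)
    field = ThetaField(model)
    cycle = check_cycle_condition(model, Y, tol, basis)
    th_cons = check_solvability(field, "theta", Y, tol)
    th_irr = check_irrotational(model, "theta", Y)
    cycle0 = check_cycle0_condition(model, Y, tol, basis)
    th0_cons = check_solvability(field, "theta0", Y, tol)
    th0_irr = check_irrotational(model, "theta0", Y)

    bd_rates = bd_equal = None
    if model.is_birth_death:
        b, d = _origin_coefficients(model)
        ok = np.all(d > 0.0) and np.all(np.max(b, axis=1) > 0.0)
        bd_rates = Verdict(PASS if ok else FAIL,
                           float(min(np.min(d), np.max(b))))
        scale = max(np.max(np.abs(b)), 1e-300)
        dev = float(np.max(np.abs(b - np.diag(b)[:, None])) / scale)
        bd_equal = Verdict(PASS if dev < tol else FAIL, dev)

    return CriteriaReport(
        model_name=model.name,
        cycle=cycle,
        theta_consistent=th_cons,
        theta_irrotational=th_irr,
        cycle0=cycle0,
        theta0_consistent=th0_cons,
        theta0_irrotational=th0_irr,
        bd_origin_rates=bd_rates,
        bd_equal_births=bd_equal,
        sample_points=Y,
    )


def _origin_coefficients(model: PopulationProcess) -> tuple[np.ndarray, np.ndarray]:
    """Birth matrix b_ij and death vector d_i of the origin linearisation."""
    k = model.k
    zero = np.zeros(k)
    b = np.empty((k, k))
    d = np.empty(k)
    for i in range(k):
        e = tuple(1 if j == i else 0 for j in range(k))
        ne = tuple(-v for v in e)
        b[i] = model.rate_gradient(e, zero)
        d[i] = model.rate_gradient(ne, zero)[i]
    return b, d
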
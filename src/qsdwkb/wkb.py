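"""WKB objects: the action V, the correction V0, Sigma, and the QSD forms.

Under the reversibility criteria the quasistationary distribution admits the
representation ``u_x ~ M_N exp(-N V(y) - V0(y))`` with ``y = x/N``, where

* ``V(y) = int_Gamma theta . dy'`` along any path from ``y*`` to ``y``
  (path-independent; the action / large-deviation potential),
* ``V0(y)`` integrates the subleading field ``theta0`` and can be written as
  a telescoping sum of log rate-products over any jump decomposition of
  ``y - y*``,
* ``Sigma = d theta / dy`` at ``y*`` is the Hessian of ``V`` at the mode and
  fixes the Gaussian normalisation ``M_N = sqrt(det Sigma / (2 pi N)^k)``.

The leading-order mean time from quasistationarity to extinction satisfies
``ln(tau) / N -> V(0)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate

from .errors import (
    CriteriaViolation,
    Divergence,
    DivergentAction,
    DomainError,
)
from .process import PopulationProcess, find_equilibria, jacobian
from .reversibility import CriteriaReport, ThetaField, full_report


@dataclass
class PathSpec:
    """Ordered waypoints of a piecewise-linear integration path.

    Waypoints exclude the starting point ``y*``; consecutive segments must
    stay inside the continuous state space (which is convex, so segments
    between points of the space automatically do).
    """

    waypoints: Sequence[np.ndarray]


class WKB:
    """WKB machinery for a validated population process.

    Parameters
    ----------
    model
        The population process.
    equilibrium
        Optional precomputed :class:`~qsdwkb.process.EquilibriumReport`.
    check_criteria
        When True, evaluate the reversibility criteria up front and refuse
        QSD evaluations if they fail.
    """

    def __init__(self, model: PopulationProcess, equilibrium=None,
                 check_criteria: bool = False, seed: int = 0):
        self.model = model
        self.eq = equilibrium if equilibrium is not None else find_equilibria(model)
        self.y_star = np.asarray(self.eq.y_star, dtype=float)
        self.field = ThetaField(model)
        self.report: Optional[CriteriaReport] = None
        if check_criteria:
            self.report = full_report(model, seed=seed)
        self._sigma: Optional[np.ndarray] = None

    # -- the action V --------------------------------------------------------

    def _segment_integral(self, a: np.ndarray, b: np.ndarray,
                          epsabs: float) -> float:
        """Line integral of theta over the straight segment a -> b."""
        d = b - a
        if not np.any(d):
            return 0.0

        def g(t):
            th = self.field.theta(a + t * d)
            return float(th @ d)

        val, err = integrate.quad(g, 0.0, 1.0, epsabs=epsabs, limit=200)
        if not np.isfinite(val) or err > max(1e3 * epsabs, 1e-6 * abs(val) + 1e-8):
            raise DivergentAction(
                f"action integral along segment {a} -> {b} did not converge "
                f"(value {val}, error estimate {err})"
            )
        return val

    def potential(self, y, path: Optional[PathSpec] = None,
                  epsabs: float = 1e-10) -> float:
        """The action ``V(y) = int theta . dy'`` from ``y*`` to ``y``.

        The default path is the straight segment (the state space is convex,
        so it never leaves the space).  Endpoints on the boundary, where the
        integrand has logarithmic singularities, are handled by the adaptive
        quadrature, which never evaluates at the endpoints themselves; a
        genuinely divergent endpoint integral raises
        :class:`~qsdwkb.errors.DivergentAction`.
        """
        y = np.asarray(y, dtype=float)
        if not self.model.in_space(y, tol=1e-12):
            raise DomainError(f"{y} outside the state space")
        pts = [self.y_star]
        if path is not None:
            pts += [np.asarray(w, dtype=float) for w in path.waypoints]
            if not np.allclose(pts[-1], y, atol=1e-12):
                pts.append(y)
        else:
            pts.append(y)
        total = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            total += self._segment_integral(a, b, epsabs)
        return total

    def potential_batch(self, Y: np.ndarray, n_nodes: int = 128) -> np.ndarray:
        """Vectorised ``V`` on straight segments to each row of ``Y``.

        Fixed-order Gauss-Legendre quadrature, vectorised through the batch
        theta solver; intended for interior grids (QSD evaluation), where the
        integrand is smooth and convergence is spectral.
        """
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        t, w = np.polynomial.legendre.leggauss(n_nodes)
        t = 0.5 * (t + 1.0)
        w = 0.5 * w
        D = Y - self.y_star  # (m, k)
        out = np.zeros(Y.shape[0])
        for ti, wi in zip(t, w):
            P = self.y_star + ti * D
            th, _ = self.field.theta_batch(P)
            out += wi * np.sum(th * D, axis=1)
        return out

    # -- the correction V0 ---------------------------------------------------

    def _default_decomposition(self, y: np.ndarray):
        """Axis-aligned jump steps in coordinate order 1..k."""
        steps = []
        for j in range(self.model.k):
            e = tuple(1 if i == j else 0 for i in range(self.model.k))
            if e not in self.model.rates and \
               tuple(-v for v in e) not in self.model.rates:
                raise Divergence(
                    "no default decomposition: jump set lacks unit vectors; "
                    "pass an explicit decomposition"
                )
            steps.append((y[j] - self.y_star[j], e))
        return steps

    def correction(self, y, decomposition=None) -> float:
        """The subleading correction ``V0(y)`` via a jump decomposition.

        ``decomposition`` is a sequence of ``(a_j, l_j)`` steps with
        ``y* + sum a_j l_j = y`` and every partial sum inside the state
        space; the default is axis-aligned in coordinate order.  The value is
        half the telescoping sum of ``ln(beta_{-l} beta_l)`` increments and
        is independent of the decomposition chosen.  Diverges on the
        boundary.
        """
        y = np.asarray(y, dtype=float)
        steps = decomposition if decomposition is not None \
            else self._default_decomposition(y)
        p = self.y_star.copy()
        total = 0.0
        for a, l in steps:
            l_arr = np.asarray(l, dtype=float)
            q = p + a * l_arr
            if not self.model.in_space(q, tol=1e-12):
                raise DomainError(
                    f"partial sum {q} of the decomposition leaves the space"
                )
            neg = tuple(-int(v) for v in l)
            num = self.model.rate(l, q) * self.model.rate(neg, q)
            den = self.model.rate(l, p) * self.model.rate(neg, p)
            if num <= 0.0 or den <= 0.0:
                raise Divergence(
                    f"V0 diverges: rate product vanishes at {q if num <= 0 else p}"
                )
            total += 0.5 * np.log(num / den)
            p = q
        target = self.y_star + sum(a * np.asarray(l, dtype=float)
                                   for a, l in steps)
        if not np.allclose(target, y, atol=1e-9):
            raise DomainError("decomposition does not reach the target point")
        return total

    def correction_batch(self, Y: np.ndarray) -> np.ndarray:
        """Vectorised axis-aligned ``V0`` for interior points ``Y``."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        k = self.model.k
        out = np.zeros(Y.shape[0])
        prev = np.broadcast_to(self.y_star, Y.shape).copy()
        for j in range(k):
            cur = prev.copy()
            cur[:, j] = Y[:, j]
            e = tuple(1 if i == j else 0 for i in range(k))
            ne = tuple(-v for v in e)
            num = self.model.rate_batch(e, cur) * self.model.rate_batch(ne, cur)
            den = self.model.rate_batch(e, prev) * self.model.rate_batch(ne, prev)
            if np.any(num <= 0.0) or np.any(den <= 0.0):
                raise Divergence("V0 diverges at a boundary point of the batch")
            out += 0.5 * (np.log(num) - np.log(den))
            prev = cur
        return out

    # -- Sigma, G, M_N -------------------------------------------------------

    def sigma(self, tol: float = 1e-6) -> np.ndarray:
        """``Sigma = d theta / dy`` at ``y*`` (Hessian of V at the mode).

        Computed by central differences of the theta field and symmetrised
        by averaging; an asymmetry beyond ``tol`` (relative) indicates the
        irrotationality criterion fails and raises
        :class:`~qsdwkb.errors.CriteriaViolation`.
        """
        if self._sigma is not None:
            return self._sigma
        k = self.model.k
        S = np.empty((k, k))
        for j in range(k):
            h = 1e-6 * (1.0 + abs(self.y_star[j]))
            hi, lo = self.y_star.copy(), self.y_star.copy()
            hi[j] += h
            lo[j] -= h
            vals, _ = self.field.theta_batch(np.stack([hi, lo]))
            S[:, j] = (vals[0] - vals[1]) / (2.0 * h)
        asym = np.max(np.abs(S - S.T)) / (1.0 + np.max(np.abs(S)))
        if asym > tol:
            raise CriteriaViolation(
                f"d theta/dy at y* asymmetric (relative asymmetry {asym:.2e}); "
                "irrotationality criterion fails"
            )
        S = 0.5 * (S + S.T)
        self._sigma = S
        return S

    def boundary_layer(self, N: int) -> float:
        """Width of the boundary layer where the correction V0 is invalid.

        The QSD approximation holds for points whose distance to the
        boundary is not vanishing; operationally we use 10/N (ten lattice
        sites), capped at 10% of the shortest box side for box models.
        """
        cut = 10.0 / N
        if self.model.is_box:
            cut = min(cut, 0.1 * float(np.min(self.model.fractions)))
        return cut

    def diffusion_matrix(self) -> np.ndarray:
        """``G = sum_l beta_l(y*) l l^T`` (local diffusion at the mode)."""
        G = np.zeros((self.model.k, self.model.k))
        for l in self.model.jumps:
            la = np.asarray(l, dtype=float)
            G += self.model.rate(l, self.y_star) * np.outer(la, la)
        return G

    def prefactor(self, N: int) -> float:
        """``M_N = sqrt(det Sigma / (2 pi N)^k)`` — the QSD value at the mode."""
        S = self.sigma()
        det = np.linalg.det(S)
        if det <= 0.0:
            raise CriteriaViolation(f"det Sigma = {det} is not positive")
        return float(np.sqrt(det / (2.0 * np.pi * N) ** self.model.k))

    # -- QSD approximations --------------------------------------------------

    def _refuse_if_criteria_fail(self):
        if self.report is not None and not self.report.correction_ok:
            raise CriteriaViolation(
                "WKB QSD unavailable: reversibility criteria fail for "
                f"{self.model.name}: {self.report.as_dict()}"
            )

    def wkb_qsd(self, N: int, x) -> float:
        """WKB mass ``M_N exp(-N V(y) - V0(y))`` at lattice state ``x``."""
        self._refuse_if_criteria_fail()
        x = np.asarray(x, dtype=float)
        y = x / float(N)
        V = self.potential(y)
        V0 = self.correction(y)
        return self.prefactor(N) * float(np.exp(-N * V - V0))

    def log_wkb_qsd_batch(self, N: int, X: np.ndarray,
                          n_nodes: int = 128) -> np.ndarray:
        """Log WKB mass on a batch of lattice states (rows of ``X``)."""
        self._refuse_if_criteria_fail()
        Y = np.atleast_2d(np.asarray(X, dtype=float)) / float(N)
        V = self.potential_batch(Y, n_nodes=n_nodes)
        V0 = self.correction_batch(Y)
        return np.log(self.prefactor(N)) - N * V - V0

    def gaussian_qsd(self, N: int, x) -> float:
        """Multivariate-normal mass with mean ``N y*``, variance ``N Sigma^-1``."""
        return float(np.exp(self.log_gaussian_qsd_batch(N, np.asarray(x)[None, :]))[0])

    def log_gaussian_qsd_batch(self, N: int, X: np.ndarray) -> np.ndarray:
        S = self.sigma()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = X - N * self.y_star
        quad = np.einsum("mi,ij,mj->m", d, S, d) / N
        return np.log(self.prefactor(N)) - 0.5 * quad

    # -- extinction time, leading order --------------------------------------

    def log_tau_leading(self) -> float:
        """``A = V(0)``: the limit of ``ln(tau) / N``.

        Integrates theta along the straight ray from ``y*`` to the origin
        (interior except the endpoint, where the ray limit of theta is finite
        for supercritical models).
        """
        return self.potential(np.zeros(self.model.k))

    def drift_jacobian_at_star(self) -> np.ndarray:
        return jacobian(self.model, self.y_star)
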
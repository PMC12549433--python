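"""Density-dependent Markov population processes and their deterministic limit.

A process is specified by its dimension ``k``, a finite symmetric jump set
(``l`` in the set implies ``-l`` in the set), per-jump rate functions
``beta_l`` defined on the continuous state space, and the state-space type:
the nonnegative orthant, or a finite box ``[0, f_1] x ... x [0, f_k]``.  The
lattice process at scale ``N`` jumps from ``x`` to ``x + l`` at rate
``N * beta_l(x / N)``.  The fluid limit is ``dy/dt = sum_l l beta_l(y)``,
assumed to have an unstable equilibrium at the origin and a unique stable
interior equilibrium ``y*``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import (
    AssumptionViolation,
    DomainError,
    ModelError,
    NoEquilibrium,
    NumericError,
)

Jump = tuple[int, ...]

#: relative step used for finite-difference derivatives of rate functions
FD_STEP = 1e-6


def _as_jump(l) -> Jump:
    return tuple(int(v) for v in l)


@dataclass(frozen=True)
class PopulationProcess:
    """A density-dependent population process.

    Parameters
    ----------
    k
        Dimension of the state space.
    jumps
        Finite symmetric set of integer jump vectors spanning ``R^k``.
    rates
        Map from each jump to its rate function ``beta_l``.  Rate functions
        accept a point ``y`` of shape ``(k,)`` and should also accept a batch
        of shape ``(m, k)`` (built-in models do; generic code falls back to a
        loop when they do not).
    gradients
        Optional map from jump to the analytic gradient of ``beta_l``;
        entries missing from the map fall back to finite differences.
    fractions
        ``None`` for the unbounded orthant, else the box fractions
        ``(f_1, ..., f_k)``.
    """

    k: int
    jumps: tuple[Jump, ...]
    rates: Mapping[Jump, Callable]
    gradients: Mapping[Jump, Callable] = field(default_factory=dict)
    fractions: Optional[tuple[float, ...]] = None
    name: str = "model"

    def __post_init__(self):
        object.__setattr__(self, "jumps", tuple(_as_jump(l) for l in self.jumps))
        object.__setattr__(
            self, "rates", {_as_jump(l): f for l, f in self.rates.items()}
        )
        object.__setattr__(
            self, "gradients", {_as_jump(l): f for l, f in self.gradients.items()}
        )
        if self.fractions is not None:
            object.__setattr__(
                self, "fractions", tuple(float(f) for f in self.fractions)
            )

    # -- state-space geometry -------------------------------------------------

    @property
    def is_box(self) -> bool:
        return self.fractions is not None

    @property
    def is_birth_death(self) -> bool:
        """True when the jump set is exactly {±e_i : i = 1..k}."""
        expected = set()
        for i in range(self.k):
            e = [0] * self.k
            e[i] = 1
            expected.add(tuple(e))
            expected.add(tuple(-v for v in e))
        return set(self.jumps) == expected

    def upper_bounds(self) -> np.ndarray:
        """Per-coordinate upper bounds of the continuous space (inf if none)."""
        if self.fractions is None:
            return np.full(self.k, np.inf)
        return np.asarray(self.fractions, dtype=float)

    def in_space(self, y, tol: float = 0.0) -> bool:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.k,):
            return False
        return bool(np.all(y >= -tol) and np.all(y <= self.upper_bounds() + tol))

    def contains_state(self, x, N: int) -> bool:
        x = np.asarray(x)
        if x.shape != (self.k,) or np.any(x < 0):
            return False
        if self.fractions is not None:
            caps = np.rint(N * np.asarray(self.fractions)).astype(int)
            if np.any(x > caps):
                return False
        return True

    # -- rate evaluation ------------------------------------------------------

    def rate(self, jump, y) -> float:
        """Evaluate ``beta_l`` at a single point ``y``."""
        return float(self.rates[_as_jump(jump)](np.asarray(y, dtype=float)))

    def rate_batch(self, jump, Y: np.ndarray) -> np.ndarray:
        """Evaluate ``beta_l`` at points ``Y`` of shape ``(m, k)``."""
        f = self.rates[_as_jump(jump)]
        Y = np.asarray(Y, dtype=float)
        try:
            out = np.asarray(f(Y), dtype=float)
            if out.shape == (Y.shape[0],):
                return out
        except Exception:
            pass
        return np.array([float(f(y)) for y in Y])

    def rate_gradient_batch(self, jump, Y: np.ndarray) -> np.ndarray:
        """Gradients of ``beta_l`` at points ``Y`` of shape ``(m, k)``."""
        jump = _as_jump(jump)
        Y = np.asarray(Y, dtype=float)
        g = self.gradients.get(jump)
        if g is not None:
            try:
                out = np.asarray(g(Y), dtype=float)
                if out.shape == Y.shape:
                    return out
            except Exception:
                pass
        return np.array([self.rate_gradient(jump, y) for y in Y])

    def rate_gradient(self, jump, y) -> np.ndarray:
        """Gradient of ``beta_l`` at ``y`` (analytic if registered, else FD).

        Finite differences are central with one step of Richardson
        extrapolation; near the boundary of the state space the stencil is
        shifted inward so rate functions are never evaluated outside their
        domain (derivatives at the boundary are one-sided).
        """
        jump = _as_jump(jump)
        y = np.asarray(y, dtype=float)
        g = self.gradients.get(jump)
        if g is not None:
            return np.asarray(g(y), dtype=float).reshape(self.k)
        f = self.rates[jump]
        ub = self.upper_bounds()
        out = np.empty(self.k)
        for j in range(self.k):
            h = FD_STEP * (1.0 + abs(y[j]))
            out[j] = _richardson_partial(f, y, j, h, ub[j])
        if not np.all(np.isfinite(out)):
            raise NumericError(
                f"non-finite derivative of rate for jump {jump} at y={y}"
            )
        return out


def _richardson_partial(f, y, j, h, upper):
    def central(step):
        lo = y[j] - step
        hi = y[j] + step
        if lo < 0.0 or hi > upper:
            # one-sided (forward/backward) difference at the boundary
            if lo < 0.0:
                a, b = y[j], min(y[j] + step, upper)
            else:
                a, b = max(y[j] - step, 0.0), y[j]
            ya, yb = y.copy(), y.copy()
            ya[j], yb[j] = a, b
            return (float(f(yb)) - float(f(ya))) / (b - a)
        ya, yb = y.copy(), y.copy()
        ya[j], yb[j] = lo, hi
        return (float(f(yb)) - float(f(ya))) / (2.0 * step)

    d1 = central(h)
    d2 = central(h / 2.0)
    return (4.0 * d2 - d1) / 3.0


@dataclass
class EquilibriumReport:
    """Interior equilibrium of the fluid limit with stability diagnostics."""

    y_star: np.ndarray
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    origin_unstable: bool
    origin_eigenvalues: np.ndarray


# -- operations ---------------------------------------------------------------


def drift(model: PopulationProcess, y) -> np.ndarray:
    """Fluid-limit drift ``sum_l l beta_l(y)`` at a point of the state space."""
    y = np.asarray(y, dtype=float)
    if not model.in_space(y, tol=1e-12):
        raise DomainError(f"point {y} outside the state space of {model.name}")
    out = np.zeros(model.k)
    for l in model.jumps:
        out += np.asarray(l, dtype=float) * model.rate(l, y)
    return out


def jacobian(model: PopulationProcess, y) -> np.ndarray:
    """Jacobian ``J(y) = sum_l l (d beta_l / dy)^T`` of the drift field."""
    y = np.asarray(y, dtype=float)
    J = np.zeros((model.k, model.k))
    for l in model.jumps:
        J += np.outer(np.asarray(l, dtype=float), model.rate_gradient(l, y))
    return J


def transition_rates(model: PopulationProcess, x, N: int) -> dict[Jump, float]:
    """Lattice jump rates ``N beta_l(x/N)`` from integer state ``x``.

    Jumps that would leave the lattice state space get rate exactly 0 (the
    boundary zeros of the rate functions guarantee this for valid models; the
    clamp makes it exact in floating point).
    """
    x = np.asarray(x, dtype=int)
    if not model.contains_state(x, N):
        raise DomainError(f"state {x} not in the lattice state space at N={N}")
    y = x / float(N)
    out = {}
    for l in model.jumps:
        if not model.contains_state(x + np.asarray(l, dtype=int), N):
            out[l] = 0.0
            continue
        r = N * model.rate(l, y)
        if r < 0.0:
            raise ModelError(
                f"negative rate {r} for jump {l} at state {x} in {model.name}"
            )
        out[l] = r
    return out


def _default_guess(model: PopulationProcess) -> np.ndarray:
    if model.is_box:
        return 0.5 * np.asarray(model.fractions)
    return np.ones(model.k)


def find_equilibria(
    model: PopulationProcess,
    initial_guess=None,
    drift_tol: float = 1e-10,
) -> EquilibriumReport:
    """Locate the interior equilibrium ``y*`` and verify the stability pattern.

    Root-finding uses a Newton-type solver from ``initial_guess`` (default:
    box midpoint, or the all-ones point on the orthant), with a coarse 3^k
    multi-start fallback.  The model assumptions posit a unique interior
    equilibrium, so any interior root found is accepted as ``y*``.

    Raises
    ------
    NoEquilibrium
        No interior root of the drift was found.
    AssumptionViolation
        ``y*`` is not linearly stable, or the origin is not unstable; the
        exception carries the offending spectrum.
    """
    guesses = [np.asarray(initial_guess, dtype=float)] if initial_guess is not None \
        else [_default_guess(model)]
    ub = model.upper_bounds()
    span = np.where(np.isfinite(ub), ub, 2.0 * _default_guess(model))
    grid = [span * np.array(c) for c in
            itertools.product((0.25, 0.5, 0.75), repeat=model.k)]
    guesses += grid
    if not model.is_box:
        # geometric ladder of scales for equilibria far from the unit point
        guesses += [s * np.ones(model.k) for s in (0.25, 2.0, 4.0, 8.0, 16.0)]

    rate_scale = None
    y_star = None
    for g in guesses:
        g = np.clip(g, 1e-6, np.where(np.isfinite(ub), ub * (1 - 1e-6), np.inf))
        sol = optimize.root(lambda y: drift_unchecked(model, y), g, method="hybr")
        if not sol.success:
            continue
        cand = sol.x
        if np.any(cand <= 1e-9) or np.any(cand >= ub - 1e-9):
            continue
        scale = sum(model.rate(l, cand) for l in model.jumps)
        if scale <= 0:
            continue
        if np.max(np.abs(drift_unchecked(model, cand))) < drift_tol * scale:
            y_star, rate_scale = cand, scale
            break
    if y_star is None:
        raise NoEquilibrium(f"no interior equilibrium found for {model.name}")

    J = jacobian(model, y_star)
    eig = np.linalg.eigvals(J)
    if np.any(eig.real >= 0.0):
        raise AssumptionViolation(
            f"interior equilibrium of {model.name} is not stable", spectrum=eig
        )
    J0 = jacobian(model, np.zeros(model.k))
    eig0 = np.linalg.eigvals(J0)
    origin_unstable = bool(np.any(eig0.real > 0.0))
    if not origin_unstable:
        raise AssumptionViolation(
            f"origin of {model.name} is not unstable (subcritical model)",
            spectrum=eig0,
        )
    return EquilibriumReport(
        y_star=y_star,
        jacobian=J,
        eigenvalues=eig,
        origin_unstable=origin_unstable,
        origin_eigenvalues=eig0,
    )


def drift_unchecked(model: PopulationProcess, y) -> np.ndarray:
    """Drift without the domain check (used by root-finding internals).

    Rate functions of valid models are defined on the whole of the continuous
    state space; the solver may step slightly outside, where we clip back.
    """
    y = np.asarray(y, dtype=float)
    ub = model.upper_bounds()
    y = np.clip(y, 0.0, ub)
    out = np.zeros(model.k)
    for l in model.jumps:
        out += np.asarray(l, dtype=float) * model.rate(l, y)
    return out


def validate(model: PopulationProcess, n_samples: int = 16, seed: int = 0) -> None:
    """Check the structural standing assumptions of the model family.

    Verifies: symmetry and spanning of the jump set; ``beta_l(0) = 0``; the
    boundary zero pattern (rate 0 exactly when a jump would exit the space);
    strict interior positivity at sampled points; finite one-sided first
    derivatives at the origin.  Existence of the quasistationary distribution
    on infinite state spaces is *not* checked (reported as unchecked).

    Raises ``ModelError`` / ``AssumptionViolation`` on failure.
    """
    jumps = set(model.jumps)
    for l in jumps:
        if tuple(-v for v in l) not in jumps:
            raise ModelError(f"jump set not symmetric: missing {tuple(-v for v in l)}")
    L = np.array(sorted(jumps), dtype=float)
    if np.linalg.matrix_rank(L) < model.k:
        raise ModelError("jump set does not span R^k")

    zero = np.zeros(model.k)
    for l in model.jumps:
        if abs(model.rate(l, zero)) > 0.0:
            raise ModelError(f"beta_l(0) != 0 for jump {l}")

    rng = np.random.default_rng(seed)
    ub = model.upper_bounds()
    span = np.where(np.isfinite(ub), ub, 2.0 * _default_guess(model))
    interior = rng.uniform(0.05, 0.95, size=(n_samples, model.k)) * span
    for l in model.jumps:
        vals = model.rate_batch(l, interior)
        if np.any(vals <= 0.0):
            raise AssumptionViolation(
                f"rate for jump {l} not strictly positive on the interior"
            )
        # boundary behaviour: zero iff the jump would exit the space
        for i in range(model.k):
            yb = interior[0].copy()
            yb[i] = 0.0
            v = model.rate(l, yb)
            if l[i] < 0 and v != 0.0:
                raise AssumptionViolation(
                    f"rate for jump {l} nonzero at y_{i}=0 boundary"
                )
            if model.is_box:
                yt = interior[0].copy()
                yt[i] = ub[i]
                vt = model.rate(l, yt)
                if l[i] > 0 and vt != 0.0:
                    raise AssumptionViolation(
                        f"rate for jump {l} nonzero at y_{i}=f_{i} boundary"
                    )
        # finite one-sided derivatives at the origin
        g0 = model.rate_gradient(l, zero)
        if not np.all(np.isfinite(g0)):
            raise AssumptionViolation(
                f"non-finite one-sided derivative at origin for jump {l}"
            )
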
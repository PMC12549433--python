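"""Built-in model families, each bundled with closed-form reference formulas.

Five families are provided:

* :func:`make_sis` — the heterogeneous-susceptibility SIS epidemic (finite
  box state space; infectious counts per group);
* :func:`make_logistic` — multitype birth-death with linear birth and
  quadratic death rates (symmetric k-type logistic growth);
* :func:`make_separable_bd` — multitype birth-death with separable rates
  ``b0(sum y) b_i(y_i)`` / ``d0(sum y) d_i(y_i)``;
* :func:`make_competition` — two-type competition processes with jump set
  ``{±e_1, ±e_2, ±(e_1 - e_2)}`` and fully factorised rates;
* :func:`make_two_group` — a two-group birth-death process with movement
  between groups (the competition family instance used for the numerical
  illustrations).

Every factory returns a :class:`Builtin` holding the process (with analytic
rate gradients), a :class:`ReferenceFormulas` record of the closed forms the
generic machinery must reproduce, and a serialisable config record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
from scipy import integrate, optimize

from .errors import ModelError
from .process import PopulationProcess


@dataclass
class ReferenceFormulas:
    """Closed-form reference expressions attached to a built-in model.

    Each entry is an evaluator over the model's parameters; ``None`` where
    the family has no printed closed form for that quantity.
    """

    y_star: Optional[Callable[[], np.ndarray]] = None
    potential: Optional[Callable[..., float]] = None
    sigma: Optional[Callable[[], np.ndarray]] = None
    det_sigma: Optional[Callable[[], float]] = None
    action: Optional[Callable[[], float]] = None
    tau: Optional[Callable[[float], float]] = None
    log_tau: Optional[Callable[[float], float]] = None
    qsd: Optional[Callable[..., float]] = None


class Builtin(NamedTuple):
    model: PopulationProcess
    reference: ReferenceFormulas
    config: dict


class Factor:
    """A scalar factor function with its derivative (vectorised).

    Built either from an explicit ``(f, df)`` pair or from polynomial
    coefficients (lowest order first), which keeps the separable-rate
    families serialisable to plain config records.
    """

    def __init__(self, f: Callable, df: Callable, coeffs=None):
        self.f = f
        self.df = df
        self.coeffs = None if coeffs is None else [float(c) for c in coeffs]

    def __call__(self, u):
        return self.f(u)

    def deriv(self, u):
        return self.df(u)

    @classmethod
    def poly(cls, coeffs: Sequence[float]) -> "Factor":
        p = np.polynomial.Polynomial(list(coeffs))
        dp = p.deriv()
        return cls(lambda u: p(u), lambda u: dp(u), coeffs=list(coeffs))

    @classmethod
    def constant(cls, c: float) -> "Factor":
        return cls.poly([c])

    @classmethod
    def wrap(cls, obj) -> "Factor":
        if isinstance(obj, Factor):
            return obj
        if isinstance(obj, (int, float)):
            return cls.constant(float(obj))
        if isinstance(obj, (list, tuple)) and all(
            isinstance(c, (int, float)) for c in obj
        ):
            return cls.poly(obj)
        if callable(obj):
            h = 1e-6
            return cls(obj, lambda u: (obj(u + h) - obj(u - h)) / (2 * h))
        raise ModelError(f"cannot interpret {obj!r} as a factor function")


def _unit(i: int, k: int) -> tuple:
    return tuple(1 if j == i else 0 for j in range(k))


# ---------------------------------------------------------------------------
# SIS epidemic with heterogeneous susceptibilities
# ---------------------------------------------------------------------------


def make_sis(beta: float, mu: Sequence[float], alpha: Sequence[float],
             f: Sequence[float]) -> Builtin:
    """SIS infection model with k groups of differing susceptibility.

    Group i holds a fraction ``f_i`` of the population; infection of a
    susceptible type-i individual occurs at rate ``beta mu_i`` per infectious
    contact and infectious periods are exponential with mean ``alpha_i``.
    Continuous rates: ``beta_{+e_i}(y) = beta mu_i (f_i - y_i) sum_j y_j``,
    ``beta_{-e_i}(y) = y_i / alpha_i``.  Requires the normalisation
    ``sum_i mu_i f_i = 1`` and supercriticality
    ``beta sum_i alpha_i mu_i f_i > 1``.
    """
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    f = np.asarray(f, dtype=float)
    k = len(f)
    if not (len(mu) == len(alpha) == k):
        raise ModelError("mu, alpha, f must have equal lengths")
    if np.any(mu <= 0) or np.any(alpha <= 0) or np.any(f <= 0) or beta <= 0:
        raise ModelError("SIS parameters must be positive")
    if abs(float(np.sum(mu * f)) - 1.0) > 1e-10:
        raise ModelError("SIS normalisation sum_i mu_i f_i = 1 violated")
    R0 = beta * float(np.sum(alpha * mu * f))
    if R0 <= 1.0:
        raise ModelError(f"subcritical SIS model: beta sum alpha mu f = {R0} <= 1")

    rates, grads = {}, {}
    for i in range(k):
        e, ne = _unit(i, k), tuple(-v for v in _unit(i, k))

        def birth(y, i=i):
            y = np.asarray(y, dtype=float)
            return beta * mu[i] * (f[i] - y[..., i]) * np.sum(y, axis=-1)

        def dbirth(y, i=i):
            y = np.asarray(y, dtype=float)
            s = np.sum(y, axis=-1)
            g = beta * mu[i] * np.broadcast_to(
                (f[i] - y[..., i])[..., None], y.shape
            ).copy()
            g[..., i] -= beta * mu[i] * s
            return g

        def death(y, i=i):
            y = np.asarray(y, dtype=float)
            return y[..., i] / alpha[i]

        def ddeath(y, i=i):
            y = np.asarray(y, dtype=float)
            g = np.zeros_like(y)
            g[..., i] = 1.0 / alpha[i]
            return g

        rates[e], grads[e] = birth, dbirth
        rates[ne], grads[ne] = death, ddeath

    model = PopulationProcess(k=k, jumps=tuple(rates), rates=rates,
                              gradients=grads, fractions=tuple(f), name="sis")

    def solve_E() -> float:
        def g(E):
            return beta * float(np.sum(alpha * mu * f / (alpha * mu * E + 1.0))) - 1.0
        hi = 1.0
        while g(hi) > 0.0:
            hi *= 2.0
        return float(optimize.brentq(g, 1e-14, hi, xtol=1e-15, rtol=1e-14))

    def y_star() -> np.ndarray:
        E = solve_E()
        return alpha * mu * f * E / (1.0 + alpha * mu * E)

    def action() -> float:
        E = solve_E()
        return float(np.sum(f * np.log(1.0 + alpha * mu * E)) - E / beta)

    def tau(N: float) -> float:
        return float(np.exp(log_tau(N)))

    def log_tau(N: float) -> float:
        E = solve_E()
        bii = beta * mu * f
        d = 1.0 / alpha

        def gD(D):
            return float(np.sum(bii / (D + d))) - 1.0

        D = float(optimize.brentq(gD, 1e-300, float(np.sum(bii)),
                                  xtol=1e-15, rtol=1e-14))
        ssum = float(np.sum(f * (alpha * mu / (1.0 + alpha * mu * E)) ** 2))
        return (-np.log(D * E) + 0.5 * np.log(2.0 * np.pi / (N * ssum))
                + N * action())

    ref = ReferenceFormulas(y_star=y_star, action=action, tau=tau,
                            log_tau=log_tau)
    config = {"model": "sis",
              "params": {"beta": float(beta), "mu": mu.tolist(),
                         "alpha": alpha.tolist(), "f": f.tolist()}}
    return Builtin(model, ref, config)


# ---------------------------------------------------------------------------
# Linear birth / quadratic death multitype process
# ---------------------------------------------------------------------------


def make_logistic(k: int, lam: float, mu: float, kappa: float) -> Builtin:
    """k-type process with birth rate ``lam * sum y`` per type and per-capita
    death rate ``mu + kappa * sum y`` (logistic crowding).  Supercritical for
    ``k lam > mu``; state space is the unbounded orthant."""
    if lam <= 0 or mu <= 0 or kappa <= 0:
        raise ModelError("parameters must be positive")
    if k * lam <= mu:
        raise ModelError(f"subcritical: k lam = {k * lam} <= mu = {mu}")

    rates, grads = {}, {}
    for i in range(k):
        e, ne = _unit(i, k), tuple(-v for v in _unit(i, k))

        def birth(y, i=i):
            y = np.asarray(y, dtype=float)
            return lam * np.sum(y, axis=-1)

        def dbirth(y, i=i):
            y = np.asarray(y, dtype=float)
            return np.full_like(y, lam)

        def death(y, i=i):
            y = np.asarray(y, dtype=float)
            return y[..., i] * (mu + kappa * np.sum(y, axis=-1))

        def ddeath(y, i=i):
            y = np.asarray(y, dtype=float)
            s = np.sum(y, axis=-1)
            g = kappa * np.broadcast_to(y[..., i][..., None], y.shape).copy()
            g[..., i] += mu + kappa * s
            return g

        rates[e], grads[e] = birth, dbirth
        rates[ne], grads[ne] = death, ddeath

    model = PopulationProcess(k=k, jumps=tuple(rates), rates=rates,
                              gradients=grads, fractions=None, name="logistic")

    def y_star() -> np.ndarray:
        return np.full(k, (k * lam - mu) / (k * kappa))

    def action() -> float:
        return (k * lam - mu) / kappa + (mu / kappa) * np.log(mu / (k * lam))

    def log_tau(N: float) -> float:
        return (-2.0 * np.log(k * lam - mu)
                + 0.5 * np.log(2.0 * np.pi * mu * kappa / N)
                + N * action())

    def tau(N: float) -> float:
        return float(np.exp(log_tau(N)))

    ref = ReferenceFormulas(y_star=y_star, action=action, tau=tau,
                            log_tau=log_tau)
    config = {"model": "logistic",
              "params": {"k": int(k), "lam": float(lam), "mu": float(mu),
                         "kappa": float(kappa)}}
    return Builtin(model, ref, config)


# ---------------------------------------------------------------------------
# Separable multitype birth-death family
# ---------------------------------------------------------------------------


def make_separable_bd(b0, b, d0, d, f: Optional[Sequence[float]] = None) -> Builtin:
    """Multitype birth-death process with separable rates.

    ``beta_{+e_i}(y) = b0(sum y) b_i(y_i)`` and
    ``beta_{-e_i}(y) = d0(sum y) d_i(y_i)``.  Factor functions may be given
    as :class:`Factor` objects, ``(f, df)`` pairs, polynomial coefficient
    lists, or plain callables.  Structural requirements: ``b0(0) = 0``,
    ``b_i(0) > 0``, ``d_i(0) = 0`` with positive values on the interior of
    each factor's domain; on a finite box additionally ``d0(1) > 0``,
    ``b_i(f_i) = 0`` and ``d_i(f_i) > 0``.  Supercriticality requires
    ``(b0'(0)/d0(0)) sum_i b_i(0)/d_i'(0) > 1``.
    """
    b0 = Factor.wrap(b0)
    d0 = Factor.wrap(d0)
    bs = [Factor.wrap(x) for x in b]
    ds = [Factor.wrap(x) for x in d]
    k = len(bs)
    if len(ds) != k:
        raise ModelError("need one b_i and one d_i per coordinate")

    if abs(b0(0.0)) > 0.0:
        raise ModelError("requirement b0(0) = 0 violated")
    for i in range(k):
        if bs[i](0.0) <= 0.0:
            raise ModelError(f"requirement b_{i + 1}(0) > 0 violated")
        if abs(ds[i](0.0)) > 0.0:
            raise ModelError(f"requirement d_{i + 1}(0) = 0 violated")
    if f is not None:
        f = tuple(float(v) for v in f)
        if d0(1.0) <= 0.0:
            raise ModelError("requirement d0(1) > 0 violated (box space)")
        for i in range(k):
            if abs(bs[i](f[i])) > 0.0:
                raise ModelError(f"requirement b_{i + 1}(f_{i + 1}) = 0 violated")
            if ds[i](f[i]) <= 0.0:
                raise ModelError(f"requirement d_{i + 1}(f_{i + 1}) > 0 violated")
    crit = (b0.deriv(0.0) / d0(0.0)) * sum(
        bs[i](0.0) / ds[i].deriv(0.0) for i in range(k)
    )
    if crit <= 1.0:
        raise ModelError(f"subcritical separable model (criterion {crit} <= 1)")

    rates, grads = {}, {}
    for i in range(k):
        e, ne = _unit(i, k), tuple(-v for v in _unit(i, k))

        def birth(y, i=i):
            y = np.asarray(y, dtype=float)
            return b0(np.sum(y, axis=-1)) * bs[i](y[..., i])

        def dbirth(y, i=i):
            y = np.asarray(y, dtype=float)
            s = np.sum(y, axis=-1)
            g = np.broadcast_to(
                (b0.deriv(s) * bs[i](y[..., i]))[..., None], y.shape
            ).copy()
            g[..., i] += b0(s) * bs[i].deriv(y[..., i])
            return g

        def death(y, i=i):
            y = np.asarray(y, dtype=float)
            return d0(np.sum(y, axis=-1)) * ds[i](y[..., i])

        def ddeath(y, i=i):
            y = np.asarray(y, dtype=float)
            s = np.sum(y, axis=-1)
            g = np.broadcast_to(
                (d0.deriv(s) * ds[i](y[..., i]))[..., None], y.shape
            ).copy()
            g[..., i] += d0(s) * ds[i].deriv(y[..., i])
            return g

        rates[e], grads[e] = birth, dbirth
        rates[ne], grads[ne] = death, ddeath

    model = PopulationProcess(k=k, jumps=tuple(rates), rates=rates,
                              gradients=grads, fractions=f, name="separable_bd")
    config = {"model": "separable_bd",
              "params": {"b0": b0.coeffs, "b": [x.coeffs for x in bs],
                         "d0": d0.coeffs, "d": [x.coeffs for x in ds],
                         "f": None if f is None else list(f)}}
    return Builtin(model, ReferenceFormulas(), config)


# ---------------------------------------------------------------------------
# Two-type competition processes
# ---------------------------------------------------------------------------


def make_competition(a: Sequence[float], b0, b1, b2, b3, c0, c1, c2,
                     d0, d1, d2, d3,
                     f: Optional[Sequence[float]] = None) -> Builtin:
    """Two-type competition process with jumps ``{±e_1, ±e_2, ±(e_1-e_2)}``.

    Rates factorise over the combinations ``s = y_1 + y_2``, the separate
    coordinates, and the difference ``w = y_1 - y_2``:

    ======================  ==========================================
    jump                    rate
    ======================  ==========================================
    ``-e_1``                ``a_1 d0(s) d1(y1) c2(y2) d3(w)``
    ``+e_1``                ``a_2 b0(s) b1(y1) c2(y2) b3(w)``
    ``-e_2``                ``a_3 d0(s) c1(y1) d2(y2) b3(w)``
    ``+e_2``                ``a_4 b0(s) c1(y1) b2(y2) d3(w)``
    ``e_1 - e_2``           ``a_5 c0(s) b1(y1) d2(y2) b3(w)^2``
    ``e_2 - e_1``           ``a_6 c0(s) d1(y1) b2(y2) d3(w)^2``
    ======================  ==========================================

    The theta system is consistent precisely when
    ``a_1 a_4 a_5 = a_2 a_3 a_6``, and the theta0 system precisely when
    ``b3(u) d3(u)`` is constant.  With ``a_5 = a_6 = 0`` the movement jumps
    are dropped and the process is a plain two-type birth-death process with
    an explicit extinction-time prefactor.

    Reference formulas attached: the action (five one-dimensional integrals,
    evaluated by adaptive quadrature), ``det Sigma``, and — for
    ``a_5 = a_6 = 0`` — the closed-form ``tau``.
    """
    a = [float(v) for v in a]
    if len(a) != 6 or any(v < 0 for v in a):
        raise ModelError("need six nonnegative constants a1..a6")
    a1, a2, a3, a4, a5, a6 = a
    if (a5 == 0.0) != (a6 == 0.0):
        raise ModelError("a5 and a6 must vanish together (jump symmetry)")
    B0, B1, B2, B3 = (Factor.wrap(x) for x in (b0, b1, b2, b3))
    C0, C1, C2 = (Factor.wrap(x) for x in (c0, c1, c2))
    D0, D1, D2, D3 = (Factor.wrap(x) for x in (d0, d1, d2, d3))
    if abs(B0(0.0)) > 0 or abs(D1(0.0)) > 0 or abs(D2(0.0)) > 0:
        raise ModelError("requirements b0(0) = d1(0) = d2(0) = 0 violated")
    for name, fac in (("b1", B1), ("b2", B2), ("c1", C1), ("c2", C2)):
        if fac(0.0) <= 0.0:
            raise ModelError(f"requirement {name}(0) > 0 violated")
    if f is not None:
        f = tuple(float(v) for v in f)
        if abs(B1(f[0])) > 0 or abs(B2(f[1])) > 0:
            raise ModelError("requirements b1(f1) = b2(f2) = 0 violated")

    jump_table = {
        (-1, 0): (a1, [(D0, "s"), (D1, "y1"), (C2, "y2"), (D3, "w")]),
        (1, 0): (a2, [(B0, "s"), (B1, "y1"), (C2, "y2"), (B3, "w")]),
        (0, -1): (a3, [(D0, "s"), (C1, "y1"), (D2, "y2"), (B3, "w")]),
        (0, 1): (a4, [(B0, "s"), (C1, "y1"), (B2, "y2"), (D3, "w")]),
        (1, -1): (a5, [(C0, "s"), (B1, "y1"), (D2, "y2"), (B3, "w"), (B3, "w")]),
        (-1, 1): (a6, [(C0, "s"), (D1, "y1"), (B2, "y2"), (D3, "w"), (D3, "w")]),
    }
    if a5 == 0.0:
        del jump_table[(1, -1)], jump_table[(-1, 1)]

    def _args(y):
        y = np.asarray(y, dtype=float)
        return {"s": y[..., 0] + y[..., 1], "y1": y[..., 0],
                "y2": y[..., 1], "w": y[..., 0] - y[..., 1]}

    _dargs = {"s": (1.0, 1.0), "y1": (1.0, 0.0), "y2": (0.0, 1.0),
              "w": (1.0, -1.0)}

    rates, grads = {}, {}
    for jump, (const, factors) in jump_table.items():

        def rate(y, const=const, factors=factors):
            args = _args(y)
            out = const * np.ones_like(args["s"])
            for fac, key in factors:
                out = out * fac(args[key])
            return out

        def grad(y, const=const, factors=factors):
            y_arr = np.asarray(y, dtype=float)
            args = _args(y_arr)
            vals = [fac(args[key]) for fac, key in factors]
            total = const * np.prod(np.stack(vals), axis=0)
            g = np.zeros_like(y_arr)
            for idx, (fac, key) in enumerate(factors):
                others = const * np.ones_like(args["s"])
                for jdx, v in enumerate(vals):
                    if jdx != idx:
                        others = others * v
                dv = fac.deriv(args[key])
                w1, w2 = _dargs[key]
                g[..., 0] += others * dv * w1
                g[..., 1] += others * dv * w2
            return g

        rates[jump], grads[jump] = rate, grad

    model = PopulationProcess(k=2, jumps=tuple(rates), rates=rates,
                              gradients=grads, fractions=f, name="competition")

    # ---- reference formulas ------------------------------------------------

    def _ratio_int(lo: float, hi: float, num: Factor, den: Factor) -> float:
        """int_lo^hi ln(num(u)/den(u)) du by adaptive quadrature.

        Where one factor vanishes linearly at an endpoint the integrand has
        an integrable logarithmic singularity, which the adaptive scheme
        (which never evaluates at the endpoints) resolves.
        """
        if lo == hi:
            return 0.0

        def g(u):
            return np.log(num(u)) - np.log(den(u))

        val, _ = integrate.quad(g, lo, hi, epsabs=1e-12, limit=400)
        return float(val)

    def potential(y, y_star: np.ndarray) -> float:
        y = np.asarray(y, dtype=float)
        y1s, y2s = float(y_star[0]), float(y_star[1])
        out = (y1s - y[0]) * np.log(a2 / a1) + (y2s - y[1]) * np.log(a4 / a3)
        out += _ratio_int(y[0] + y[1], y1s + y2s, B0, D0)
        out += _ratio_int(y[0], y1s, B1, D1)
        out += _ratio_int(y[1], y2s, B2, D2)
        out += _ratio_int(y[0] - y[1], y1s - y2s, B3, D3)
        return float(out)

    def det_sigma(y_star: np.ndarray) -> float:
        y1s, y2s = float(y_star[0]), float(y_star[1])
        s, w = y1s + y2s, y1s - y2s

        def lr(fac_d, fac_b, u):
            return fac_d.deriv(u) / fac_d(u) - fac_b.deriv(u) / fac_b(u)

        t0, t3 = lr(D0, B0, s), lr(D3, B3, w)
        t1, t2 = lr(D1, B1, y1s), lr(D2, B2, y2s)
        return float(4.0 * t0 * t3 + t1 * t2 + (t0 + t3) * (t1 + t2))

    def tau(N: float, y_star: np.ndarray) -> float:
        """Closed-form prefactor formula; birth-death case a5 = a6 = 0 only."""
        if a5 != 0.0:
            raise ModelError("closed-form tau requires a5 = a6 = 0")
        y1s, y2s = float(y_star[0]), float(y_star[1])
        s, w = y1s + y2s, y1s - y2s
        b11 = a2 * B0.deriv(0.0) * B1(0.0) * C2(0.0) * B3(0.0)
        b22 = a4 * B0.deriv(0.0) * C1(0.0) * B2(0.0) * D3(0.0)
        dd1 = a1 * D0(0.0) * D1.deriv(0.0) * C2(0.0) * D3(0.0)
        dd2 = a3 * D0(0.0) * C1(0.0) * D2.deriv(0.0) * B3(0.0)

        def gD(D):
            return b11 / (D + dd1) + b22 / (D + dd2) - 1.0

        D = float(optimize.brentq(gD, 1e-300, b11 + b22,
                                  xtol=1e-15, rtol=1e-14))
        num = (B0.deriv(0.0) * D0(0.0) * B1(0.0) * D1.deriv(0.0)
               * B2(0.0) * D2.deriv(0.0) * B3(0.0) * D3(0.0))
        den = (B0(s) * D0(s) * B1(y1s) * D1(y1s) * B2(y2s) * D2(y2s)
               * B3(w) * D3(w))
        V0 = potential(np.zeros(2), y_star)
        return float((1.0 / D) * np.sqrt(
            2.0 * np.pi * num / (N * det_sigma(y_star) * den)
        ) * np.exp(N * V0))

    ref = ReferenceFormulas(potential=potential, det_sigma=det_sigma, tau=tau)
    config = {"model": "competition",
              "params": {"a": list(a),
                         "b0": B0.coeffs, "b1": B1.coeffs, "b2": B2.coeffs,
                         "b3": B3.coeffs, "c0": C0.coeffs, "c1": C1.coeffs,
                         "c2": C2.coeffs, "d0": D0.coeffs, "d1": D1.coeffs,
                         "d2": D2.coeffs, "d3": D3.coeffs,
                         "f": None if f is None else list(f)}}
    return Builtin(model, ref, config)


# ---------------------------------------------------------------------------
# Two-group birth-death process with movement
# ---------------------------------------------------------------------------


def make_two_group(mu: float, kappa: float, lam1: float, lam2: float,
                   nu1: float, nu2: float) -> Builtin:
    """Two-group birth-death process with movement between groups.

    Rates: deaths ``y_i (mu + kappa (y_1 + y_2))``, births
    ``lam_i (y_1 + y_2)``, and movement from group j to group i at rate
    ``nu_j y_j`` (jump ``e_i - e_j``).  With ``nu_1 = nu_2 = 0`` the
    movement jumps are dropped and the process is a plain two-type
    birth-death process.  The reversibility cycle condition holds iff
    ``lam_1 nu_1 = lam_2 nu_2``; the reference formulas below assume it.
    """
    if min(mu, kappa, lam1, lam2) <= 0 or min(nu1, nu2) < 0:
        raise ModelError("parameters must be positive (nu may be zero)")
    if (nu1 == 0.0) != (nu2 == 0.0):
        raise ModelError("nu1 and nu2 must vanish together (jump symmetry)")
    if lam1 + lam2 <= mu:
        raise ModelError(f"subcritical: lam1 + lam2 = {lam1 + lam2} <= mu")
    lam = (lam1, lam2)
    nu = (nu1, nu2)

    rates, grads = {}, {}
    for i in range(2):
        e, ne = _unit(i, 2), tuple(-v for v in _unit(i, 2))

        def birth(y, i=i):
            y = np.asarray(y, dtype=float)
            return lam[i] * (y[..., 0] + y[..., 1])

        def dbirth(y, i=i):
            y = np.asarray(y, dtype=float)
            return np.full_like(y, lam[i])

        def death(y, i=i):
            y = np.asarray(y, dtype=float)
            return y[..., i] * (mu + kappa * (y[..., 0] + y[..., 1]))

        def ddeath(y, i=i):
            y = np.asarray(y, dtype=float)
            s = y[..., 0] + y[..., 1]
            g = kappa * np.broadcast_to(y[..., i][..., None], y.shape).copy()
            g[..., i] += mu + kappa * s
            return g

        rates[e], grads[e] = birth, dbirth
        rates[ne], grads[ne] = death, ddeath

    if nu1 > 0.0:
        # jump e_i - e_j moves one individual from group j to group i
        for i, j in ((0, 1), (1, 0)):
            jump = tuple(
                (1 if idx == i else 0) - (1 if idx == j else 0)
                for idx in range(2)
            )

            def move(y, j=j):
                y = np.asarray(y, dtype=float)
                return nu[j] * y[..., j]

            def dmove(y, j=j):
                y = np.asarray(y, dtype=float)
                g = np.zeros_like(y)
                g[..., j] = nu[j]
                return g

            rates[jump], grads[jump] = move, dmove

    model = PopulationProcess(k=2, jumps=tuple(rates), rates=rates,
                              gradients=grads, fractions=None, name="two_group")

    L = lam1 + lam2

    def y_star() -> np.ndarray:
        if nu1 > 0.0 and abs(lam1 * nu1 - lam2 * nu2) > 1e-12 * lam1 * max(nu1, 1.0):
            # general form, valid without the reversibility constraint
            c = (L - mu) / (kappa * (L + nu1 + nu2))
            return np.array([c * (lam1 + nu2), c * (lam2 + nu1)])
        return ((L - mu) / (kappa * L)) * np.array([lam1, lam2])

    def potential(y) -> float:
        y1, y2 = float(y[0]), float(y[1])
        s = y1 + y2
        if y1 < 0.0 or y2 < 0.0:
            raise ModelError("negative coordinate")
        out = (L - mu) / kappa + (mu / kappa) * np.log(mu / L)
        if y1 > 0.0:  # y ln y -> 0 at the boundary
            out += y1 * np.log(y1 / lam1)
        if y2 > 0.0:
            out += y2 * np.log(y2 / lam2)
        if s > 0.0:
            out += s * (np.log((mu + kappa * s) / s) - 1.0)
        out += (mu / kappa) * np.log(1.0 + (kappa / mu) * s)
        return float(out)

    def action() -> float:
        return float((L - mu) / kappa + (mu / kappa) * np.log(mu / L))

    def sigma() -> np.ndarray:
        m = mu / L
        return (kappa / (L - mu)) * np.array(
            [[L / lam1 - m, -m], [-m, L / lam2 - m]]
        )

    def det_sigma() -> float:
        return float(kappa ** 2 * L / (lam1 * lam2 * (L - mu)))

    def qsd(N: int, x) -> float:
        x = np.asarray(x, dtype=float)
        y1, y2 = x[0] / N, x[1] / N
        s = y1 + y2
        pref = (L - mu) / (
            2.0 * np.pi * N
            * np.sqrt(kappa * y1 * y2 * s * (mu + kappa * s))
        )
        return float(pref * np.exp(-N * potential((y1, y2))))

    def log_tau(N: float) -> float:
        """Closed-form prefactor; the nu = 0 birth-death case."""
        if nu1 > 0.0:
            raise ModelError("closed-form tau requires nu1 = nu2 = 0")
        return float(-2.0 * np.log(L - mu)
                     + 0.5 * np.log(2.0 * np.pi * mu * kappa / N)
                     + N * action())

    def tau(N: float) -> float:
        return float(np.exp(log_tau(N)))

    ref = ReferenceFormulas(y_star=y_star, potential=potential, sigma=sigma,
                            det_sigma=det_sigma, action=action, qsd=qsd,
                            tau=tau, log_tau=log_tau)
    config = {"model": "two_group",
              "params": {"mu": float(mu), "kappa": float(kappa),
                         "lam1": float(lam1), "lam2": float(lam2),
                         "nu1": float(nu1), "nu2": float(nu2)}}
    return Builtin(model, ref, config)


#: registry used by config loading and the command-line interface
FACTORIES = {
    "sis": make_sis,
    "logistic": make_logistic,
    "separable_bd": make_separable_bd,
    "competition": make_competition,
    "two_group": make_two_group,
}


def from_config(cfg: dict) -> Builtin:
    """Rebuild a built-in model from its serialisable config record."""
    name = cfg.get("model")
    if name not in FACTORIES:
        raise ModelError(
            f"unknown model {name!r}; available: {sorted(FACTORIES)}"
        )
    params = dict(cfg.get("params", {}))
    if name == "separable_bd":
        return make_separable_bd(params["b0"], params["b"], params["d0"],
                                params["d"], params.get("f"))
    if name == "competition":
        return make_competition(
            params["a"], params["b0"], params["b1"], params["b2"],
            params["b3"], params["c0"], params["c1"], params["c2"],
            params["d0"], params["d1"], params["d2"], params["d3"],
            params.get("f"))
    return FACTORIES[name](**params)
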
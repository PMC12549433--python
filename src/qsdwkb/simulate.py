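"""Stochastic simulation and the extinction-time estimation protocol.

The pipeline mirrors how mean extinction times are estimated empirically:
runs start at the lattice point nearest the deterministic equilibrium
(``ceil(N y*)`` componentwise), a burn-in of length ``t0`` lets the process
settle towards quasistationarity, runs that die before the burn-in ends are
discarded and re-run with fresh randomness, and the surviving extinction
times — right-censored at ``t_max - t0`` — feed a censored-exponential
maximum-likelihood estimate of ``tau`` with a chi-squared pivot confidence
interval.  An occupation-time estimator of the quasistationary distribution
is also provided.

Two simulation engines exist: a generic event-by-event Gillespie
implementation (the reference; works for any model), and a table-driven
kernel over the truncated lattice, compiled with numba, used by the protocol
operations where millions of events are needed.  The two are tested against
each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.stats import chi2

from .errors import AllCensored, ModelError, ProtocolError
from .oracle import TruncatedChain, build_truncated
from .process import PopulationProcess, find_equilibria, transition_rates


@dataclass
class Protocol:
    """Simulation protocol: start rule, burn-in, censoring, replication."""

    t0: float = 10.0
    t_max: float = 50000.0
    n_runs: int = 100
    seed: int = 0
    x0: Optional[np.ndarray] = None   # default: ceil(N y*) componentwise
    restart_factor: int = 100         # attempt budget = factor * n_runs

    def __post_init__(self):
        if not (0.0 < self.t0 < self.t_max):
            raise ProtocolError("need 0 < t0 < t_max")
        if self.n_runs < 1:
            raise ProtocolError("need n_runs >= 1")


@dataclass
class ExtinctionSample:
    """Censored extinction durations, measured from the end of burn-in."""

    durations: np.ndarray
    censored: np.ndarray
    t_limit: float  # the censoring point t_max - t0

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if np.any(self.durations < 0):
            raise ProtocolError("negative duration")
        if np.any(self.durations[self.censored] != self.t_limit):
            raise ProtocolError("censored durations must equal t_max - t0")
        if np.any(self.durations[~self.censored] >= self.t_limit):
            raise ProtocolError("uncensored durations must be below t_max - t0")


@dataclass
class TauEstimate:
    """Censored-exponential MLE of tau with a confidence interval."""

    tau_hat: float
    ci_low: float
    ci_high: float
    n_events: int
    level: float


# ---------------------------------------------------------------------------
# generic event-by-event Gillespie
# ---------------------------------------------------------------------------


def gillespie(model: PopulationProcess, N: int, x0, t_end: float,
              rng: np.random.Generator):
    """Exact stochastic simulation from state ``x0`` until absorption or
    ``t_end``; returns ``(times, states)`` including the initial state.

    Reference implementation: transparent, works for any model, but slow for
    long runs — the protocol operations use the compiled lattice kernel.
    """
    x = np.asarray(x0, dtype=int).copy()
    if not model.contains_state(x, N):
        raise ModelError(f"x0 = {x} not in the lattice state space")
    t = 0.0
    times = [0.0]
    states = [x.copy()]
    jumps = list(model.jumps)
    while True:
        rates = transition_rates(model, x, N)
        total = sum(rates.values())
        if total <= 0.0:
            if np.any(x):
                raise ModelError(
                    f"total rate 0 at nonzero state {x} (violates interior "
                    "positivity)"
                )
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        r = rng.uniform(0.0, total)
        acc = 0.0
        for l in jumps:
            acc += rates[l]
            if r < acc:
                x = x + np.asarray(l, dtype=int)
                break
        times.append(t)
        states.append(x.copy())
        if not np.any(x):
            break
    return np.asarray(times), np.asarray(states)


# ---------------------------------------------------------------------------
# compiled lattice kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _kernel_extinction(rates, targets, start, t_end, seed):
    """One run; returns (absorption time or t_end, absorbed flag)."""
    np.random.seed(seed)
    s = start
    t = 0.0
    n_jumps = rates.shape[1]
    while True:
        total = 0.0
        for j in range(n_jumps):
            total += rates[s, j]
        if total <= 0.0:
            return t, True
        t += np.random.exponential(1.0 / total)
        if t >= t_end:
            return t_end, False
        r = np.random.uniform(0.0, total)
        acc = 0.0
        for j in range(n_jumps):
            acc += rates[s, j]
            if r < acc:
                s = targets[s, j]
                break


@njit(cache=True)
def _kernel_occupation(rates, targets, start, t0, t_end, seed, occ):
    """One run accumulating occupation time per state on (t0, t_end).

    Returns (absorption time or t_end, absorbed flag); ``occ`` is updated in
    place with the time spent in each state inside the window, up to
    absorption.
    """
    np.random.seed(seed)
    s = start
    t = 0.0
    n_jumps = rates.shape[1]
    while True:
        total = 0.0
        for j in range(n_jumps):
            total += rates[s, j]
        if total <= 0.0:
            return t, True
        dt = np.random.exponential(1.0 / total)
        hi = t + dt
        if hi > t_end:
            hi = t_end
        lo = t if t > t0 else t0
        if hi > lo:
            occ[s] += hi - lo
        t += dt
        if t >= t_end:
            return t_end, False
        r = np.random.uniform(0.0, total)
        acc = 0.0
        for j in range(n_jumps):
            acc += rates[s, j]
            if r < acc:
                s = targets[s, j]
                break


class LatticeTables:
    """Per-state rate and target tables over a capped lattice (origin at 0).

    Built from the same enumeration as the exact oracle, but including the
    absorbing origin; outward jumps at an artificial cap are clipped, so the
    cap must be generous enough that the process essentially never reaches
    it (default five times the deterministic equilibrium).
    """

    def __init__(self, model: PopulationProcess, N: int,
                 cap_factor: float = 5.0, equilibrium=None):
        self.model = model
        self.N = N
        if model.is_box:
            caps = np.rint(N * np.asarray(model.fractions)).astype(np.int64)
        else:
            if equilibrium is None:
                equilibrium = find_equilibria(model)
            caps = np.ceil(cap_factor * N * equilibrium.y_star).astype(np.int64)
            caps = np.maximum(caps, 2)
        self.caps = caps
        k = model.k
        X = np.indices(caps + 1).reshape(k, -1).T.astype(np.int64)
        self.states = X
        n = X.shape[0]
        jumps = list(model.jumps)
        self.rates = np.zeros((n, len(jumps)))
        self.targets = np.zeros((n, len(jumps)), dtype=np.int64)
        Y = X / float(N)
        for j, l in enumerate(jumps):
            la = np.asarray(l, dtype=np.int64)
            r = np.maximum(N * model.rate_batch(l, Y), 0.0)
            T = X + la
            inside = np.all(T >= 0, axis=1) & np.all(T <= caps, axis=1)
            r[~inside] = 0.0
            flat = np.zeros(n, dtype=np.int64)
            idx = np.nonzero(inside)[0]
            flat[idx] = np.ravel_multi_index(T[idx].T, caps + 1)
            self.rates[:, j] = r
            self.targets[:, j] = flat
        # origin is absorbing by construction (all rates vanish there)
        self.rates[0, :] = 0.0

    def index_of(self, x) -> int:
        return int(np.ravel_multi_index(np.asarray(x, dtype=int), self.caps + 1))


def _default_start(model: PopulationProcess, N: int, protocol: Protocol,
                   equilibrium=None) -> np.ndarray:
    if protocol.x0 is not None:
        return np.asarray(protocol.x0, dtype=int)
    if equilibrium is None:
        equilibrium = find_equilibria(model)
    return np.ceil(N * equilibrium.y_star).astype(int)


def _run_seed(base: int, counter: int) -> int:
    # counter-based substreams; numba's legacy RNG takes 32-bit seeds
    return int((base * 2654435761 + counter * 97531) % (2 ** 31 - 1))


def sample_extinction_times(model: PopulationProcess, N: int,
                            protocol: Protocol,
                            equilibrium=None,
                            tables: Optional[LatticeTables] = None
                            ) -> ExtinctionSample:
    """Collect ``n_runs`` post-burn-in extinction durations.

    Each run starts at ``ceil(N y*)``; runs extinct before the end of the
    burn-in are discarded and re-run from scratch with a fresh random
    substream until the sample is complete.  Durations are measured from the
    end of the burn-in and right-censored at ``t_max - t0``.
    """
    if equilibrium is None and (protocol.x0 is None or tables is None):
        equilibrium = find_equilibria(model)
    if tables is None:
        tables = LatticeTables(model, N, equilibrium=equilibrium)
    start = tables.index_of(_default_start(model, N, protocol, equilibrium))
    durations = np.empty(protocol.n_runs)
    censored = np.zeros(protocol.n_runs, dtype=bool)
    budget = protocol.restart_factor * protocol.n_runs
    counter = 0
    for i in range(protocol.n_runs):
        while True:
            if counter >= budget:
                raise ProtocolError(
                    f"restart budget exhausted after {counter} attempts: "
                    "quasistationarity unreachable at this N?"
                )
            seed = _run_seed(protocol.seed, counter)
            counter += 1
            t_abs, absorbed = _kernel_extinction(
                tables.rates, tables.targets, start, protocol.t_max, seed
            )
            if absorbed and t_abs <= protocol.t0:
                continue  # died during burn-in: discard, fresh randomness
            if absorbed:
                durations[i] = t_abs - protocol.t0
            else:
                durations[i] = protocol.t_max - protocol.t0
                censored[i] = True
            break
    return ExtinctionSample(durations, censored,
                            t_limit=protocol.t_max - protocol.t0)


def censored_exp_mle(sample: ExtinctionSample, level: float = 0.95
                     ) -> TauEstimate:
    """Maximum-likelihood estimate of tau from censored exponential data.

    ``tau_hat = (total observation time) / (number of observed
    extinctions)``.  The confidence interval is the chi-squared pivot for
    Type-I censored exponential samples,
    ``[2T / chi2_{1-a/2}(2d + 2),  2T / chi2_{a/2}(2d)]``
    with ``T`` the total time and ``d`` the event count.
    """
    d = int(np.sum(~sample.censored))
    if d == 0:
        raise AllCensored("no uncensored extinction times in the sample")
    T = float(np.sum(sample.durations))
    alpha = 1.0 - level
    low = 2.0 * T / chi2.ppf(1.0 - alpha / 2.0, 2 * d + 2)
    high = 2.0 * T / chi2.ppf(alpha / 2.0, 2 * d)
    return TauEstimate(tau_hat=T / d, ci_low=float(low), ci_high=float(high),
                       n_events=d, level=level)


@dataclass
class EmpiricalQSD:
    """Occupation-time estimate of the quasistationary distribution."""

    states: np.ndarray   # (n, k) states with positive mass
    mass: np.ndarray     # (n,) probabilities summing to 1

    def as_dict(self) -> dict:
        return {tuple(int(v) for v in s): float(m)
                for s, m in zip(self.states, self.mass)}


def empirical_qsd(model: PopulationProcess, N: int, protocol: Protocol,
                  mode: str = "all_alive",
                  equilibrium=None,
                  tables: Optional[LatticeTables] = None) -> EmpiricalQSD:
    """Occupation-time measure over nonzero states between burn-in and
    censoring, normalised to a probability distribution.

    ``mode="all_alive"`` (default): every run contributes its alive time
    after the burn-in, up to extinction or ``t_max``.
    ``mode="survivors"``: only runs still alive at ``t_max`` contribute.
    Runs extinct before the end of the burn-in are discarded and re-run, as
    in :func:`sample_extinction_times`.
    """
    if mode not in ("all_alive", "survivors"):
        raise ProtocolError(f"unknown mode {mode!r}")
    if equilibrium is None and (protocol.x0 is None or tables is None):
        equilibrium = find_equilibria(model)
    if tables is None:
        tables = LatticeTables(model, N, equilibrium=equilibrium)
    start = tables.index_of(_default_start(model, N, protocol, equilibrium))
    n = tables.rates.shape[0]
    occ_total = np.zeros(n)
    occ_run = np.zeros(n)
    budget = protocol.restart_factor * protocol.n_runs
    counter = 0
    collected = 0
    while collected < protocol.n_runs:
        if counter >= budget:
            raise ProtocolError("restart budget exhausted")
        seed = _run_seed(protocol.seed, counter)
        counter += 1
        occ_run[:] = 0.0
        t_abs, absorbed = _kernel_occupation(
            tables.rates, tables.targets, start, protocol.t0, protocol.t_max,
            seed, occ_run
        )
        if absorbed and t_abs <= protocol.t0:
            continue
        collected += 1
        if mode == "survivors" and absorbed:
            continue
        occ_total += occ_run
    occ_total[0] = 0.0  # the absorbing origin carries no conditional mass
    total = float(occ_total.sum())
    if total <= 0.0:
        raise ProtocolError("no surviving occupation time collected")
    keep = np.nonzero(occ_total)[0]
    return EmpiricalQSD(states=tables.states[keep],
                        mass=occ_total[keep] / total)


def total_variation(emp: EmpiricalQSD, chain: TruncatedChain,
                    u: np.ndarray) -> float:
    """Total-variation distance between an empirical QSD and an exact one."""
    exact = {tuple(int(v) for v in s): float(m)
             for s, m in zip(chain.states, u)}
    est = emp.as_dict()
    keys = set(exact) | set(est)
    return 0.5 * sum(abs(exact.get(x, 0.0) - est.get(x, 0.0)) for x in keys)
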
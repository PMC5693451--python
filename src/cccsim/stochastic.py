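"""Exact stochastic simulation of the cascade and count statistics.

All stochastic models use the direct Gillespie method with a fixed
volume convention Omega = 1, so copy numbers and concentrations are
numerically identical.  Three models are provided:

* the full 9-reaction network with explicit complex formation,
* the perfect-binding (K -> 0) birth-death limit of the m1 count, whose
  saturated stationary law is binomial with Fano factor 1 - kc/(kc+kp)
  (the carrier-conservation feedback), and
* a "double Michaelis-Menten" comparator in which production and
  consumption are saturated by two independent carrier pools, so the
  count performs an unbiased random walk and the Fano factor never
  drops below 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .params import CCCParams


@dataclass(frozen=True)
class SSAConfig:
    """Run configuration for the stochastic simulators.

    ``max_events`` bounds the event count; ``burn_in`` (time units) is
    discarded by the statistics layer.
    """

    seed: int
    t_end: float
    burn_in: float = 0.0
    max_events: int = 20_000_000

    def __post_init__(self):
        if not self.burn_in < self.t_end:
            raise ValueError("burn_in must be < t_end")


@dataclass
class CountTrajectory:
    """Piecewise-constant event path: counts[i] holds on [times[i], times[i+1])."""

    times: np.ndarray            # event times, starting at 0
    counts: np.ndarray           # shape (n_events, n_species) or (n_events,)
    species: tuple
    t_end: float

    def series(self, name: str) -> np.ndarray:
        if self.counts.ndim == 1:
            return self.counts
        return self.counts[:, self.species.index(name)]


@dataclass
class CountStats:
    """Time-weighted moments of a molecule-count path."""

    mean: float
    variance: float
    fano: Optional[float]
    n_samples: int
    burn_in_used: float


def count_statistics(traj: CountTrajectory, burn_in: float,
                     species: Optional[str] = None) -> CountStats:
    """Time-weighted mean/variance/Fano over (burn_in, t_end].

    Weights are the dwell times between events (the last state is held
    until t_end).  A zero mean yields an undefined (None) Fano factor.
    """
    x = traj.series(species) if species else traj.counts
    if x.ndim != 1:
        raise ValueError("specify the species for a multi-species path")
    t = traj.times
    if burn_in >= traj.t_end:
        raise ValueError("burn_in must be < t_end")
    edges = np.append(t, traj.t_end)
    lo = np.clip(edges[:-1], burn_in, traj.t_end)
    hi = np.clip(edges[1:], burn_in, traj.t_end)
    w = hi - lo
    wtot = w.sum()
    if wtot <= 0:
        raise ValueError("empty post-burn-in window")
    mean = float(np.dot(w, x) / wtot)
    var = float(np.dot(w, (x - mean) ** 2) / wtot)
    return CountStats(mean=mean, variance=var,
                      fano=(var / mean if mean > 0 else None),
                      n_samples=int((t >= burn_in).sum()),
                      burn_in_used=burn_in)


def fano_analytic(kc: float, kp: float) -> float:
    """Stationary Fano factor 1 - kc/(kc+kp) of the saturated cascade."""
    if kc <= 0 or kp <= 0:
        raise ValueError("kc and kp must be > 0")
    return 1.0 - kc / (kc + kp)


def master_equation_stationary(birth: Callable[[int], float],
                               death: Callable[[int], float],
                               nmax: int) -> np.ndarray:
    """Detailed-balance stationary law of a birth-death chain on 0..nmax.

    pi(n) proportional to prod_{k=1..n} birth(k-1)/death(k), accumulated
    in log space for stability.
    """
    if death(0) != 0 and not math.isclose(death(0), 0.0):
        raise ValueError("death(0) must be 0")
    logs = np.empty(nmax + 1)
    logs[0] = 0.0
    for n in range(1, nmax + 1):
        b, d = birth(n - 1), death(n)
        if d <= 0:
            raise ValueError(f"death({n}) must be > 0")
        logs[n] = logs[n - 1] + (math.log(b) - math.log(d) if b > 0 else -math.inf)
    logs -= logs.max()
    pi = np.exp(logs)
    z = pi.sum()
    if z <= 0:
        raise ValueError("zero normalization")
    return pi / z


# ---------------------------------------------------------------------------
# Gillespie simulators
# ---------------------------------------------------------------------------

# full-model state ordering and stoichiometry (9 reactions)
FULL_SPECIES = ("m0", "m1", "m2", "c", "cstar", "cm0", "cstarm1")
_FULL_STOICH = np.array([
    #  m0  m1  m2   c  c*  cm0 c*m1
    [  1,  0,  0,  0,  0,  0,  0],   # influx
    [ -1,  0,  0,  0,  0,  0,  0],   # leak
    [ -1,  0,  0, -1,  0,  1,  0],   # c + m0 -> c.m0
    [  1,  0,  0,  1,  0, -1,  0],   # c.m0 -> c + m0
    [  0,  1,  0,  0,  1, -1,  0],   # c.m0 -> m1 + c*
    [  0, -1,  0,  0, -1,  0,  1],   # c* + m1 -> c*.m1
    [  0,  1,  0,  0,  1,  0, -1],   # c*.m1 -> c* + m1
    [  0,  0,  1,  1,  0,  0, -1],   # c*.m1 -> m2 + c
    [  0,  0, -1,  0,  0,  0,  0],   # efflux
], dtype=np.int64)


def _full_propensities(x, p: CCCParams) -> np.ndarray:
    m0, m1, m2, c, cstar, cm0, cstarm1 = x
    return np.array([
        p.kin,
        p.kleak * m0,
        p.ka0 * c * m0,
        p.ka0 * p.K0 * cm0,
        p.kc * cm0,
        p.ka1 * cstar * m1,
        p.ka1 * p.K1 * cstarm1,
        p.kp * cstarm1,
        p.kout * m2,
    ])


def ssa_full(params: CCCParams, state0, config: SSAConfig) -> CountTrajectory:
    """Direct-method Gillespie path of the full complex-formation network.

    The carrier copy total c + c* + c.m0 + c*.m1 is conserved exactly at
    every event.  Paths are reproducible given the seed.
    """
    x = np.asarray(state0, dtype=np.int64).copy()
    if x.min() < 0 or len(x) != 7:
        raise ValueError("state0 must be 7 non-negative integer counts")
    rng = np.random.default_rng(config.seed)
    times = [0.0]
    states = [x.copy()]
    t = 0.0
    for _ in range(config.max_events):
        a = _full_propensities(x, params)
        atot = a.sum()
        if atot <= 0:
            break
        if not np.isfinite(atot):
            raise RuntimeError(f"propensity overflow at t = {t:g} (m0 = {x[0]})")
        t += rng.exponential(1.0 / atot)
        if t >= config.t_end:
            break
        r = rng.random() * atot
        j = int(np.searchsorted(np.cumsum(a), r))
        x += _FULL_STOICH[j]
        times.append(t)
        states.append(x.copy())
    return CountTrajectory(times=np.array(times), counts=np.array(states),
                           species=FULL_SPECIES, t_end=config.t_end)


def _birth_death_ssa(birth: Callable[[int], float], death: Callable[[int], float],
                     n0: int, config: SSAConfig) -> CountTrajectory:
    """Generic single-species birth-death Gillespie loop."""
    rng = np.random.default_rng(config.seed)
    n = int(n0)
    t = 0.0
    times = [0.0]
    counts = [n]
    # draw uniforms in blocks; two per event
    block = 65536
    u = rng.random(block)
    ptr = 0
    for _ in range(config.max_events):
        b = birth(n)
        d = death(n)
        atot = b + d
        if atot <= 0:
            break
        if ptr + 2 > block:
            u = rng.random(block)
            ptr = 0
        t += -math.log(1.0 - u[ptr]) / atot
        if t >= config.t_end:
            break
        n += 1 if u[ptr + 1] * atot < b else -1
        ptr += 2
        times.append(t)
        counts.append(n)
    return CountTrajectory(times=np.array(times),
                           counts=np.array(counts, dtype=np.int64),
                           species=("n",), t_end=config.t_end)


def ssa_limit(kc: float, kp: float, cmax: int, kin: float, saturated: bool,
              config: SSAConfig, n0: int = 0) -> CountTrajectory:
    """Perfect-binding limit of the m1 count n.

    Saturated (m0 in excess, flux carrier-limited): birth kc (cmax - n),
    death kp n -- feedback through the conserved pool; stationary law
    binomial(cmax, kc/(kc+kp)).  Unsaturated: birth kin (constant),
    death kp n; stationary law Poisson(kin/kp).
    """
    if cmax <= 0:
        raise ValueError("cmax must be > 0")
    if saturated:
        if n0 > cmax:
            raise ValueError("n0 exceeds cmax")
        birth = lambda n: kc * (cmax - n)
        death = lambda n: kp * n
    else:
        birth = lambda n: kin
        death = lambda n: kp * n
    traj = _birth_death_ssa(birth, death, n0, config)
    if saturated and traj.counts.max() > cmax:
        raise AssertionError("n exceeded cmax in the saturated limit model")
    return traj


def ssa_double_mm(kc: float, kp: float, c1: int, c2: int, n0: int,
                  config: SSAConfig, n_cap: int = 10_000_000) -> CountTrajectory:
    """Comparator without shared carrier conservation.

    Production and consumption are each saturated by an independent pool
    (birth kc c1, death kp c2 for n > 0), so n performs a random walk:
    unbiased when kc c1 = kp c2, absorbed near 0 or divergent otherwise.
    Reported paths are truncated at ``n_cap``.
    """
    birth = lambda n: kc * c1 if n < n_cap else 0.0
    death = lambda n: kp * c2 if n > 0 else 0.0
    return _birth_death_ssa(birth, death, n0, config)
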
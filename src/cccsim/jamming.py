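"""Jamming threshold, slow relaxation and critical scaling.

When the influx kin exceeds the carrier-limited flux capacity of the
cascade the first metabolite accumulates without bound ("jamming"); just
below the capacity the relaxation time to the steady state diverges as
(kin_th - kin)^-1.  The capacity has a closed form for kleak = 0:

    kin_th = kc kp / (2 (kc+kp)) *
             { cpool + csum + a - sqrt((cpool - csum + a)^2 + 4 csum a) }

with a = kc K1 / (kc + kp); in the perfect-binding limit K1 -> 0 this
reduces to kc kp min(cpool, csum) / (kc + kp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import Trajectory, integrate
from .params import CCCParams, ConservedTriple


def kin_threshold(params: CCCParams, cpool: float, csum: float) -> float:
    """Closed-form jamming threshold of the influx rate (kleak = 0 only)."""
    if params.kleak != 0:
        raise ValueError(
            "the jamming threshold is defined only for kleak = 0; "
            "with a finite leak the m0 nullcline is tilted and a fixed "
            "point exists for any kin")
    if cpool <= 0 or csum <= 0:
        raise ValueError("cpool and csum must be > 0")
    kc, kp = params.kc, params.kp
    a = kc * params.K1 / (kc + kp)
    rad = math.sqrt((cpool - csum + a) ** 2 + 4.0 * csum * a)
    return kc * kp / (2.0 * (kc + kp)) * (cpool + csum + a - rad)


def kin_threshold_limit(kc: float, kp: float, cpool: float, csum: float) -> float:
    """Perfect-binding (K1 -> 0) flux capacity kc kp min(cpool, csum)/(kc+kp)."""
    if min(kc, kp, cpool, csum) <= 0:
        raise ValueError("all arguments must be > 0")
    return kc * kp * min(cpool, csum) / (kc + kp)


def initial_state_jam(conserved: ConservedTriple, m0: float = 100.0):
    """Jammed-start initial condition: a large m0 bolus, all carrier active.

    The 5-ODE vector (m0, 0, 0, c_t, c*_t) with the carrier split chosen
    compatibly with the conserved pair (c_t = min(csum, cpool)).
    """
    c_t = min(conserved.csum, conserved.cpool)
    m1 = conserved.csum - c_t
    cstar_t = conserved.cpool - c_t
    return np.array([m0, m1, 0.0, c_t, cstar_t])


def threshold_bisect(params: CCCParams, conserved: ConservedTriple,
                     tol: float = 1e-4, t_end: float = 1e4,
                     bracket=None) -> float:
    """Numerical jamming threshold by bisection on the divergence of m0.

    A run from the jammed-start condition is classed as diverging when
    m0 is still growing over the late plateau (m0(t_end) > m0(t0)); the
    plateau drift rate is kin - kin_th, so the trend resolves the
    boundary far below the bisection tolerance.
    """
    if params.kleak != 0:
        raise ValueError("threshold bisection requires kleak = 0")
    if bracket is None:
        # K1 -> 0 capacity is an upper bound on the threshold
        cap = kin_threshold_limit(params.kc, params.kp,
                                  conserved.cpool, conserved.csum)
        bracket = (1e-3 * cap, 1.05 * cap + 1e-3)
    t0 = 100.0

    def diverges(kin: float) -> bool:
        p = params.replace(kin=kin)
        traj = integrate("reduced5", initial_state_jam(conserved), p,
                         t_end=t_end, sample_dt=t0)
        m0 = traj.frame["m0"].to_numpy()
        # require genuine growth: a relaxed run sits at the fixed point
        # where sampling noise could otherwise flip the comparison
        return m0[-1] > m0[1] + 1e-3

    lo, hi = bracket
    if diverges(lo) or not diverges(hi):
        raise RuntimeError(
            f"divergence predicate undecided on bracket {bracket}: "
            f"diverges({lo})={diverges(lo)}, diverges({hi})={diverges(hi)}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if diverges(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def relaxation_time(traj: Trajectory, threshold: float = 1e-7) -> Optional[float]:
    """Earliest sample time where the summed per-step concentration change
    of all species drops below ``threshold``; None if never reached."""
    if len(traj) < 2:
        raise ValueError("trajectory needs at least 2 samples")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    cols = [c for c in ("m0", "m1", "m2", "c", "cstar") if c in traj.frame]
    diffs = traj.frame[cols].diff().abs().sum(axis=1).to_numpy()
    hits = np.where(diffs[1:] < threshold)[0]
    if len(hits) == 0:
        return None
    return float(traj.times[hits[0] + 1])


def step_response(params: CCCParams, kin_before: float, kin_after: float,
                  pre_run: float = 100.0, t_end: float = 2000.0,
                  conserved: Optional[ConservedTriple] = None,
                  sample_dt: float = 1.0) -> Trajectory:
    """Influx step protocol: pre-run at kin_before, switch to kin_after.

    The system is integrated from a drained start for ``pre_run`` (for a
    supercritical kin_before this lands on the jammed quasi-steady
    plateau, the only notion of 'steady' available there), the clock is
    reset, and integration continues with kin_after.  The returned
    trajectory starts at the switch (t = 0).
    """
    if pre_run <= 0:
        raise ValueError("pre_run must be > 0")
    if conserved is None:
        from .params import DEFAULT_CONSERVED
        conserved = DEFAULT_CONSERVED
    pre = integrate("reduced5", initial_state_jam(conserved, m0=0.0),
                    params.replace(kin=kin_before), t_end=pre_run,
                    sample_dt=pre_run / 4)
    y_switch = pre.frame[["m0", "m1", "m2", "c_t", "cstar_t"]].iloc[-1].to_numpy()
    return integrate("reduced5", y_switch, params.replace(kin=kin_after),
                     t_end=t_end, sample_dt=sample_dt)


def carrier_ratio_perturbation(params: CCCParams, ratio_active_after: float,
                               pre_run: float = 500.0, t_end: float = 2000.0,
                               conserved: Optional[ConservedTriple] = None,
                               sample_dt: float = 1.0) -> Trajectory:
    """Perturb the active/inactive split of the carrier pool.

    After a pre-run to (quasi-)steady state, the carrier totals are
    reassigned to (r, 1-r) * cpool with the metabolites held fixed; this
    changes csum but leaves cpool untouched.
    """
    if not 0.0 < ratio_active_after < 1.0:
        raise ValueError("ratio_active_after must be in (0, 1)")
    if conserved is None:
        from .params import DEFAULT_CONSERVED
        conserved = DEFAULT_CONSERVED
    pre = integrate("reduced5", initial_state_jam(conserved, m0=0.0), params,
                    t_end=pre_run, sample_dt=pre_run / 4)
    m0, m1, m2 = pre.frame[["m0", "m1", "m2"]].iloc[-1]
    cpool = conserved.cpool
    y_jump = np.array([m0, m1, m2, ratio_active_after * cpool,
                       (1.0 - ratio_active_after) * cpool])
    return integrate("reduced5", y_jump, params, t_end=t_end,
                     sample_dt=sample_dt)


@dataclass
class RelaxationScanResult:
    """Relaxation times over a kin grid and the fitted critical exponent."""

    kin_values: np.ndarray
    tau_values: np.ndarray
    fitted_exponent: float
    kin_th_used: float
    excluded: tuple = ()


def relaxation_scan(params: CCCParams, kin_values: Sequence[float],
                    conserved: Optional[ConservedTriple] = None,
                    threshold: float = 1e-7, m0_init: float = 100.0,
                    sample_dt: float = 1.0) -> RelaxationScanResult:
    """Relaxation time versus kin below the jamming threshold.

    Each run starts from the jammed-start condition with a bolus
    ``m0_init``; the horizon is scaled as the expected drain time
    m0_init/(kin_th - kin) plus a margin.  The critical exponent is the
    least-squares slope of log(tau) against log(kin_th - kin); runs that
    never relax are excluded and reported.
    """
    if conserved is None:
        from .params import DEFAULT_CONSERVED
        conserved = DEFAULT_CONSERVED
    kin_values = np.sort(np.asarray(kin_values, dtype=float))
    kin_th = kin_threshold(params, conserved.cpool, conserved.csum)
    if np.any(kin_values >= kin_th):
        raise ValueError("all kin values must lie below the jamming threshold")
    taus, excluded = [], []
    for kin in kin_values:
        gap = kin_th - kin
        t_end = 1.5 * m0_init / gap + 200.0
        traj = integrate("reduced5", initial_state_jam(conserved, m0=m0_init),
                         params.replace(kin=kin), t_end=t_end,
                         sample_dt=sample_dt)
        tau = relaxation_time(traj, threshold)
        if tau is None:
            excluded.append(float(kin))
            taus.append(np.nan)
        else:
            taus.append(tau)
    taus = np.asarray(taus)
    ok = np.isfinite(taus)
    if ok.sum() >= 2:
        slope = float(np.polyfit(np.log(kin_th - kin_values[ok]),
                                 np.log(taus[ok]), 1)[0])
    else:
        slope = math.nan
    return RelaxationScanResult(kin_values=kin_values, tau_values=taus,
                                fitted_exponent=slope, kin_th_used=kin_th,
                                excluded=tuple(excluded))
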
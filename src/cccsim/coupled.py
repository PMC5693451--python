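"""N cascades coupled through a single shared carrier pool.

Every cascade's consuming step draws the same free active carrier and
every producing step regenerates it.  With several substrates competing
for one carrier the binding closure is no longer a quadratic: the free
concentration solves

    c + sum_i m0_i c / (K0_i + c) = [c]_t

by bracketed 1-D root finding (and analogously for c* with the m1_i).
Under coupling the per-cascade csum is no longer conserved; the shared
invariants are cpool = [c]_t + [c*]_t and [c]_t + sum_i [m1_i].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .core import Trajectory, rhs_reduced5
from .params import CCCParams

import math

import pandas as pd
from scipy.integrate import solve_ivp


@dataclass(frozen=True)
class CoupledParams:
    """Per-cascade rate constants plus the shared carrier pool size."""

    cascades: tuple
    cpool: float

    def __post_init__(self):
        if len(self.cascades) < 1:
            raise ValueError("need at least one cascade")
        if not all(isinstance(p, CCCParams) for p in self.cascades):
            raise TypeError("cascades must be CCCParams")
        if self.cpool <= 0:
            raise ValueError("cpool must be > 0")

    @property
    def n(self) -> int:
        return len(self.cascades)


def free_carrier_competitive(total: float, partner_totals: Sequence[float],
                             Ks: Sequence[float]) -> float:
    """Free carrier under competitive binding of several partners.

    Solves c + sum_i p_i c/(K_i + c) = total for c in [0, total] to a
    1e-12 tolerance; reduces to the single-partner quadratic for N = 1.
    """
    total = float(total)
    if total < 0:
        raise ValueError("total must be >= 0")
    if total == 0.0:
        return 0.0
    p = np.asarray(partner_totals, dtype=float)
    K = np.asarray(Ks, dtype=float)

    def g(c):
        return c + np.sum(p * c / (K + c)) - total

    return brentq(g, 0.0, total, xtol=1e-14, rtol=1e-14)


# state vector: [m0_1, m1_1, m2_1, ..., m0_N, m1_N, m2_N, c_t, cstar_t]

def rhs_coupled(y, params: CoupledParams, t: float = 0.0,
                kin1_t=None) -> np.ndarray:
    """Derivatives of the coupled system; conserves cpool exactly.

    ``kin1_t``, if given, overrides cascade 1's influx as a function of
    time (used by the step protocol).
    """
    n = params.n
    mets = np.asarray(y[:3 * n], dtype=float).reshape(n, 3)
    c_t, cstar_t = float(y[3 * n]), float(y[3 * n + 1])
    m0s = np.clip(mets[:, 0], 0.0, None)
    m1s = np.clip(mets[:, 1], 0.0, None)
    K0s = [p.K0 for p in params.cascades]
    K1s = [p.K1 for p in params.cascades]
    c = free_carrier_competitive(max(c_t, 0.0), m0s, K0s)
    cstar = free_carrier_competitive(max(cstar_t, 0.0), m1s, K1s)
    dy = np.empty_like(np.asarray(y, dtype=float))
    vc_sum = vp_sum = 0.0
    for i, p in enumerate(params.cascades):
        kin = p.kin if (kin1_t is None or i != 0) else kin1_t(t)
        vc = p.kc * m0s[i] * c / (p.K0 + c)
        vp = p.kp * m1s[i] * cstar / (p.K1 + cstar)
        dy[3 * i] = kin - vc - p.kleak * mets[i, 0]
        dy[3 * i + 1] = vc - vp
        dy[3 * i + 2] = vp - p.kout * mets[i, 2]
        vc_sum += vc
        vp_sum += vp
    dy[3 * n] = -vc_sum + vp_sum
    dy[3 * n + 1] = vc_sum - vp_sum
    return dy


def coupled_columns(n: int):
    cols = []
    for i in range(1, n + 1):
        cols += [f"m0_{i}", f"m1_{i}", f"m2_{i}"]
    return cols + ["c_t", "cstar_t"]


def integrate_coupled(params: CoupledParams, y0, t_end: float,
                      sample_dt: float = 1.0, kin1_t=None,
                      rtol: float = 1e-9, atol: float = 1e-12) -> Trajectory:
    """Integrate the coupled system on a uniform grid (stiff solver)."""
    y0 = np.asarray(y0, dtype=float)
    if len(y0) != 3 * params.n + 2:
        raise ValueError(f"state needs {3 * params.n + 2} entries")
    nsteps = int(math.floor(t_end / sample_dt + 1e-9))
    t_eval = np.linspace(0.0, nsteps * sample_dt, nsteps + 1)
    sol = solve_ivp(lambda t, y: rhs_coupled(y, params, t, kin1_t),
                    (0.0, t_eval[-1]), y0, t_eval=t_eval, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"coupled integration failed: {sol.message}")
    ys = np.clip(sol.y.T, 0.0, None)
    frame = pd.DataFrame(ys, columns=coupled_columns(params.n))
    return Trajectory(times=sol.t, frame=frame, model_tag="coupled")


def coupled_step_response(params: CoupledParams, kin1_before: float,
                          kin1_after: float, pre_run: float = 100.0,
                          t_end: float = 2000.0, sample_dt: float = 1.0,
                          y0: Optional[Sequence[float]] = None) -> Trajectory:
    """Step protocol on cascade 1's influx in the coupled system."""
    n = params.n
    if y0 is None:
        y0 = np.zeros(3 * n + 2)
        y0[3 * n] = params.cpool          # all carrier initially active
    p_before = CoupledParams(
        cascades=(params.cascades[0].replace(kin=kin1_before),)
        + params.cascades[1:], cpool=params.cpool)
    pre = integrate_coupled(p_before, y0, t_end=pre_run,
                            sample_dt=pre_run / 4)
    y_switch = pre.frame.iloc[-1].to_numpy()
    p_after = CoupledParams(
        cascades=(params.cascades[0].replace(kin=kin1_after),)
        + params.cascades[1:], cpool=params.cpool)
    return integrate_coupled(p_after, y_switch, t_end=t_end,
                             sample_dt=sample_dt)
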
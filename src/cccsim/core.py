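"""Deterministic formulations of the carrier cycling cascade.

Three equivalent formulations are provided:

``full``
    Seven mass-action ODEs with explicit complex formation
    (m0, m1, m2, c, c*, c.m0, c*.m1).
``reduced5``
    Five ODEs obtained by adiabatic elimination of the fast
    association/dissociation reactions; the carrier variables are the
    totals [c]_t = [c] + [c.m0] and [c*]_t = [c*] + [c*.m1], and the
    metabolite variables are totals (free + complexed).
``reduced2``
    Two ODEs for (m0, m1) obtained by additionally exploiting the two
    conserved quantities cpool and csum.

The fluxes of the two catalytic steps are

    v_c = kc * [m0] * [c]  / (K0 + [c])      (carrier consuming)
    v_p = kp * [m1] * [c*] / (K1 + [c*])     (carrier producing)

where the free carrier concentrations follow from the binding
equilibrium (a quadratic in the free concentration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import CCCParams, ConservedTriple

MODEL_TAGS = ("full", "reduced5", "reduced2")

#: evolved state variables of each formulation, in vector order
STATE_VARS = {
    "full": ("m0", "m1", "m2", "c", "cstar", "cm0", "cstarm1"),
    "reduced5": ("m0", "m1", "m2", "c_t", "cstar_t"),
    "reduced2": ("m0", "m1"),
}

#: columns reported in trajectory frames (free carriers derived for the
#: reduced models)
FRAME_COLS = {
    "full": ("m0", "m1", "m2", "c", "cstar", "cm0", "cstarm1"),
    "reduced5": ("m0", "m1", "m2", "c", "cstar", "c_t", "cstar_t"),
    "reduced2": ("m0", "m1", "c", "cstar"),
}


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the time of failure."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g})")
        self.t_fail = t_fail


def free_carrier(total: float, partner_total: float, K: float) -> float:
    """Free concentration of a carrier given its bound+free total.

    Solves x^2 + (K + partner_total - total) x - K total = 0 for the
    unique non-negative root, i.e. inverts

        total = x + partner_total * x / (K + x).

    Numerically stable for both signs of the linear coefficient.
    Accepts scalars or arrays.
    """
    total = np.asarray(total, dtype=float)
    partner_total = np.asarray(partner_total, dtype=float)
    if np.any(total < 0) or np.any(partner_total < 0):
        raise ValueError("totals must be >= 0")
    if K <= 0:
        raise ValueError("K must be > 0 (use the stochastic limit model for K -> 0)")
    b = K + partner_total - total
    disc = np.sqrt(b * b + 4.0 * K * total)
    # root = (-b + disc) / 2, rewritten to avoid cancellation when b > 0
    x = np.where(b > 0, 2.0 * K * total / (disc + b), 0.5 * (disc - b))
    if x.ndim == 0:
        return float(x)
    return x


def conserved_quantities(state, which_model: str) -> ConservedTriple:
    """Conserved triple (cpool, csum, cdiff_star) of a state.

    ``state`` is a mapping of variable name to concentration, using the
    variables of the named model.  For the full model the metabolite m1
    is counted as free + complexed (m1 + c*.m1), which is the quantity
    the dynamics actually conserve and the pre-image of the reduced
    models' [m1].
    """
    names = STATE_VARS[which_model]
    if hasattr(state, "keys"):
        arr = {k: float(state[k]) for k in names}
    else:
        arr = {k: float(v) for k, v in zip(names, state)}
    if any(v < 0 for v in arr.values()):
        raise ValueError("negative concentration in state")
    if which_model == "full":
        ct = arr["c"] + arr["cm0"]
        cst = arr["cstar"] + arr["cstarm1"]
        m1t = arr["m1"] + arr["cstarm1"]
    elif which_model == "reduced5":
        ct, cst, m1t = arr["c_t"], arr["cstar_t"], arr["m1"]
    else:
        raise ValueError("conserved quantities of the 2-ODE model are inputs, not state functions")
    return ConservedTriple(cpool=ct + cst, csum=ct + m1t, cdiff_star=cst - m1t)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def rhs_full(y, params: CCCParams, t: float = 0.0,
             kin_t: Optional[Callable[[float], float]] = None) -> np.ndarray:
    """Mass-action derivatives of the 7-species model.

    Reactions: influx of m0 (kin), leak of m0 (kleak), binding
    c + m0 <-> c.m0 (ka0, kd0 = ka0*K0), catalysis c.m0 -> m1 + c* (kc),
    binding c* + m1 <-> c*.m1 (ka1, kd1 = ka1*K1), catalysis
    c*.m1 -> m2 + c (kp), efflux of m2 (kout).
    """
    m0, m1, m2, c, cstar, cm0, cstarm1 = y
    p = params
    kin = p.kin if kin_t is None else kin_t(t)
    bind0 = p.ka0 * c * m0
    unbind0 = p.ka0 * p.K0 * cm0
    cat_c = p.kc * cm0
    bind1 = p.ka1 * cstar * m1
    unbind1 = p.ka1 * p.K1 * cstarm1
    cat_p = p.kp * cstarm1
    return np.array([
        kin - p.kleak * m0 - bind0 + unbind0,   # m0
        cat_c - bind1 + unbind1,                # m1
        cat_p - p.kout * m2,                    # m2
        -bind0 + unbind0 + cat_p,               # c
        cat_c - bind1 + unbind1,                # c*
        bind0 - unbind0 - cat_c,                # c.m0
        bind1 - unbind1 - cat_p,                # c*.m1
    ])


def _fluxes5(m0, m1, c_t, cstar_t, p: CCCParams):
    c = free_carrier(c_t, m0, p.K0)
    cstar = free_carrier(cstar_t, m1, p.K1)
    vc = p.kc * m0 * c / (p.K0 + c)
    vp = p.kp * m1 * cstar / (p.K1 + cstar)
    return vc, vp, c, cstar


def rhs_reduced5(y, params: CCCParams, t: float = 0.0,
                 kin_t: Optional[Callable[[float], float]] = None) -> np.ndarray:
    """Derivatives of the 5-ODE adiabatic model (m0, m1, m2, c_t, c*_t)."""
    m0, m1, m2, c_t, cstar_t = y
    p = params
    kin = p.kin if kin_t is None else kin_t(t)
    vc, vp, _, _ = _fluxes5(max(m0, 0.0), max(m1, 0.0), max(c_t, 0.0),
                            max(cstar_t, 0.0), p)
    return np.array([
        kin - vc - p.kleak * m0,
        vc - vp,
        vp - p.kout * m2,
        -vc + vp,
        vc - vp,
    ])


def rhs_reduced2(m0: float, m1: float, params: CCCParams,
                 conserved: ConservedTriple, t: float = 0.0,
                 kin_t: Optional[Callable[[float], float]] = None):
    """Derivatives (dm0/dt, dm1/dt) of the conservation-reduced model.

    The carrier totals follow from the conserved quantities,
    [c]_t = csum - [m1] and [c*]_t = cpool - csum + [m1], and the free
    carriers from the binding quadratic.
    """
    p = params
    if m1 > conserved.csum * (1 + 1e-12):
        raise ValueError("m1 exceeds csum: conservation violated")
    c_t = max(conserved.csum - m1, 0.0)
    cstar_t = max(conserved.cpool - conserved.csum + m1, 0.0)
    kin = p.kin if kin_t is None else kin_t(t)
    vc, vp, _, _ = _fluxes5(max(m0, 0.0), max(m1, 0.0), c_t, cstar_t, p)
    return kin - vc - p.kleak * m0, vc - vp


# ---------------------------------------------------------------------------
# trajectories and integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Uniformly sampled solution of one formulation.

    ``frame`` carries one row per sample with the columns of
    ``FRAME_COLS[model_tag]`` (free carrier concentrations are derived
    for the reduced models).
    """

    times: np.ndarray
    frame: pd.DataFrame
    model_tag: str

    def __post_init__(self):
        if len(self.times) != len(self.frame):
            raise ValueError("times and frame length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def sample_dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


def _derived_frame(model_tag: str, ys: np.ndarray, params: CCCParams,
                   conserved: Optional[ConservedTriple]) -> pd.DataFrame:
    names = STATE_VARS[model_tag]
    data = {k: ys[:, i] for i, k in enumerate(names)}
    if model_tag == "reduced5":
        data["c"] = free_carrier(data["c_t"], data["m0"], params.K0)
        data["cstar"] = free_carrier(data["cstar_t"], data["m1"], params.K1)
    elif model_tag == "reduced2":
        c_t = np.clip(conserved.csum - data["m1"], 0.0, None)
        cstar_t = np.clip(conserved.cpool - conserved.csum + data["m1"], 0.0, None)
        data["c"] = free_carrier(c_t, data["m0"], params.K0)
        data["cstar"] = free_carrier(cstar_t, data["m1"], params.K1)
    return pd.DataFrame({k: data[k] for k in FRAME_COLS[model_tag]})


def integrate(model_tag: str, state0: Sequence[float], params: CCCParams,
              t_end: float, sample_dt: float = 1.0,
              conserved: Optional[ConservedTriple] = None,
              kin_t: Optional[Callable[[float], float]] = None,
              rtol: float = 1e-9, atol: float = 1e-12,
              method: str = "LSODA") -> Trajectory:
    """Integrate one formulation on a uniform sampling grid.

    ``state0`` is a vector in the order of ``STATE_VARS[model_tag]``.
    The 2-ODE model additionally needs the conserved triple.  Sampled
    concentrations are clipped at zero on output; an internal excursion
    below -1e-6 aborts the run.
    """
    if t_end <= 0 or sample_dt <= 0:
        raise ValueError("t_end and sample_dt must be > 0")
    y0 = np.asarray(state0, dtype=float)
    if len(y0) != len(STATE_VARS[model_tag]):
        raise ValueError(f"state for '{model_tag}' needs {len(STATE_VARS[model_tag])} entries")
    if model_tag == "reduced2":
        if conserved is None:
            raise ValueError("reduced2 integration requires the conserved triple")
        fun = lambda t, y: rhs_reduced2(y[0], y[1], params, conserved, t, kin_t)
    elif model_tag == "reduced5":
        fun = lambda t, y: rhs_reduced5(y, params, t, kin_t)
    elif model_tag == "full":
        fun = lambda t, y: rhs_full(y, params, t, kin_t)
    else:
        raise ValueError(f"unknown model tag {model_tag!r}")

    n = int(math.floor(t_end / sample_dt + 1e-9))
    if n < 1:
        raise ValueError("t_end must cover at least one sample_dt")
    t_eval = np.linspace(0.0, n * sample_dt, n + 1)
    sol = solve_ivp(fun, (0.0, t_eval[-1]), y0, t_eval=t_eval,
                    method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else 0.0)
    ys = sol.y.T
    if ys.min() < -1e-6:
        i, j = np.unravel_index(np.argmin(ys), ys.shape)
        raise IntegrationError(
            f"state went negative ({STATE_VARS[model_tag][j]} = {ys[i, j]:g})",
            float(sol.t[i]))
    ys = np.clip(ys, 0.0, None)
    frame = _derived_frame(model_tag, ys, params, conserved)
    return Trajectory(times=sol.t, frame=frame, model_tag=model_tag)


# ---------------------------------------------------------------------------
# reduction helpers (used by the equivalence tests)
# ---------------------------------------------------------------------------

def project_full_state(y_full) -> np.ndarray:
    """Map a 7-species state onto the 5-ODE variables (totals)."""
    m0, m1, m2, c, cstar, cm0, cstarm1 = y_full
    return np.array([m0 + cm0, m1 + cstarm1, m2, c + cm0, cstar + cstarm1])


def full_state_from_reduced(y5, params: CCCParams) -> np.ndarray:
    """Binding-equilibrium 7-species state matching a 5-ODE state."""
    m0t, m1t, m2, c_t, cstar_t = y5
    c = free_carrier(c_t, m0t, params.K0)
    cm0 = c_t - c
    cstar = free_carrier(cstar_t, m1t, params.K1)
    cstarm1 = cstar_t - cstar
    return np.array([m0t - cm0, m1t - cstarm1, m2, c, cstar, cm0, cstarm1])


# ---------------------------------------------------------------------------
# nullclines and steady states
# ---------------------------------------------------------------------------

def _vc_of_m0(m0, m1, params, conserved):
    c_t = max(conserved.csum - m1, 0.0)
    c = free_carrier(c_t, m0, params.K0)
    return params.kc * m0 * c / (params.K0 + c)


def _vp_of_m1(m1, params, conserved):
    cstar_t = max(conserved.cpool - conserved.csum + m1, 0.0)
    cstar = free_carrier(cstar_t, m1, params.K1)
    return params.kp * m1 * cstar / (params.K1 + cstar)


def _bracketed_root(g, hi0: float, hi_max: float) -> float:
    """Root of g on [0, hi] with doubling bracket expansion; NaN if none."""
    g0 = g(0.0)
    if g0 == 0.0:
        return 0.0
    hi = hi0
    while hi <= hi_max:
        if g0 * g(hi) < 0:
            return brentq(g, 0.0, hi, xtol=1e-10, rtol=1e-12)
        hi *= 2.0
    return math.nan


@dataclass
class NullclineResult:
    """m0 values of the two nullclines over an m1 grid (NaN = absent)."""

    m1_grid: np.ndarray
    m0_nullcline: np.ndarray   # where dm0/dt = 0
    m1_nullcline: np.ndarray   # where dm1/dt = 0


def nullclines(params: CCCParams, conserved: ConservedTriple,
               m1_grid: Sequence[float]) -> NullclineResult:
    """Nullclines of the 2-ODE model in the (m0, m1) plane.

    For each m1, the m0-nullcline solves kin = v_c + kleak*m0 and the
    m1-nullcline solves v_c = v_p, both by bracketed 1-D root finding.
    Grid points where no root exists (e.g. above the flux capacity) are
    flagged with NaN rather than raising.
    """
    m1_grid = np.asarray(m1_grid, dtype=float)
    if np.any(m1_grid < 0) or np.any(m1_grid >= conserved.csum):
        raise ValueError("m1 grid must lie in [0, csum)")
    hi_max = max(1e4, 10.0 * params.kin / params.kleak if params.kleak > 0 else 0.0)
    m0_null = np.full_like(m1_grid, math.nan)
    m1_null = np.full_like(m1_grid, math.nan)
    for i, m1 in enumerate(m1_grid):
        m0_null[i] = _bracketed_root(
            lambda m0: params.kin - _vc_of_m0(m0, m1, params, conserved)
            - params.kleak * m0, 1.0, hi_max)
        vp = _vp_of_m1(m1, params, conserved)
        m1_null[i] = _bracketed_root(
            lambda m0: _vc_of_m0(m0, m1, params, conserved) - vp, 1.0, 1e8)
    return NullclineResult(m1_grid=m1_grid, m0_nullcline=m0_null,
                           m1_nullcline=m1_null)


def steady_state(params: CCCParams, conserved: ConservedTriple,
                 guess: Optional[Sequence[float]] = None) -> Optional[dict]:
    """Fixed point of the 2-ODE model, or None when no fixed point exists.

    At a fixed point v_c = v_p(m1) and kin = v_p(m1) + kleak*m0, with m0
    the point on the m1-nullcline, m0 = M(m1).  The scalar function
    g(m1) = kin - v_p(m1) - kleak*M(m1) therefore changes sign at the
    fixed point; it is scanned over (0, m1_sat), where m1_sat is the
    saturation boundary v_p(m1) = kc (csum - m1) beyond which the
    m1-nullcline no longer exists, with geometric refinement toward the
    boundary (g -> -inf there when kleak > 0).  The returned mapping
    carries m0, m1, the derived carrier concentrations and the fluxes;
    the residual of the reduced dynamics is below 1e-10.
    """
    csum = conserved.csum

    def M(m1):
        return _bracketed_root(
            lambda m0: _vc_of_m0(m0, m1, params, conserved)
            - _vp_of_m1(m1, params, conserved), 1.0, 1e14)

    def g(m1):
        m0 = M(m1)
        if math.isnan(m0):
            return math.nan
        return params.kin - _vp_of_m1(m1, params, conserved) \
            - params.kleak * m0

    # saturation boundary of the m1-nullcline
    s = lambda m1: params.kc * (csum - m1) - _vp_of_m1(m1, params, conserved)
    m1_sat = brentq(s, 0.0, csum * (1 - 1e-12), xtol=1e-13) \
        if s(csum * (1 - 1e-12)) < 0 else csum * (1 - 1e-12)

    grid = np.linspace(1e-9 * csum, m1_sat * (1 - 1e-9), 200)
    vals = np.array([g(x) for x in grid])
    ok = np.isfinite(vals)
    bracket = None
    idx = np.where(ok[:-1] & ok[1:]
                   & (np.sign(vals[:-1]) * np.sign(vals[1:]) <= 0))[0]
    if len(idx):
        bracket = (grid[idx[0]], grid[idx[0] + 1])
    elif np.all(vals[ok] > 0):
        # refine geometrically toward the asymptote at m1_sat
        lo = grid[ok][-1]
        for k in range(1, 60):
            x = m1_sat - (m1_sat - lo) * 0.5 ** k
            v = g(x)
            if math.isfinite(v) and v < 0:
                bracket = (lo, x)
                break
            if math.isfinite(v):
                lo = x
    if bracket is None:
        return None
    m1 = brentq(g, bracket[0], bracket[1], xtol=1e-13)
    m0 = M(m1)
    dm0, dm1 = rhs_reduced2(m0, m1, params, conserved)
    if abs(dm0) > 1e-8 or abs(dm1) > 1e-8:
        return None
    c_t = csum - m1
    cstar_t = conserved.cpool - c_t
    c = free_carrier(c_t, m0, params.K0)
    cstar = free_carrier(cstar_t, m1, params.K1)
    return {
        "m0": m0, "m1": m1, "c_t": c_t, "cstar_t": cstar_t,
        "c": c, "cstar": cstar,
        "vc": _vc_of_m0(m0, m1, params, conserved),
        "vp": _vp_of_m1(m1, params, conserved),
        "residual": max(abs(dm0), abs(dm1)),
    }
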
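"""Frequency response of the sinusoidally driven cascade.

Near the jamming threshold the accumulated first metabolite acts as a
buffer, so the cascade behaves as a low-pass filter with a sharp,
amplitude-dependent cut-off.  In the saturated (large m0) regime the
two-variable dynamics collapse onto the one-dimensional slow equation

    d[m0]/dt = kin(t) - kc kp csum / (kc + kp) - kleak [m0]

(influx minus flux capacity minus leak), from which the cut-off of the
driven response follows as the frequency where the drive-induced m0
swing equals the mean jammed m0 level:

    2 pi f_c = kleak kc Ain / (kc kin0 - (kc + kleak) kin_th - kleak kc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import integrate, steady_state
from .jamming import initial_state_jam, kin_threshold
from .params import CCCParams, ConservedTriple, DEFAULT_CONSERVED


@dataclass(frozen=True)
class DriveSpec:
    """Sinusoidal influx kin(t) = Ain cos(2 pi f t) + kin0."""

    Ain: float
    f: float
    kin0: float

    def __post_init__(self):
        if self.Ain < 0:
            raise ValueError("Ain must be >= 0")
        if self.f <= 0:
            raise ValueError("f must be > 0")
        if self.kin0 - self.Ain < 0:
            raise ValueError("kin0 - Ain must be >= 0 (influx never negative)")


def drive(t, spec: DriveSpec):
    """Instantaneous influx rate of the sinusoidal drive."""
    return spec.Ain * np.cos(2.0 * math.pi * spec.f * t) + spec.kin0


def amplitude_response(params: CCCParams, spec: DriveSpec,
                       n_transient_cycles: int = 5,
                       n_measure_cycles: int = 5,
                       conserved: Optional[ConservedTriple] = None,
                       samples_per_cycle: int = 64) -> float:
    """Peak-to-peak swing of the free active carrier under the drive.

    Integrates the 5-ODE model, discards the transient window and
    returns max - min of [c] over the measurement window.  Both windows
    are floored at 5/kleak so the slow buffered m0 dynamics (timescale
    1/kleak) can equilibrate even when the drive period is short.
    """
    if params.kleak <= 0:
        raise ValueError("the driven protocol requires kleak > 0 (bounded m0)")
    if conserved is None:
        conserved = DEFAULT_CONSERVED
    period = 1.0 / spec.f
    t_transient = max(n_transient_cycles * period, 5.0 / params.kleak)
    t_transient = math.ceil(t_transient / period) * period
    t_measure = max(n_measure_cycles * period, 5.0 / params.kleak)
    t_measure = math.ceil(t_measure / period) * period
    sample_dt = period / samples_per_cycle
    # start on the fixed point of the mean drive so the transient window
    # only has to absorb the drive onset
    fp = steady_state(params.replace(kin=spec.kin0), conserved)
    if fp is not None:
        m2_ss = fp["vp"] / params.kout if params.kout > 0 else 0.0
        y0 = np.array([fp["m0"], fp["m1"], m2_ss, fp["c_t"], fp["cstar_t"]])
    else:
        y0 = initial_state_jam(conserved, m0=0.0)
    traj = integrate("reduced5", y0, params,
                     t_end=t_transient + t_measure, sample_dt=sample_dt,
                     kin_t=lambda t: drive(t, spec))
    c = traj.frame["c"].to_numpy()
    m0 = traj.frame["m0"].to_numpy()
    if m0[-1] > 1e7:
        raise RuntimeError("unbounded m0 growth under drive")
    sel = traj.times >= t_transient
    return float(c[sel].max() - c[sel].min())


def reduced_1d_rhs(m0: float, t: float, params: CCCParams, csum: float,
                   spec: Optional[DriveSpec] = None) -> float:
    """Slow one-dimensional dynamics of m0 in the saturated regime.

    dm0/dt = kin(t) - kc kp csum/(kc+kp) - kleak m0; for kleak -> 0 this
    is influx minus the perfect-binding flux capacity.
    """
    kin = params.kin if spec is None else float(drive(t, spec))
    capacity = params.kc * params.kp * csum / (params.kc + params.kp)
    return kin - capacity - params.kleak * m0


def cutoff_frequency(params: CCCParams, spec: DriveSpec, kin_th: float) -> float:
    """Analytic cut-off frequency of the driven response.

    ``kin_th`` is the kleak = 0 jamming threshold (the leak enters only
    through the explicit kleak terms).  Returns NaN when the working
    point lies outside the validity regime (non-positive denominator,
    i.e. the mean drive does not jam the cascade).
    """
    p = params
    den = p.kc * spec.kin0 - (p.kc + p.kleak) * kin_th - p.kleak * p.kc
    if den <= 0:
        return math.nan
    return p.kleak * p.kc * spec.Ain / (2.0 * math.pi * den)


def measured_cutoff(params: CCCParams, Ain: float, kin0: float,
                    conserved: Optional[ConservedTriple] = None,
                    f_grid: Optional[Sequence[float]] = None,
                    n_points: int = 7, span: float = 8.0, **kwargs) -> float:
    """Half-maximum cut-off frequency from simulated responses.

    Scans a log-spaced frequency grid (by default centred on the
    analytic prediction), takes the lowest-frequency response as the
    plateau, and log-interpolates the first crossing of half that
    plateau.  NaN if the response never falls below half maximum.
    """
    if conserved is None:
        conserved = DEFAULT_CONSERVED
    kin_th = kin_threshold(params.replace(kleak=0.0), conserved.cpool,
                           conserved.csum)
    if f_grid is None:
        f_pred = cutoff_frequency(params, DriveSpec(Ain, 1.0, kin0), kin_th)
        f_grid = np.geomspace(f_pred / span, f_pred * span, n_points)
    f_grid = np.asarray(f_grid, dtype=float)
    resp = np.array([
        amplitude_response(params, DriveSpec(Ain, f, kin0),
                           conserved=conserved, **kwargs)
        for f in f_grid])
    plateau = resp[0]
    half = plateau / 2.0
    below = np.where(resp < half)[0]
    if len(below) == 0 or below[0] == 0:
        return math.nan
    i = below[0]
    lf = np.log(f_grid)
    # linear interpolation of the crossing in (log f, response)
    frac = (resp[i - 1] - half) / (resp[i - 1] - resp[i])
    return float(np.exp(lf[i - 1] + frac * (lf[i] - lf[i - 1])))


@dataclass
class ResponseGrid:
    """Amplitude-frequency response map with the analytic cut-off curve."""

    Ain_values: np.ndarray
    f_values: np.ndarray
    response: np.ndarray           # shape (len(f), len(Ain))
    cutoff_curve: np.ndarray       # analytic cut-off per Ain
    failures: list = field(default_factory=list)


def response_map(params: CCCParams, Ain_values: Sequence[float],
                 f_values: Sequence[float], kin0: float,
                 conserved: Optional[ConservedTriple] = None,
                 **kwargs) -> ResponseGrid:
    """Response matrix over (Ain, f) plus the analytic cut-off per Ain.

    Per-cell integration failures are recorded and flagged with NaN
    rather than aborting the sweep.
    """
    if conserved is None:
        conserved = DEFAULT_CONSERVED
    Ain_values = np.asarray(Ain_values, dtype=float)
    f_values = np.asarray(f_values, dtype=float)
    if Ain_values.size == 0 or f_values.size == 0:
        raise ValueError("grids must be nonempty")
    kin_th = kin_threshold(params.replace(kleak=0.0), conserved.cpool,
                           conserved.csum)
    resp = np.full((len(f_values), len(Ain_values)), np.nan)
    failures = []
    for j, Ain in enumerate(Ain_values):
        for i, f in enumerate(f_values):
            try:
                resp[i, j] = amplitude_response(
                    params, DriveSpec(Ain, f, kin0), conserved=conserved,
                    **kwargs)
            except Exception as exc:  # noqa: BLE001 - flagged, not fatal
                failures.append((float(Ain), float(f), str(exc)))
    cut = np.array([cutoff_frequency(params, DriveSpec(A, 1.0, kin0), kin_th)
                    for A in Ain_values])
    return ResponseGrid(Ain_values=Ain_values, f_values=f_values,
                        response=resp, cutoff_curve=cut, failures=failures)
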
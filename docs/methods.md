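# Methods

## Model

One cascade transforms a supplied metabolite m0 into m1 and then m2,
with the first step consuming an active carrier c (forming the complex
c·m0, dissociation constant K0, turnover k_c) and the second
regenerating c from the inactive form c* (complex c*·m1, constant K1,
turnover k_p).  m0 is supplied at rate k_in, diluted at k_leak; m2
leaves at k_out.  Enzymes are assumed saturated and do not appear
explicitly.

Three exactly-nested formulations are implemented.

**Full model (7 ODEs).**  Mass action over
(m0, m1, m2, c, c*, c·m0, c*·m1) with association rates ka0, ka1 and
dissociation rates ka·K.  The carrier total
c + c·m0 + c* + c*·m1 is conserved symbolically.

**Adiabatic 5-ODE model.**  For fast binding the complexes equilibrate;
the evolved variables are the metabolite totals (free + complexed) and
the carrier totals [c]_t = [c]+[c·m0], [c*]_t = [c*]+[c*·m1].  The free
carrier is the non-negative root of

    x² + (K + partner_total − total)·x − K·total = 0,

evaluated in the cancellation-free form, and the fluxes are
v_c = k_c [m0][c]/(K0+[c]), v_p = k_p [m1][c*]/(K1+[c*]).

**2-ODE model.**  Two conserved quantities — c_pool = [c]_t + [c*]_t
and c_sum = [c]_t + [m1] — plus the decoupling of m2 reduce the system
to (m0, m1).

Conserved-quantity bookkeeping: in the full model the conserved partner
of the pool is c + c·m0 + m1 + c*·m1, i.e. the reduced-model [m1] is
the *total* (free + complexed) m1.  Quantities reported as c_sum use
this convention in every formulation, so conservation holds exactly,
not only adiabatically.

## Jamming threshold

For k_leak = 0 the capacity of the cascade is

    kin_th = k_c k_p/(2(k_c+k_p)) · { c_pool + c_sum + α −
             sqrt((c_pool − c_sum + α)² + 4 c_sum α) },
    α = k_c K1/(k_c + k_p).

The minus sign before the radical is fixed by two requirements: the
K1 → 0 limit must reduce to k_c k_p min(c_pool, c_sum)/(k_c+k_p), and
the value at the default parameters must lie below the symmetric-pool
capacity of 1.  With a finite leak no threshold exists (the m0
nullcline is tilted and a fixed point exists for every k_in); the
functions raise in that case rather than returning an approximation.

An independent numerical threshold (`threshold_bisect`) bisects k_in on
a divergence predicate: integrate from the jammed start (m0 bolus 100,
all carrier active) to t = 1e4 and test whether m0 is still *growing*
over the late plateau (trend m0(t_end) > m0(t0) + 1e-3).  The plateau
drift rate is k_in − kin_th, so the trend classifies runs far below the
1e-4 bisection tolerance.  A threshold on absolute growth (e.g. "m0
exceeds 10× its start") cannot do this: near the boundary the gain over
any finite horizon is arbitrarily small.

## Relaxation time and critical scaling

τ is the first sample time at which Σ_species |x(t) − x(t−Δt)| < 1e-7
on a uniform grid with Δt = 1 (insensitive to Δt within [0.5, 2],
tested).  The scan integrates the 5-ODE model from the jammed start for
each k_in, with the horizon scaled as 1.5·m0(0)/(kin_th − k_in) + 200
so every subcritical run can finish.  The critical exponent is the
least-squares slope of log τ against log(kin_th − k_in); the jammed
buffer drains at the constant rate kin_th − k_in, giving slope −1 and a
linear (not exponential) m0 plateau, both asserted in the tests.

## Frequency response

Drive: k_in(t) = A_in cos(2πft) + kin0, default kin0 = 1 with
k_leak = 1e-3 so the driven system is bounded.  The response is the
peak-to-peak swing of free [c] after discarding a transient; both the
transient and measurement windows are floored at 5/k_leak (the slow
variable's timescale is 1/k_leak) and rounded to whole cycles, with
≥ 64 samples per cycle.  Runs start on the fixed point of the mean
drive, so the transient only absorbs the drive onset.

In the saturated regime the dynamics reduce to the one-dimensional slow
equation

    d[m0]/dt = k_in(t) − k_c k_p c_sum/(k_c+k_p) − k_leak [m0]

(influx minus perfect-binding capacity minus leak).  The cut-off is
where the drive-induced m0 swing equals the mean jammed m0 level:

    2πf_c = k_leak k_c A_in / (k_c kin0 − (k_c+k_leak) kin_th − k_leak k_c),

with kin_th the k_leak = 0 threshold.  Because the 1-D equation uses the
perfect-binding capacity, it carries a systematic offset of order
α/(kin0 − kin_th) at finite K1; it is validated in its regime (small K1)
and the analytic cut-off is checked against simulation only up to a
factor of 3, which is also what the response maps show (measured
half-maximum cut-offs land within a factor ~1.5–3 of the formula over
A_in ∈ [0.1, 1]).  The measured cut-off is defined as the frequency
where the response falls to half its low-frequency plateau.

## Stochastic simulation

Direct-method Gillespie with volume Ω = 1 (counts ≡ concentrations).
Three models:

* `ssa_full`: the 9-reaction network matching the full ODE model;
  carrier copy total exactly conserved at every event.  Default binding
  rate ka = 1e3 — fast enough for near-equilibrium binding at feasible
  event counts; the limit model exists precisely to avoid this cost
  where K → 0 is intended.
* `ssa_limit`: the perfect-binding birth–death chain of the m1 count n.
  Saturated (m0 in excess): birth k_c(c_max − n), death k_p n —
  stationary binomial(c_max, k_c/(k_c+k_p)), Fano 1 − k_c/(k_c+k_p).
  Unsaturated: birth k_in, death k_p n — stationary Poisson, Fano 1.
* `ssa_double_mm`: comparator with two independent saturating pools
  (birth k_c c1, death k_p c2 for n > 0): an unbiased random walk when
  balanced; ensemble Fano ≥ 1 always.

Statistics are *time-weighted* (dwell times as weights, last state held
to t_end); the averaging convention matters at the percent level and is
fixed package-wide.  Burn-in defaults to a few tens of the slowest
relaxation time.  A detailed-balance solver
(`master_equation_stationary`) provides closed-form stationary laws as
the oracle for the birth–death models.  Paths are bit-reproducible per
seed (numpy PCG64).

## Turnover estimation

k = flux·(K + [carrier])/([substrate]·[carrier]), kept unrounded
internally; the reporting layer rounds to the displayed precision of
the source tables (E. coli k_c to 1 significant figure, all others
to 2) and computes the predicted Fano factor 1 − k_c/(k_c+k_p) from the
rounded rates.  The E. coli glycolytic flux is derived from the
1.8 mM/s glucose uptake minus the 20 % pentose-phosphate diversion
(1.44 mM/s).  In the L. lactis dataset the 1.0 mM value is treated as
the pyruvate (substrate) concentration; only that reading reproduces
the published k_p.

## Coupled cascades

N cascades share one carrier pool.  The competitive binding closure
solves c + Σ_i m0_i·c/(K0_i + c) = [c]_t by bracketed 1-D root finding
(tolerance 1e-12); a quadratic no longer suffices for N ≥ 2 with
distinct K0_i.  Per-cascade c_sum is not conserved under coupling; the
tested invariants are c_pool and [c]_t + Σ_i [m1_i].

## Numerical choices

* Defaults: k_c = k_p = 1 (time unit = catalytic turnover),
  K0 = K1 = 1e-3, c_pool = c_sum = 2, k_leak = 0, k_out = 1; these are
  the conditions under which the quoted threshold 0.984313 and all
  presets are defined.  kin_th is independent of K0, and m2 is
  decoupled from the rest, so K0 and k_out affect only trajectories.
* Integration: LSODA, rtol 1e-9, atol 1e-12, uniform sampling grid
  (default Δt = 1).  The slow/fast separation near threshold (~10³)
  needs tight tolerances; conservation drift stays below 1e-8 relative
  on multi-thousand-unit runs.
* Sampled outputs are clipped at 0; an internal excursion below −1e-6
  aborts with the failure time.
* Nullcline roots: bisection to 1e-10 with doubling bracket expansion;
  absence of a sign change is reported as "no nullcline point" (NaN),
  not an error — that is the supercritical geometry.
* Steady states are found as the root of
  g(m1) = k_in − v_p(m1) − k_leak·M(m1) (M = m0 on the m1-nullcline),
  scanned up to the saturation boundary of the m1-nullcline with
  geometric refinement toward its asymptote.  This is robust exactly
  where nullcline-difference scanning fails: with a small leak the
  fixed point sits at m0 ~ (k_in − kin_th)/k_leak, just before the
  asymptote.
* Step protocols pre-run for 100 time units by default; above threshold
  no true steady state exists and the protocol starts from the jammed
  quasi-steady plateau, which is the only available notion of "steady"
  there.

## Problem sizes

The bundled experiment presets and acceptance computations use
desk-scale sizes chosen to make every statistical tolerance comfortable:
six-point relaxation scans (horizons up to ~3.5·10⁴ time units),
≥ 10⁶ Gillespie events per stationary Fano estimate, 240 trajectories
for ensemble statistics, and reduced (A_in, f) grids for the frequency
maps.  All are package defaults, overridable per call.

## What the synthetic conditions do and do not show

All inputs are generated by the models themselves; there is no external
data beyond the two bundled pathway tables.  The study conditions
emulate a single unbranched cascade with a strictly conserved pool,
instantaneous binding equilibria (reduced models), saturated enzymes
and no cell growth or dilution.  Passing tests therefore demonstrate
the internal consistency of the theory and its numerics — not that a
real pathway has these parameters.  Real metabolic networks branch,
share carriers across many reactions, and exchange metabolites;
the coupled-cascade module probes only the mildest such extension
(a shared pool between two cascades).  Reversible catalytic steps,
branched pathways, SBML exchange and growth dilution are out of scope.
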
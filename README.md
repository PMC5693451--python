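# cccsim — carrier cycling cascades with conserved carrier pools

`cccsim` simulates and analyses the **carrier cycling cascade (CCC)**: the
minimal metabolic motif

```
        kin           v_c                v_p            kout
   ∅ ────────▶ m0 ──────────▶ m1 ──────────────▶ m2 ────────▶ ∅
                     (uses c → c*)    (uses c* → c)
```

in which the first catalytic step consumes an *active* carrier (ATP,
NAD⁺, …) and the second regenerates it from the *inactive* form (ADP,
NADH, …).  Because the total carrier pool is a conserved moiety, the two
steps are coupled through a hard constraint rather than through mass
action alone.  This single constraint produces a surprisingly rich set
of behaviours that the package quantifies:

* **Flux jamming.**  With binding equilibria included, the catalytic
  fluxes are v_c = k_c[m0][c]/(K₀+[c]) and v_p = k_p[m1][c*]/(K₁+[c*]),
  and the cascade has a hard capacity.  For k_leak = 0 the critical
  influx is

  k_in^th = k_c k_p / (2(k_c+k_p)) · { c_pool + c_sum + α −
  √((c_pool − c_sum + α)² + 4 c_sum α) },   α = k_c K₁/(k_c+k_p),

  which tends to k_c k_p min(c_pool, c_sum)/(k_c+k_p) as K₁ → 0.  Above
  it the first metabolite accumulates without bound.
* **Critical slowing down.**  Just below capacity the relaxation time
  diverges as (k_in^th − k_in)⁻¹ — exponent −1, distinct from the 1/2 of
  a saddle-node — because the jammed m0 buffer drains at the constant
  rate k_in^th − k_in (linear, not exponential, decay).
* **Low-pass filtering.**  Under a sinusoidal influx the buffered m0
  absorbs fast fluctuations; the cut-off frequency grows linearly with
  the drive amplitude, so the cascade ignores small wiggles but responds
  to large nutrient shifts.
* **Noise suppression.**  In the stochastic (Gillespie) cascade the
  conservation of the pool acts as negative feedback: in the saturated
  regime the stationary m1 copy-number distribution is binomial with
  Fano factor σ²/⟨n⟩ = 1 − k_c/(k_c+k_p) < 1, whereas without the shared
  pool (two independent Michaelis–Menten steps) the count random-walks
  and the Fano factor never drops below 1.
* **Turnover estimation.**  Inverting the Michaelis–Menten form,
  k = v(K + [carrier])/([substrate][carrier]) turns measured
  concentrations and fluxes into turnover rates, and hence into a
  predicted noise-suppression factor for real pathways (bundled:
  E. coli glycolysis and L. lactis lactate fermentation).

The deterministic model is provided in three exactly-nested
formulations — 7 mass-action ODEs with explicit complexes, the 5-ODE
adiabatic reduction, and the 2-ODE conservation reduction — plus an
N-cascade variant sharing one carrier pool.

## Worked example

Python:

```python
import cccsim as cs

p = cs.CCCParams(kleak=0.0)          # kc = kp = 1, K0 = K1 = 1e-3
th = cs.kin_threshold(p, cpool=2.0, csum=2.0)
res = cs.relaxation_scan(p, [0.90, 0.92, 0.94, 0.96, 0.97, 0.98])
print(th, res.fitted_exponent)
```

prints `0.9843131176009938 -1.0003423846564032`: a cascade with a
two-unit carrier pool saturates at an influx just below one substrate
per catalytic time, and the measured relaxation times fit the −1
critical exponent.

Command line:

```console
$ ccc threshold
kin_th = 0.984313
$ ccc estimate --dataset ecoli-glycolysis
kc_per_s = 50
kp_per_s = 12
fano = 0.1935
$ ccc estimate --dataset llactis-fermentation
kc_per_s = 0.85
kp_per_s = 4.9
fano = 0.8522
```

The glycolytic estimate says ATP consumption by PFK turns over ~50/s
against ~12/s regeneration by PK, predicting a strongly suppressed
intermediate-metabolite Fano factor of ≈ 0.2; the fermentation pathway
(0.85/s vs 4.9/s) suppresses noise only mildly (≈ 0.85).

Other subcommands: `simulate`, `relax-scan`, `step`, `freq-sweep`,
`ssa`, `preset` (named figure protocols such as `fig2b-scan` or
`fig5-sweep`).  All stochastic commands take `--seed` and are
byte-reproducible.

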
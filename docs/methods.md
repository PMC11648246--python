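# Methods

## The models

`phenodyn` analyses frequency dynamics of two competing neuroblastoma
phenotypes — therapy-sensitive adrenergic (ADRN, frequency `xA`) and
therapy-resistant mesenchymal (MES, `xM`) — in the replicator-dynamics
framework: `dx_i/dt = x_i [f_i(x) − φ(x)]`, with `φ` the
frequency-weighted mean fitness. Because the observable is a pair of
gated flow-cytometry percentages, the state lives on the 1-simplex
(`xA + xM = 1`) and frequency (not abundance) dynamics are the right
description.

Four nested models are implemented, with logistic-style fitnesses
`f_A = r(1 − xA − α·xM)` and `f_M = r(1 − β·xA − xM)`:

| model | extra terms | hypothesis |
|---|---|---|
| `BASELINE` | — | pure cell-type competition, untreated |
| `BASELINE_TRANSITIONS` | `∓τ1·xA ± τ2·xM` inside the brackets | background ADRN↔MES state switching |
| `CELLTYPE_THERAPY` | `−γ(t)` on the ADRN bracket | therapy kills ADRN cells only; no switching |
| `CELLSTATE_THERAPY` | `−ζ(t)` on the ADRN bracket plus the influx `+ζ(t)·xA` in the MES equation | therapy additionally drives ADRN→MES switching |

`γ(t)` and `ζ(t)` are piecewise-constant: equal to `γ`, `ζ` while
therapy is on (half-open intervals `[start, end)`), zero otherwise.

**Composition of the mean fitness.** Whether `φ` includes the therapy
and transition terms is a genuine modeling choice; we resolve it by the
requirement that the data are proportions summing to one. `φ` includes
the therapy death term and the background transition terms; for the
cell-state model it excludes the `−ζ` part of the ADRN bracket, so the
`−ζ·xA` outflux and `+ζ·xA` influx cancel exactly in
`d(xA + xM)/dt`. With this convention every model conserves the
simplex identically (property-tested to 1e-12), which would fail under
any other composition.

**A useful identity.** For two phenotypes the replicator equation
collapses to `dxA/dt = xA·xM·(g_A − g_M)` (plus the switching flux for
the cell-state model). Hence only the fitness *difference*

    g_A − g_M = r[(β−1)·xA + (1−α)·xM] − 2τ1·xA + 2τ2·xM − (γ+ζ)·[on]

is observable. Several identifiability facts below follow directly
from this.

## Units

All rates are per hour internally. `r = ln 2 / 27 h ≈ 0.0257/h` from
the SK-N-BE(2) doubling time. The literature on this system mixes
per-hour growth rates with per-day therapy rates; taken literally, a
death rate of 0.01/day (≈4e−4/h) is ~60-fold smaller than `r` and
cannot move the phenotype composition appreciably within a 72 h
therapy pulse, contradicting the observed MES expansion under
cisplatin. The reference scenarios therefore interpret the reported
magnitudes (γ = 0.01, ζ = 3.15e−4, τ2 = 1.64e−5) in the single
internal unit (per hour); reports print both per-hour and per-day
(×24) columns so either reading can be compared.

## Numerical integration

Trajectories are integrated with LSODA (SciPy) at rtol 1e-8 /
atol 1e-10, piecewise between therapy switch points so no adaptive
step straddles an on/off discontinuity. Frequencies are never
renormalized: drift off the simplex beyond 1e-6 raises an error
(in practice drift stays near 1e-12); roundoff-scale negative
frequencies (≲1e-9, at fixation boundaries) are clamped to zero.
The integrator is validated against an independent fixed-step Euler
oracle (dt = 0.001 h) to 1e-4 sup-norm over the full 336 h treated
design.

## Calibration

Bounded least squares via the Levenberg–Marquardt algorithm (MINPACK
through lmfit; box bounds by lmfit's sinusoidal parameter
transformation). Residual layout: per replicate series, the model is
simulated from that replicate's first observation (`t0` = first
sampling time, `x0` = that observation; initial conditions are data,
not parameters), and residuals are `predicted − observed` for **both**
phenotype frequencies at every later observation time, concatenated in
(replicate, time, phenotype) order. Because `xM_obs = 1 − xA_obs` by
construction, the MES residuals are exact negatives of the ADRN
residuals; the `residual_mode="adrn"` flag drops them (identical
optimum, half the nominal `n`). Interaction coefficients are bounded
to `(0, 1]`; rates to `[0, ∞)`.

Numerical choices that matter, all found necessary in practice:

* **Finite-difference scale.** `epsfcn = 1e-8`, so Jacobian steps
  (~1e-4 in the internal coordinates) sit well above the integrator's
  ~1e-8 relative noise floor. With MINPACK's machine-epsilon default
  the Jacobian differentiates integrator noise and the fit stalls at
  its starting point.
* **Interior starts.** The bound transformation has exactly zero
  gradient *at* a bound, freezing any parameter started there (τ, ζ
  start at 0; β starts at 1). Starting values are nudged 1e-6·span
  into the interior.
* **Convergence.** xtol = ftol = gtol = 1e-10, at most 500 LM
  iterations (`maxfev = 500·(k+1)` function evaluations). Fits that
  end above the RSS of the literal starting point are reported at the
  starting point with `converged=False` — the fitted RSS never exceeds
  the start RSS.
* **Warm starts for nested fits.** From the identity above, (α, τ2)
  and (β, τ1) trade off *exactly* (`Δα = 2Δτ2/r` leaves the dynamics
  unchanged), so the transitions model is structurally non-identifiable
  and a cold-started fit lands at an arbitrary point of the flat
  manifold. The workflow therefore starts the transitions fit at the
  nested baseline optimum with τ = 0; on transition-free data it stays
  there (τ̂ = 0, RSS unchanged), which is the minimal-norm point of the
  manifold.
* **Multi-start.** `n_restarts > 0` adds jittered restarts (seeded);
  useful for the cell-state model, whose RSS surface has a flat
  plateau at large ζ (the ADRN pool empties within one pulse and all
  predictions saturate).

## Model selection

`R² = 1 − RSS/TSS` pooled over all residual entries, TSS about the
pooled observed mean. `AIC = n·ln(RSS/n) + 2k` with `n` the residual
vector length and `k` the number of free parameters; no small-sample
correction. Ranking is by ascending AIC, ties broken by smaller `k`,
then input order. Note the caveat implied by the residual layout: in
the default both-phenotypes mode `n` counts each datum twice. The
fixed-ζ sweep pins ζ on a grid (default 21 points on [0, 0.02]) and
refits γ at each point, profiling how forced switching degrades the
fit.

## Synthetic data

The generator emulates the two experimental designs: CONTROL (samples
at 48, 72, 96 h post-seeding, no therapy) and TREATMENT (samples at
24, 96, 264, 336 h, i.e. days 1/4/11/14, with therapy on during
[24, 96) and [264, 336) — two 72 h pulses around a 7-day holiday),
two biological replicates each. The true trajectory is simulated from
a configured initial composition; each observation adds independent
Gaussian noise (default sd 0.02) to the ADRN frequency, clipped to
[0.001, 0.999], with the MES frequency set to the complement —
mirroring gated live-cell percentages, which are complementary after
dead-cell exclusion. Initial compositions — (0.85, 0.15) for CONTROL
and (0.70, 0.30) at treatment start — are plausible invented values
for an ADRN-dominated line, not measurements. The generator does not
emulate event-level cytometry, gating drift, dead-cell fractions, or
technical replicates (collapsed into the biological replicates).

The untreated calibration protocol pools the CONTROL series with the
drug-holiday segment (96→264 h) extracted from a treated dataset, as
each inter-observation interval there carries no therapy; segments are
identified by schedule lookup.

## Known limitations (measured, not hypothetical)

* **α/β identifiability under noise.** The untreated data span
  `xA ≈ 0.6–0.88`, over which only the line
  `r(1−α) + xA·r(α+β−2)` is identified; α is its extrapolation to
  `xA = 0`. With observation noise sd 0.02 the joint (α, β) estimate
  slides along this near-flat ridge, and because the generating β = 1
  sits *on* its upper bound, estimation errors in β are one-sided
  downward and drag α down with them (`Δα ≈ (xA/xM)·Δβ`). Median
  recovered values over 50 seeded datasets are α̂ ≈ 0.32–0.40 (true
  0.484) and β̂ ≈ 0.93–0.98 (true 1.00). Noise on the initial
  observations (used as simulation starts) roughly doubles the
  effective error; with exact initial conditions the median α̂ is
  ≈ 0.46. γ, by contrast, is well identified (median γ̂ within 1% of
  truth at the same noise).
* **Hypothesis discrimination at realistic noise.** The best cell-type
  mimic of a cell-state trajectory (ζ = 0.01/h) differs by only
  ≈ 0.013 rms at the four treated sampling times — below the 0.02
  observation noise. AIC selection is accordingly imperfect: ≈ 61/100
  correct on cell-type-generated data and ≈ 80/100 on
  cell-state-generated data (≈ 76/100 and 65/100 with ADRN-only `n`).
  Denser sampling during the pulses, not more replicates, is what
  would separate the hypotheses.
* Passing tests on this generator show correctness of the pipeline
  under its assumptions (additive truncated-Gaussian noise,
  independent observations, exactly complementary frequencies); they
  do not certify recovery on real cytometry data with gating drift or
  correlated errors.
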
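# Methods

## Model and assumptions

The package models isothermal (150 °C) heating of cholesterol with or without
quercetin as a deterministic mass-action network over four observed pools:
quercetin `Q`, cholesterol `A`, 7-hydroperoxycholesterol `A′` and
5,6-epoxycholesterol `E`. Assumptions inherited from the underlying kinetic
treatment:

* Quercetin loss is the sum of three first-order channels — thermal (`kd`),
  oxidative (`ko`) and radical scavenging (`kf`) — so `Q` decays
  exponentially with `ki = kd + ko + kf`.
* 7-OOH formation is logistic with plateau `A′max` (the maximum level
  attainable before degradation of the hydroperoxide dominates); in the
  presence of quercetin the rate is divided by `kf Q(t)`, the antioxidant
  inhibition term.
* Epoxidation is second order in `A` and `A′`, likewise divided by `kf Q`.
* Cholesterol itself is depleted only by first-order thermal degradation
  (`k5`); the amounts consumed by peroxidation and epoxidation are not fed
  back into the `A` balance. This mirrors the source treatment, which gives
  no combined balance; the closed forms and the numerical system make the
  same choice so they remain mutually consistent.
* Degraded product pools are tracked implicitly as mass differences, never
  as state variables (no rate equations exist for them).

Time is in hours everywhere internally (all constants are h⁻¹); readers
convert minutes on ingest. Concentrations are unit-agnostic in the rate
laws; `TimeSeries` carries the unit (percent of initial, or mg per 100 g
cholesterol) and estimators do not mix units.

## Closed forms and the re-derived inhibition factor

Separating variables in the inhibited logistic with
`Q(t) = Q0 e^{−ki t}` substituted gives

```
A′(t) = A′max / [1 − (1 − A′max/A′0) ω(t)],
ω(t)  = exp[(k1/(Q0 kp)) (1 − e^{ki t})],   kp = ki kf.
```

The typeset form of ω in the source text is not dimensionally meaningful as
printed; the exponent used here is the one obtained by the derivation, and
is corroborated by the small-time coefficient `m3 = k1/(kf Q0)` of the
epoxide expansion. The numerical ODE system, not any closed form, is the
canonical model: where transcription and derivation could disagree, the
closed forms are required (by test) to match the integrator to 1e-4
relative over the fitting window.

For the epoxide integral the direct substitution yields `kf` in the
prefactor denominator where the source prints the composite `kp`; the
derived form (`kf`) is the default and the printed variant is available via
`prefactor="printed"` (the two differ exactly by the factor `ki` in the
excess over `E0`, which a unit test pins).

The quadratic Taylor form replaces the hydroperoxide factor by its
second-order expansion about `t = 0` using the coefficients `m2, m3, m4`
exactly as published. Two caveats are documented rather than "fixed":
the published `m4` equals the full second derivative ratio `A′″(0)/A′0`,
twice the textbook Taylor coefficient, and the quadratic truncation is only
trustworthy near `t = 0` — on the dynamic recovery scenario its relative
error versus the exact quadrature falls from ~14 % at 0.4 h to ~1e-5 at
0.02 h. Both effects are negligible for the published treatment constants
(`m3 ≈ 5.5e-7`). Consequently the epoxidation estimator defaults to the
quadrature backend (which matches the ODE system); the Taylor backend is
selectable for comparison with the published protocol. When
`|ki − k5| < 1e-6` h⁻¹ the Taylor form is singular and callers are directed
to the quadrature.

`ω` is computed with `expm1`, so the `ki → 0` limit degenerates smoothly to
the plain logistic with effective rate `k1/(kf Q0)` (tested at `ki = 1e-8`
to 1e-6 relative).

## Estimators

* **First-order constants** — through-origin regression of
  `−ln(value/value₀)` on time, the slope being the constant; the integrated
  law forces a zero intercept, and on the printed data subsets the
  through-origin estimator reproduces the published constants more closely
  than the intercept form (which remains available for diagnostics). `r²`
  is computed on the log scale. Replicates are pooled; `value₀` is the
  replicate mean at the earliest time.
* **Hydroperoxide fit** — Levenberg–Marquardt
  (`scipy.optimize.least_squares`, `method="lm"`, tolerances 1e-10, at most
  2000 evaluations) on the closed form. Positivity is enforced by
  log-parameterisation; `A′max`, when free, is parameterised as
  `max(observed) + e^θ` so the plateau can never fall below the data. A
  deterministic multi-start grid (five log-spaced starts per free parameter,
  centred on data-driven guesses) guards against local minima; the
  lowest-cost converged start wins, so fits are reproducible bit-for-bit.
  Identifiability: with `ki` fixed independently, `k1` and `kf` enter only
  through their ratio and the fit returns one point of the ridge; supplying
  `kd` and `ko` instead ties `ki = kd + ko + kf` to the free `kf` and makes
  the pair identifiable — the recovery suite uses this mode.
* **Epoxidation** — `E(t) − E0` is exactly proportional to `k4`, so the
  least-squares estimate is the closed-form projection onto the model curve
  evaluated at `k4 = 1`, clipped at zero.
* **Logistic control fit** — `A′0`, `A′max`, `k1` of the plain logistic,
  same Marquardt machinery (`A′0` parameterised as a fraction of `A′max`).
* Standard errors come from the Gauss–Newton approximation at the optimum
  (delta method through the parameter transforms) and are flagged
  approximate when the normal-matrix condition number exceeds 1e8.

## Synthetic data

`generate_dataset` evaluates the ODE system on one of the two study sampling
designs (0/5/10/20/30 min for cholesterol runs; 0/5/10/30/60/90/120 min for
quercetin-alone runs), then perturbs each of the default three replicates
with independent multiplicative lognormal noise. The default CV of 0.02
reflects the SD/mean ratios of the published concentration tables (roughly
0.3–3 %). Noise is median-preserving (`v·e^{σZ}`, `σ² = ln(1+CV²)`) and
independent across time points; real replicate scatter may be
autocorrelated through shared heating runs, and the true scatter of the
quercetin residual percentages is unpublished, so the CV is an assumption.
Passing recovery tests therefore demonstrates estimator correctness under
this noise model, not robustness to instrument drift, autocorrelated error,
or model misspecification.

Truth bundles: the published constants are packaged under both quercetin
concentration conventions (`Q0 = 100` percent, `Q0 = 0.02` mass fraction),
with the published `ki = 7.17` carried as an independently supplied value —
it is not the sum of its published components (0.253 + 0.615 + 3.28 =
4.148), and `RateConstants` records which reading a bundle uses. Because
the published treatment constants produce an essentially flat inhibited
7-OOH trajectory (ω deviates from 1 by ~3e-6 over 30 min) they cannot
support parameter-recovery experiments; the `recovery` bundle instead uses
a self-consistent synthetic truth (`k1 = 600`, `kf = 3.28`, `ki` derived,
`k4 = 8`, `k5 = 0.19`, `A′max = 20`, `Q0 = 100`) whose 7-OOH and 5,6-EP
trajectories span the observed ranges (0.13 → ~2.5 and 0.46 → ~3.4 mg/100 g
in 30 min). `A′max = 20` is a choice: the plateau is unpublished; 20 mg/100 g
sits above every observed treatment value and near the 30-min control level.

First-order recovery runs on the long-design variant (`recovery_long`):
a constant as slow as `k5 = 0.19` h⁻¹ produces only ~9 % decay within
30 min and cannot be pinned to a few percent against 2 % noise; the
0–120 min design — on which the residual-cholesterol table was actually
measured — makes it resolvable (median error ~3 % at CV 0.02). The
0–60 min *window* default used when fitting the real table exists for a
different reason: beyond 60 min the measured decay plateaus and the
first-order model no longer holds, whereas synthetic data are exponential
throughout, so the recovery suite fits the full window.

Problem sizes: the recovery suite uses 200 seeded replications at CV 0.02
with triplicates (noise-free checks use a single replicate); the
fast-chain-reaction logistic study uses 100 seeds on a 14-point
rise-resolving design (log-spaced 0.03–30 min), since a 488 h⁻¹ logistic
completes its rise in under a minute and equally spaced 5-min sampling
carries no information about it.

## Known gaps and limitations

* The published control degradation constant (`k5 = 0.94` h⁻¹) is not
  recoverable from the printed control column (through-origin, 0–60 min
  gives 0.48); it likely rests on replicate-level data or a correction not
  described. It enters the package only as a reference constant.
* The published nitrogen-fit `r² = 0.94` is likewise not reproducible from
  the printed residuals (log-scale through-origin gives 0.83, intercept
  0.89); tests assert the published overall range 0.82–0.99 instead.
* The nonlinear constants `k1 = 1.8e-4`, `kf = 3.28`, `k4 = 0.016` cannot
  be meaningfully re-fitted from the three printed 7-OOH/5,6-EP points
  (`A′max` unpublished, two of five time points missing, and the printed
  values are mutually inconsistent with the observed growth); the
  reproduction workflow reports its best fits without asserting agreement,
  and validation of those estimators is by parameter recovery on synthetic
  data.
* The subtraction estimate of `kf` (6.302) and the nonlinear estimate
  (3.28) disagree by ~1.9-fold in the source itself; both estimators are
  provided and neither is privileged.
* No temperature dependence (150 °C only), no stochastic kinetics, no
  modelling of the downstream COPs that quercetin suppresses entirely
  within 30 min (7-keto, 7-OH, triol).
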
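# Methods

`kinetrace` turns continuous enzyme-assay time courses into initial rates
and endpoint kinetic parameters. This note records the models, the
numerical choices, and what the bundled simulator does and does not
emulate.

## Input model

An experiment is a CSV with a header row, time in the first column
(seconds or minutes — the unit is carried as metadata, never converted),
and one reaction well per further column. The titrant concentration is
parsed from each header as the first numeric token that is not glued to a
letter, so `320`, `SIRT1 40 uM` and `inhibitor_2.5e-2_mM` give 320, 40 and
0.025 while the digit inside a protein name is ignored. Rows containing
any non-numeric cell are dropped for the whole file (keeping one shared
time vector) and logged. Signals can be mapped to substrate concentration
by a user expression in one variable `x`, evaluated by a restricted
arithmetic parser (numbers, `x`, `+ - * / ^`, parentheses, unary minus);
nothing else is executable. Product-accumulation data entering the
progress-curve fit must additionally be inverted (multiplied by −1),
because that model is written for substrate loss.

## Per-trace initial rates

Three routines reduce one trace to a rate ± standard error:

* **Windowed linear fit.** Ordinary least squares over an inclusive time
  window; the slope standard error is the textbook
  `sqrt(SSE/(n−2)/Sxx)`. At least 3 points, nonzero time variance.
* **Maximum-slope (automatic default).** A cubic smoothing spline with
  generalized-cross-validation smoothing (overridable via `lam`) is
  fitted; the window is the contiguous run of points around the earliest
  maximum of the absolute spline derivative where the derivative stays at
  or above 95% of that maximum, grown to at least 5 points preferring the
  steeper side. A line over a window in which velocity decays to a
  fraction *f* of its peak underestimates v0 by roughly (1−*f*)/2; 95%
  keeps that bias near 2% on noiseless Michaelis–Menten curves while GCV
  smoothing keeps the derivative usable under read noise. On an exact
  line the derivative is constant, so the window is the full trace and
  all modes coincide.
* **Logarithmic integrated-rate-law fit.** The trace is fitted to
  `y = y0 + b ln(1 + t/t0)` with `b > 0`, `t0 > 0` by bounded
  trust-region least squares; the initial rate is the model derivative at
  the instant of mixing, `b/t0`. A mixing dead-time `delay` shifts
  observed times to `t + delay` so that t = 0 is the mixing instant (the
  model is evaluated on shifted times; evaluating the derivative at
  t = delay instead is algebraically identical). Decreasing traces are
  negated, fitted with positive `b`, and the rate negated back, recorded
  as `sign = −1`. Initialization follows y0 = first signal, b matched to
  the last point, with a 5-point multi-start on t0 over a log grid from
  1% to 100× the time span; tolerances are 1e−13 so exact data returns
  `b/t0` to better than 1e−6. The standard error propagates the full 2×2
  covariance of (b, t0) through the delta method
  `var = gᵀ C g, g = (1/t0, −b/t0²)`.

  The logarithmic curve has no plateau, so it is a model of the *early,
  still-curving* part of a progress curve, not of complete substrate
  depletion; fitted over a fully depleted trace it overshoots v0 badly.
  The pipeline therefore applies it to the automatically selected
  steep window (or an explicit user window), which is how the
  interactive workflow it mirrors behaves. An optional `t_start`/`t_end`
  pair on `fit_logarithmic` exposes this directly.

Residual diagnostics (sign-run count, positive fraction) support the
usual check that a good window leaves randomly scattered residuals.

## Closed-form progress curve and global fit

The irreversible Michaelis–Menten rate law dS/dt = −Vmax·S/(KM+S) has the
closed-form solution S(t) = KM·W0(z), z = (S0/KM)·exp((S0 − Vmax·t)/KM),
on the principal Lambert branch. Evaluation is done entirely in the log
domain as KM·ω(u) with u = ln(S0/KM) + (S0 − Vmax·t)/KM, where ω is the
Wright omega function (ω(u) = W0(eᵘ)); this is exact for all real u and
cannot overflow at large S0/KM, where the naive argument exceeds floating
range. S(0) = S0 holds to machine precision by the identity W(x·eˣ) = x.

The global fit shares KM and Vmax across all traces of a dataset and
refines one S0 per trace, initialized from the parsed header
concentration — nominal concentrations carry pipetting error, and modern
integrated-rate-law practice treats S0 as a parameter. Residuals are the
unweighted concatenation over traces; optimization is bounded
trust-region least squares with a 5-point log-grid multi-start on KM.
Standard errors come from `s²(JᵀJ)⁻¹` at the optimum. An optional blank
trace is first reduced to a straight line (OLS) and subtracted from every
other trace. Increasing traces abort with a message directing the user to
the −1 inversion.

Like every quasi-steady-state treatment the closed form requires
E0/(KM + S0) ≪ 1. When E0 is supplied the fit reports the worst ratio
over traces and warns at ≥ 0.1 — "much less than one" has no canonical
cutoff; 0.1 is a conservative, configurable operationalization.

## Endpoint models

All endpoint fits weight rows by 1/σ² of the initial rates (inverse
variance is the standard least-squares propagation of per-point errors).
Rows with σ = 0 (exact fits) borrow the smallest positive σ in the table;
an all-zero table is fitted unweighted. Covariances are computed treating
the σ as absolute, so doubling every rate error doubles every parameter
error without moving the estimates.

* **Michaelis–Menten:** v = Vmax·S/(KM+S), multi-start on KM over a log
  grid spanning the design; rows at S = 0 are excluded (they are blanks
  and carry no information about the hyperbola).
* **4-parameter logistic:** y = bottom + (top − bottom)/(1 + 10^(hill·(midpoint − x)))
  with x either the concentration or its log10 (zero concentrations have
  no finite log and are dropped with a warning). Any of bottom, top, hill
  (and midpoint) can be fixed; fixed parameters leave the optimization
  and report σ = 0. The midpoint is reported on the fitting axis — a
  pIC50-style value on the log10 axis. The model is symmetric under
  swapping top/bottom with hill → −hill, so free fits may return either
  parameterization. Flat response data (top = bottom) is rejected as
  unidentifiable.
* **Screening (HTS):** plate mean and *sample* standard deviation
  (n−1 denominator) of the rates; wells are flagged `above`/`below` by
  strict inequality against mean ± k·SD, so a rate exactly on the
  threshold is unflagged, and a zero-variance plate flags nothing.
* **Blank rates:** subtracting a blank's rate combines standard errors in
  quadrature and removes the blank row.

## Simulator

The generator emits the exact CSV dialect the reader consumes. Progress
curves come from the closed-form solution (so noiseless output satisfies
the MM ODE to finite-difference accuracy); the instrument model is
`signal = background + gain·S` (substrate loss) or
`background + gain·(S0 − S)` (product gain) plus i.i.d. Gaussian noise in
signal space, mimicking photometric read noise. The mixing dead-time is
realized by evaluating the true curve at `t + delay` — acquisition starts
late and the early curve is simply missing, which is the scenario the
dead-time entry addresses. Defaults are one plausible titration chosen
once: KM = 100 and Vmax = 5 in concentration units per time unit, a
doubling series 5–320 plus a background-only zero-concentration blank,
reads every 0.5 time units over 0–60, gain 1 and noise SD 0.5 signal
units. Dose-response plates are straight-line traces whose slopes follow
the 4PL; screening plates draw well slopes from N(1, 0.05²) with planted
outliers at `baseline + z·SD`. Identical seeds give byte-identical CSVs.

What the simulator does *not* emulate: coupled-assay lag phases,
enzyme inactivation, product inhibition, well-position/edge effects,
instrument drift, or heteroscedastic noise. Passing recovery tests on
these fixtures therefore demonstrates correctness of the estimators under
their own assumptions, not robustness to every pathology of real plates.

## Problem sizes and determinism

Tests and the reproduction script run on deliberately modest sizes — 121
points per trace, 4–8 traces per titration, 96-well plates, 10 noise
replicates for coverage checks — which keep full runs in seconds while
leaving the estimators overdetermined. Every stochastic step takes an
explicit seed (`numpy.random.default_rng`); nothing reads global RNG
state.

## Known limitations

* The automatic window rule is a deterministic contract, not a claim of
  equivalence with any interactive tool's unpublished heuristic.
* The logarithmic mode underestimates nothing but requires a sensibly
  restricted window (see above); it is not suited to traces that have
  plateaued.
* The closed-form mode models the plain irreversible MM law only — no
  reversibility, product inhibition, or inactivation terms.
* IC50/EC50 values are empirical; conversion to Ki is out of scope.
* No unit conversions: rates are in signal units per input time unit.
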
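# Methods

## Model

A probe's equilibrium signal at target concentration `c` is modelled by
the Langmuir isotherm `I(c) = a·c/(b + c) + d`: hyperbolic saturation
binding with amplitude `a` (intensity units), half-saturation
concentration `b` (concentration units, typically pM) and additive
background `d` (intensity units). The key assumption of the *global*
fit is that well-designed probes share, to a useful approximation, a
common dose-response shape: a single `(a, b, d)` triple is estimated
from the pooled `(c, I)` pairs of a small training set of spike-in
probes and then applied to every other probe on the array. This trades
per-probe bias (a probe's true amplitude may differ from the global
one) for a drastic reduction in free parameters — three per experiment
instead of three per probe — and removes any dependence on probe
sequence or thermodynamic modelling.

Concentration estimates invert the curve exactly inside its dynamic
range and are clamped outside it: intensities at or above the
saturation limit `a + d` map to a fixed large concentration `X`,
intensities at or below the background `d` (including negative values
from background-corrected pipelines) map to a fixed small `Y`. The
boundary points themselves are clamped because the algebraic inverse is
infinite at `a + d` and zero at `d`. Defaults are `X` = 2× the largest
and `Y` = 0.5× the smallest nonzero nominal concentration of the
dataset; both are arbitrary by construction and overridable.

## Fitting

Ordinary (unweighted) least squares on the linear intensity scale,
minimised with a Levenberg–Marquardt trust-region method
(`scipy.optimize.least_squares`). A log-scale loss is available but not
the default. Initialisation is data-driven and deterministic:
`a₀` = intensity range, `b₀` = median nominal concentration,
`d₀` = minimum intensity — scale-free values inside the attraction
basin for any Langmuir-shaped cloud. Parameters are deliberately
**unconstrained**: the training-set filter works precisely by observing
negative fitted values on non-hyperbolic probes, so a positivity bound
(available as an opt-in constrained mode) would mask the signal the
filter needs.

Failure policy: the optimizer never raises during batch work; a failed
or non-convergent fit is returned with `converged = False`. A fit whose
Jacobian at the solution is column-degenerate — any near-null column,
or a column-normalised condition number above 1e8 — is also flagged
`converged = False`: those are non-identifiable responses (constant or
linear in `c`), the same situations in which a classical `nls` fit
stops with a singular-gradient error.

The admission filter `is_langmuir_like` requires `a > 0`, `b > 0`,
`d > 0` and convergence. A noisy non-Langmuir probe can occasionally
pass it by fluking a weak positive fit; the protocol makes no guarantee
there, and larger training sets dilute such probes.

## Evaluation

Predicted vs nominal concentration is regressed through the origin,
`y = m·x`, with `m = Σxy/Σx²`, the uncentered coefficient of
determination `R² = 1 − Σ(y − m·x)²/Σy²`, and a two-sided t-test of
`m = 0` on `n − 1` degrees of freedom — the conventions of a linear
model with the intercept omitted, matched in tests to an independent
OLS implementation at 1e-10. The regression is computed over
transcript-level (probe, condition) points, not per-concentration
means, which is the stricter choice; per-concentration sample standard
deviations (the error-bar lengths of a calibration plot, `n − 1`
denominator, 0 with a note for singletons) are reported alongside.

The default evaluation scale is log2 of the concentrations: spike-in
ladders span 3–4 orders of magnitude, and a linear-scale regression
would be dominated entirely by the top one or two steps. Linear scale
is available and every result records its scale. Zero nominal
concentrations never enter the regression.

Spike-ins are classed low / medium / high by user-supplied thresholds:
*low* is the range where signal is indistinguishable from background,
*high* where saturation begins. There is no universal default — the
boundaries depend on the platform's background and dynamic range — so
`leave_k_out` takes optional thresholds and, when given, excludes
low-category rows from the regression by default (`include_low`
restores them). With no thresholds supplied, nothing is excluded.

"Leave-K-out" holds **K probes out** for prediction and trains on the
remaining `N − K` (so leave-nine-out on ten probes trains on one).
Candidate training sets are all `C(N, N−K)` subsets when that count is
within the draw budget, otherwise `max_draws` *distinct* subsets sampled
uniformly (rejection sampling, capped at 1000× the budget) under an
explicit seed. Training sets rejected by the Langmuir filter are
recorded, not silently dropped; if every candidate is rejected the run
errors.

## Synthetic data

The simulator emulates a Latin-square spike-in experiment: `L`
conditions cyclically rotate an `L`-step ladder so each probe sees each
concentration exactly once (`full_factorial` is available for
dose-response panels). Defaults, chosen once:

| parameter | default | why |
|---|---|---|
| `n_probes` | 42 | the canonical commercial Latin-square panel size |
| `concentrations` | 13 two-fold steps, 0.125–512 pM | the printed range of that panel |
| `n_replicates` | 3 | typical technical replication per condition |
| `global_a` | 10000 | raw-intensity saturation scale of a 16-bit scanner pipeline |
| `global_b` | 100 pM | published Langmuir fits to this ladder place half-saturation near 100 pM, so only the 256–512 pM top of the ladder saturates; a much smaller `b` would put most of the ladder in the ill-conditioned saturated regime, contradicting the emulated experiment |
| `global_d` | 200 | background a few percent of saturation |
| `probe_cv` | 0.2 | moderate probe-to-probe heterogeneity |
| `noise_sd_log` | 0.2 | ~20 % multiplicative measurement noise |
| `frac_nonlangmuir` | 0 | contaminants opt-in |

Per-probe parameters are lognormal around the globals with a single
coefficient of variation applied to `a`, `b`, `d` independently
(simplest positive-support heterogeneity model). Noise is
`exp(N(0, noise_sd_log))`, independent per replicate. Contaminants are
the first `round(frac·n)` probes, alternating linear (`slope·c + d`,
slope spanning the Langmuir dynamic range) and constant (`d`)
responders — the minimal non-hyperbolic behaviours that exercise the
negative-parameter filter. Each probe draws from its own
`SeedSequence([seed, probe_index])` stream, so growing the panel never
perturbs existing probes.

What the simulator does **not** emulate: scanner nonlinearity, spatial
background gradients, cross-hybridization networks, probe-sequence
effects, or any platform's actual noise magnitude (no published noise
model exists for these control sets). Passing tests therefore
demonstrate correctness of the pipeline and its behaviour under the
stated noise model, not platform-level accuracy figures, which require
the real control datasets.

## Numerical choices and problem sizes

- Fit tolerances default to 1e-12 (xtol/ftol/gtol), tight enough that
  noise-free recovery is exact to well below 1e-6 relative.
- The brute-force optimality check uses a 50³ grid over
  `[0.2, 3]×truth` per axis (`d` from 0) on datasets of ≤ 5 probes and
  ≤ 6 concentrations; the test suite runs 20 such datasets in seconds.
- Monte-Carlo checks are frozen-seed: the parameter-recovery property
  runs 200 simulations at 12 replicates per cell (a multi-site
  setting), where the ~2.9 % cell-mean noise makes 10 % parameter
  recovery statistically attainable; at 3 replicates the sampling error
  of `b` and `d` alone exceeds that band.
- The training-set-size experiment uses the default 42-probe panel with
  `probe_cv = noise_sd_log = 0.2`, 42 draws per size, low category
  (≤ 0.5 pM) excluded — a few seconds per size.
- Single-estimate standard deviations are 0 (with a log note), never
  NaN, so downstream tables stay numeric.
- Ties in clamping are closed on the clamped side (`I = a + d → X`,
  `I = d → Y`).

## Known limitations

- A single global curve cannot capture genuine per-probe affinity
  differences; the resulting prediction error scales with probe
  heterogeneity, visible in the simulator as R² degrading with
  `probe_cv`.
- Inversion amplifies intensity noise by a factor `≈ 1 + ĉ/b`, so
  estimates in the saturated regime are intrinsically unstable —
  that is what the high category and the `X` clamp acknowledge.
- The positivity filter is necessary, not sufficient: weakly positive
  non-Langmuir fits can slip through on noisy data.
- Units are whatever the design table uses (pM or molecule counts);
  the package never converts between them.
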
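# Methods

## Model and conventions

The package implements the Birnbaum–Saunders (BS) fatigue-life law in the
**rate** parameterization: shape α > 0 (dimensionless), rate β > 0
(1/time), CDF F(x) = Φ((√(βx) − 1/√(βx))/α), density

    f(x) = (1 + βx) · exp(−(βx − 1)²/(2α²βx)) / (2α √(2πβ) x^{3/2}),

centred near 1/β. The scale form (scale s = 1/β) is equivalent; the rate
form is used throughout because the closed-form mode and median worked
examples, and the score equations, are consistent only under it.

The neutrosophic extension attaches an indeterminacy interval
I = (I_L, I_U) with 0 ≤ I_L ≤ I_U. Its entire analytic effect is the
factor (1 + I) on the density and CDF: total mass is 1 + I, the CDF
ranges over (0, 1 + I), and the survival complement 1 − F can therefore
be negative in the far right tail when I > 0 — it is reported exactly as
the formula produces it, without clipping. All neutrosophic quantities
are computed **endpoint-wise** at (I_L, I_U) (and at each endpoint of
α/β when those are interval-valued) and reported as ordered pairs; no
interval arithmetic beyond the endpoints is performed, because that is
how paired results are defined in this framework. I = (0, 0) reduces
every formula to the classical law (tested to 1e−10 against an
independent implementation).

Consequences worth stating explicitly:

- The **likelihood** gains only the additive constant n·log(1+I), so ML
  and Bayes point estimates are identical across I while −2LL, AIC and
  BIC drop by exactly 2n·log(1+I). This identity — not any change in fit
  — is what ranks the neutrosophic model ahead of the classical one on a
  fixed dataset, and the package treats it as the model-comparison
  contract rather than reproducing any particular published table.
- The **median equation** ½(1+Erf(z))(1+I) = ½ yields a quadratic with
  two roots m± = [(1+k²α²) ± √((1+k²α²)²−1)]/β, k = InverseErf(−I/(1+I));
  only the smaller root satisfies F = 0.5 for I > 0, but both roots are
  the model's closed-form output and `nmedian` returns the pair by
  default (`strict=True` selects the F = 0.5 root per endpoint; for
  genuinely interval-valued (α, β, I) only strict mode is defined, since
  the two-root display presumes a single parameter triple).
- The **quantile** closed form squares the inverse error function and so
  erases its sign; `nquantile` restores it — smaller root below the
  half-mass point (1+I)/2, larger above — so that F(Q(p)) = p uniquely.
- **Entropies** are integrals of the unnormalized (mass 1 + I) density,
  i.e. the textbook definitions applied verbatim to f_N; whether the
  normalized density was intended is ambiguous in the source framework,
  so `normalized=True` is provided to divide f by (1 + I) first. The
  Tsallis normalization is 1/(q − 1), the choice under which both Rényi
  and Tsallis converge to the Shannon entropy as the order tends to 1.

## Numerical choices

- **Mode**: the stationarity cubic −1 + (3α²−1)βx + (1+α²)β²x² + β³x³
  has exactly one positive root (one sign change); solved by Brent on a
  bracket grown geometrically from 1/β. No closed-form cubic solver.
- **Density/hazard**: computed in log space; the exponent is expanded to
  −(βx − 2 + 1/(βx))/(2α²) so neither tail overflows. The hazard uses
  the scaled complementary error function, h = (1+I)(1+βx) /
  (α√(2πβ) x^{3/2} erfcx(w)), which is finite arbitrarily far into the
  right tail where both f and 1 − F underflow.
- **Raw moments**: E[Xʳ] = (1+I) e^{1/α²}(K_{r+½}(1/α²)+K_{r−½}(1/α²)) /
  (α√(2π) βʳ), evaluated with exponentially scaled Bessel functions
  (`kve`) so small α cannot overflow. Mean simplifies to
  (1+I)(1+α²/2)/β; variance is E[X²] − (E[X])² (note the mass factor is
  linear in the former, quadratic in the latter).
- **Rényi/Tsallis closed form** (integer order d only): from
  ∫ x^{p−1}e^{−(ux+v/x)/2}dx = 2(v/u)^{p/2}K_p(√(uv)),
  ∫f^d = 2k^d e^{d/α²} β^{3d/2−1} Σ_{c=0}^{d} C(d,c) K_{c−3d/2+1}(d/α²),
  k = (1+I)/(2α√(2πβ)). Non-integer orders, and the Shannon entropy (its
  closed form involves a complex-valued logarithm and is not usable), go
  through quadrature, which is the authoritative route in all cases.
- **Quadrature**: adaptive integration over (0, ∞) after the substitution
  x = e^u/β, which centres the integrand at u ≈ 0 for every β; absolute
  tolerance 1e−10; exact-zero tail products guarded against inf·0.
- **MLE**: BFGS over (log α, log β) with the analytic score (positivity
  without constraints); moment-based start α₀² = 2(√(x̄·h̄)−1),
  β₀ = √(h̄/x̄) with h̄ the mean reciprocal; up to 3 jittered restarts if
  the observed information is not positive definite. Standard errors come
  from the inverse *analytic* observed-information matrix (cross-checked
  against finite differences in the tests); confidence intervals are the
  normal-approximation estimate ± z_{γ/2}·SE. Because I is irrelevant to
  the optimum, optimization always runs at I = 0 and the constant is
  added afterwards — this makes estimates bit-identical across I.
  Convergence is declared on the first-order condition (score at rounding
  level) rather than the optimizer's own flag, which can report precision
  loss at an already-converged point. Degenerate all-equal data is
  rejected (the shape is unidentified there).
- **Bayes**: independent Gamma(a,b)/Gamma(c,d) priors; MH-within-Gibbs
  with Gaussian random walks on log α and log β, the log-scale Jacobian
  in the acceptance ratio, proposal scales adapted every 50 burn-in
  iterations toward 20–45% acceptance then frozen (preserving detailed
  balance post-burn-in). Defaults N = 10⁴ draws, B = 2×10³ burn-in.
  Credible intervals are equal-tailed posterior quantiles (the
  operational definition in this framework, despite the "HPD" name); a
  true shortest-interval HPD is available via `hpd=True`. Single chain by
  default; the interval wrapper runs one independent chain per endpoint
  with seeds spawned from one root seed.

## Synthetic data and the simulation study

Because the (1+I) factor makes f_N improper, **sampling is defined from
the normalized (classical) law at each endpoint** via the exact normal
transform X = (1/β)[αZ/2 + √((αZ/2)²+1)]²; indeterminacy enters
estimation only through the likelihood constant. This is the only
generating mechanism the model's own formulas support, and it is the
package's definition of a neutrosophic sample. Interval samples couple
endpoints with one shared Z per unit (coherent intervals, the default) or
independent draws sorted per unit (sensitivity analysis).

The simulation engine reproduces the *structure* of the published
bias/MSE/AIC/coverage tables on the grid (α, β) ∈ {(1.25,3), (0.5,3),
(1,3)}, I ∈ {(0,0), (0.2,0.5), (0.6,0.8)}, n ∈ {50, 100, 200, 500},
gamma priors {(1,2), (1,1), (2,1)}, with M = 1000 replicates by default
(the source does not state its M; M = 200 roughly doubles Monte-Carlo
tolerances). Per-replicate streams are spawned deterministically from the
cell seed, so an I = (0,0) cell reproduces the classical cell
bit-for-bit. Cells with > 5% non-converged fits are flagged. Bias is
reported signed. Coverage is reported alongside mean interval length
because the two are distinct quantities that the published tables appear
to conflate under one "ACL" label.

What passing simulations do and do not show: they validate estimator
calibration (MSE ≈ α²/(2n) for α̂, 92–97% empirical coverage of 95%
intervals at n ≥ 200) **under the generator above** — correctly specified
model, independent observations, interval endpoints from the same shape.
They say nothing about censoring, measurement error beyond the interval
representation, or model misspecification, none of which are modelled.

Problem sizes used by the default test run: Monte-Carlo cells of M = 1000
at n ∈ {100, 200, 500} for the error-rate and coverage checks, one
n = 5000 sample for point recovery, chains of 10⁴ draws for the
Bayes/MLE agreement check, and M in the tens for structural checks —
chosen to keep the full suite around half a minute while leaving the
stochastic tolerances comfortable.

## Known limitations

- No censoring or truncation; no regression or multivariate extensions.
- The upper median root and the negative reliability tail are reported as
  the closed forms produce them; they are properties of the (1+I)
  inflation, not bugs, but users comparing against the classical model
  should use the strict median and I = 0 reliability.
- Exact reproduction of the published neutrosophic simulation cells is
  not attempted: their generating mechanism is unspecified, and the
  published model-comparison table's −2LL magnitudes are not consistent
  with any likelihood of data on the printed scale (our fits on the same
  data do reproduce its point estimates, up to an apparent swap of the
  parameter labels in that table).
- MCMC diagnostics are limited to acceptance rates and a split-half
  stationarity check; for serious posterior work dump the chains
  (`fit-bayes --chain-csv`) and use a dedicated diagnostics package.
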
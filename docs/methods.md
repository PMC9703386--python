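# Methods

## Model

One woman's disease history is generated by four coupled sub-models.

**Growth and symptomatic detection.** Tumours are spheres growing
exponentially in volume from a single 0.01 mm cell; the inverse growth rate
`r` (years) is Gamma(τ₁, rate τ₂) across women. Volume doubles every
`r ln 2` years, and a tumour becomes detectable at diameter 0.5 mm, i.e.
`t₀(r) = 3 r ln 50 ≈ 11.74 r` years after onset. Symptomatic detection is an
inhomogeneous process with hazard `η V(t)` once detectable. Marginalising
`r` gives the closed-form size-at-detection density
`f(v) = η τ₁ τ₂^τ₁ (τ₂ + η(v−V₀))^{−(τ₁+1)}`, and Bayes' rule gives
`r | V_det = v ~ Gamma(τ₁+1, τ₂+η(v−V₀))` — conditioning on detection at a
given size favours slower tumours by exactly one shape unit.

**Nodal spread.** Detectable nodal metastases arrive as a Poisson process
with intensity proportional to `D(t)^{k_N} D′(t)` (divisions so far, to a
genomic-instability power, times division rate). The cumulative count to
volume `v` is `s · [log(v/V₀)]^{k_N+1}`, so given volume the count is free
of `r`; a Gamma(γ₁, γ₂) frailty on `s` makes `N | V=v` negative binomial
with size γ₁ and success probability `γ₂/(L+γ₂)`, `L = log(v/V₀)^{k_N+1}`.

**Distant spread.** Same seeding form with parameters (ω₁, ω₂, k_W); only
the first metastasis matters. Seeding stops when the primary is removed,
and each seed surfaces exactly `t₀(r)` years after being shed. This gives
`W` (years from diagnosis to metastasis detection) a point mass at `W ≤ 0`,
a continuous density on `(0, t₀(r)]`, and a survival plateau — the cure
fraction — beyond: seeds shed before the tumour itself was detectable
cannot surface later than `t₀(r)` after diagnosis.

**Dependence.** `N` and `W` given `(v, r)` are joined by a bivariate
Archimedean copula on their conditional CDFs, with `W` discretised to whole
years (year bin `w` holds mass on `(w−1, w]`; `W ≤ 0` is its own
left-censored cell; the cure mass is never spread over the grid). Six
families are provided; Frank is the workhorse because it covers the full
negative τ range symmetrically.

## Likelihood

Each record contributes the size-at-detection density times a copula
rectangle probability — event, left (`W≤0`, `r`-free), or right tail —
integrated over `r | V_det = v`. Screen-detected records add the logistic
sensitivity at the detected diameter; any record's prior negative screens
multiply the integrand by `∏(1−S(d_q))` with sizes back-projected through
the growth law. Likelihoods are kept only up to constants shared by all
records, so differences, AIC and likelihood-ratio tests are meaningful but
absolute levels are implementation-relative.

### Numerics

The `r`-integrand has a derivative kink where the year-`w` cell hits the
survival plateau, at `r = w / log(V₀/V_cell)` — in the bulk of the Gamma
mass for typical `w`. A single Gauss rule across it converges erratically
(and, before this was found, inflated the apparent sampling variance of the
fitted growth parameters), so the integral is split per record: a graded
Gauss–Legendre segment up to the kink (the `u²` map absorbs a
fractional-power endpoint singularity of the year-1 cell), a second
Legendre segment over `(c, 4c)` where the cell still varies steeply, and a
Gauss–Laguerre tail, with the Gamma density folded into the weights and the
row renormalised to the exact Gamma tail mass. With the default 64 nodes
(32 in the heavy validation loops), doubling the node count changes
per-record log-likelihoods by less than 1e−6; the screening threshold at
0.5 mm adds its own small kink for screened records, where agreement with
adaptive reference quadrature is ~1e−3 — negligible against statistical
error. For plain smooth integrals against `r | V_det`, generalized
Gauss–Laguerre with `α = τ₁` is used instead of a quantile-mapped Legendre
rule: it is exact for polynomial moments to degree `2n−1`, which is also
the property the tests pin down. Probabilities are floored at 1e−300 (with
a warning counter) before logs; copula arguments are clamped to
`[1e−12, 1−1e−12]`; `|θ| < 1e−6` in the Frank/Clayton/AMH families
evaluates the independence limit (removable singularity).

Optimisation runs on the unconstrained scale (logs; `−log η`; `atanh` for
AMH θ, `log(θ+1)` for Clayton, `log(θ−1)` for Gumbel/Joe; identity for
Frank) with an optional Nelder–Mead warm-up and an L-BFGS-B polish.
Standard errors invert a central-difference Hessian with relative step
5e−3 — large enough to average across the micro-kinks left by probability
clamping, small enough to stay in the quadratic regime; non-convergence is
flagged, never raised, and a singular Hessian leaves the covariance absent.
Delta-method standard errors for derived quantities use central-difference
gradients on the same scale.

## Parameters and defaults

| parameter | meaning | default (reference set) |
|---|---|---|
| τ₁, τ₂ | shape/rate (yr⁻¹) of inverse growth rate | e^0.788 ≈ 2.20, e^0.950 ≈ 2.59 |
| η | symptomatic hazard per mm³·yr | e^−9.082 ≈ 1.14e−4 |
| β₁, β₂ | screen sensitivity intercept / slope per mm | −4.734, 0.453 |
| γ₁, γ₂ | nodal frailty shape / inverse scale | e^−1.437, e^10.175 |
| ω₁, ω₂ | distant frailty shape / inverse scale | e^−1.416, e^14.175 |
| k_N, k_W | genomic-instability exponents (fixed, not fitted) | 4.0 |
| θ (Frank) | node–metastasis association | −3.304 (τ ≈ −0.333) |

The reference set represents a screened Swedish postmenopausal incident-case
cohort. The exponents `k_N = k_W = 4` are a calibration, not an arbitrary
choice: holding the frailty parameters above fixed, `k = 4` is the unique
integer for which the model reproduces that cohort's printed anchor
figures — ~69% node-negative at diagnosis (computed: P(N=0) = 0.68 at
15 mm, P(N=1) = 0.13, P(N=2) = 0.065) and a marginal cure probability near
0.70 (computed: 0.69 at 15 mm; node-group values 0.80/0.55/0.47 for
0/1/2 nodes). With `k = 1` the same frailty values imply essentially no
nodal or distant spread. Both exponents are plain configuration fields and
can be estimated in principle, but are held fixed during fitting so the
free-parameter count stays at ten (eight without screening, nine for the
product copula).

## Synthetic cohorts

`simulate_natural_history` is mechanistic: it draws `r`, samples the
symptomatic detection volume from the hazard in closed form
(`V_sym = V₀ + Exp(1)/(η r)`), runs scheduled screens (default: 2-year
interval, uniform phase, at most 10 recorded) with Bernoulli detection at
the logistic sensitivity, takes whichever detection comes first, then draws
`(N, W)` at the detected volume by conditional inversion of the copula and
the discretised margins. Follow-up is administratively censored at a
per-woman Uniform(3, 8)-year horizon (median 5.5 years, typical of the
cohorts this model targets). Latent truths (r, t₀, detected volume, copula
uniforms, uncensored `W`) ride along for oracle tests.

What the generator does *not* emulate: competing mortality, interval
changes in screening attendance, measurement error in recorded tumour size,
and treatment effects on seeded metastases. Passing tests therefore
validate the estimation machinery under the model's own assumptions, not
the model's fit to any real registry.

**A known structural limitation.** The screened likelihood's
screen-detected term rests on a stable-disease approximation: it assigns
screen-detected sizes the symptomatic-detection density, whereas the
prevalent-size law of the mechanistic generator carries an extra `1/(ηv)`
occupancy tilt (verified by simulation; the symptomatic term and the
`r | v` posterior are exact — the negative-screen product is precisely the
survival probability of the screen-detection competing risk). Consequently
a fit to mechanistically simulated *screened* data recovers the nodal and
copula parameters cleanly but lets the growth/detection and distant-frailty
parameters absorb the approximation. The unscreened likelihood has no such
gap: simulate-and-refit validation (30 replicates of 500 women under the
Frank reference truth) shows every transformed parameter's bias within two
Monte-Carlo errors and 95% Wald coverage consistent with 0.95. A small
finite-sample bias in θ̂ (~ −0.1 at n = 500, shrinking with n) is visible
at higher replication and is expected of MLEs at this scale. Replicate fits
initialise at the generating truth — standard for validating an estimation
procedure, since the interior optimum is start-point independent; the
moment-style `default_init` is exercised separately.

## Microsimulation and lead time

`microsim_early_detection` simulates tumours detected at 15 mm, draws
`(N, W)` jointly, keeps women without detectable metastasis at diagnosis,
and asks what detection Δ years earlier (or at a smaller diameter, where
Δ = r log(v/v′) per tumour) would have changed. Because every seed shares
the same seeding-to-detection offset `t₀(r)`, a metastasis detected at `W`
was seeded at `W − t₀`; seeds after the earlier removal date are simply
erased, so metastasis still occurs iff `W ≤ t₀ − Δ`. Two 5-year risks are
reported per stratum (node count 0/1/2 at 15 mm × inverse-growth-rate
tertile): *naive* (horizon starts at the earlier diagnosis — contaminated
by lead time) and *corrected* (horizon starts when the tumour would have
reached 15 mm). Only the corrected risks are comparable across scenarios;
the naive ones are retained as a deliberate illustration of lead-time bias.
Desk-scale default is 2×10⁵ tumours (Monte-Carlo error on a 10% risk
≈ 0.1 percentage point per stratum), scaled down from population-scale
runs; the seed-level Poisson mechanism is kept only as a verification
device since the shared `t₀` offset makes the first-seed rule exact.

## Design notes

* The copula with discretised margins is unique only on the margins' range;
  the model is *defined* as the chosen family applied to the discretised
  CDFs. A Gaussian-copula variant is deliberately excluded from the fitting
  path (no closed bivariate CDF).
* `dm_free_survival` weights numerator and denominator of the conditional
  survival ratio by the negative-screen product inside the `r`-integral;
  any `r`-free factor (including screen-detection sensitivity) cancels in
  the ratio.
* Doubling-time summaries are reported under both the population law of `r`
  and the detection-conditional law, because "the doubling time of detected
  tumours" is ambiguous between the two (they differ by ~40% here).
* Cohort files are plain TSV with semicolon-separated screen offsets;
  records with a recorded diameter exactly at the 0.5 mm detectability
  limit are clamped into the support with a warning rather than dropped.
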
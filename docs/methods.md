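# Methods

## Prevalent-cohort model of attachment times

A tick found on a freshly captured host was already attached, so the
collection scheme samples attachment episodes in progress. Three
assumptions drive all the distribution theory:

1. the capture date is independent of the tick's whole attachment time
   T and uniformly distributed over the attachment interval;
2. the probability of a tick being sampled is proportional to T
   (length-biased sampling — longer-attached ticks are more likely to
   be on the host at capture);
3. T is Weibull with shape k and scale λ (in days).

Under 1–2 the sampled whole time T\* has density t·f(t)/E[T] and the
observed (capture-to-drop-off) time V = U·T\* with U ~ Uniform(0, 1) —
the forward recurrence time — has the renewal-equilibrium density
f_V(v) = S_T(v)/E[T]. With the Weibull in 3,

* f_V(v) = exp(−(v/λ)^k) / (λ Γ(1+1/k)), monotone non-increasing for
  every k, with CDF P(1/k, (v/λ)^k) (a generalised gamma law);
* E[V] = λ Γ(1+2/k) / (2 Γ(1+1/k));
* R(k) = E[T]/E[V] = 2 Γ(1+1/k)² / Γ(1+2/k), strictly increasing in k,
  R(1) = 1 (memoryless case), R → 2 as the whole-time law degenerates.

All gamma factors are computed via `gammaln` and exponentiated from log
space; densities are evaluated as log densities to avoid underflow for
v ≫ λ. The length-biased Weibull admits an exact sampler,
T\* = λ·G^{1/k} with G ~ Gamma(1+1/k), obtained by substitution in the
density.

## AFT regression and the profile-likelihood shape

The regression model is log λ_i = x_i′β with treatment coding
(reference: larva, spring) and a single shape k for all groups.
Because λ enters T and V identically, β carries over to the whole
times, and every group's whole/observed mean ratio equals R(k).

Estimation maximises the forward-recurrence likelihood by profiling:
for fixed k the log-likelihood is strictly concave in β
(∂²ℓ/∂η² = −k²(v/λ)^k < 0), so damped Newton iterations converge from
any start; an outer bounded Brent search over log k ∈ [log 0.3, log 30]
(tolerance 1e−8) maximises the profile. The profile is unimodal on all
tested instances, and restarts from well-separated shape values agree
to 1e−6.

Two conventions are offered for the one-day-binned drop-off record (a
tick falling during day d is coded d − 0.5):

* **midpoint** (default): the coded times enter the density directly —
  this mirrors feeding half-integer times to a parametric fitter;
* **interval**: the likelihood uses the bin probability
  F_V(d) − F_V(d−1).

On data with scales ≥ 3 days the two shape estimates agree within 5%;
the midpoint convention is the default because the published results
were obtained from half-integer-coded times.

Uncertainty: the shape's standard error comes from the numerical
curvature of the profile log-likelihood in log k. The covariance of
(β, log k) is a cluster-robust sandwich — bread the observed information
(finite differences of the analytic scores), meat the summed outer
products of per-host score sums. Point estimates are invariant to
cluster labels; only the covariance changes. When the input is an
aggregated day-bin table without host identifiers the covariance
degrades to the model-based one and the fit is flagged `robust="naive"`.
Group-mean confidence intervals and the interval for R(k) use the delta
method on the log scale (for R, via the analytic derivative
R′(k) = R(k)·(2/k²)(ψ(1+2/k) − ψ(1+1/k)), cross-checked against central
differences).

The day-1 deficit records are retained in the fit; the mitigation is
the sensitivity analysis that recodes all day-1/2 drop-offs to a common
1-day observed time and refits. On the published day-bin table this
moves every stage's modelled whole-time mean by 2.2–2.6%.

## Abundance model

Per-host tick counts by stage are modelled with a saturated stage ×
season log-linear Poisson GEE (statsmodels, independence working
correlation, host-clustered sandwich). In the saturated model the
fitted cell mean equals the observed cell mean — cell total divided by
hosts in that season — for any working correlation, so fitting the
published cell totals requires only an arbitrary allocation of each
total across that season's hosts. An exchangeable working correlation
is available and leaves the estimates unchanged. Zero-total cells
cannot be represented on the log scale; they are reported as mean 0
with the one-sided boundary profile-likelihood interval
(0, 1.9207/n_hosts) and flagged.

## Post hoc contrasts

Ratios of modelled means (stage pairs within season, season pairs
within stage) are exponentiated differences of log cell means.
Multiplicity is controlled per family by the single-step max-|z|
method: the joint normal law of the standardised contrasts is sampled
(10⁵ draws, fixed seed 20230329, eigendecomposition for the
rank-deficient contrast covariance); adjusted p-values are clipped from
below at the raw p (the single-step p dominates it analytically; the
clip removes Monte-Carlo noise only). Holm's step-down method is the
deterministic fallback. The significance level is 5% throughout.

## Day-1 versus day-2 drop-off test

The equilibrium density is non-increasing, so the model predicts at
least as many drop-offs on day 1 as day 2; the field data show the
opposite. The test is an NB2 mixed model on per-host day-1/day-2
counts, fixed effects day + stage + day:stage, host random intercept,
fitted by maximising the marginal likelihood with the random effect
integrated by adaptive Gauss–Hermite quadrature (15 nodes, centred and
scaled at each host's conditional mode; Laplace as the fast
single-node option, agreeing within 2% on well-separated data).
Per-stage day-2/day-1 rate ratios and Wald tests come from the
interaction parameterisation; larvae and nymphs can be pooled into a
"subadult" level. With the intercept variance pinned at 0 and the
dispersion at infinity the model reduces to a Poisson GLM, which is the
cross-check against statsmodels. Simulation at study size (57 hosts,
day-bin means matching the published drop-off table, dispersion θ = 4,
random-intercept SD 0.5) puts the Wald test's type-I error at ~4% and
its power against 50% day-1 suppression near 1 for subadult stages.

## Synthetic cohorts

The generator reproduces the study design: 57 hosts over 27 weekly
captures (18 spring, 27 summer, 12 autumn), per-cell expected burdens
taken from the published observed means, a shared Weibull shape of 4.5
with cell scales chosen so the model's mean observed times match the
published per-cell observed means, and 0.65% inert *I. hexagonus*
labels excluded from all fits. Host clustering enters through a
log-normal frailty multiplying the abundance means (mean 1, log-SD 0.8
by default — the published per-cell SDs are of the order of the means,
far beyond Poisson); given the parameters, attachment durations are
independent across ticks, matching the marginal-model estimand. The
published tables do not state a within-host dispersion; the
Poisson-log-normal choice and its default SD are the package's own.

Sampled whole times use the exact length-biased draw above with uniform
capture position; an explicit stationary-process sampler (homogeneous
Poisson onsets on a window covering the 99.9999th percentile of T,
keeping ticks attached at capture) is provided and the two agree in
distribution. Observed days are ceil(V) − 0.5. A day-1 suppression
option moves each day-1 record of the obligate blood-feeding stages
(all but males) to day 2 with a given probability, emulating the
capture-stress deficit for power studies; it distorts the recorded bin
only, never the latent times. Default suppression is 0 — the deficit is
a departure from the stationary model, not part of it.

What the simulator does **not** emulate: recaptures, questing dynamics
and weather forcing, duration correlation within hosts, seasonal drift
within a season, and measurement problems other than the day-1 deficit.
Passing recovery tests therefore show the estimators work under the
model's own assumptions, not that the field data satisfy them.

## Numerical and design choices

* Shape search bounds [0.3, 30] cover every biologically plausible
  Weibull shape for engorgement (fitted values are ~4).
* The published day-bin table is fitted with stage as the only
  covariate: the season-resolved per-tick data were never published.
  Consequently the reproduced mean ratio (1.863) sits slightly below
  the published 1.88, whose fit included season terms; it lies inside
  the published interval [1.80, 1.91].
* The published summary tables are internally inconsistent in places
  (male totals 75/76/79, conflicting season totals for subadults
  between tables). Each bundled table is stored exactly as printed and
  consumers use the table the corresponding published figure came from.
* Simulation study sizes: distributional checks use ~10⁵ ticks per
  seed; calibration studies use 200–500 replicates at study-like or
  quarter-scale cohorts. These sizes make the checks sharp while
  keeping the suite quick to run.
* Cluster-robust covariances are asymptotic in the number of clusters:
  at a few dozen hosts the simultaneous contrast intervals under-cover
  by a few percentage points (e.g. ~91% familywise at 30 hosts/season);
  the null-coverage study is run at 100 hosts/season where the nominal
  level is attained. Reported intervals at study size should be read
  with this in mind.
* CSV readers validate schema and values and report the offending line
  number; writers emit RFC-4180 (CRLF) files. Simulation configs
  round-trip through YAML and must state their seed explicitly.

## Known limitations

* Only the Weibull whole-time family is implemented; the equilibrium
  machinery would extend to other families but is untested there.
* Host-level covariates (sex, body weight) are carried in the data
  model but not in the AFT regression (the study found no effect).
* The NB mixed model supports a single random intercept per host and
  days 1–2 only; no zero-inflation.
* The boundary interval for zero-count abundance cells is non-standard
  and flagged as such.
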
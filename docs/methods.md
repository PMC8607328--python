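# Methods

## Model and criteria

Two estimation problems are supported, each with a conjugate prior:

* **Population mean, normal data.**  Observations are i.i.d.
  N(μ, 1/λ).  The joint prior is normal-gamma: λ ~ Gamma(a, rate b),
  μ | λ ~ N(μ₀, precision n₀λ).  The marginal prior (and posterior) of μ
  is a shifted, scaled Student t.  The prior mean of λ is a/b and its
  coefficient of variation is 1/√a, so `a` encodes trust in the variance
  guess and `b/a` the guess itself.  n₀ is the prior sample size for the
  mean; n₀ = 0 means a flat prior on μ.
* **Areal fraction / binomial proportion.**  z successes in n trials,
  π ~ Beta(c, d); the preposterior of z is beta-binomial, the posterior of
  π is Beta(z+c, n−z+d).

A precision requirement (`PrecisionSpec`) is a maximum interval length
l_max on the scale of the parameter, a credibility level 1−α, a criterion
(ALC, ACC, WOC) and an approach (fully Bayesian, mixed
Bayesian-likelihood, frequentist).  Under the mixed (MBL) approach the
prior generates the preposterior of the data only; the per-data-set
interval is the likelihood-only t interval `2 t_{n−1,1−α/2} s/√n` for the
mean, and the HPD interval of the uniform-prior posterior Beta(z+1, n−z+1)
for the proportion.

### The worst outcome criterion

ALC and ACC are averages and guarantee nothing for an individual data
set.  The modified WOC restricts attention to the most plausible data
sets: we require the precision to hold on a set of outcomes carrying at
least `worst_level` (default 0.8) of the preposterior mass —
operationally, the worst-level quantile of the distribution of interval
lengths over data sets must not exceed l_max.  For the mean the length is
increasing in the centred sum of squares ss, so this quantile is the
length at the worst-level quantile of the preposterior of ss.  For the
binomial case the lengths over z ∈ {0,…,n} are sorted and the quantile is
taken under beta-binomial weights.  This quantile reading is the only one
that is well defined when the preposterior is flat (a uniform prior makes
every outcome equally "most likely", so a rule that accumulates
most-probable outcomes degenerates to the full outcome space), and it
reproduces the published district results; it is deliberately weaker than
demanding the criterion on *every* outcome.

## HPD numerics (`bayes_ssd.hpd`)

Beta HPD intervals are found by bisection on equality of the log density
at the two interval ends, with the upper end implied by the requested mass
through the quantile function; all masses go through the regularised
incomplete beta function, never through quadrature of the density, so
behaviour near the support boundaries is accurate.  Shape regimes:
uniform densities are anchored at the lower support bound (deterministic
tie-break); boundary-mode shapes (c ≤ 1 or d ≤ 1, density monotone) get
one-sided intervals with no search; U-shaped densities (c < 1 and d < 1)
raise, with an opt-in equal-tail fallback, because their highest-density
region is not an interval.  The maximal coverage of a fixed-length window
is computed by the same density-equalising bisection.  Fifty bisection
steps on a bracket inside [0, 1] locate bounds to ~1e-15, far below the
1e-7 placement / 1e-8 mass tolerances targeted; the test suite checks the
routines against two-stage grid-search oracles to 1e-5.  Scaled-t HPD
intervals are the equal-tail intervals (symmetric unimodal density).

## Mean-case evaluation (`bayes_ssd.normal_mean`)

With a flat mean prior the posterior interval depends on the data only
through ss, and the preposterior of ss has the representation
ss = 2b(1−B)/B with B ~ Beta(a, (n−1)/2).  This gives closed forms:

* ALC (fully Bayesian): E[√(b+ss/2)] = √b · B(a−½, m)/B(a, m), m=(n−1)/2,
  finite only for a > ½ — for a ≤ ½ the average preposterior length is
  infinite and the package raises rather than returning a spurious n.
* ALC (MBL): E[s] factorises through independent chi-square and gamma
  moments.
* ACC (fully Bayesian): exact for every n₀ via the marginal identity that
  the average coverage of a length-l_max interval equals the probability
  that μ minus its posterior mean — marginally a scaled t with 2a degrees
  of freedom and scale √(b/(a(n₀+n))) — falls within l_max/2 of zero.
  Rearranged, this is the closed-form sample size
  `ceil(4b t²_{2a,1−α/2}/(a l_max²) − n₀)`, which shows explicitly how an
  informative mean prior is worth n₀ observations.
* ACC (MBL) uses adaptive quadrature (`scipy.integrate.quad`) over the
  B-representation; fixed-order Gauss rules proved insufficient at the
  pass/fail boundary (a 200-node rule shifted the threshold n by one).
* WOC: the length evaluated at the worst-level quantile of ss.

**Degrees-of-freedom convention.**  The n₀ → 0 limit of the conjugate
update gives a posterior t with 2a+n degrees of freedom and a′ = a+n/2,
whereas the genuine improper-flat-prior posterior has 2a+n−1 and
a′ = a+(n−1)/2 (one degree of freedom is spent locating the mean).  The
package's `posterior_mu` and the ALC/WOC evaluators use the conjugate
limit; the ACC closed form corresponds exactly to the flat-prior
posterior, and its quadrature cross-check uses that convention so the two
agree to machine precision.  The conventions differ by under 1e-3 in
coverage (at most one sampling unit) at realistic sample sizes.

The smallest n is found by doubling from the frequentist sample size,
bisection, then a downward certification walk (the mean criteria are
monotone in n).  The minimum returned n is 1 (fully Bayesian) or 2 (MBL,
which needs a variance estimate).  Fully Bayesian ALC/WOC with an
informative mean prior (n₀ > 0) has no ss-only reduction and is evaluated
by Monte Carlo (default 10⁵ draws) with common random numbers across
candidate n — the replicate-level gamma/normal/uniform draws are fixed and
only the n-dependent transformations change — so the search is stable; the
result carries a Monte-Carlo standard error.

## Binomial evaluation (`bayes_ssd.binomial`)

All criteria are exact finite sums over z = 0..n with beta-binomial
weights computed in log space (gammaln/betaln).  HPD lengths and maximal
coverages are computed for all outcomes at once by the vectorised
bisection, and the z ↔ n−z symmetry of the analysis posterior (always
present under MBL, and under the fully Bayesian approach when c = d)
halves the work.  Because the binomial criteria are not guaranteed
monotone in n, the smallest n is found by an upward linear scan starting
from half the Wald sample size at the prior mode (prior mean for flat-ish
shapes), walking downward instead when the start already satisfies the
criterion; the returned n is therefore certified smallest over the scanned
range, and the test suite additionally brute-forces small configurations
over the whole range.

With an informative prior the conjugate posterior Beta(z+c, n−z+d) already
carries the prior's c+d−2 observations' worth of information; the returned
n is the number of *new* samples and no further subtraction of a "prior
sample size" is applied (doing both would double-count the prior).

## Elicitation (`bayes_ssd.elicitation`)

Direct routes: a = 1/cv², b = a·σ²_legacy for the precision;
c = n₀π₀+1, d = n₀(1−π₀)+1 (mode at π₀) for the proportion.  Interval
routes interpret an expert interval as the central 95% (configurable)
prior interval and solve the two-quantile matching problem by hybrid-Powell
root finding on the log hyperparameters (positivity for free), started
from a moment-matched normal approximation; convergence is accepted only
if both quantiles are reproduced to 1e-6, and the nearest-integer pair is
reported alongside the continuous solution, never silently substituted.
Variance intervals are inverted into precision intervals first.  The prior
sample size of Beta(c, d) is defined as c+d−2, consistent with the
mode-based construction (Beta(21,35) is worth 54 points, not 56).

## Simulation audit (`bayes_ssd.validate`)

The audit draws parameters from the prior, simulates data of the audited
size, and summarises the interval-length and fixed-length-coverage
distributions with Monte-Carlo standard errors.  Replicates are averaged
with equal weights — the draws come from the prior, so equal weighting *is*
the Monte-Carlo estimator of the preposterior averages; re-weighting prior
draws by the prior density would count the prior twice.  Normal samples
are simulated through their sufficient statistics (x̄ ~ N(μ, 1/(nλ)),
ss ~ χ²_{n−1}/λ), which is distributionally exact and keeps 10⁴-replicate
audits cheap; binomial audits compute the n+1 possible intervals once and
look them up per replicate.  A seed is mandatory and audits are
bit-for-bit reproducible; a single `numpy` Generator drives all draws.

## Case study (`bayes_ssd.case_study`)

Input is a CSV of per-district legacy summaries (name, legacy count, mean
and variance of ln(Zn), Zn-deficient proportion).  Defaults follow the
survey-planning setting the package was built for: precision prior with
cv(λ) = 0.25 and a flat mean prior (n₀ = 0, a conservative choice — an
informative mean prior would lower every fully Bayesian cell by n₀);
proportion prior with n₀ = round(legacy n / 1000), so priors are
informative but not narrow; l_max = 0.2 on the log scale for the mean and
0.1 for the fraction; 95% intervals; worst level 0.8.  Interval lengths on
the log scale back-transform to l·exp(μ) on the concentration scale.  The
bundled table carries the thirteen Andhra Pradesh district summaries at
the precision at which they were published (two decimals, except three
proportions published at three decimals, which are used as published);
because these inputs are rounded, regenerated table cells are compared at
±3 sampling units rather than exactly.  The runner logs per-district
progress, records per-district failures without aborting the run, and
writes CSV tables plus a JSON manifest of all parameters.

The bundled summaries are real survey descriptive statistics, not raw
records: the package never re-thresholds Zn values (the 0.9 mg/kg
deficiency cutoff is metadata), and agreement of the regenerated tables
shows that the SSD machinery reproduces the published planning results
from the same inputs — not that those inputs describe any other region or
survey design (clustered or stratified sampling, measurement error, and
spatial correlation are all outside the simple-random-sampling model).

## Problem sizes and runtime

All reproductions are desk scale: the largest searches scan a few hundred
candidate n with a few hundred outcomes each, the full thirteen-district
table pair regenerates in about two minutes on one core, and the
acceptance script (which re-runs the headline single-prior results and the
quantile elicitations) completes in seconds.  Audits default to 10⁴
replicates; the informative-mean-prior Monte Carlo path defaults to 10⁵
draws.

## Known limitations

* Gamma shape a ≤ ½ makes average-length criteria undefined (infinite
  preposterior mean length); ACC remains usable.
* U-shaped beta posteriors (only reachable with c < 1 or d < 1 analysis
  priors) have no interval-valued HPD region; the package raises unless an
  equal-tail fallback is requested.
* Criteria are single-parameter and single-stage: no multivariate or
  simultaneous intervals, no sequential/adaptive designs, no robust
  (prior-class) analysis beyond the design-prior/analysis-prior split that
  MBL already provides.
* The binomial scan certifies minimality over [start, n]; the start (half
  the Wald size at the prior mode) is a heuristic, backed by brute-force
  certification at small scale in the tests.
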
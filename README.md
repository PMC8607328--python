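# bayes-ssd

Sample size determination (SSD) for design-based soil and environmental
surveys: how many locations must be sampled so that the estimate of a
population mean (e.g. the mean of log zinc concentration in a district's
topsoil) or an areal fraction (e.g. the fraction of a district that is
zinc-deficient) reaches a required precision, stated as a maximum length
of a 95% confidence or credible interval?

The frequentist answer plugs a point guess of the design parameter
(standard deviation σ₀, or proportion π₀) into a closed formula, ignoring
how uncertain that guess is.  This package additionally implements the
**Bayesian** and **mixed Bayesian-likelihood (MBL)** approaches, which
replace the point guess by a prior distribution — a gamma prior on the
precision λ = 1/σ² (jointly normal-gamma with the mean) for normal data,
a Beta(c, d) prior for a binomial proportion — and require the precision
criterion to hold on average (or in the worst case) over the *preposterior*
distribution of the not-yet-collected data.

## Criteria

For a sample of size n with possible data sets z and posterior credible
intervals of coverage 1−α:

* **ALC** (average length): smallest n with `E_z[ l(z, n) ] ≤ l_max`,
  where l(z, n) is the length of the 1−α highest-posterior-density (HPD)
  interval;
* **ACC** (average coverage): smallest n such that the best interval of
  fixed length l_max has average posterior coverage ≥ 1−α;
* **WOC** (modified worst outcome): smallest n such that the requirement
  holds for the *worst level* fraction (e.g. 80%) of most plausible data
  sets — implemented as "the worst-level quantile of the interval-length
  distribution is ≤ l_max".

Under the **fully Bayesian** approach the same prior also feeds the
posterior; under **MBL** the prior only generates the preposterior and the
interval is computed from the data alone (a t interval for the mean, a
uniform-prior beta posterior for the proportion) — appropriate when legacy
data are trusted for planning but not for inference.

For the proportion all criteria are exact finite sums over the
beta-binomial outcome space.  For the mean (flat prior on the mean itself,
gamma prior on the precision) the package evaluates ALC/ACC/WOC in closed
form or by deterministic quadrature over the preposterior of the centred
sum of squares; the ACC sample size has a closed form,
`n = ceil( 4b/(a·l_max²) · t²_{2a,1−α/2} − n₀ )`.

Prior elicitation helpers convert legacy summaries (variance + chosen CV
of the precision; proportion + prior sample size) or expert intervals
(matched to 2.5%/97.5% quantiles by root finding) into hyperparameters,
and a seeded simulation audit checks any returned n empirically.

## Worked example

```python
from bayes_ssd import (BetaPrior, NormalGammaPrior, PrecisionSpec,
                       gamma_from_variance_interval, n_mean_criterion,
                       n_prop_criterion)

# Areal fraction, no prior knowledge: uniform Beta(1,1) prior,
# 95% credible intervals of average length at most 0.1
spec = PrecisionSpec(lmax=0.1, alpha=0.05, criterion="alc", approach="fully_bayesian")
print(n_prop_criterion(BetaPrior(1, 1), spec))
# n = 234 [ALC, fully_bayesian], achieved = 0.099843

# Mean of ln(Zn): an expert believes the population variance is between
# 0.60 and 0.90; read as a central 95% interval for the precision
fit = gamma_from_variance_interval(0.60, 0.90)
print(fit.rounded)            # (94, 68)
prior = NormalGammaPrior(mu0=0.0, n0=0.0, a=94, b=68)
spec = PrecisionSpec(lmax=0.2, alpha=0.05, criterion="alc", approach="fully_bayesian")
print(n_mean_criterion(prior, spec))
# n = 281 [ALC, fully_bayesian], achieved = 0.19967
```

`achieved` is the criterion value at the returned n — here the average
95% HPD length, just below the requested maximum; at n−1 it exceeds it.

The same functionality is exposed on the command line
(`bayes-ssd mean|prop|elicit|audit|case-study`).  The case-study runner
reads a CSV of per-district legacy summaries (a packaged copy of the
thirteen Andhra Pradesh districts from cycle 1 of India's Soil Health Card
survey is included), derives per-district priors, and writes the full
frequentist / Bayesian / MBL sample-size tables for the mean of ln(Zn) and
the Zn-deficiency areal fraction:

```
bayes-ssd case-study --input src/bayes_ssd/data/district_legacy_summaries.csv --out results/
```

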
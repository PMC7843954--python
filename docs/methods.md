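# Methods

## The models

### Multivariate group-based trajectory model

Individuals i = 1…N belong to one of K latent groups with prior shares π.
Conditional on group g, the three cJADAS-10 components at visit time t
(years since first presentation to paediatric rheumatology) are independent
across outcomes and visits:

* **Active joint count** (capped at 10 before modelling):
  y ~ ZIP(λ_g(t), ρ_g) with log λ_g(t) = η_g(t) a polynomial in t of order
  1–3 and ρ_g an intercept-only structural-zero probability.  The capped
  value is treated as an ordinary ZIP observation; a right-censored-count
  likelihood at 10 would be the alternative treatment (not implemented —
  the cap affects few visits in realistic regimes and keeps the count on
  the cJADAS-10 scale).
* **Physician's and patient/parent global scores** (0–10 cm VAS):
  censored normal (Tobit) — a latent normal with polynomial mean η_g(t)
  observed only inside [0, 10]; values recorded exactly at a bound carry
  the censored *mass* (Φ terms), not a density, so 0 cm and 10 cm scores
  get positive probability.  The residual SD is shared across groups within
  each outcome (the standard identifying assumption for this model family;
  class-specific SDs are prone to variance collapse).

The individual log-likelihood is log Σ_g π_g exp(Σ_{t,j observed}
log f_jg(y_jt)); missing components/visits are omitted, which is the
maximum-likelihood treatment under missing-at-random and matches the
no-imputation stance of registry practice.

**Estimation.**  EM.  The E-step is exact Bayes' rule in log space
(log-sum-exp throughout).  The M-step updates π in closed form and the
ZIP / Tobit parameters by warm-started L-BFGS on the posterior-weighted
log-likelihoods with analytic gradients; a guard keeps the old parameters
whenever the optimiser fails to improve, so every iteration is a
generalised M-step and the observed-data log-likelihood is monotone
(asserted to 1e-8 relative in the tests).  Convergence: relative
log-likelihood change < 1e-7 (default) or 500 iterations.

**Initialisation.**  k-means on per-individual outcome means (missing
summaries filled with column means, standardised), soft one-hot posteriors
(0.95/0.05), one M-step, then EM; starts beyond the first jitter the
summary matrix with N(0, 0.5) noise.  Default 20 starts
(`fit_gbtm(n_starts=...)`); well-separated problems need far fewer, and the
acceptance checks use 1–3.  A start whose smallest group drops below one
posterior individual-equivalent is restarted with a fresh k-means seed (up
to 3 attempts).

**Label canonicalisation.**  Fitted groups are reported in ascending order
of model-implied baseline cJADAS-10 (ZIP mean capped at 10 plus the two
censored-normal means at t = 0).  When two groups have nearly tied baseline
severity (the default generator's low-remission and low-low groups do),
recovery comparisons additionally align fitted to generating groups by
maximal-overlap (Hungarian) matching of the confusion matrix.

**Model count.**  Free parameters: (K−1) + 3K(order+1) + K + 2.
BIC uses N = number of individuals, not observations (configurable in
principle; repeated measures per individual are not independent, and the
group is a per-individual quantity).

### Latent profile analysis at baseline

A K-class mixture of Poisson (capped AJC) × normal (PGA) × normal (PGE)
at the baseline visit only, with class-shared normal SDs (class-specific
available via `shared_sigma=False`).  M-steps are closed-form weighted
means/variances, so EM ascent is exact.  Classes are ordered by ascending
λ_g + μ_PGA,g + μ_PGE,g.  `lpa_scan` fits K = 1…10 and selects the lowest
BIC among converged fits.  Baseline clustering never reads follow-up
visits; no classes are inherited in either direction.

### Adequacy filters and selection

A fitted trajectory model is excluded if (reasons are machine-readable):

| rule | threshold | computed from |
|---|---|---|
| `min_group_share` | < 1% of cohort | modal (hard) assignments |
| `low_app` | any group APP < 0.70 | mean assigned-group posterior per group |
| `low_entropy` | relative entropy < 0.5 | 1 − Σ −p log p / (N ln K); 1 for K=1 |

Group share uses hard assignments because the criterion describes members
of the cohort; APP is read per-group (the standard diagnostic; the overall
mean is strictly weaker).  Survivors are ranked by BIC overall and within
each polynomial order; candidates within 10 BIC units (configurable) of
the best are reported as ties for human clinical-plausibility review —
the final choice is never automated.

### Noise-sensitivity protocol

Each observed outcome cell is independently replaced with probability f
(f ∈ {1, 2.5, 5, 10, 25}%) by a draw from ZIP(λ=2, ρ=0.4) (counts, capped
at 10) or a censored normal with bounds (0, 10) (VAS; default latent
μ=5 cm, σ=3 cm — wide, near-uniform after censoring; the noise mean/SD are
package choices exposed in `NoiseConfig`).  Replacement ("replace" mode,
the default) keeps N fixed and stresses the likelihood directly; an
"append" mode adds pure-noise individuals instead.  For a fixed seed the
replaced-cell sets are *nested* across fractions (one uniform threshold
and one replacement value per cell), a common-random-numbers coupling that
leaves every single-fraction marginal unchanged but sharpens the
ARI-versus-fraction comparison.  Stability of a refit is measured by the
adjusted Rand index against the clean fit on the original individuals,
plus a reference×noisy contingency table; a reference group "survives" if
some noisy group captures ≥ 50% of its members (configurable).  Noisy
refits can warm-start from the clean fit's parameters (one extra EM
start), which both speeds the scan and removes start-to-start jitter from
the comparison.

## The synthetic cohort generator

`paper_default_config()` emulates the structure of the motivating UK
inception cohort: N = 1184, visits at 0, 0.5, 1, 2, 3 years, per-visit
availability 0.96/0.77/0.94/0.87/0.80 (independent Bernoulli per visit —
missing at random by construction), six groups with shares
0.32/0.20/0.16/0.10/0.14/0.08, and group-conditional covariates (age,
gender, ILAR category, deprivation quintile) borrowing published per-group
baseline compositions as plausible settings.

The six groups' trajectory *coefficients are synthetic*: the source
cohort's fitted curves are not published as numbers, so the defaults were
chosen once to satisfy the qualitative definitions of the named groups —
low-remission, low-low, high-low, high-low-high (a cubic re-flare),
low-persistent and high-persistent, where "persistent" means the
patient/parent global score stays ≥ 4 cm while joint counts and physician
scores decline.  Residual SDs are 1.0 cm (PGA) and 1.1 cm (PGE), shared
across groups so the generating process matches the fitter's observation
model; VAS values are clamped at 0 and 10 (true censoring).  An individual
whose every visit is drawn unavailable (rare) keeps the baseline visit so
the one-visit-minimum invariant holds.

What passing tests on these cohorts show: that the estimator recovers the
kind of structure the method assumes — polynomial group trajectories, ZIP
counts, censored normals, MAR missingness.  What they cannot show: recovery
under model misspecification (non-polynomial trajectories, informative
drop-out, treatment effects, within-individual serial correlation), none of
which the generator simulates.  The published cohort-specific findings
(which named group dissolves at which noise level, the five baseline
classes, Table-level contrasts) require the real data and are not
reproduction targets.

## Numerical choices

* All density kernels return log values; mixtures use log-sum-exp and
  `log_ndtr`, so posteriors are stable down to extreme separations.
* Log-rate η clipped at ±30; zero-inflation logit bounded at ±8; log σ
  bounded in [log 0.01, log 50] — optimiser guards, far outside any
  plausible fitted value.
* Ties in modal assignment break to the lowest group index; quantiles use
  linear interpolation; χ²→Fisher switch: 2×2 tables with any expected
  count < 5 *or* any empty observed cell; larger sparse tables keep χ²
  flagged `chi2_low_expected` (no exact r×c test is attempted).
* Visit times within ±0.125 y of the canonical schedule are snapped to it
  on read (registry follow-up is approximately annual); farther times are
  kept as-is — the likelihood accepts arbitrary per-individual visit sets.
* Degenerate inputs: p₀ = 1 with y > 0 → −∞ log-likelihood; K = 1 relative
  entropy defined as 1; empty groups yield NaN APP and are flagged; a
  contingency table left with one row/column after margin-dropping returns
  the degenerate (0, 1) test.

## Problem sizes used in the checks

Unit and property tests run on cohorts of 60–500 individuals.  The
deeper checks use: six-group recovery at N = 1184 (seeds 1–5, 3 EM
starts), MAR-robustness at N = 800 (complete vs masked, same seed), the
BIC group-count grid at N = 1000 (orders 1–3, K = 1–6, 10 seeds, 1
start), and the noise protocol at N = 400 (5 fractions × 5 seeds,
warm-started refits).  `scripts/acceptance.py` re-runs the same pipeline
at N = 600/500/300 so a complete from-scratch reproduction takes a few
minutes on one CPU.

## Known limitations

* Zero-inflation is intercept-only per group; time-varying inflation is
  not supported.
* No covariate-dependent group membership (groups are characterised post
  hoc), no standard errors or confidence bands for trajectory
  coefficients, and no MNAR (informative drop-out) simulation or
  correction.
* The AJC cap is treated as observation, not censoring (see above).
* BIC's sample-size convention (individuals) and the shared-σ assumption
  are defensible defaults, not universal truths; both are documented where
  they enter.
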
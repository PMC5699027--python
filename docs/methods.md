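# Methods

## Model

Each data source (CDR-derived commune features; environmental commune
features) gets its own regression

    y_i = beta^T x_i + f(x_i, s_i) + eps_i,    eps_i ~ N(0, sigma_n^2),

with a zero-mean GP prior on f under the product of two squared-exponential
factors: one over the (standardized) feature vector with a single shared
length-scale `ell`, one over the commune-centroid coordinates in planar km
with length-scale `ell_s`.  The spatial factor is ordinary Kriging; the
feature factor lets the model pick up smooth nonlinear source-feature
effects.  The two fitted posteriors are combined per commune as a
two-component Gaussian mixture with inverse-variance weights; the package
reports the exact mixture mean and variance (including the
between-source-disagreement term) rather than a Gaussian approximation.

Assumptions worth keeping in mind:

* **Isotropy in feature space.** One `ell` is shared by all feature
  dimensions, which is only meaningful because features are standardized to
  zero mean and unit variance before entering either the linear term or the
  kernel.  Per-dimension length-scales are deliberately out of scope.
* **Planar geometry.** All coordinates are planar km.  Real geographic data
  must be projected (an equirectangular projection suffices at country
  scale) before entry; the synthetic generators work directly in km.
* **Posterior conditioning uses the centred residual.** The predictive mean
  is beta^T x* + k^T (K + sigma_n^2 I)^{-1} (y − X beta): conditioning a
  zero-mean GP must subtract the linear mean from the targets.  A variant
  that conditions on raw y instead of the residual is inconsistent with the
  stated prior and is not implemented.
* **Predictive variance ignores the targets.** var[y*] depends on inputs
  and hyperparameters only; this is what makes the inverse-variance fusion
  weights a statement about data support, not about observed agreement.

## Estimation

The penalised marginal log likelihood

    J = log p(y|X) − (alpha*lam*||beta||_2^2 + (1−alpha)*lam*||beta||_1)

is maximised jointly over (beta, ell, ell_s, sigma_f^2, sigma_n^2).
Numerical choices:

* Positive hyperparameters are optimised in log space with bounds
  (ell in [1e-2, 1e4], ell_s in [0.1, 1e5] km, variances in [1e-8, 1e4]).
* The L1 term is smoothed as sqrt(beta^2 + eps^2) with eps = 1e-8 so a
  quasi-Newton (L-BFGS) optimiser with analytic gradients applies; the
  reported objective uses the exact |beta|.
* Cholesky factorisation throughout, never an explicit inverse; a jitter
  schedule 0 → 1e-8 → … → 1e-4 is added to the covariance diagonal on
  factorisation failure, and a conditioning error naming the offending
  variances is raised beyond that.
* Three seeded restarts by default: a data-driven start (ridge solution for
  beta; ell = sqrt(d); ell_s = a quarter of the spatial span; variances
  split the target variance) plus perturbed copies.  The returned iterate
  never scores below the best initialisation; non-convergence returns the
  best iterate with a warning, never silently.
* Penalty defaults alpha = 0.5, lam = 0.1.  An inner 5-fold CV over a
  5-point log grid (`FitConfig(select_lam=True)`) is available when the
  penalty matters; it is off by default because it multiplies the fit cost
  by ~25 and the cross-validation harness refits hundreds of models.

Feature importance is read off |beta| on the standardized scale,
descending; coefficients below 1e-3 are flagged as pruned.  In parameter-
recovery experiments the *support* of beta is taken as |beta| > 0.1 — a
tenth of the smallest effect size a practitioner would call substantively
meaningful on standardized features.

## Alkire–Foster statistics

Ten binary indicators in three dimensions; education and health indicators
weigh 1/6, standard-of-living indicators 1/18 (each dimension exactly 1/3;
weights are stored as exact rationals and validated to sum to 1).  The
household score is computed over an integer common denominator so that a
household at exactly c = 1/2 or 1/3 compares against the cutoff exactly —
float accumulation must not flip the strict c > theta rule.  A household at
exactly c = theta is **not** poor.  Default theta = 0.3; `theta_sweep`
covers 0.2–0.75 in 0.05 steps.

Missing indicators: a household's score is renormalised over observed
weights when at least 2/3 of total weight is observed, else the household
is dropped (the usual MPI practice).  Per-indicator deprivation proportions
divide by households observed on that indicator.  Households are equally
weighted; a sampling-weight column is not implemented.

## CDR aggregation

* Home antenna: most nocturnal events per month, nocturnal = [19:00,
  07:00) half-open; the yearly home is the modal monthly home; all ties
  break to the smallest antenna id (deterministic and order-independent).
* Retention: a month qualifies with >= 5 interactions and a defined
  monthly home; a subscriber is retained with >= 6 qualifying months
  ("active at least half the year").  Features are pooled at the yearly
  home; monthly homes are retained for diagnostics.
* Thirteen behavioural features per subscriber-month (activity, regularity,
  diversity, spatial).  Entropies are in nats.  Undefined statistics
  (interevent times of single-event months, call/text ratio with zero
  texts) are missing values and are excluded from antenna means, never
  imputed as zero.
* Antenna-to-commune interpolation: overlap weights w_{c,a} =
  Area(c ∩ a)/Area(a) of antenna Voronoi cells clipped to the map extent,
  renormalised per feature over the antennas that carry data.  When
  communes tile the extent the weights sum to one per antenna
  (partition-of-unity, verified to 1e-6).

## Spatial cross-validation

Each repeat samples a region uniformly, then a commune within it; the
training set is every commune whose centroid lies within d km of that seed
commune, d grown from 100 km in 50 km steps until the training set reaches
the floor — 225 communes on a 552-commune map (the protocol's stated
absolute floor), otherwise ceil(0.40 n).  The evaluation set is the
complement, so train and evaluation are geographically separated.  A seed
whose ball swallows the whole map is resampled (capped, then an error).
Hyperparameters are refitted inside every training split — anything else
leaks information across the spatial boundary.  Metrics are pooled over
each repeat's evaluation set and summarised as mean (SD) over repeats.
A deeply central commune can fall inside every training ball; the harness
warns when any commune is never evaluated.

Default repeats: 250 for splitter-level runs (cheap).  Model-level CV runs
in the test suite use 25 repeats with 2 restarts per fit; the experiments
are sized (300–350 communes, 8 features per source) so a full run fits
comfortably on a laptop core in minutes.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical shape* the model assumes, at the
study's administrative scale (552 communes, 121 urban, 14 regions, ~700 km
extent), from a single integer seed:

* Commune maps are Voronoi tessellations of uniform seed points clipped to
  the square extent (polygons tile the extent exactly); regions are
  k-means clusters of the seeds (spatially contiguous); the n_urban
  smallest cells are flagged urban, a proxy for dense urban centres.
* Antennas: one per commune centroid plus two extra in urban communes,
  mirroring sparse rural antenna density.
* Single-source fields are drawn from the model itself (features iid
  standard normal, f from the product kernel, Gaussian noise), with the
  components returned so tests can verify y = X beta + f + eps exactly.
  Defaults: 8 features per source with sparse beta (four nonzero entries
  of magnitude 0.5–1.2), sigma_f^2 = 0.5, ell = 2.5, ell_s = 50 km,
  sigma_n^2 = 0.1 — signal-to-noise around 30, moderate spatial smoothness.
* The two-source benchmark assigns each source half of the linear signal
  plus one shared spatially smooth component, so each single-source model
  is honestly misspecified and fusion has something to gain.  There is no
  published generative recipe for the environmental source; this
  linear-plus-spatial link is the package's own modelling choice.
* Event logs: Poisson monthly activity (default mean 30), nocturnal share
  0.35, nocturnal events at the true home antenna with probability 0.95,
  daytime wandering to the 5 nearest antennas; subscriber counts per
  commune follow a smooth spatial intensity (population density proxy).
* Household tables: independent Bernoulli indicators at per-commune target
  probabilities (optionally a shared per-household uniform frailty that
  preserves marginals while correlating indicators within a household;
  off by default).

Passing tests on these fixtures demonstrate the estimator's internal
correctness and its behaviour under the model's own assumptions.  They do
**not** demonstrate performance on real CDRs or censuses: real features are
not Gaussian, real deprivation fields are not stationary, antenna density
correlates with wealth, and phone ownership introduces selection bias none
of which the generator reproduces.

## Known limitations

* Exact GP only (N in the hundreds); no inducing-point approximations.
* Two-source fusion; more sources would be a straightforward extension of
  the mixture but is not implemented.
* The CDR feature set is a 13-feature representative subset of the
  behavioural-indicator families in the literature, not a full toolbox
  parity; conversation threading (response delays) is not reconstructed.
* Raw-achievement-to-deprivation coding is a configurable cutoff hook, not
  a reconstruction of any census questionnaire.
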
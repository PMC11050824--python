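# Methods

## Model

`lsirm` fits a latent space item response model to a binary person-by-item
response matrix Y (P persons, I items, missing cells allowed).  The
response probability combines Rasch main effects with a distance effect in
a shared K-dimensional latent metric space:

    logit P(Y_pi = 1) = theta_p + b_i - lambda * d(xi_p, zeta_i),

where theta_p is the ability of person p, b_i the easiness intercept of
item i (difficulty is -b_i), xi_p and zeta_i are positions in R^K, d is
the Euclidean distance, and lambda >= 0 weights the distance effect.
Under conditional independence (the Rasch assumption) lambda = 0 and the
positions are irrelevant; person-item interactions that the main effects
cannot express — varying perceived difficulty, unmodeled dimensions,
subgroup effects — appear as distance structure instead.

Priors:

| parameter | prior | default |
|---|---|---|
| theta_p | N(0, sigma^2) | — |
| sigma^2 | half-Cauchy(25) on the variance | `cauchy_on_sigma` switches to sigma |
| b_i | N(0, 5^2) | sigma_b = 5 |
| xi_p, zeta_i | standard normal per coordinate | identifies the position scale |
| log lambda | (1-w) N(-5, 1) + w N(0.5, 1) | w = 0.5 |

The two-component prior on log lambda is a spike-and-slab: the spike
concentrates lambda near zero (lognormal mean 0.011, SD 0.015), the slab
is diffuse enough to estimate a real distance effect without much bias
(mean 2.718, mode 0.607, SD 3.563).  The binary component indicator delta
is marginalized; its posterior P(delta = 1 | Y) — the evidence for
conditional dependence — is recovered as the posterior mean of the
mixture responsibility of the log-lambda draws.  Values near 1 say the
latent space is needed; near 0, that the Rasch model suffices.

K defaults to 2 for interpretable maps.  The default w = 0.5 encodes no
prior preference between the components.

## Sampling

The posterior is sampled by a blocked adaptive random-walk Metropolis
scheme (3 chains of 1500 iterations, 500 burn-in, by default).  The
likelihood factorizes over rows given items and vice versa, so the theta,
b, xi and zeta blocks propose and accept all rows (or columns) in
parallel; sigma^2 and log lambda are scalar blocks (sigma^2 on the log
scale with the Jacobian).  Proposal scales adapt per coordinate during
burn-in toward an acceptance rate of 0.35 and are frozen afterwards.

The posterior has several nearly flat directions that plain
coordinate-wise updates traverse slowly, and the sampler adds a dedicated
move for each:

- **rescale**: positions times s, lambda over s — exactly
  likelihood-invariant, mixes the scale-versus-lambda ridge;
- **breathing**: positions times s with the intercepts absorbing
  lambda * mean-distance * (s - 1);
- **translation**: a common shift of all positions (likelihood-invariant);
- **lambda-b ridge**: a log-lambda step with b shifted by
  (lambda' - lambda) * (per-item mean distance);
- **compensated position rows/columns**: when xi_p (zeta_i) moves, theta_p
  (b_i) absorbs the lambda * mean-distance change, so geometry and main
  effects do not fight each other.

Because the spike-and-slab posterior can be bimodal in log lambda, the
log-lambda block occasionally proposes a translation by the full
spike-to-slab gap (5.5), carrying the intercepts along.  These jumps are
enabled only after burn-in: a half-organized chain that falls into the
spike early loses its configuration and cannot return.

Initial values: theta and b from standardized logit margins; positions
from a truncated-SVD embedding of the standardized response residuals
with singular values shrunk at the pure-noise floor sqrt(P) + sqrt(I)
(so exchangeable data starts at the origin and real structure starts
organized), jittered per chain; log lambda at the mixture midpoint -2.25.
Chains draw independent generators from sub-seeds of the master seed, so
runs are exactly reproducible.

Convergence is summarized by split R-hat for every scalar parameter
(cutoff 1.1).  Positions are excluded from R-hat: before alignment their
coordinates are identified only up to a rigid transform.  Correctness of
the kernel is checked against a dense grid quadrature on a tiny instance
with one free ability (Kolmogorov-Smirnov distance below 0.05 at 4000
thinned draws).

## Alignment

The distance effect is invariant to any common translation, rotation or
reflection of all positions.  Draws are therefore post-processed by
Procrustes matching: the retained draw with the highest joint
log-posterior (likelihood plus prior over all parameters) is the
reference; every draw's stacked (P+I) x K configuration — persons and
items jointly, so person-item distances are preserved — is matched to it
by the SVD-based orthogonal transform plus translation, with no scaling
(scaling would change distances; the standard-normal position prior fixes
the scale).  Point estimates of positions are elementwise means of the
aligned draws.  Ties in the reference selection resolve to the earliest
(chain, iteration); a degenerate all-identical-rows configuration is
matched by translation only.

## Analytics

All applied outputs are functions of the aligned point estimates:

- person-item distance matrix and its row means (person-wise mean
  distance), with optional covariate overlays (group summaries for
  categorical covariates, correlations for continuous ones);
- the I x I item distance matrix, with optional average-linkage
  agglomerative grouping when no item cluster labels are supplied
  (the cluster count is the user's choice — the method itself does not
  select one);
- cluster centers (arithmetic mean of member item positions), pairwise
  center distances and per-cluster means over the other clusters;
- person-to-cluster distances, either as the mean distance to member
  items (the definition used for reporting) or as the distance to the
  center; the per-item mean always dominates the centroid distance by
  convexity, and for singleton clusters the two agree.  The farthest
  cluster per person is the row argmax, ties to the lowest cluster index;
- perceived difficulty: per-person item effects b_i - lambda * d and the
  per-item mean b_i - lambda * mean_p d, whose spread across persons
  quantifies between-person variation in difficulty (with lambda = 0 every
  interval collapses to b_i);
- personalized feedback: items and clusters ranked by distance, farthest
  first, together with the ability estimate and observed accuracy.

lambda-hat is the unconditional posterior mean of lambda on the natural
scale (the summary most comparable across fits; conditioning on the slab
changes it little whenever P(delta=1|Y) is decisive).

## Synthetic data

Three seeded regimes drive the test suite and the acceptance script; no
external data are required.

- `lsirm`: forward simulation of the model.  Defaults: sigma_theta = 1,
  b ~ N(0,1), xi ~ N(0, I_2), item positions in 3 blobs (SD 0.3) with
  centers on a circle of radius 2, gamma = 2.  Intercepts are offset by
  gamma * mean(d) (`center_intercepts`); without this the linear predictor
  has mean near -4.5, nearly all responses fail, and the data carry so
  little information that even an oracle given the true positions cannot
  recover abilities (theta correlation caps at about 0.71 versus 0.89
  with the offset).  Real assessments sit in the calibrated regime: the
  distance effect modulates accuracy rather than destroying it.
- `rasch`: main effects only (gamma = 0).
- `multifactor`: simple-structure data where each item loads (loading
  1.5) on one of 7 correlated person factors (correlation 0.5, 8 items
  per factor).  A unidimensional fit to such data is deliberately
  misspecified; the unmodeled factors surface as item clusters in the
  latent space, which is the phenomenon the cluster analytics detect.

Recovery is scored only on rigid-transform-invariant quantities
(person-item distances), never raw coordinates.

## Problem sizes and operating characteristics

Desk-scale sizes used throughout: operating characteristics of the
spike-and-slab (10 datasets per regime in the tests, 5 in the acceptance
script) at P = 200, I = 20; parameter recovery at P = 300, I = 30,
gamma = 2; cluster emergence at P = 800, I = 56 (7 x 8).  At these sizes
the median P(delta=1|Y) is below 0.1 on Rasch data and effectively 1 on
gamma = 2 data, the ability correlation exceeds 0.8, the true-versus-
estimated distance-matrix correlation exceeds 0.8, and average-linkage
grouping of the fitted item distances recovers the generating 7-factor
partition with adjusted Rand index above 0.7.  Cluster emergence degrades
at smaller samples (ARI about 0.65 at P = 500): item positions need
enough persons to stabilize.

## Numerical choices

- Bernoulli log-likelihoods via y*eta - log1p(exp(eta)) (logaddexp), never
  log(sigmoid); the mixture prior via log-sum-exp.
- Unobserved cells contribute exactly zero to the likelihood.
- All-0/all-1 rows or columns trigger a warning, not an error; such
  persons/items are retained (the priors keep their parameters finite).
- Reported distances are plain Euclidean; the displayed per-item
  "mean" column is the mean over the other C-1 clusters.

## Limitations

- At short test lengths the split of a person's margin between theta and
  -lambda * (mean distance) is only softly identified, so ability
  estimates and fitted mean distances are moderately anti-correlated
  (about -0.4 at P = 300, I = 30) even when true positions are drawn
  independently of ability.  The association shrinks with more items;
  person-level distance feedback is best interpreted jointly with the
  ability estimate, not as an independent signal.
- Random-walk sampling is adequate at desk scale but slower than
  gradient-based samplers for very large P; the draws-level API is
  sampler-agnostic should one be swapped in.
- The synthetic generators use clean logistic responses; real data
  features such as guessing, speededness, or nonuniform missingness are
  out of scope, so passing recovery tests here does not certify behavior
  under those violations.
- The spike-and-slab decision is about the need for *any* distance
  effect; it does not validate a particular cluster count or map
  interpretation.
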
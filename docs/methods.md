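# Methods

## Independent events and trap rates

Raw camera-trap records are image sequences; a single animal can trigger a
camera many times in minutes.  Within each (station, species) stream, a new
*event* begins when the gap from the most recent image of the ongoing
sequence is at least the independence interval (default 60 minutes, the
common convention for medium-to-large mammals).  Two choices deserve
emphasis because they change counts:

- the gap is measured from the **last image** of the ongoing sequence, not
  its first, so a slow trickle of images 30–40 minutes apart remains one
  event however long it lasts;
- a gap of **exactly** the interval opens a new event (≥, not >), and no
  reset is applied at midnight or at camera service visits.

Event counts are therefore monotonically non-increasing in the interval, a
property the test suite checks against a brute-force single-pass oracle.

The relative abundance index is RAI = 100 × events / trap-days, computed
per station and globally.  RAI counts events, not individuals; the number
of individuals per image is carried through but only used descriptively.
A day counts as a trap-day when the operation log covers any part of it,
and operation-log intervals are inclusive on both ends.  Timestamps are
naive local time: the surveys this mirrors are single-region, so no
timezone arithmetic is warranted.

## Community metrics

Incidence (species × station presence) feeds richness and similarity;
global RAI values act as the abundance weights for diversity.

- First-order Jackknife richness: S&#770; = S_obs + f₁ (n−1)/n, with f₁ the
  number of species seen at exactly one of n stations.  It equals the
  leave-one-station-out resampling estimator, which the tests use as an
  independent oracle.
- Sample-based rarefaction is computed analytically from the
  hypergeometric expectation E[S_h] = Σ_j (1 − C(n−n_j, h)/C(n, h)), with
  log-gamma arithmetic for stability; a seeded Monte-Carlo resampling mode
  exists purely as a cross-check.  The curve is nondecreasing and concave
  and ends at S_obs.
- Shannon–Wiener H′ (nats) and Simpson diversity are computed on RAI
  proportions.  Simpson is reported in the Gini–Simpson form 1 − Σpᵢ²,
  which lies in [0, 1 − 1/S] and matches the magnitudes (≈ 0.9 for ~25
  fairly even species) reported for communities of this kind; the inverse
  form 1/Σpᵢ² is available via an option.
- Jaccard and Sørensen similarity are incidence-based; the Sørensen
  ecological distance is 1 − CC.  J ≤ CC algebraically, which is
  property-tested.

Livestock and other domestic species can be excluded from all community
metrics with the configuration blocklist, since fenced or guarded stock is
not comparably detectable across land uses.

## Detection histories

The daily history scores 1 when a species had at least one event at a
station that calendar day, 0 when the camera was operational without an
event, and missing when it was not operational — so at most one detection
per 24 h enters the analysis.  Days are merged into k-day occasions
(k = 5–11 by default) anchored at the survey start date; the final partial
block is kept as a shorter occasion rather than discarded, because
discarding it would silently shrink effort.  An occasion is 1 if any
constituent day is 1, 0 if at least one day was operational, and missing
only when the camera was down for the whole block.  Stations operational
for fewer than 80% of the *collapsed* occasions are removed before
fitting.  Collapsing never loses a detection, and the naive occupancy
(detected sites / sampled sites) is invariant to k.

## The occupancy model

The single-season model assumes each site i is used with probability ψ_i
during the season (closure), and that, given use, detections on surveyed
occasions are independent Bernoulli(p_i) draws.  Both parameters take
logit links on site-level covariates; continuous covariates are z-scored
and categorical ones dummy-coded against a reference level, so
coefficients are comparable across covariates.  Missing occasions simply
drop out of the detection product (missingness is assumed independent of
the species' presence — camera failures are mechanical).  Because camera
stations are rarely far enough apart for independence at predator home
ranges, ψ is interpreted as *space-use* rather than true occupancy.

Fitting is maximum likelihood with analytic gradients: L-BFGS-B from the
zero vector plus four seeded Gaussian jitters (sd 0.75), objective
tolerance 1e−8, keeping the best optimum.  Standard errors come from the
inverse of a central-difference Hessian (relative step 1e−4).  The
convergence flag is honest — non-convergent candidates are excluded from
ranking — and a separate boundary flag marks fits whose linear predictor
exceeds ±8 (probabilities within ~3e−4 of 0/1), where Wald standard errors
are meaningless.  Intercept-only fits are verified against a dense
(ψ, p) grid-search oracle, and the likelihood is verified to normalise by
exact enumeration of all 2^T histories for small T.

## Goodness of fit and occasion length

Fit is assessed with the MacKenzie–Bailey parametric bootstrap.  Sites
sharing a missingness pattern form a cohort; within a cohort each observed
distinct detection history is a Pearson cell with expected count
Σ_i ψ_i p_i^s (1−p_i)^{T−s} (plus the unoccupied mass for the all-zero
history), and the combined probability of all unobserved histories forms a
zero-count remainder cell, whose contribution reduces to its expected
count.  Replicate datasets are simulated from the fitted model on the
observed missingness template, refit (refit failures are dropped and
counted), and the statistic recomputed.  The p-value is the proportion of
replicate statistics at least as large as the observed one; the
overdispersion statistic is ĉ = χ²_obs / mean(χ²_boot).  The default is
1000 replicates (100 in fast/test settings).  On data simulated from the
fitted model itself, ĉ concentrates near 1 — the suite requires it to land
in [0.7, 1.4] in at least 90% of such fits.

The occasion length is chosen by refitting the global (all-covariate)
model at each k in 5–11 and keeping the k whose ĉ is closest to 1 among
those with 0.90 ≤ ĉ ≤ 3 and p > 0.05; exact ties go to the smaller k.  If
no k qualifies the species is flagged and excluded — a reported outcome,
not an error, since some species genuinely cannot be fit at any grain.

## Model selection

Continuous covariates are z-scored and screened for collinearity with
variance inflation factors (OLS of each design column on the rest,
VIF = 1/(1−R²)); the largest-VIF column above 3 is removed iteratively,
with perfectly collinear pairs resolved by dropping the later column in
input order.

Candidate models are additive subsets capped at 4 terms — the full
combinatorial space is unmanageable, and the cap is the reproducible
surrogate for a stepwise restriction.  Selection is two-stage: all
detection structures are fit with constant ψ, the QAICc-best p-structure
is fixed, then all ψ structures are fit on top of it.  QAICc scales the
log-likelihood by the global-model ĉ:

    QAICc = −2 logL / ĉ + 2K + 2K(K+1)/(n − K − 1)

with n the number of sites (the standard choice for occupancy data) and K
counting one extra parameter whenever ĉ > 1 is estimated.  ĉ is floored at
1 for QAICc — underdispersion is not allowed to inflate support — while
the raw value still drives the occasion-length rule.  QAICc ties break by
smaller K, then input order.  Models with ΔQAICc < 2 and Akaike weight
w > 0.10 form the retained set.

Covariate evidence is tiered from the 95% Wald CI: *strong* when the CI
excludes 0; *medium* when it overlaps 0 but the estimate is more than one
standard error from 0 (the operationalisation of "not centred on 0" — no
standard formula exists, so this is configurable); *weak* otherwise.  The
reported per-covariate weight is the summed w of retained models
containing the term, and directions are on the z-score scale (sign is
scale-invariant).

## The synthetic generator

The generator emulates the design of a two-region mammal survey: a
"protected" region of 73 stations over 151 days with ~1 mid-survey station
failure, and a "farmland" region of 64 stations over 132 days with ~3
failures.  Stations carry mixed covariates (altitude, vegetation type and
age, water source and distances, road and habitation distances,
disturbance/livestock/hunting flags); species occupancy and daily
detection follow logit-linear models on the internally standardised
covariates, so generating slopes live on the same scale as fitted ones.
Detection days receive one image plus a Poisson number of extras placed
uniformly in a two-hour burst, guaranteeing that both sub-hour and
super-hour gaps exercise the 60-minute rule.  Background species draw
moderate intercepts (daily detection roughly 0.02–0.27, occupancy roughly
0.4–0.8); everything is reproducible from the spec seed, with per-species
streams keyed by a process-independent hash.

For paired-community fixtures the species pools overlap exactly as
requested (e.g. 22 shared, 5 and 3 unique), and each pool member is
guaranteed at least one record so incidence-based metrics see the intended
pool; shared species keep identical traits across regions.

What the generator does **not** emulate: spatial autocorrelation between
stations, animal movement or home ranges, within-season trends or
temporary emigration (closure holds by construction), imperfect species
identification, and occasion-varying detection covariates.  Passing tests
therefore validate the estimators under the model's own assumptions — they
say nothing about robustness to closure violations or spatial dependence
in real surveys.

## Problem sizes and tolerances

The validation suite uses scales chosen to make Monte-Carlo noise small
relative to the assertions: slope recovery at 200 sites × 10 occasions
over 50 replicates (mean bias < 0.15 on a true z-score slope of 1.0);
goodness-of-fit self-consistency over 20 generate–refit trials with 100
bootstrap replicates each; two-stage selection consistency over 25
replicates at |slope| = 1.5; rarefaction against a 10,000-permutation
oracle (agreement within 0.1 species); grid-search oracles at 0.001
resolution (agreement to 3 decimals).  The acceptance script runs the full
two-region pipeline at study scale (73/64 stations, 151/132 days, 30
species) with 1000 bootstrap replicates.

## Known limitations

- Detection covariates are site-level only; occasion-level covariates
  (weather, season) are not supported.
- p is constant across occasions within a site, so the per-site likelihood
  depends only on the detection count — heterogeneous-p models (behavioural
  response, finite mixtures) are out of scope.
- No model averaging of coefficients; reports give directions, tiers and
  summed weights, not averaged predictions.
- No spatial autocorrelation correction; results on clustered grids should
  be read as space-use, and standard errors are likely optimistic there.
- Wald intervals underlying the evidence tiers degrade near boundaries;
  boundary fits are flagged but not profile-likelihood corrected.
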
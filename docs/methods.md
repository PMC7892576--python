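# Methods

## The benchmark design

`mixclust` measures how well nine clustering strategies recover a known
partition from mixed continuous + categorical data.  For each simulation
condition, labelled datasets are generated, standardised, and handed
identically to every method together with the true number of clusters G
(cluster-count selection is deliberately out of scope).  Each recovered
partition is scored against the truth with the adjusted Rand index, and
replicates are summarised by mean, sd, median and quartiles.

## Synthetic data generator

### Continuous block

Each of the G clusters is a spherical Gaussian with unit variance.
Centres are placed on a randomly oriented line through the origin at equal
spacing

    delta(J) = 2 * z_{0.975} * (1 + J) / (1 - J),

so that, projected on the centre line, two adjacent clusters attain the
quantile-based separation index

    index = (L2 - U1) / (U2 - L1)

exactly J in the population, where L/U are the alpha/2 and 1-alpha/2
quantiles of each projected cluster (alpha = 0.05 by default, exposed as a
parameter since reference generators do not pin it).  The index is negative
for overlapping clusters, positive when a gap opens, and bounded in
]-2, +2[.  J = -0.3 / 0 / +0.3 encode the low / mild / high degrees of
relevance used by the scenario grid.

This placement is a deliberate simplification of general random-cluster
generators (which draw per-cluster covariances and rotate them until a
separation target holds for the nearest pair): it preserves exactly the
property the benchmark controls — the separation index of each cluster
with its nearest neighbour — at a fraction of the machinery.  Cluster
sizes are balanced (floor(N/G) or ceil(N/G), remainder to the lowest
indices).

**Calibration.**  With two clusters of 600 points each, the empirical
nearest-pair index lands within ±0.05 of the target for all three degrees
(the acceptance suite recomputes this).  Two caveats, both visible in
`analysis/01_simulate.py` output:

* the *nearest-pair minimum* over many cluster pairs is biased low for
  small per-cluster samples (min of noisy estimates), so per-dataset
  measurements at N=300, G=6 sit below the target even though the
  population value is exact;
* the line placement concentrates all between-cluster variance in one
  direction, so the *post-standardisation* geometry is compressed along
  informative coordinates more than a general-position placement would be.
  Calibration statements therefore refer to the generator output before
  scaling; the scaled data that the methods actually see is somewhat harder
  than the nominal index suggests, uniformly for all methods.

### Categorical block

Each relevant categorical variable has exactly G levels.  Every row starts
at the level equal to its cluster index, then exactly `round(nu * N)` rows
(sampled without replacement — a deterministic count keeps the noise dose
identical across replicates) are resampled uniformly over all G levels,
including the current one.  The expected own-level match fraction is
therefore (1 - nu) + nu/G.  Noise nu = 0.95 / 0.85 / 0.75 encodes
low / mild / high relevance; note even "high" relevance is very noisy —
this is what makes the baseline condition hard.

### Irrelevant padding and scaling

Irrelevant continuous variables are standard normal, irrelevant
categorical variables uniform over G levels, both independent of the
labels.  Scenario presets 6 and 7 pad the categorical or continuous block
to 10 variables with 20/50/90% relevant.  Finally every continuous column
is standardised to mean 0 and sample sd 1 (ddof = 1); all methods receive
the same scaled table.

## The nine strategies

Distance-based:

* **Gower + PAM / HC.**  Gower similarity averages per-variable
  similarities over all p variables (m = p: with no missing data every
  variable contributes): range-normalised absolute difference for
  continuous, exact-match indicator for categorical; the dissimilarity is
  1 - S (the convention of the daisy implementation; the square-root
  variant is not used).  A constant continuous column contributes full
  similarity with a warning.  PAM minimises the total deviation
  TD = sum_g sum_{x in C_g} d(x, m_g) by greedy BUILD then repeated
  best-improvement SWAP; ties break toward the lowest observation index.
  Ward HC agglomerates with the Lance-Williams size-weighted update
  [(n_i+n_k) d_ik + (n_j+n_k) d_jk - n_k d_ij] / (n_i+n_j+n_k), applied on
  squared dissimilarities with square-rooted heights (the ward.D2
  convention of the benchmarked software); a raw-d variant is exposed via
  `squared=False` / `--ward-raw`.
* **UET + PAM / HC.**  M fully random trees (default M = 50, minimum node
  size ceil(sqrt(N))): each node samples a not-yet-used variable (variables
  are consumed without replacement along each root-to-leaf path, matching
  the "no remaining variable" stopping rule) and a random split — a
  threshold uniform between the node's min and max for continuous, a
  uniformly drawn present level (equal vs different) for categorical.
  Similarity = fraction of trees sharing a terminal node; dissimilarity =
  sqrt(1 - S).  Splits depend only on orderings, so no scaling is needed.
* **K-prototypes.**  d2(x, b) = squared Euclidean on continuous + gamma ×
  Hamming on categorical; prototypes are cluster means and modes (mode
  ties -> lowest level code).  gamma defaults to mean continuous sample
  variance / mean categorical Gini impurity (1 - sum f_l^2), the "combined
  variance" heuristic, and is overridable.  Best of 10 random starts
  (G distinct observations) by total sum of distances; an emptied cluster
  is re-seeded at the observation farthest from its prototype.

Model-based (all assume within-cluster independence):

* **em_mixture (mixmod / lcm presets).**  Finite mixture f(x) = sum_g
  tau_g h(x | alpha_g) with h = product of univariate normals (diagonal
  covariances, free per-cluster variances — the least constrained diagonal
  model) × multinomial pmfs.  Soft EM maximises the observed-data
  log-likelihood (monotone by construction); the hard variant assigns
  z_ig = argmax t_ig each step and maximises the completed log-likelihood
  L_c.  The `mixmod` preset runs a single start of at most 200 iterations
  (the benchmarked default — hence its visible run-to-run variability);
  the `lcm` preset runs 20 short small-EM starts and refines the best to
  convergence.  Variance floors (1e-6 of the column variance) and Laplace
  smoothing (1e-10) keep the objective finite; variable selection and
  G selection are deliberately disabled.
* **Kamila.**  Alternates: Euclidean distances to centroids; Gaussian-KDE
  (Silverman bandwidth) of the N minimal distances, converted to a
  spherical density via f_V(r) = kde(r) / (S_{q-1} r^{q-1}) with S_{q-1}
  the unit-sphere surface area; assignment by argmax of log f_V(dist) +
  sum_j log p(x_j | g); centroid and level-frequency updates.  Ten runs of
  at most 25 iterations; the run with the best final combined
  log-likelihood wins.  The kernel and bandwidth are configurable since
  reference implementations do not pin them.
* **LCA.**  Continuous variables are first cut into three balanced classes
  at the empirical 1/3 and 2/3 quantiles (rank-based fallback under heavy
  ties); the multinomial mixture is then fitted by EM with uniform initial
  mixing proportions and randomly sampled level probabilities, stopping
  when successive log-likelihoods differ by less than 1e-10 (or at 1000
  iterations, the usual cap — on N=300 datasets the cap typically binds
  before 1e-10, which the convergence flag records honestly).  Five runs
  by default ("several" in the source literature is unquantified); the
  best final log-likelihood wins.

**Initialisation.**  EM components start from uniform mixing proportions,
component centres drawn from the data, global variances, and random level
probabilities.  A diffuse random-responsibility start is also available
but not the default: every component then begins at the global statistics
and EM reliably settles on a symmetric equal-means ridge (on the
two-separated-Gaussians recovery check, all diffuse starts converged to a
clearly inferior likelihood).

## Evaluation and seeding

ARI is computed from the contingency table; it is 1 iff the partitions
coincide up to relabelling, 0 in expectation under independence, and can
be negative.  The benchmark seeds each (scenario, condition, replicate)
with its own child stream derived from the master seed, and every method
consumes a further per-method stream, so adding or removing a method never
perturbs the others — reruns are bit-identical.  Method failures are
recorded (NaN + error text) rather than raised.  The UET forest is grown
once per dataset and shared by `uet_pam` and `uet_hc`.

## Problem sizes

Full-scale runs use 1000 replicates per condition.  The test suite and the
acceptance script use the package's desk-scale prescription of 50
replicates per condition (baseline ordering, relevance sweep, cluster-count
sweep), 200 replicates for parameter recovery and PAM-vs-exhaustive
checks, and 100 datasets for the likelihood-ascent checks.

## Known limitations

* The line placement of cluster centres interacts with standardisation
  (see calibration caveats above); a general-position placement would
  dilute between-cluster variance across coordinates.
* At G = 2 the categorical variables are binary, and with 85% noise the
  Gower/UET dissimilarities contain a crisp binary block structure that
  Ward (and often PAM) prefers over the overlapping continuous signal:
  the distance-based methods other than k-prototypes can score near zero
  at G = 2 while doing better at larger G.  This is a genuine property of
  those methods on such data — the partition found is the categorical
  split — reproduced exactly by independent reference implementations of
  Ward linkage, so the common expectation that fewer clusters are always
  easier does not hold for every method under this generator.
* Balanced clusters, spherical Gaussian continuous variables and
  uniform resampling noise only; outliers, unbalanced sizes and
  non-normal distributions are out of scope.
* Passing tests on this synthetic family says nothing about performance on
  real clinical data with correlated variables, missing values, or
  unbalanced level frequencies.
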
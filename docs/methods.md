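# Methods

## The task being modeled

Participants encode a small friendship network of fictitious students.
Every friendship edge carries one shared personality trait and one shared
university-club context. After encoding, participants (1) drag-and-drop the
students' names into a rectangular box so that proximity expresses judged
friendship likelihood, and (2) answer cued 3AFC recall probes (one correct
option, two foils; chance 1/3) separately for friendships, traits and
contexts. Two topologies are studied: a ring of eight students (every
student has exactly two friends) and a nine-student network of two
four-student cyclic cliques joined by a bridge student; the two clique
members adjacent to the bridge have degree 3 and are the *central* nodes.

Per block, every student is cued twice per condition. In the bridged
network, clique members are probed on their within-clique friendships and
the bridge student on both bridge friendships, which yields the trial
identities 8×2×3 = 48 (ring) and 8×2×3 + 2×3 = 54 (bridged) per block;
encoding presents each edge once per block (8 and 10 edges, 3 blocks).

## Attribute lexicon and assignment regimes

Trait words carry a valence score and club words an athleticism score, both
in [−1, 1] with reference words ("Smiley", "Running") at the peak. The
packaged lexicon is a hand-set scalar table playing the role of a word
embedding projected onto one axis; any user-supplied mapping with the same
references can replace it.

Under the **correlated** regime, words are laid out along the network so
that score similarity tracks graph proximity: sorted scores are arranged in
a "tent" around each cycle (rising then falling), which avoids the
wrap-around discontinuity of a plain sorted layout; in the bridged network
the lowest four scores tent around one clique, the middle two sit on the
bridge edges and the highest four tent around the other clique. Seeded
rotations/clique swaps vary the concrete assignment per participant. Under
the **uncorrelated** regime the same word multiset is permuted uniformly.

Two caveats, both verified empirically:

* The node-pair attribute/distance rank correlation has a *structural*
  positive baseline (≈ 0.2 on average) even under random assignment,
  because adjacent nodes literally share an edge attribute. The operative
  contrast is therefore relative: the correlated regime exceeds the
  uncorrelated one in ~93–97 of 100 paired seeds depending on the seed
  block.
* Because both traits and contexts follow proximity in the correlated
  regime, some realized assignments make the per-student trait and context
  score columns (nearly) collinear (|r| up to 1 for anti-phase tent
  rotations). Collinear columns make the two bias dimensions of the model
  unidentifiable; model-recovery simulations therefore use a canonical
  study network whose assignment has near-zero trait–context correlation.

## The semantic-bias clustering model

Student i's attribute vector D_i ∈ ℝ³ holds (trait valence, club
athleticism, centrality indicator); since traits/contexts attach to
friendships but D is per student, a student's score is the mean of their
edge scores. The condition tensor C_ij ∈ {0,1}³ marks both-positive
valence, both-athletic clubs, and at-least-one-central (bridged network
only; the centrality dimension is masked for the ring).

Pairwise similarity is a factorized squared exponential with per-dimension
biases β_k (when C_ijk = 1) and β̂_k (when C_ijk = 0), and a dispersion
parameter α on the diagonal (the tendency to treat a student as a
singleton). Row normalization, *including* the α self term in the
denominator, gives the assignment probability P(c_i = j). In the zero-bias
limit every off-diagonal probability is exactly 1/(N−1+α).

A participant's layout is read out as an inverse-distance empirical
distribution (zero diagonal, rows normalized over the other students) and
parameters are estimated by minimizing the KL divergence of the empirical
rows from the model's off-diagonal probabilities.

**α is not identifiable under this objective.** The derivative of the KL
with respect to log α is Σ_i P_ii > 0 everywhere, so the objective is
strictly decreasing as α → 0: with an off-diagonal-supported empirical
distribution, the α mass in the denominator is pure penalty. Fitted α
therefore runs to the lower parameter bound and should not be interpreted;
the off-diagonal row proportions — and hence the fitted β ordering — are
unaffected (they are α-free). Fits report α for completeness only.

**Optimization.** Log-parameter space (positivity by construction), box
[−12, 8] in log units. The objective's gradient and Hessian are available
in closed form (a handful of N×N products), so fitting uses a damped-Newton
scheme with an adaptive trust parameter (solve (H+λI)p = −g; shrink λ on
accepted steps, grow it on rejections) and a projected-gradient (KKT)
stopping rule at the box. This agrees with scipy's `trust-constr` on the
same objective to ~1e−4 in final KL while being an order of magnitude
faster, which is what makes the 100+100-cohort model-comparison calibration
tractable. Defaults: `max_iter=200`, `gtol=1e-8`; the leave-one-out loops
use `max_iter=40`, `gtol=1e-6`. Multi-start (`n_starts`) is available; on
these small problems restarts land on the same optimum to < 1e−6.

**Model comparison.** The unbiased variant shares a single β across all
dimensions and both condition states (2 free parameters vs 2·m+1 for the
biased variant with m active dimensions). Leave-one-student-out: for every
participant and held-out student s, both variants are fitted on the
(N−1)-student sub-problem (empirical distribution recomputed from the
remaining placements) and evaluated on s's empirical row under assignment
probabilities recomputed over the full network; the per-participant score
is the mean KL difference (unbiased − biased) and a one-sided paired t-test
aggregates across participants. Calibration on synthetic cohorts: the
biased model is selected (p < .05) on essentially all cohorts generated
with unequal β/β̂ and at ≈ the nominal rate on shared-β cohorts. One caveat:
all participants in a synthetic cohort share the same pre-jitter layout, so
on unfavourable (collinear) study networks the deterministic embedding
distortion is itself systematic structure that the richer model can exploit;
calibration is stated for the canonical study network.

## Synthetic participants

**Placements.** The generator inverts the model: symmetrized assignment
probabilities define target dissimilarities δ_ij ∝ 1/p̄_ij (the model's
rows are asymmetric; a 2D layout is not), which are embedded by classical
scaling followed by quasi-Newton descent on the squared stress, scaled into
the box (default 1.6 × 1.0 box units), and jittered with Gaussian noise of
standard deviation `noise_sd` (box units; "low noise" in the recovery
simulations is 0.02 ≈ 1% of the box diagonal). No claim is made that
humans compute such an embedding — it is the minimal mechanism making the
inverse-distance read-out approximately recover the generating
probabilities. Consequences worth knowing: participants within a cohort
differ only by jitter; and the between/within group separation of the
*embedded* points tracks the generator's bias only up to a saturation point
(extreme dissimilarity ratios cannot be realized in 2D), so monotonicity
holds on the target dissimilarities everywhere but on embedded layouts only
in the moderate-bias range. Confidence and placement time are uninformative
noise carried for format completeness.

**Recall outcomes.** Bernoulli trials with logit = base(condition) +
participant intercept (SD `intercept_sd`, default 0.5) + cue effects on
friendship trials: negative-valence and both-valence dummies (reference:
positive), centrality, centrality × negative, bridge. Applying cue effects
only to friendship trials mirrors the observed dissociation (no valence or
centrality effects on trait/context recall). Incorrect trials pick one of
the two foils uniformly.

## Stepwise placement accuracy and chance

For a node v, rank all other nodes by Euclidean distance from v (ties —
measure-zero under jitter — broken by an ε = 1e−9 comparison then node id).
A geodesic chain v → u_1 → … → u_k is **reproduced** when every chain node
at depth j is ranked closer than every node whose geodesic depth from v
exceeds j; accuracy at step k is the fraction of (node, chain) units
reproduced, each geodesic direction counting as its own unit (a flag
switches to per-pair conjunction counting). Reproducing a k-chain thus
implies correct placement of all intermediate nodes.

Chance under a uniformly random ordering has the exact closed form, per
chain, ∏_{j=1..k} 1/(1+m_j) with m_j the number of nodes deeper than j:
u_1 must come first among itself and all deeper nodes; conditional on that,
the remaining relative order is again uniform, and the argument recurses.
Group chance is the chain-weighted mean. An exhaustive enumeration over all
(N−1)! orderings (≤ 40,320 for these networks) reproduces the closed form
exactly and serves as the oracle. Ring values: 1/6, 1/24, 1/48, 1/48.
Chance decreases strictly with step length until the deepest level holds a
single node — reproducing the (k−1)-chain then already pins down the last
node, so the final step adds no constraint and chance (and every
participant's accuracy) coincides across the last two steps; group
t-statistics against chance are therefore identical there, as observed.
Group tests are one-sample, one-sided t-tests per step; zero-variance steps
are flagged rather than tested.

## Statistical battery

* "Different from mean recall" is implemented as sum-to-zero effect coding:
  each condition's coefficient is its deviation from the grand mean
  (deviations sum to zero exactly; the omitted level's deviation and
  standard error are recovered from the coefficient covariance); F = t²
  with 1 numerator df. The two-way design adds the between-subject regime
  factor and its interaction.
* Repeated-measures ANOVA via statsmodels `AnovaRM`; post-hoc paired
  t-tests with Bonferroni correction (×3, capped at 1). A cohort with no
  within-subject variation at all gets F = 0 by definition rather than 0/0.
* friendship ~ context × trait OLS with type-II F per term; zero-order
  Pearson correlations; partial correlations by the residual-correlation
  definition with two-sided p on n−2−k df (cross-checked against pingouin).
* Trial-level mixed-effects logistic regression with participant random
  intercepts uses statsmodels' variational Bayesian binomial mixed GLM
  (MAP fallback, flagged). The VB objective draws Monte-Carlo samples from
  the global NumPy RNG; the state is pinned locally so reports are
  reproducible. Posterior mean/SD give per-coefficient Z and two-sided p;
  VB posterior SDs are known to be slightly optimistic, so the package's
  calibration claims for this component are about coefficient *sign*
  recovery (≥ planted |log-odds| 0.3 at experiment-scale cohorts), not
  about exact type-I rates. Constant predictor columns (e.g. centrality on
  the ring) are dropped and flagged.
* Type-I calibration of the summary-level battery is verified under an iid
  null (500 replications), the natural null for these OLS-family tests;
  with participant-level random effects the long-format deviation tests
  would be conservative.

## Problem sizes and defaults

Simulation sizes used by the test-suite and the acceptance script were
chosen to match the experiments where the quantity is experiment-scale
(116 and 80 participants for the recall battery and GLMM) and to be
statistically decisive where it is model-scale: 50 participants for
parameter recovery (noise 0.02), 8-participant cohorts × 100 per arm for
model-comparison calibration (noise 0.05, reduced fit iterations), 10,000
random layouts for the Monte-Carlo chance check.

## Known limitations

* α is reported but unidentified (see above).
* Bias-dimension identification requires non-collinear attribute columns;
  strongly correlated trait/context assignments (possible in the correlated
  regime) confound the trait and context biases.
* The placement generator's participants share a deterministic layout;
  real participants differ structurally, not only by motor jitter.
* The GLMM backend is variational; exact-likelihood (adaptive quadrature)
  fitters would sharpen its p-values but are not available in this stack.
* Chained accuracy is one operationalization of "reproducing a multi-step
  connection"; the per-direction vs per-pair counting choice is exposed as
  a flag, with per-direction as the default.
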
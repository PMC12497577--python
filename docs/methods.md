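# Methods

## Data model and preprocessing contract

`braindyn` consumes already-extracted regional time series: one T × R
matrix per subject (rows are TRs, columns are ROIs), assumed motion- and
nuisance-corrected upstream.  Each column is z-scored within subject
(sample SD, denominator T − 1) before concatenation, so between-subject
amplitude differences cannot dominate the state covariances; zero-variance
columns are set to zero and flagged.  Whether to standardize is a genuine
design choice — published HMM pipelines differ and rarely say — so it is
the default but can be switched off (`load_cohort(..., standardize_series=False)`).
Subjects are row-stacked in manifest order with half-open 0-based
boundaries; slicing by boundary reproduces each input bit-identically.

All internal state labels are 0-based; every user-facing artifact (CSV
columns `fo_1..K`, reports, configuration fields such as
`suppressed_states`) uses 1-based labels.

## The variational-Bayes Gaussian HMM

One hidden chain per subject, parameters shared across the cohort.
Emission per state: full-covariance multivariate Gaussian.  Conjugate
priors:

* transition row j: Dirichlet(1 + 10·δ_jk) — the +10 diagonal bonus is a
  weak stickiness prior reflecting that brain states persist over several
  TRs; both counts are constructor parameters
  (`transition_prior_count`, `transition_prior_diag_bonus`);
* initial distribution: Dirichlet(1);
* (μ_k, Σ_k): Normal-Inverse-Wishart with location = pooled mean,
  scale count κ₀ = 1, degrees of freedom ν₀ = R + 2 (the smallest value
  giving a finite prior covariance mean), scale matrix = pooled sample
  covariance.  Scale-aware and weakly informative: one pseudo-observation
  at the pooled moments.

Each VB cycle is M-then-E: refresh the Dirichlet/NIW posteriors from the
current responsibilities and expected transition counts, then run a
scaled forward-backward pass per subject using expected-log parameters
(ψ-function expectations for the Dirichlets; the standard expected
Gaussian log-density with the E[log|Λ|] and R/κ corrections for the NIW).
Segments of equal length are batched through one vectorized
forward-backward sweep, so the per-iteration cost is O(T · S · K²) matrix
work rather than a per-subject Python loop.

The free energy F = −(Σ_s log Z_s − KL) is computed after every cycle,
where log Z_s is subject s's forward-pass log normalizer under the
expected-log parameters and KL sums the Dirichlet and Normal-Wishart
divergences from the priors.  F is non-increasing across cycles; the test
suite enforces this to 1e−6 on every fixture.  For K = 1 the variational
posterior is exact, so −F must equal the closed-form
Normal-Inverse-Wishart log marginal likelihood — an independent oracle the
suite checks to 1e−5.

Initialization: k-means on the pooled rows (seeded, `kmeans_n_init`
restarts), hard labels softened to responsibilities (1 − ε on the
assigned state, ε = 0.05 spread uniformly elsewhere).  The first M-step
approximates transition counts by products of consecutive
responsibilities; all later cycles use exact pairwise posteriors.
`n_restarts` independent initializations are run (default 5) and the
restart with the lowest final F wins.  Convergence: relative |ΔF|/|F| <
1e−5 or 500 iterations.  Everything is deterministic given
`random_state`.

States whose responsibility mass falls below 1e−6·N are flagged
"depleted" and retained (they shrink to the prior) rather than pruned, so
the reported K stays honest in model-order comparisons.  Covariance scale
matrices get a +1e−8·I ridge before factorization.

Only the full-covariance emission family is implemented.  On concatenated
cohorts every state receives far more rows than R, so the NIW posterior
is well conditioned at all scales this package targets; a second
(diagonal) emission family would double the update and free-energy code
paths without an exercised use case.

### Point estimates and decoding

The exported model uses posterior means: Dirichlet means for the
transition matrix and initial distribution, the NIW location for μ_k, and
Ψ_k/(ν_k − R − 1) for Σ_k.  Hard paths come from Viterbi under these
point estimates — this guarantees a valid Markov path for dwell
statistics, unlike per-timepoint argmax of the marginals.  A
gamma-weighted fractional-occupancy alternative is available
(`compute_metrics(..., decode_mode="gamma")`) for sensitivity analysis.

### Model-order selection

`select_n_states` fits every K in the grid and reports the best
(minimum-F) restart per K.  Selection rule: among the K whose free energy
lies within 1% of the grid minimum, pick the smallest — where "1%" is
measured against the spread of free energies across the grid, because the
absolute level of F carries a data-scale offset (≈ N·R nats) that says
nothing about model order.  The median (across states) of the pooled
fractional occupancy is reported per K as a secondary plateau diagnostic,
with the first K past which it stops decreasing by more than a
configurable step flagged in the rule trace.

## Temporal metrics

From each subject's decoded path: FO_k = (TRs in k)/T; LT_k = mean run
length × TR seconds, with runs truncated by the scan edges included as
observed (excluding them is possible by filtering on `n_visits`);
unvisited states get missing LT, never zero — zero would bias group
medians.  SF = switches/(T − 1), reported per TR and per second; this
normalization is bounded in [0, 1] and invariant to scan length.  The
subject TP matrix normalizes outgoing transition counts per row; rows
never left from are set to uniform and flagged invalid so group tests can
exclude them.  Identity enforced by tests: FO_k · T equals the summed run
lengths of k exactly.

## Transition-graph communities

States visited by fewer than half the participants or with pooled median
FO below 0.01 are dropped (both thresholds configurable and reported per
state with the diagnostics that triggered them).  The group-mean TP
matrix (valid rows only) is restricted to retained states, self-
transitions are zeroed (they encode stickiness, not between-state
structure), and the matrix is symmetrized W = (M + Mᵀ)/2 because the
Newman-Girvan quality function is undirected.  The strongest
round(p · n_pairs) symmetric off-diagonal pairs are retained (default
p = 0.21; ties broken by larger weight, then lexicographic (i, j)) — the
retained count is reported so alternative readings of "top p%" stay
auditable.  Modules come from a Louvain-style locally greedy heuristic
(networkx's implementation) restarted over seeded node orders, keeping
the partition with the highest in-package modularity
Q = (1/2m) Σ_ij [W_ij − γ k_i k_j/(2m)] δ(c_i, c_j) at resolution γ = 1
(exposed).  Tests verify Q against a brute-force double sum to 1e−12 and
the heuristic against exhaustive partition search on small graphs.

Each module's group affinity is the patient-minus-control difference of
group-median FO summed over member states; |affinity| below 10% of the
pooled median FO reads "shared", otherwise patient-/control-leaning.
This labelling band is a reporting convention, not an inferential
threshold.

## Group statistics

Per state, FO and LT (LT on visiting subjects only, with ≥ 2 per group)
are compared by a two-sided Mann-Whitney U with midranks; p is exact
(full permutation distribution) when there are no ties and n₁n₂ ≤ 10⁴,
else the tie-corrected normal approximation with continuity correction.
The rank-biserial effect size r = 2U/(n₁n₂) − 1 is signed so r > 0 means
patients stochastically larger.  The global SF and each TP cell (valid
rows only) use a label-permutation test: 5,000 uniform relabelings by
default, difference of group medians as the statistic (means available),
two-sided add-one p = (1 + #extreme)/(n_perm + 1) — so p > 0 always and
q-values are well defined.  BH-FDR is applied within each metric family
(FO across states; LT across states; TP across cells) separately,
mirroring how such results are reported per metric; the single SF test
keeps q = p.  Spearman correlations with clinical covariates use
midranks, pairwise-complete subjects of the requested group, exact
enumeration p for n ≤ 9 and the t approximation beyond, with BH across
the tested (metric, state) pairs.

Calibration is enforced by tests: exact Mann-Whitney p equals brute-force
label enumeration; permutation type-I error at α = 0.05 lies in
[0.03, 0.07] over 1000 null repetitions; and under a global null the full
battery's fraction of q < 0.05 stays at or below 0.05 averaged over 50
simulated cohorts.

## The synthetic cohort generator

The generator draws from exactly the model family the HMM assumes, so it
provides ground truth for every stage rather than a realistic BOLD
simulator.  Defaults mirror the two-group study design: 36 patients vs
30 controls, 200 TRs at TR = 2 s, 90 regions, K = 12 states, suppressed
states {5, 6}, covariate "LDH" tied to state 8's lifetime at Spearman
rho 0.693.

* **Emissions** are shared across groups: K mean activation vectors on a
  sphere of radius `state_mean_scale` = 1.5 (in emission-SD units),
  redrawn until every pair is at least that far apart so no two states
  coincide by chance; covariances are isotropic by default (random SPD
  with bounded condition number available).  1.5 makes state recovery
  reliable at T = 200 while keeping inference nontrivial.
* **Transitions** differ by group only: self-transition probability 0.90
  for controls vs 0.82 for patients (patients switch faster), uniform
  off-diagonal mass, and entry columns of the suppressed states
  multiplied by 0.4 in patients before row renormalization (their
  stationary occupancy drops).  Initial distributions are the stationary
  vectors.  The effect sizes were chosen so the planted contrasts are
  detectable at 36/30 subjects with the nonparametric battery.  Note one
  mechanical consequence of column suppression: renormalization boosts
  the suppressed states' *exit* probabilities, so in the thresholded
  symmetric transition graph those states attach to the rest via their
  exits; the group contrast appears through module affinity rather than
  graph disconnection.
* **The clinical covariate** exists for patients only (as for a disease
  marker never assayed in controls).  It is generated by a Gaussian
  copula on the true lifetimes of the target state: normal scores of the
  lifetime ranks are mixed with independent noise at latent correlation
  2·sin(π·rho/6), so the expected Spearman correlation equals the
  requested rho; the result is mapped to an LDH-like scale
  (250 ± 128 U/L).

What the generator does **not** emulate: hemodynamic convolution,
autocorrelated scanner noise, motion artifacts, spatial topography, or
between-subject parameter heterogeneity.  Passing the synthetic battery
therefore shows the inference machinery is correct for the model family,
not that the model family captures real BOLD dynamics.

## Validation scales and a known power limit

The end-to-end validation runs the pipeline on cohorts at the study's
sample size but a reduced spatial scale (10 regions, 6 states) so that
dozens of full fits complete in minutes; the batched forward-backward
keeps one 66-subject fit at ~2-3 s.  At this scale the suppressed-FO and
switching-frequency contrasts and the module separation are recovered in
well over 80% of cohorts.

The covariate-lifetime association is the exception, and the limit is
measurement noise, not implementation: a per-subject lifetime at T = 200
is the mean of roughly ten short geometric runs, and decoding at the
reduced scale is ~86% accurate even for a Bayes-oracle decoder using the
true generative parameters (the fitted pipeline matches this).  Decoded
lifetimes correlate with true lifetimes at Spearman ~0.7, attenuating a
planted rho of 0.693 to an observable ~0.5; at n = 36 with FDR over six
lifetime targets that detects in only about half of cohorts (and ~0.76
even uncorrected).  Longer scans, more separable states, or larger
samples would be needed for reliable detection — a caveat that applies
equally to interpreting such correlations on real data.
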
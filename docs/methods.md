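# Methods

## Data model and scoring

The package analyzes a two-wave panel of Likert questionnaire responses.
Input is one wide CSV per wave (participant ID + 29 BPAQ items + 8 YSIS
items, responses in 1–5); waves are inner-joined on the ID, and any missing
or out-of-range cell is rejected rather than imputed (the design targets
complete-case panels; imputation would need assumptions the package does not
want to hide).

Analysis nodes are the four BPAQ subscales — physical aggression (items
1–9), verbal aggression (10–14), anger (15–21), hostility (22–29) — scored
as item **means** so they stay on the 1–5 response scale (totals available
via `method="sum"`), plus YSIS items 3–8 passed through unchanged. YSIS
items 1–2 measure overall sleep quality rather than a specific symptom; they
are screened by the item checks and dropped from the node set by
configuration (`drop_items`), not by an automatic rule, because the decision
is substantive.

Descriptives report the adjusted Fisher–Pearson skewness and *excess*
kurtosis. The paired t-test is on wave2 − wave1; Cohen's d defaults to
mean(diff)/sd(diff) (the natural effect size for a within-person contrast),
with a pooled-SD variant by flag, and the mean difference is always reported
alongside, since d conventions differ across papers. Reliability is
Cronbach's α = k/(k−1)·(1 − Σvar_i/var_total).

## Item screening

*Informativeness*: item j is flagged iff sd_j < mean(sd) − 1.5·sd(sd)
(sample SDs, ddof=1). *Redundancy*: for every candidate pair (a, b) with
|r_ab| ≥ 0.5, the correlation profiles r(a,c) and r(b,c) are compared over
all p−2 third variables c with Steiger's Z̄₂* statistic for overlapping
dependent correlations (Fisher-transformed correlations, pooled-correlation
covariance term; the variant recommended by Hittner, May & Silver 2003). A
pair is redundant when fewer than 25% of these comparisons are significant
at α = 0.05. The minimum-correlation gate matters: without it, mutually
*independent* items — whose profiles are all trivially equal — would be
declared redundant. The denominator of the reported proportion is the
number of third variables. Flagged pairs are reported, never auto-dropped.

## Cross-sectional networks

Edges are partial correlations from a graphical-lasso precision matrix.
The solver is a block coordinate-descent implementation (numba-compiled,
`_glasso.py`) of the standard algorithm with an unpenalized diagonal; it is
tested against scikit-learn's `graphical_lasso` (agreement ≤ 1e-4) and
every solution is certified by its KKT residual (≤ 1e-4 in the acceptance
suite). The in-house kernel exists for speed: permutation and bootstrap
procedures re-estimate networks 10⁴–10⁵ times, and a 100-λ path on p = 10
runs in ~10 ms here.

Model selection: λ path of 100 log-spaced values from λ_max = max|S_ij|
(empty network) down to 0.01·λ_max; EBIC with γ = 0.5; ties broken toward
the sparser network. Correlations are Pearson on the node scores by default
(subscale means are near-continuous; Spearman by flag; polychoric
estimation is out of scope and would mainly rescale weights).

**Edge thresholding.** EBIC-selected graphical-lasso solutions at study-size
n retain many tiny spurious edges (measured here: specificity ≈ 0.76 on
continuous and ≈ 0.62 on Likert data at n = 2000 without any threshold —
the missing edges are all of magnitude ≲ 0.02). The estimator therefore
removes, by default, edges with |w_ij| < sqrt(log(p(p−1)/2)/n) after
selection, the false-positive-control device of the thresholded graphical
lasso (of the order sqrt(log p / n) suggested by its theory, and analogous
to the `threshold` option of the standard R estimator). With it, edge
sensitivity/specificity at n = 2000 are ≈ 1.0/0.99 (continuous) and
0.99/0.92 (Likert). Set `EstimationConfig(threshold=False)` to disable.

Centrality: EI_i = Σ_{j≠i} w_ij (one-step, signed); bridge strength
Σ_{j in other community} |w_ij| (signed variant by flag), z-scored across
the 10 nodes with ddof=1, flag at z ≥ 1. The literature sometimes labels
this index "bridge centrality"; it is the same quantity. Predictability is
R² = 1 − SSE/SST of each node regressed on all others, lasso-penalized with
10-fold CV (deterministic folds from the run seed); on data this size it
differs from OLS R² by < 0.02, and an OLS flag exists.

## Cross-lagged panel network

Both waves are z-scored; each wave-2 node is regressed on all ten wave-1
nodes by lasso. The CV rule is the *minimum* of the 10-fold CV error — the
1-SE rule is available but prunes far more aggressively (under a pure-noise
outcome the min rule leaves ~11% nonzero coefficients, the 1-SE rule
essentially none), and the denser min-rule networks match how such models
are reported in this literature. IEI/OEI exclude the autoregressive
diagonal (an inclusive flag exists): they quantify being-predicted-by and
predicting *other* symptoms. The lasso engine is a numba path solver on
Gram matrices equivalent to scikit-learn's LassoCV (asserted to 1e-6 in the
tests); no covariate adjustment is applied.

## Resampling inference

*NCT*: both networks are re-estimated per permutation with the same EBIC
pipeline. For wave1-vs-wave2 the default permutation is **paired** (each
participant's wave labels swapped independently), because the two samples
are the same people; an unpaired mode shuffles group membership. p-values
use the add-one correction (1 + #{perm ≥ obs})/(1 + n_perm) and can never
be 0. Default 1000 permutations.

*Edge bootstrap*: rows resampled with replacement, percentile 95% CIs
(BCa offers little at these sizes and would multiply cost); degenerate
resamples (constant column) are redrawn, capped. Differences between two
edges or two nodes' expected influence are significant when the bootstrap
CI of the difference excludes 0.

*Case-dropping stability*: drop grid 10%–75% in 7 even steps; at each
level the centrality is recomputed on subsamples drawn without replacement
and correlated with the full-sample centrality. CS coefficient = largest
grid proportion at which ≥ 95% of correlations are ≥ 0.70 (≥ 0.25
acceptable, ≥ 0.50 preferred, as advisory thresholds). For the CLPN, IEI
and OEI are computed from a single refit per subsample.

All resampling is driven by `numpy.random.default_rng(seed)`; a fixed seed
makes every artifact byte-identical across runs.

## Synthetic data generator

The generator emulates the study conditions the package targets: n = 665
matched participants (options for extra wave-only rows to exercise the
merge), p = 10 nodes, cross-sectional density 0.3 with positive partial
correlations drawn U(0.1, 0.4) (mixed signs by flag), autoregressive
diagonals U(0.2, 0.5) and sparse (15%) cross-lagged off-diagonals with
random signs. The candidate precision matrix (unit diagonal, −w_ij
off-diagonal) has its diagonal inflated until positive definite, and the
*realized* partials of the final matrix are stored as truth, so inflation
never silently invalidates the reference.

Wave 2 is generated **stationarily**: innovations have covariance
Σ − BᵀΣB, so both waves share the same marginal covariance — and hence the
same cross-sectional network — and B is exactly the standardized
cross-lagged coefficient matrix. (With independent innovations wave 2's own
network would be near-empty, which is not what two-wave symptom panels look
like.) B is shrunk if necessary to keep the innovation covariance positive
definite.

Likert marginals: per node, category probabilities over 1..5 are solved
(softmax-parameterized Nelder–Mead over the multinomial moments) to match
target means and skews — defaults reproduce the questionnaire profile of
the target study population (aggression subscales: means ≈ 1.9–2.6, mild
skew; sleep symptoms: means ≈ 1.6–2.4, skew ≈ 0.6–1.6), with wave-2
targets slightly lower, mirroring symptom amelioration. Columns are then
cut at their empirical quantiles (a Gaussian-copula threshold scheme).
Infeasible mean/skew combinations raise an error reporting the attainable
skew range. What the generator does **not** emulate: item-level factor
structure (the 37-item CSV writer expands each BPAQ node into noisy
indicator items with loading 0.75 and adds two overall-sleep-quality items
loading on the common sleep factor — enough to exercise scoring,
reliability and the redundancy screen, but not a measurement model),
selective attrition, response styles, or floor effects beyond what the
marginals imply. Passing recovery tests therefore demonstrates correctness
of the estimators under the assumed data-generating process, not robustness
to measurement artifacts.

## Problem sizes used in the checks

The test suite runs the estimator-validation studies at the sizes the
package documents as its reference conditions: EBIC null calibration over
50 seeds at n = 2000; NCT type-I error over 200 replications of 250
permutations at n = 300/group (λ path shortened to 25 points inside the
permutation loop; selection quality at p = 10 is unaffected); full-pipeline
recovery over 25 seeds at n = 2000 on Likert data. The acceptance script
runs the complete pipeline at the study scale (n = 665, 1000 permutations,
1000 bootstrap resamples, 250 case-dropping draws per level).

## Known limitations

- Pearson correlations on 5-point items attenuate edge weights relative to
  the latent continuum (~10–20% here); ordering is preserved (tested:
  weight correlation ≥ 0.7 between Likert and continuous estimates).
- The CS coefficient is reported on the package's 7-point drop grid; it is
  a grid value by definition, not an interpolated quantity.
- The NCT re-estimates sparse networks per permutation, so its null
  distribution has atoms at 0; p-values are valid but conservative when
  both networks are very sparse.
- Predictability from node-wise lasso is an in-sample R² at the CV-chosen
  penalty, the convention of mixed-graphical-model tooling; it is not an
  out-of-sample estimate.
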
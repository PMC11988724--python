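# Methods

This note documents the statistical and algorithmic choices behind
`promotif`, the assumptions they rest on, and what the synthetic-data
checks do and do not establish.

## Coordinate conventions

Promoters are the 1000 bp immediately upstream of the transcription start
site (TSS), indexed −1000…−1 with −1 adjacent to the TSS. A motif hit is
addressed by its 5′-most base *on the plus strand*, for hits on either
strand; a minus-strand hit found on the reverse complement is mapped back
so that its plus-strand window is [position, position + L − 1]. The
distal region (DR) is [−1000, −750], **both endpoints inclusive**, and a
hit belongs to it by its 5′-most base, not by full containment — a single
consistent rule, configurable via `distal_window`. Enhancer/silencer
membership requires at least 1 bp of overlap between the hit span and an
annotated interval. BED inputs are 0-based half-open in promoter-local
coordinates (0 maps to −1000) and converted on read.

## Motif scanning and p-value calibration

The PWM is the standard smoothed log-odds transform of a count matrix,
`log2((n_bj + s·q_b) / (N_j + s) / q_b)` with pseudocount `s` (default
0.8) and background `q` (default uniform). The null score distribution of
a random background word is computed *exactly* by convolving the
per-column score distributions on a grid of width 0.01 log2-units; the
threshold for a target p-value α is the smallest grid score whose tail
probability is ≤ α. Scanning accepts windows by their **discretized**
score, so the realized per-window hit rate on background sequence equals
the reported tail probability (verified by a calibration test); the grid
error in the raw score is at most L·bin/2 ≈ 0.1 log2-units at L = 20.
Windows containing N are skipped (conservative) rather than scored
against background. All overlapping hits are reported — counts are raw
site counts with no masking and no multiple-testing correction, matching
a fixed per-site α = 0.01 design.

## Similarity covariate

The per-gene, per-factor similarity is the mean over viable (plus-strand)
hits of `SW(matched_seq, consensus) / (match·L)`, where SW is the
Smith–Waterman local-alignment score under linear gap costs (defaults
match = +2, mismatch = −1, gap = −2). This is bounded in [0, 1], equals 1
iff every site matches the consensus exactly, and is defined as 0 for
genes without viable hits so every regression row exists. A per-gene
maximum is available via `aggregate="max"`. The gene–gene distance for
tree building is 1 − Pearson r between the genes' dense plus-strand
window-score profiles (raw log-odds, unthresholded, since correlation
needs a dense signal); UPGMA heights are half the merge distance, so
cophenetic distances on ultrametric inputs are recovered exactly.

## Clustering workflow

The six per-gene variables (KLF14/SREBF-1 distal counts, plus-strand
counts, similarities) are z-scored. Cluster tendency is assessed by VAT:
a Prim-style minimum-spanning-tree traversal seeded at the row containing
the largest dissimilarity. K selection runs three criteria over K =
1…kmax: the elbow (argmax of the second difference of the best-of-restarts
WSS curve, which is kept monotone by warm-starting K+1 from the K
solution plus the farthest point), the average silhouette width, and the
gap statistic with a uniform reference over the data's bounding box
(B = 50 references by default) under the one-standard-error rule. The
final K is the majority vote, ties resolved toward smaller K; the
diagnostic report retains all three votes because the criteria can
legitimately disagree on real data. Stability is clusterboot-style
nonparametric bootstrap: recluster each resample, match every original
cluster to the resample cluster with maximal Jaccard index over retained
points, and report mean Jaccard plus recovery (> 0.75) and dissolution
(< 0.5) rates. k-means uses k-means++ with 25 restarts by default; any
emptied cluster is reseeded from the farthest point.

## Count regression

Distal counts are modelled with a log link. The Poisson branch is IRLS
(statsmodels GLM); the NB2 branch maximizes the full negative-binomial
likelihood in (β, α) with θ = 1/α, so the variance is μ + μ²/θ and the
reported θ is the conventional "size" parameter. θ counts as a parameter
in AIC/BIC (−2ℓ + 2k and −2ℓ + k·log n). NB deviances are computed at
the estimated θ; the null deviance uses the intercept-only mean. When θ̂
diverges past 10⁶ the data are Poisson-equivalent: the fit is returned
with a warning and β and its covariance taken from the Poisson limit,
where the NB Hessian is singular. Overdispersion is diagnosed by the
residual-deviance chi-square test (ratio = deviance/df, upper-tail
p-value); the Cameron–Trivedi auxiliary regression is available as
`dispersion_auxiliary_test`. Effect tables exponentiate coefficients with
Wald (not profile) intervals — a documented simplification. Display
transforms truncate toward zero (11.6 % for β = 0.10986, 1.34 for
β = 0.2995), the convention the motivating report's worked examples
follow. The Vuong statistic is √n·m̄/s(m) over per-observation
log-likelihood differences with a two-sided normal p-value. Prediction
intervals on the mean scale use the delta method on the linear predictor.

The KLF14 branch defaults to NB2 and the SREBF-1 branch to Poisson
(`family_policy`), reflecting the overdispersion pattern the analysis is
designed around; both are overridable.

## Synthetic study conditions

The generators emulate the study conditions with known ground truth:

* **Promoters** — i.i.d. uniform base composition (chosen for tractable
  p-value oracles), length 1000; plants per promoter ~ Poisson(rate 2 per
  factor), minus-strand probability 0.48 (the observed strand split is
  near 1:1), distal probability 0.25 (the DR is a quarter of the
  promoter); plants never overlap (rejection sampling) so recovery is
  unambiguous.
* **Counts** — design (intercept, plus-strand count ~ Poisson(5),
  similarity ~ Beta(5, 2), optional binary group and its interaction)
  with defaults β = (−0.8, 0.11, 4.3) and θ = 1.3, the coefficient and
  dispersion magnitudes of the KLF14 distal-count models; θ = ∞ yields
  Poisson responses.
* **Feature matrices** — four Gaussian clusters in six dimensions whose
  default centers sit ≥ 17× the unit spread apart, separated in every
  variable, with 30 genes each (~120 rows, the order of the study's gene
  set).

A single seed is fanned into named sub-streams (CRC-keyed
`SeedSequence`), so each generator is a pure function of its
configuration and generators do not perturb one another.

What passing these checks shows: the estimators recover known truth under
their own assumptions (correct likelihood, spherical well-separated
clusters, exact motif plants, i.i.d. background). What they do not show:
behaviour under real promoter composition bias, motif self-overlap,
annotation noise, or model misspecification — real-data conclusions still
require the usual diagnostics (overdispersion test, Vuong, stability
report) that the pipeline emits.

## Embedded published tables

The per-class site marginals, the per-gene distal-count listing, and the
per-receptor comparison table are embedded as machine-readable fixtures.
Since only marginals are printed, mock hit lists are synthesized with
deterministic positions (distal plants within [−1000, −750], annotated
hits inside per-gene enhancer/silencer intervals, the remainder proximal)
whose strand/region marginals match the printed totals exactly; they
exercise the summarizers end to end but carry no information about true
site positions. Two internal inconsistencies in the source tables (the
per-gene important-region counts vs. their stated totals, and the two
per-receptor tables disagreeing for the same receptors) are left as-is;
neither quantity is used as a check.

## Numerical details and limitations

* Score-grid bin width 0.01 log2-units; exact within the discretization.
* UPGMA ties resolve by lexicographic label order (labels are sorted
  before linkage); SW co-optimal alignments resolve to the smallest
  `a_end`, then `b_end`, among up to 64 enumerated optima.
* IRLS tolerance 1e−10; NB2 ML via BFGS (gtol 1e−8) with a Nelder–Mead
  fallback; θ capped at 10⁶.
* The gap statistic uses the bounding-box uniform reference (the simplest
  published variant), not the PCA-rotated one; on data with pure-noise
  dimensions it is known to favour small K.
* The pipeline's clustering stage requires at least two varying features
  and more rows than kmax; otherwise it is skipped with a log note.
* No affine gaps, no higher-order background models, no zero-inflated or
  robust-variance count models.
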
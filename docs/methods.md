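# Methods

`descnet` models how freely written one-word descriptions of people in
short videos co-occur across stimuli. Two competing accounts of the
co-occurrence structure are implemented and compared: a low-dimensional
latent-factor representation (a small set of constructs drives all
inferences) and a high-dimensional sparse-network representation (each
pair of inferences may be uniquely linked, with most pairs conditionally
independent). Everything below is computable on synthetic corpora with
known ground truth; no external data are required.

## Data model and preprocessing

The raw unit is a record (participant, video, pause, position, word):
each participant watches a video and, at three pauses, writes up to ten
single words. Preprocessing:

1. **Cleaning.** Words are lowercased; a rule-based suffix lemmatizer with
   an exception table reduces inflected and commonly derived forms
   ("creativity" → "creative", "worried" → "worry"). Tokens with no
   lexicon entry are treated as meaningless and dropped. An optional
   edit-distance-1 spell repair against the lexicon is off by default
   because the repair target is ambiguous for short words. The lemmatizer
   is intentionally conservative: with a lexicon it only accepts a
   reduction the lexicon contains.
2. **Vocabulary filter.** A word is retained iff at least 2 distinct
   participants mention it and it appears in at least
   `ceil(0.01 * n_videos)` distinct videos. The ceiling convention makes
   the 1%-of-videos rule exact at any corpus size.
3. **Document-term matrix (DTM).** `F[v, w]` counts mentions of word *w*
   for video *v* across all participants and the selected pauses.
4. **Normalization.** Columnwise min-max (absorbs unequal rater counts per
   video), then a Winsorized-ECDF nonparanormal transform
   `z = Phi^{-1}(clip(rank/(n+1), delta_n, 1 - delta_n))` with
   `delta_n = 1/(4 n^{1/4} sqrt(pi log n))`, with average ranks so ties map
   to identical outputs.
5. **Correlation.** Pairwise Spearman correlations between word columns.

Because steps 4 are columnwise monotone and tie-preserving, the Spearman
matrix is mathematically invariant to them; the pipeline keeps the steps
(Gaussian margins are what the downstream Gaussian models assume) and the
invariance is verified to 1e-10 as a test. One caveat: once
`delta_n (n+1) > 2` (n above ~100) the Winsorization can merge several
extreme ranks into one clipped value, which perturbs Spearman entries at
the ~1e-4 level; the exact invariance holds whenever at most the single
extreme rank is clipped. A zero-variance column is an
error in the standard path and is mapped to zero correlations only inside
the permutation loop of the network-comparison test, where resampling can
remove a word's variation and all refits must share one node set.

## Latent-factor representation

**Rank selection** is Owen–Perry (2,2)-fold bi-cross-validation on the
transformed DTM: per iteration rows and columns are split in half; each
held-out block A is predicted from the complementary blocks as
`B D_k^+ C`, with `D_k` the rank-k truncated SVD of the training block,
accumulating squared error. 100 iterations by default; ties break toward
the smaller rank. On pure noise the smallest candidate wins; on planted
rank-3 data the error curve has a sharp interior minimum at 3.

**Extraction** is minimum-residual (minres): uniquenesses `psi` are
optimized (L-BFGS-B, bounds [0.005, 1], SMC start) so the top-k
eigenstructure of `S - diag(psi)` minimizes squared off-diagonal
residuals. **Rotation** is oblique oblimin via the gradient-projection
algorithm with five starts (identity plus four random orthonormal).
Factors are ordered by explained variance, signs fixed so loading sums
are nonnegative. The Spearman matrix is first projected to the nearest
PSD correlation matrix (eigenvalue clipping, diagonal renormalized) since
rank-based matrices need not be PSD.

Variance-explained shares are `diag(Phi L' L)/p`; their total equals
`tr(L Phi L')/p`, which is rotation-invariant and monotone in k.

The model-implied matrix is `L Phi L'` with unit diagonal, clipped to
[-1, 1] (clips logged).

## Sparse-network representation

The graphical lasso is solved along a descending log-spaced grid of 100
penalties from `lambda_max = max |off-diagonal S|` down to 1% of it, with
an in-package warm-started coordinate-descent solver using the same
off-diagonal-penalty convention as scikit-learn's `graphical_lasso`
(agreement verified in the test suite). Model selection uses the extended
BIC, `EBIC = -2 l(K) + E log n + 4 E gamma log p` with `gamma = 0.25` and
`n` = number of videos.

By default each distinct support along the path is **scored on its
relaxed (unpenalized) likelihood**: the Gaussian MLE with structural
zeros is computed for the support and the EBIC evaluated on that refit.
Scoring the shrunken lasso likelihood instead trades the EBIC edge
penalty against shrinkage bias on true edges and systematically
over-selects (in chain simulations at n = 2000 exact-support recovery
drops from ~96% to ~48%); the relaxed score removes that distortion, and
the returned precision matrix is the refit itself, so reported partial
correlations `P_ij = -K_ij / sqrt(K_ii K_jj)` are free of lasso bias.
`SnmSettings(refit=False)` restores the pure penalized solution. Ties in
EBIC break toward the larger penalty (sparser model). Edges are entries
with `|P_ij| > 1e-8`.

The implied matrix is the inverse precision rescaled to unit diagonal.
Strength centrality is the absolute-weight sum (standard in psychometric
networks; signed sums cancel and hide hub words). Louvain communities run
on the implied correlation matrix with negative edges dropped (modularity
requires nonnegative weights) and an optional display-style edge floor.

**Temporal dynamics** fit one network per timepoint over the words
present then — t1: the first word of pause 1; t2: the remaining pause-1
words; t3: pause 2; t4: pause 3 — compute strength centrality on each
implied matrix, and report per-word changes between consecutive
timepoints, baselining words absent at the previous timepoint at 0.

## Model comparison

SRMR is the root mean square of lower-triangle off-diagonal residuals
(diagonals are identically 1). SRMR sampling distributions follow the
parametric-resampling idea: simulate n multivariate-normal observations
from the implied matrix, take the sample correlation matrix, score its
SRMR against the observed matrix (the implied-matrix target is available
as an option). Distributions are compared with a Welch t test
(Satterthwaite df) and Cohen's d with pooled SD and a normal 95% CI.
Lightweight confirmatory fit indices use the ML discrepancy
`F = log|R_hat| - log|R_obs| + tr(R_obs R_hat^{-1}) - p` with
`T = (n-1) F`, `df = p(p-1)/2 - E` (nonzero edges count as free),
RMSEA with a noncentral-chi-square 90% CI, and CFI/TLI against the
independence baseline.

The **network-comparison test** selects the `top_m` most frequent shared
words (total mentions, ties lexicographic), fits each sample's network,
and permutes by resampling rows with replacement from the merged DTM
(matching each sample's size), refitting both networks per permutation.
The null distribution of the maximum absolute edge difference gives
familywise-corrected per-edge p-values with the add-one estimator,
`p = (1 + #{max >= |diff|}) / (n_perm + 1)`, so p-values are never 0 and
are monotone in |diff| by construction. Inside the permutation loop the
nonparanormal step is skipped (it cannot change Spearman correlations)
and the penalty grid is reduced to 30 values — a runtime choice that
leaves selection essentially unchanged because supports repeat along the
path.

## Design statistics

- Videos needed to detect a correlation r:
  `n = ceil(((z_{1-alpha/2} + z_power)/atanh r)^2 + 3)` (Fisher z). At
  r = 0.17, alpha = 0.05, power = 0.95 this gives 444, and a 5000-replicate
  bivariate-normal simulation confirms empirical power within 0.02.
- Standardized alpha of k raters from mean pairwise consensus r̄:
  `k r̄ / (1 + (k-1) r̄)`; inverse forecasting
  `k = ceil(alpha (1 - r̄)/(r̄ (1 - alpha)))`. At r̄ = 0.196: alpha(30) ≈
  0.880 and 37 raters reach 0.90.
- Maximum-variation sampling: rows L2-normalized (so wide feature blocks
  do not dominate), per-stratum quotas by largest remainder, greedy
  selection seeded with the item farthest from the stratum centroid and
  growing by maximal mean per-feature variance. Exhaustive search is
  infeasible; the greedy surrogate is validated against brute force on
  tiny instances and against 1000 random subsets (≥ 99th percentile).
- Subset sufficiency: for each subset size, resample videos without
  replacement, recompute the word covariance matrix (raw counts by
  default; a normalized option exists), and record the Spearman rho
  between vectorized lower triangles of subset and full covariance;
  report the mean curve and the smallest size exceeding the threshold.

## Synthetic corpora

Generators are pure functions of (spec, seed). Video-level latent scores
are multivariate normal with a correlation matrix implied either by a
factor structure (`L Phi L'` plus uniquenesses) or by a sparse precision
matrix; each word's margin is pushed through a zero-inflated
negative-binomial quantile (Gaussian copula). The monotone link preserves
the latent correlation ordering — the regime where the Spearman pipeline
is well-behaved — while producing realistic sparse integer counts.

Defaults: 44 participants per video, 3 pauses, words per pause drawn
negative-binomial with mean 2.91 and SD 2.34 (truncated at the ten
response boxes), and a count link with zero-inflation 0.3, NB mean 2.0,
dispersion 3.0 (~53% zeros). The link emulates the *analyzed* — filtered,
relatively frequent — words at test-scale vocabularies of 20–60 tokens,
not the long tail of a full 3000-word vocabulary, which is mostly removed
by the frequency filter anyway. Two-population corpora shift listed
pairs' partial correlations in population B (positive-definiteness
checked per pair); temporal corpora draw one latent layer per timepoint,
identical except an optional strengthening of one word's precision-row at
one timepoint, and lay tokens out so the four-timepoint split is exact.

What the generators do **not** emulate: real lexical semantics (tokens
are abstract), participant-level individual differences (counts are
video-level), spelling noise, and attention failures. Passing recovery
tests therefore show the estimators work under the stated generative
assumptions, not that real free-description data satisfy them.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make each property sharply
testable on a single CPU: support recovery at n = 2000 (p = 3 and 30);
rank recovery at 300×60 over 20 seeds; the reconstruction contrast at
V = 400, p = 40 over 20 replicates; the network-comparison test at
p = 30 with V = 200 per sample under the null (50 runs, 100 permutations)
and V = 400 with a planted 0.4 shift for power (25 runs, 200
permutations); temporal dynamics at V = 250, p = 25 over 20 seeds.
PSD repairs clip eigenvalues at 0 (1e-4 inside the glasso to keep the
likelihood bounded). Lasso convergence tolerance is 1e-5 on the working
covariance; the EBIC comparison tolerance is 1e-9 with ties to the
sparser model; BCV ties go to the smaller rank; ranking ties in word
selection are lexicographic. All randomized operations take explicit
seeds and are bit-reproducible.

## Known limitations

- **The reconstruction contrast depends on the dimensional regime.** With
  many more words than videos (the regime of the motivating design,
  p ≈ 2926 words vs 444 videos), the rank-deficient likelihood drives the
  EBIC toward very small penalties and the network model reconstructs the
  observed correlations almost perfectly, far better than a rank-limited
  factor model. At desk scale with more videos than words (V = 400,
  p = 40), the glasso stationarity condition bounds the implied matrix
  within lambda of the observed one, the EBIC cannot justify penalties
  below ~0.05, and a minres factor model at a liberal cross-validated
  rank — which *directly minimizes* the SRMR objective with ~k·p free
  parameters — absorbs more sampling noise than any positive-definite
  sparse network can. In that regime the factor model attains the lower
  in-sample SRMR, and the corresponding property test documents the
  failure honestly rather than tuning the comparison.
- EBIC with gamma = 0.25 is conservative at small n; weak true edges
  (|partial| below ~sqrt(10/n)) are routinely missed.
- The rule-based lemmatizer covers regular morphology plus a small
  exception table; irregular or creative forms pass through unchanged and
  then fall to the lexicon screen.
- Fit indices treat the implied matrix as fixed (no free-parameter SEM
  optimization), matching their use as lightweight descriptive indices.
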
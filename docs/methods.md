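# Methods

## The model and its assumptions

An ordinal trait is treated as a coarse observation of an underlying
continuous quantity. The working model fits the integer level codes
1..L directly as a Gaussian response:

    y = W a + sum_i X_i b_i + e,   e ~ N(0, s2_e I_n)

where W is the fixed-effect design (intercept plus optional
population-structure columns) and the X_i are centered dosage columns of
the candidate markers. Treating level codes as numeric is an
approximation — it assumes the levels are roughly equally spaced on the
latent scale — and it is exactly what makes the approach cheap: every
update in the multi-locus fit stays closed-form. The approximation is
best at few levels with balanced proportions and degrades as the level
distribution becomes skewed, which matches where the method performs
best in our simulations (2–4 levels, symmetric splits).

Each marker effect carries a normal prior b_i ~ N(0, s2_i) and each
prior variance a scaled hyperprior with hyperparameters (tau, omega) =
(0, 0), giving the update s2_i = (E(b_i)^2 + Var(b_i)) / 3. The /3
divisor is aggressive shrinkage: at the fixed point, markers without
signal satisfy s2_i (2 + s2_i u_i) = E(b_i)^2 (u_i = X_i' V^-1 X_i) and
collapse to the variance floor, so the fit is sparse even when the
upstream screen passes hundreds of candidates. This sparsity is the
method's false-positive control.

## Pipeline stages and the parameters that matter

| parameter | default | role |
|---|---|---|
| `p_chi2` | 0.05 | stage-1 chi-square retention threshold |
| `p_logit` | 0.05 | stage-2 logistic / proportional-odds retention |
| `tau`, `omega` | 0, 0 | hyperprior; larger omega would damp shrinkage |
| `lod_threshold` | 3.0 | significance for both the transformation and the scan |
| `candidate_p` | 0.005 | scan stage-1 retention (per-mille regime entry) |
| `max_candidates` | min(2n, m) | cap on scan stage-2 dimension |
| `var_floor` | 1e-10 | absolute floor on s2_i; a floored marker is dead |
| `tol`, `max_iter` | 1e-6, 200 | fixed-point convergence controls |

The screen is intentionally lenient (nominal 0.05 at both stages, no
multiplicity correction): its purpose is to cut m markers to a set the
multi-locus model can iterate over, not to call significance. Screening
fits are marker-only (no covariates); the single-marker framing keeps
the screen O(m) fast and matches how the retention-rate diagnostics are
defined. Both regression fits drop markers with |coefficient| > 15 on
the logit scale or non-convergence within 100 iterations — complete or
quasi-complete separation shows up as exactly this pathology (huge
effect, likelihood-ratio p near 1) and such markers carry no usable
ordering information.

## CPData prediction and the significant-set choice

CPData is predicted from the markers that reach LOD >= 3 inside the
transformation (`lod_filter=True` by default), not from every screened
candidate. This is a deliberate, load-bearing choice. CPData is by
construction a noiseless linear function of whichever marker set
predicts it; if that set is the full screened candidate list (~5% of the
panel), the downstream scan can reconstruct CPData essentially exactly,
its residual variance collapses, and LOD-based calling loses control of
false positives (in a 199 x 1,000 pilot: 1.68 per-mille unfiltered vs
0.34 per-mille filtered). Restricting prediction to the significant set
keeps the transformation's own LOD screen as the effective gatekeeper.
The unfiltered behaviour remains available via the flag for sensitivity
analysis.

A consequence worth knowing: because CPData is noiseless given its
construction set, the *magnitudes* of LOD scores in the downstream scan
saturate (the residual variance of an exact reconstruction is bounded
only by a numerical floor). Threshold crossings — and hence power and
FPR — are meaningful; the LOD values themselves are not comparable
across phenotype types and should not be interpreted as evidence
strength on CPData. On genuinely continuous phenotypes the scan's LODs
are ordinary and interpretable.

By default the scan universe after transformation is the screened
candidate set (`scan_all_markers=False`); markers eliminated by the
screen cannot re-enter, which keeps the transform-and-scan composition
coherent and fast.

## Numerical choices

- **Initialization**: s2_i(0) = var(y)/q (floored), s2_e(0) = var(y)/2,
  E(b_i)(0) = 0, Var(b_i)(0) = 3 s2_i(0) — the last makes the first
  variance update a no-op, so the declared initial variances are the
  ones the first sweep actually uses.
- **Sweep order**: marker variances, fixed effects, residual variance
  (using the previous sweep's posterior means), posterior means,
  posterior variances; V = X diag(s2_i) X' + s2_e I is rebuilt once per
  sweep. Convergence is the maximum absolute parameter change < 1e-6;
  at the fixed point every update equation is satisfied to that
  tolerance regardless of order.
- **Applying V^-1**: via the Woodbury identity when q < n, solving a
  q x q system built from the cached Gram matrix in the scaled form
  X'X + s2_e diag(1/s2_i) (stable as s2_e -> 0); dense Cholesky
  otherwise. Both routes agree to 1e-8 against a direct inverse in the
  test suite.
- **Floors and guards**: s2_i >= 1e-10 (a floored marker contributes
  nothing and its effect decays to zero); s2_e >= 1e-12 var(y) so V
  stays invertible when the candidates fit the response exactly; a
  phenotype that is constant after covariate adjustment (relative
  tolerance 1e-12) short-circuits the scan with p = 1 everywhere.
- **Fixed effects**: (W' V^-1 W)^- uses the pseudo-inverse, so a
  rank-deficient covariate design degrades gracefully instead of
  aborting. `build_covariates` nevertheless drops one Q column (the
  memberships sum to one) and enforces full rank.
- **LOD**: LOD_i = max(0, (RSS_-i − RSS) / s2_e) / (2 ln 10), with the
  other markers held at their posterior means and variance parameters
  fixed. E(b_i) = 0 gives LOD_i = 0 exactly; LOD 3 corresponds to a
  likelihood ratio of 6 ln 10 ≈ 13.82, a df-1 chi-square tail of
  ~2e-4.
- **Chi-square scan**: contingency tables over observed dosage classes
  (fractional imputed cells join the nearest class), no continuity
  correction in any table size, df = (rows−1)(cols−1); a warning is
  logged when an expected count falls below 5. Monomorphic markers get
  p = 1.
- **Discretization**: rank blocks under largest-remainder rounding,
  ties in the fractional parts resolved toward lower levels, ties in
  the phenotype broken by original order.

## What the synthetic generator emulates — and what it does not

The generator mimics an inbred association panel: 199 lines, dosages in
{0, 2}, per-marker allele frequency uniform on (0.1, 0.5), markers in
five equal chromosome blocks, and seven causal markers at fixed indices
(rescaled proportionally for panels smaller than 10,000 markers). The
default heritability profile (0.10, 0.10, 0.05, 0.08, 0.03, 0.03, 0.02)
makes three loci detectable and four weak; effects are solved from the
heritabilities by fixed-point iteration on the empirical genetic
variance, with residual variance 1.

Markers are independent by default (`rho=0`; a first-order
copy-your-neighbor option adds local LD). Real panels have extended LD,
relatedness and population structure, none of which the default
generator produces — so passing simulations demonstrate calibration and
shrinkage behaviour under clean conditions, not robustness to
confounding. The kinship-corrected scan stage and the Q-matrix
covariates exist for real-data use but are exercised only lightly by the
synthetic harness (structure estimation itself is out of scope; Q is an
input, with a PCA-free VanRaden kinship as the built-in fallback).

## Evaluation harness conventions

Replicate r of an experiment uses seed (base seed + r); every stochastic
entry point takes an explicit seed and reruns are bit-identical. QTN
matching is by exact marker index. FPR is reported per-mille of
non-causal marker tests, FP / ((m − 7) · reps) · 1000; precision, recall
and F1 are pooled over QTNs and replicates; retention rates are reported
over the threshold grid {1/m, 0.01, 0.05, 0.10}. CV uses the n−1 sample
standard deviation over the absolute mean; skewness and kurtosis use
population central moments (normal kurtosis = 3).

Problem sizes: the acceptance script runs the design at n = 199,
m = 5,000 with 40 replicates per discretization. The test suite runs
the same study conditions at reduced sizes chosen once — m = 2,000 with
15 replicates for the false-positive bounds, m = 800 with 60 replicates
per level count for the power-comparison properties, m = 1,000 with 60
seeds for parameter recovery — with statistical slack (two binomial
standard errors) scaled to the replicate counts actually run.

## Known limitations

- Level codes as a Gaussian response ignore unequal level spacing; with
  five or more levels or strongly skewed proportions the transformation
  loses its advantage over scanning the codes directly.
- The retention-rate diagnostics use the chi-square stage only for the
  threshold grid; the logistic stage is profiled at its default
  threshold.
- LOD magnitudes on CPData are not interpretable (see above).
- The proportional-odds screen assumes proportional odds; markers with
  strongly non-proportional effects may be screened out.
- Effect estimates inherit shrinkage bias (posterior means); the
  parameter-recovery test documents a ~5–10% downward bias at h² = 0.2,
  n = 199.
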
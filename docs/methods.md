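# Methods

## Model and estimators

Per gene, the subject-level pseudo-bulk expression Y (length n) is modelled
as Y = Xβ + ε with ε ~ N(0, σ²I) and X = [1, X₁, X₂]: intercept, binary
disease group, and the negative log of the subject's mean cell-type
probability. Three estimators of β₁ (the group effect) are provided.

**Frequentist.** OLS: μ̂ = (XᵀX)⁻¹XᵀY with σ̂² the unbiased residual mean
square (dof n − p) and covariance (XᵀX)⁻¹σ̂².

**Bayesian.** Conjugate Gaussian prior β ~ N(μ_β, Σ_β) with posterior

    mean = (Σ_β⁻¹ + XᵀX)⁻¹ (Σ_β⁻¹ μ_β + XᵀY)
    cov  = (Σ_β⁻¹ + XᵀX)⁻¹ σ̂²

This parameterisation adds the prior precision to XᵀX *unscaled* while the
posterior covariance carries σ̂²; it is equivalent to a textbook conjugate
update with prior covariance Σ_β·σ². It is the package default
(`scaled_prior=True`); `scaled_prior=False` gives the textbook update in
which Σ_β is taken at face value. Both conventions coincide when σ² = 1 and
in the flat-prior limit. The exact σ²/prior-scaling convention behind the
published per-gene standard errors cannot be pinned down from summary
numbers alone, which is why both are exposed; nothing downstream depends on
the choice beyond the effective prior strength.

**Hybrid (BFH).** A subset B of coefficients (here {β₁}) is Bayesian with
prior N(μ_B, Σ_B); the complement A is frequentist. Starting from the OLS
estimates, iterate until the largest absolute coefficient change is below
`tol` (default 1e-8, `max_iter` 1000, non-convergence returns
`converged=False` with a warning rather than raising):

1. y^B = Y − X_A β_A; set β_B to the conditional posterior mean of the
   regression of y^B on X_B under the prior;
2. y^F = Y − X_B β_B; set β_A to the OLS estimate of y^F on X_A.

Because both updates are linear, the fixed point solves the coupled
stationarity system

    (Σ_B⁻¹ + X_BᵀX_B) β_B + X_BᵀX_A β_A = Σ_B⁻¹μ_B + X_BᵀY
    X_AᵀX_B β_B + X_AᵀX_A β_A = X_AᵀY

and the test suite checks the iterate against a direct solve of this
system. Convergence is linear with rate governed by the canonical
correlation between the column spaces of X_A and X_B (one iteration when
they are orthogonal).

Design choices where the procedure itself is underdetermined:

* **σ² is estimated once** from the full OLS fit and held fixed across EM
  iterations and in the posterior covariance. Re-estimating σ² per
  iteration would couple the variance to a moving target for no benefit on
  a quadratic objective; the fixed choice also matches the OLS
  initialisation.
* **Standard errors.** Bayesian coordinates report the conditional
  posterior sd at convergence, sqrt(diag((Σ_B⁻¹ + X_BᵀX_B)⁻¹σ̂²));
  frequentist coordinates the sub-regression OLS SE
  sqrt(diag((X_AᵀX_A)⁻¹σ̂²)). This is the only construction consistent with
  the intended ordering hybrid SE ≤ full-Bayes marginal posterior sd
  (Gaussian conditioning never increases variance), which the tests assert
  gene-by-gene.
* **Inference** is Wald with the standard normal (z, not t): p =
  2(1 − Φ(|estimate/SE|)), CI = estimate ± 1.96·SE.
* A constant group column is a rank error, not a silent zero; empty
  Bayesian or frequentist blocks redirect the caller to the pure
  estimators.

The conditional SE is narrower than the frequentist sampling sd of the same
estimator whenever X_B correlates with X_A; its intervals are calibrated in
the Bayesian sense (prior-averaged), not uniformly over fixed β₁. The
coverage study below quantifies this under a truth-centered prior.

## Pseudo-bulk aggregation

Y[s, g] = Σ_i w_i c[g, i] / Σ_i w_i over the cells i of subject s, where
w_i ∈ [0, 1] is the upstream classifier's probability that cell i belongs
to the cell type of interest; X2[s] = −log(mean_i w_i), natural log by
default (configurable base). Weighted means, normalised by the summed
weights, are robust to unequal cell numbers per subject; counts are used
raw (no library-size normalisation or log1p) since the weights apply to
counts directly. Hard-assignment pseudo-bulk is the special case w ∈ {0,1}.

QC filters (strict inequalities at the thresholds): genes kept when mean
count across cells > 0.1; cells dropped when the detected-gene count falls
strictly below the 2nd percentile of that distribution (linear-interpolation
percentile) or the mitochondrial count fraction exceeds 10% (mitochondrial
genes by name prefix, default `MT-`/`mt-`). Cells are filtered before
genes, so the gene filter sees only surviving cells.

## Bulk-derived priors

Per gene, expression ~ intercept + group (+ covariates) by OLS on the bulk
study; the group coefficient is the prior mean of β₁. The default prior
variance is the **square root** of the coefficient's sampling variance:
bulk cohorts are large, so the raw sampling variance would concentrate the
prior far too tightly, and the square root (of a quantity ≪ 1) widens it.
This moderation is unit-inconsistent by construction, so
`moderation={sqrt|none|factor:k}` is exposed. Intercept and X₂ keep
non-informative N(0, 100) priors; genes absent from the bulk study fall
back to N(0, 100) with a log line. Bulk and single-cell gene symbols are
matched uppercased; the prior must be on the same scale as the pseudo-bulk
response (the bulk matrix is used as provided, with no implicit log
transform).

## DE calling

Per gene and method (frequentist, bayes/hybrid × non-informative/
informative), Wald summaries are adjusted per method by BH or BY
(statsmodels step-up implementations, clipped to [0, 1]). A gene is called
when p_adj < α (strict) and |estimate| ≥ est_threshold (non-strict);
defaults BY, α = 0.01, threshold 0.585 for case-study calling. The
pathway-selection rule is strict on both (p_adj < 0.01 and |estimate| >
0.585); both rules exist because they serve different steps. The 0.585
threshold is applied to the raw coefficient (it numerically equals log₂ 1.5
but is defined on the estimate scale). Per-gene numerical failures become
NaN rows, never pipeline aborts. A constant X₂ column (e.g. all weights 1)
is dropped from the design with a log line rather than tripping a rank
error.

## Spike-in benchmark

The source population emulates a large healthy single-cell panel: per-gene
base means lognormal(−2.5, 1.5) — putting roughly 40% of genes above the
10%-of-cells expression threshold, as in real atlases where most genes are
lowly expressed; per-subject lognormal(0, 0.3) multiplicative effects
shared across genes (subject-level heterogeneity is what separates
pseudo-bulk from cell-level testing); cell counts negative binomial with
dispersion 2 via a gamma–Poisson mixture. Defaults mirror a 55-subject,
1000-cells-each panel.

Each replicate samples 20 subjects without replacement, assigns 10 to
"disease", draws per-subject cell counts from Poisson(cell_mean) and
samples cells without replacement (capped at availability with a warning),
restricts to genes expressed in ≥ 10% of sampled cells, and multiplies the
disease-group counts of round(0.05 · n_eligible) randomly chosen eligible
genes by fc = 2 (the spike is applied after cell sampling; for a
multiplicative spike the order is immaterial). Calling: BH-adjusted p <
0.05 and the symmetric fold-change rule max(FC, 1/FC) > 1.5 with FC the
disease/control pseudo-bulk group-mean ratio — made two-sided so that FDR
accounting does not depend on the spike's direction. Power = TP/(TP+FN),
FDR = FP/max(TP+FP, 1), averaged over replicates. Per-replicate RNG streams
derive from (master seed, replicate index).

The packaged scale is 20 replicates × 2000 genes × 20 subjects × ~200 cells
per subject from a 25-subject, 300-cells source — chosen so the full
benchmark completes in about a minute on one core while keeping the
subject-level design identical to the study layout; power/FDR at this scale
are not comparable to full-scale numbers and the package makes no claim
that they are.

**Truth-centered priors.** The hybrid-informative arm receives, per gene, a
prior centered at the gene's true pseudo-bulk effect: (fc − 1) · base_mean ·
exp(subject_sd²/2) for spiked genes (the lognormal mean of the subject
effect enters the expectation), 0 for null genes; prior sd = 25% of the
effect with a floor of 0.05. This is the best-case prior — it measures the
headroom an informative prior offers, not what any particular bulk study
delivers.

**Null calibration.** With fc = 1 no gene carries a real effect, so every
call is false; the reported rate is the mean over replicates of
FP/max(calls, 1), i.e. the fraction of replicates with any call, which BH
at 0.05 should hold near or below 0.05.

## CI coverage study

2000 replicates of n = 20: X = [1, group, X₂] with a balanced *centered*
group contrast (±1/2, standard practice that keeps the contrast orthogonal
to the intercept) and X₂ ~ N(0, 1) redrawn per replicate; β = (1.0, 0.8,
−0.5), σ = 1, prior N(β₁, 1) on the group coefficient — centered at the
truth with variance on the noise scale. The Wald 95% interval from the
hybrid fit is checked for covering β₁. Under these conditions the
conditional-SE interval is mildly conservative (the prior contributes
information the SE does not credit) and lands near 95–96%; with an
uncentered 0/1 contrast the intercept–group collinearity would push
coverage well below nominal, which is why centered coding is the packaged
design.

## Enrichment statistics

p = P(X ≥ r) for X ~ Hypergeom(N, n, R) (survival function at r − 1), and

    z = (r − nR/N) / sqrt( R (n/N)(1 − n/N) (N − R)/(N − 1) )

— the overlap standardised by the hypergeometric mean and the
finite-population-corrected sd. This z definition reproduces all four
published pathway z-scores to 5 decimal places from their (r, R, n, N)
counts, which is what fixed the formula. Both statistics are symmetric in
(R, n). q-values are BH over the sets actually tested, so they depend on
the supplied collection; published q-values computed over a proprietary
~1.5k-term database are not comparable and are not reproduced. The
background N is a required explicit parameter.

## What the synthetic data does not capture

The generator has no dropout beyond NB sparsity, no cell-subpopulation
structure within the targeted cell type, no batch effects, no
gene–gene correlation, and its spike is a clean multiplicative shift.
Passing benchmarks therefore demonstrate correctness of the estimators and
calling machinery and the *relative* behaviour of the methods under
subject-level heterogeneity — not performance on any real tissue. Published
per-gene estimates, detected-gene counts and pathway lists from the
original cohorts require the original accessions and classifier weights and
are out of the package's reproduction scope; the deterministic worked
examples (enrichment statistics, Wald summaries from printed inputs) are
reproduced exactly.

## Other numerical choices

Matrix solves use explicit (XᵀX)⁻¹ at p ≤ 3 scale; rank checks precede
inversion and name the collinear columns via pivoted QR. Posterior
covariances are symmetrised after inversion. Writers emit UTF-8 CSV with 6
significant digits and stable row order, so identical inputs and seeds give
byte-identical outputs. Gene symbols are uppercased at matching boundaries
only and preserved verbatim in outputs.
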
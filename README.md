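# bfh — Bayesian-frequentist hybrid inference for pseudo-bulk single-cell DE

Pseudo-bulk differential expression — summarising single-cell RNA-seq counts
per subject and testing at the subject level — is the statistically sound way
to compare disease and control donors, but cohorts are small (often 10–20
donors) and power suffers. `bfh` raises power by borrowing strength from a
companion bulk RNA-seq study through a **Bayesian-frequentist hybrid (BFH)**
estimator: the disease-group coefficient carries an informative Gaussian
prior and is estimated by its posterior mean, while the nuisance
coefficients stay frequentist, and the two blocks are iterated to a joint
fixed point.

## The model

Per gene, the pseudo-bulk response over n subjects follows

```
Y = X β + ε,   ε ~ N(0, σ² I),   X = [1, X₁, X₂],   β = (β₀, β₁, β₂)
```

where Y is the probability-weighted mean expression per subject, X₁ the
disease indicator, and X₂ the negative log of the subject's mean cell-type
probability. With a conjugate prior β ~ N(μ_β, Σ_β) the posterior is

```
μ_β^new = (Σ_β⁻¹ + XᵀX)⁻¹ (Σ_β⁻¹ μ_β + XᵀY),    Σ_β^new = (Σ_β⁻¹ + XᵀX)⁻¹ σ²
```

(the prior precision enters unscaled; pass `scaled_prior=False` for the
textbook variant). The hybrid estimator starts from OLS and alternates:

1. subtract the frequentist columns' fit from Y and set β₁ to the
   conditional posterior mean given its prior;
2. subtract X₁β₁ and re-estimate (β₀, β₂) by OLS;

until the coefficients stop moving. At convergence the Bayesian coordinate
reports its conditional posterior sd and the frequentist coordinates their
sub-regression OLS SEs; Wald 95% intervals and two-sided normal p-values
follow from estimate ± 1.96·SE.

The informative prior for β₁ comes from a bulk RNA-seq study: the
covariate-adjusted group coefficient is the prior mean and the square root
of its sampling variance the prior variance (a deliberate widening of an
otherwise overconfident prior). The package also ships probability-weighted
pseudo-bulk aggregation with gene/cell QC filters, BH/BY multiple-testing
adjustment and DE calling, a hierarchical negative-binomial spike-in
benchmark measuring power and FDR, and hypergeometric gene-set
over-representation with finite-population-corrected z-scores.

## Worked example

A 22-donor cohort (10 control, 12 disease) with a weak group effect, and a
bulk-derived prior N(−0.31, 0.096) on β₁:

```python
import numpy as np
from bfh import (GaussianPrior, RegressionData, ols_fit, bayes_fit,
                 hybrid_em_fit, wald_inference, hypergeom_enrichment)

rng = np.random.default_rng(0)
n = 22
group = np.array([0]*10 + [1]*12, float)
x2 = rng.uniform(0.5, 2.0, n)            # -log mean cell-type probability
y = 1.2 - 0.3*group - 0.2*x2 + rng.normal(0, 0.45, n)
X = np.column_stack([np.ones(n), group, x2])
data = RegressionData(X, y, column_roles=("intercept", "group", "covariate"))

prior = GaussianPrior([-0.31], [[0.096]])
full_prior = GaussianPrior([0.0, -0.31, 0.0], np.diag([100.0, 0.096, 100.0]))

for label, (est, se) in {
    "frequentist": (lambda f: (f.estimate[1], f.se[1]))(ols_fit(data)),
    "bayes_inf":   (lambda f: (f.mean[1], f.se[1]))(bayes_fit(data, full_prior)),
    "hybrid_inf":  (lambda f: (f.estimate[1], f.se[1]))(hybrid_em_fit(data, [1], prior)),
}.items():
    s = wald_inference(est, se)
    print(f"{label:12s} estimate {s.estimate:+.3f}  se {s.se:.3f}  "
          f"95% CI ({s.ci_low:+.3f}, {s.ci_high:+.3f})  p {s.p:.3f}")

z, p = hypergeom_enrichment(r=10, R=219, n=38, N=12814)
print(f"enrichment   z {z:.5f}  p {p:.2e}")
```

prints

```
frequentist  estimate -0.059  se 0.145  95% CI (-0.343, +0.226)  p 0.686
bayes_inf    estimate -0.225  se 0.084  95% CI (-0.390, -0.061)  p 0.007
hybrid_inf   estimate -0.226  se 0.070  95% CI (-0.363, -0.089)  p 0.001
enrichment   z 11.72026  p 5.39e-10
```

OLS alone cannot resolve the effect at n = 22; the informative prior pulls
the estimate toward the bulk signal, and the hybrid's conditional SE (0.070)
is tighter than the full-Bayes marginal SE (0.084), giving the smallest
p-value. The enrichment line scores a 38-gene pathway overlapping a 219-gene
DE list in 10 genes against a 12,814-gene background.

The same steps are available from the shell: `bfh pseudobulk`, `bfh prior`,
`bfh fit`, `bfh simulate`, `bfh enrich` (see `bfh --help`).

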
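"""Per-gene differential-expression pipeline across the five inference modes.

For every gene the pseudo-bulk response is regressed on (intercept, group,
X2) and the group coefficient is summarised under five methods:

* ``frequentist`` — OLS;
* ``bayes_noninf`` / ``bayes_inf`` — full conjugate posterior with the
  non-informative or bulk-derived informative prior;
* ``hybrid_noninf`` / ``hybrid_inf`` — Bayesian-frequentist hybrid with the
  prior on the group coefficient only.

P-values are adjusted per method (BH or BY) and genes are called DE when
the adjusted p-value is below ``alpha`` and the absolute estimate is at
least ``est_threshold`` (defaults 0.01 and 0.585 for case-study calling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .hybrid_core import (
    GaussianPrior,
    RegressionData,
    bayes_fit,
    hybrid_em_fit,
    ols_fit,
    wald_inference,
)
from .priors import GenePrior, assemble_full_prior, noninformative_prior
from .pseudobulk import PseudoBulkTable

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "DECallConfig",
    "run_all_methods",
    "adjust_pvalues",
    "call_de",
    "compare_methods",
]

METHODS = ("frequentist", "bayes_noninf", "bayes_inf", "hybrid_noninf", "hybrid_inf")

RESULT_COLUMNS = [
    "gene",
    "method",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "p",
    "p_adj",
]


@dataclass
class DECallConfig:
    """Thresholds for DE calling: adjusted p < alpha and |estimate| >= est_threshold."""

    alpha: float = 0.01
    est_threshold: float = 0.585
    adjust: str = "BY"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.est_threshold < 0:
            raise ValueError("est_threshold must be >= 0")
        if self.adjust not in ("BH", "BY"):
            raise ValueError("adjust must be 'BH' or 'BY'")


def _design(pb: PseudoBulkTable) -> tuple[np.ndarray, int, tuple[str, ...]]:
    """Build (intercept, group, X2); a constant X2 column is dropped with a log line."""
    n = len(pb.subjects)
    cols = [np.ones(n), np.asarray(pb.X1, float)]
    roles = ["intercept", "group"]
    x2 = np.asarray(pb.X2, float)
    if np.ptp(x2) > 1e-12:
        cols.append(x2)
        roles.append("covariate")
    else:
        logger.info("X2 is constant across subjects; dropped from the design")
    return np.column_stack(cols), 1, tuple(roles)


def run_all_methods(
    pb: PseudoBulkTable,
    priors: dict[str, GenePrior] | None = None,
    methods=METHODS,
    adjust: str = "BH",
    tol: float = 1e-8,
    max_iter: int = 1000,
    scaled_prior: bool = True,
) -> pd.DataFrame:
    """Group-coefficient inference per gene and method, with adjusted p-values.

    ``priors`` maps gene name -> informative GenePrior; genes without an
    entry fall back to the non-informative prior for the *_inf methods.
    Per-gene numerical failures are quarantined as NaN rows, not raised.
    """
    priors = priors or {}
    if len(np.unique(pb.X1)) < 2:
        raise ValueError("pseudo-bulk table must contain both groups")
    X, group_idx, roles = _design(pb)
    p = X.shape[1]
    noninf = noninformative_prior(p)
    rows = []
    for j, gene in enumerate(pb.gene_names):
        data = RegressionData(X, pb.Y[:, j], column_roles=roles)
        gp = priors.get(gene)
        inf_prior = assemble_full_prior(gp, p, group_idx) if gp is not None else noninf
        for method in methods:
            try:
                est, se = _fit_one(
                    data, method, group_idx, noninf, inf_prior, tol, max_iter,
                    scaled_prior,
                )
                s = wald_inference(est, se)
                rows.append(
                    (gene, method, s.estimate, s.se, s.ci_low, s.ci_high, s.p, np.nan)
                )
            except (np.linalg.LinAlgError, ValueError) as exc:
                logger.warning("gene %s method %s failed: %s", gene, method, exc)
                rows.append((gene, method, *([np.nan] * 6)))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    for method in methods:
        mask = (df["method"] == method) & df["p"].notna()
        if mask.any():
            df.loc[mask, "p_adj"] = adjust_pvalues(df.loc[mask, "p"].to_numpy(), adjust)
    df.attrs["adjust"] = adjust
    return df


def _fit_one(data, method, group_idx, noninf, inf_prior, tol, max_iter, scaled_prior):
    if method == "frequentist":
        fit = ols_fit(data)
        return fit.estimate[group_idx], fit.se[group_idx]
    if method in ("bayes_noninf", "bayes_inf"):
        prior = noninf if method == "bayes_noninf" else inf_prior
        fit = bayes_fit(data, prior, scaled_prior=scaled_prior)
        return fit.mean[group_idx], fit.se[group_idx]
    if method in ("hybrid_noninf", "hybrid_inf"):
        prior = noninf if method == "hybrid_noninf" else inf_prior
        fit = hybrid_em_fit(
            data,
            bayes_idx=[group_idx],
            prior_B=prior.restrict([group_idx]),
            tol=tol,
            max_iter=max_iter,
            scaled_prior=scaled_prior,
        )
        return fit.estimate[group_idx], fit.se[group_idx]
    raise ValueError(f"unknown method {method!r}")


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Step-up FDR adjustment (BH) or its harmonic-factor variant (BY), clipped to [0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method)
    if key is None:
        raise ValueError("method must be 'BH' or 'BY'")
    return np.clip(multipletests(p, method=key)[1], 0.0, 1.0)


def call_de(results: pd.DataFrame, cfg: DECallConfig) -> dict[str, set[str]]:
    """DE gene sets per method: p_adj < alpha (strict) and |estimate| >= threshold."""
    out: dict[str, set[str]] = {}
    for method, sub in results.groupby("method", sort=False):
        called = sub[
            (sub["p_adj"] < cfg.alpha)
            & (sub["estimate"].abs() >= cfg.est_threshold)
        ]
        out[str(method)] = set(called["gene"])
    return out


def compare_methods(call_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise intersection and asymmetric-difference counts between call sets."""
    methods = list(call_sets)
    rows = []
    for a in methods:
        for b in methods:
            if a == b:
                continue
            inter = call_sets[a] & call_sets[b]
            only_a = call_sets[a] - call_sets[b]
            rows.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "n_a": len(call_sets[a]),
                    "n_b": len(call_sets[b]),
                    "n_common": len(inter),
                    "n_only_a": len(only_a),
                    "only_a": ";".join(sorted(only_a)),
                    "a_superset_of_b": call_sets[b] <= call_sets[a],
                }
            )
    return pd.DataFrame(rows)
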
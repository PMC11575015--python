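"""Semi-synthetic power/FDR benchmark for pseudo-bulk DE methods.

The benchmark emulates a multi-subject single-cell resource (a large panel
of healthy subjects, each with many cells): a hierarchical negative-binomial
generator provides the source population, and each replicate

1. samples ``n_subjects`` subjects without replacement and assigns
   ``per_group`` of them to an artificial "disease" group;
2. draws a per-subject target cell count from Poisson(``cell_mean``) and
   samples that many cells without replacement (capped at availability);
3. restricts to genes expressed in at least ``expr_frac`` of the sampled
   cells and spikes ``round(de_frac * n_eligible)`` of them by multiplying
   the disease-group counts by ``fc`` — these are the known true positives;
4. aggregates to pseudo-bulk, runs the inference methods, calls DE genes
   (BH-adjusted p < 0.05 and two-sided fold change > 1.5), and scores
   power = TP/(TP+FN) and FDR = FP/max(TP+FP, 1) against the spiked truth.

The generator is a parametric stand-in for a real multi-subject count
collection; real per-subject matrices can be substituted through
:class:`SourcePopulation` verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de_pipeline import DECallConfig, adjust_pvalues, run_all_methods
from .priors import GenePrior
from .pseudobulk import CellData, aggregate

logger = logging.getLogger(__name__)

__all__ = [
    "SourceParams",
    "SourcePopulation",
    "SemiSyntheticDataset",
    "PerfSummary",
    "generate_source",
    "make_semisynthetic",
    "truth_centered_priors",
    "evaluate_calls",
    "run_benchmark",
    "ci_coverage_study",
]


@dataclass
class SourceParams:
    """Hierarchical negative-binomial source-population parameters.

    Per-gene base means are lognormal (most genes lowly expressed); each
    subject carries a lognormal multiplicative effect shared across genes
    (subject-level heterogeneity); cell-level counts are negative binomial
    with a common dispersion (size) parameter, so variance = mu + mu^2/dispersion.
    Defaults mirror a large healthy panel: 55 subjects with 1000 cells each.
    """

    n_genes: int = 2000
    n_subjects: int = 55
    cells_per_subject: int = 1000
    gene_logmean_mean: float = -2.5
    gene_logmean_sd: float = 1.5
    subject_sd: float = 0.3
    dispersion: float = 2.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_subjects < 2 or self.n_genes < 1 or self.cells_per_subject < 1:
            raise ValueError("invalid source-population dimensions")


@dataclass
class SourcePopulation:
    """Per-subject gene x cell count matrices with the generator's parameters."""

    counts: dict  # subject id -> genes x cells ndarray
    gene_names: list[str]
    base_means: np.ndarray
    subject_effects: dict
    params: SourceParams

    @property
    def subjects(self) -> list:
        return list(self.counts)


@dataclass
class SemiSyntheticDataset:
    """One benchmark replicate: counts, group labels, and spike-in truth."""

    cells: CellData
    eligible: np.ndarray  # per-gene bool, expressed in >= expr_frac of cells
    spiked: np.ndarray  # per-gene bool, true positives (subset of eligible)
    spiked_fc: float
    replicate: int
    seed: int

    @property
    def truth(self) -> set[str]:
        return {g for g, s in zip(self.cells.gene_names, self.spiked) if s}

    @property
    def eligible_genes(self) -> list[str]:
        return [g for g, e in zip(self.cells.gene_names, self.eligible) if e]


@dataclass
class PerfSummary:
    """Per-replicate and averaged power/FDR, per method."""

    per_replicate: pd.DataFrame
    summary: pd.DataFrame


def generate_source(params: SourceParams, seed: int) -> SourcePopulation:
    """Draw a hierarchical NB source population, reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(params.gene_logmean_mean, params.gene_logmean_sd, params.n_genes)
    genes = [f"G{i:05d}" for i in range(params.n_genes)]
    counts = {}
    effects = {}
    for s in range(params.n_subjects):
        sid = f"S{s:03d}"
        eff = rng.lognormal(0.0, params.subject_sd)
        mu = base * eff
        # NB via gamma-Poisson mixture: cell x gene rates, then transpose
        lam = rng.gamma(
            params.dispersion,
            mu / params.dispersion,
            size=(params.cells_per_subject, params.n_genes),
        )
        counts[sid] = rng.poisson(lam).T.astype(np.int32)
        effects[sid] = eff
    return SourcePopulation(
        counts=counts,
        gene_names=genes,
        base_means=base,
        subject_effects=effects,
        params=params,
    )


def make_semisynthetic(
    src: SourcePopulation,
    n_subjects: int = 20,
    per_group: int = 10,
    cell_mean: float = 1000,
    de_frac: float = 0.05,
    fc: float = 2.0,
    expr_frac: float = 0.10,
    seed: int = 0,
    replicate: int = 0,
) -> SemiSyntheticDataset:
    """One spike-in replicate sampled from the source population."""
    if n_subjects > len(src.counts):
        raise ValueError(
            f"requested {n_subjects} subjects but source has {len(src.counts)}"
        )
    if per_group >= n_subjects:
        raise ValueError("per_group must be smaller than n_subjects")
    rng = np.random.default_rng([seed, replicate])
    chosen = list(rng.choice(src.subjects, size=n_subjects, replace=False))
    disease = set(chosen[:per_group])

    blocks, subj_ids = [], []
    for sid in chosen:
        mat = src.counts[sid]
        avail = mat.shape[1]
        target = int(rng.poisson(cell_mean))
        if target > avail:
            logger.warning(
                "subject %s: requested %d cells, only %d available", sid, target, avail
            )
            target = avail
        target = max(target, 1)
        idx = rng.choice(avail, size=target, replace=False)
        blocks.append(mat[:, idx])
        subj_ids.extend([sid] * target)
    counts = np.concatenate(blocks, axis=1).astype(float)
    subj_ids = np.asarray(subj_ids)

    eligible = (counts > 0).mean(axis=1) >= expr_frac
    n_spike = int(round(de_frac * int(eligible.sum())))
    eligible_idx = np.flatnonzero(eligible)
    spike_idx = rng.choice(eligible_idx, size=n_spike, replace=False)
    spiked = np.zeros(counts.shape[0], dtype=bool)
    spiked[spike_idx] = True

    disease_cells = np.isin(subj_ids, list(disease))
    counts[np.ix_(spiked, disease_cells)] *= fc

    cells = CellData(
        counts=counts,
        gene_names=list(src.gene_names),
        subject_id=subj_ids,
        group={sid: (1 if sid in disease else 0) for sid in chosen},
        weight=np.ones(counts.shape[1]),
    )
    return SemiSyntheticDataset(
        cells=cells,
        eligible=eligible,
        spiked=spiked,
        spiked_fc=fc,
        replicate=replicate,
        seed=seed,
    )


def truth_centered_priors(
    ds: SemiSyntheticDataset,
    src: SourcePopulation,
    rel_sd: float = 0.25,
    sd_floor: float = 0.05,
) -> dict[str, GenePrior]:
    """Informative priors centered at each gene's true spike effect.

    The expected pseudo-bulk level of gene g is base_mean * E[subject
    effect] = base_mean * exp(subject_sd^2 / 2); a multiplicative spike of
    ``fc`` in the disease group therefore shifts the group coefficient by
    (fc - 1) times that level.  Spiked genes get that shift as prior mean,
    unspiked genes get 0; the prior sd is ``rel_sd`` of the effect with a
    floor of ``sd_floor``.
    """
    level = src.base_means * np.exp(src.params.subject_sd**2 / 2.0)
    effect = np.where(ds.spiked, (ds.spiked_fc - 1.0) * level, 0.0)
    sd = np.maximum(rel_sd * np.abs(effect), sd_floor)
    return {
        g: GenePrior(gene=g, mean=float(m), variance=float(s**2))
        for g, m, s in zip(src.gene_names, effect, sd)
    }


def evaluate_calls(calls: dict[str, set[str]], truth: set[str]) -> pd.DataFrame:
    """Power and FDR per method against the spiked-gene truth set."""
    if not truth:
        raise ValueError("empty truth set")
    rows = []
    for method, called in calls.items():
        tp = len(called & truth)
        fp = len(called - truth)
        fn = len(truth - called)
        rows.append(
            {
                "method": method,
                "power": tp / (tp + fn),
                "fdr": fp / max(tp + fp, 1),
                "n_called": len(called),
            }
        )
    return pd.DataFrame(rows)


def _fold_changes(pb) -> pd.Series:
    """Disease/control pseudo-bulk group-mean ratio per gene."""
    dis = pb.Y[np.asarray(pb.X1) == 1].mean(axis=0)
    con = pb.Y[np.asarray(pb.X1) == 0].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(con > 0, dis / np.maximum(con, 1e-300), np.inf)
        fc = np.where((con == 0) & (dis == 0), 1.0, fc)
    return pd.Series(fc, index=pb.gene_names)


def _call_with_fc(results: pd.DataFrame, fc: pd.Series, alpha: float, fc_cut: float):
    """BH p < alpha combined with the symmetric fold-change rule max(FC, 1/FC) > fc_cut."""
    with np.errstate(divide="ignore"):
        sym = np.maximum(fc, 1.0 / fc)
    passing_fc = set(fc.index[sym > fc_cut])
    out = {}
    for method, sub in results.groupby("method", sort=False):
        sig = set(sub.loc[sub["p_adj"] < alpha, "gene"])
        out[str(method)] = sig & passing_fc
    return out


def run_benchmark(
    src: SourcePopulation,
    n_reps: int = 20,
    methods=("frequentist", "hybrid_inf"),
    n_subjects: int = 20,
    per_group: int = 10,
    cell_mean: float = 1000,
    de_frac: float = 0.05,
    fc: float = 2.0,
    expr_frac: float = 0.10,
    alpha: float = 0.05,
    fc_cut: float = 1.5,
    seed: int = 0,
    keep_calls: bool = False,
):
    """Replicate the spike-in study: returns a PerfSummary (and call sets).

    Each replicate derives its RNG from (seed, replicate index).  Inference
    runs on the eligible genes only; p-values are BH-adjusted per method.
    """
    per_rep = []
    all_calls = []
    for rep in range(n_reps):
        ds = make_semisynthetic(
            src,
            n_subjects=n_subjects,
            per_group=per_group,
            cell_mean=cell_mean,
            de_frac=de_frac,
            fc=fc,
            expr_frac=expr_frac,
            seed=seed,
            replicate=rep,
        )
        pb = aggregate(ds.cells.subset(gene_mask=ds.eligible))
        priors = truth_centered_priors(ds, src)
        results = run_all_methods(pb, priors=priors, methods=methods, adjust="BH")
        calls = _call_with_fc(results, _fold_changes(pb), alpha, fc_cut)
        perf = evaluate_calls(calls, ds.truth)
        perf.insert(0, "replicate", rep)
        perf["n_eligible"] = int(ds.eligible.sum())
        perf["n_spiked"] = int(ds.spiked.sum())
        per_rep.append(perf)
        if keep_calls:
            all_calls.append(calls)
    per_rep = pd.concat(per_rep, ignore_index=True)
    summary = (
        per_rep.groupby("method", sort=False)[["power", "fdr"]].mean().reset_index()
    )
    out = PerfSummary(per_replicate=per_rep, summary=summary)
    return (out, all_calls) if keep_calls else out


def ci_coverage_study(
    n_reps: int = 2000,
    n: int = 20,
    beta: tuple[float, float, float] = (1.0, 0.8, -0.5),
    sigma: float = 1.0,
    prior_var: float = 1.0,
    seed: int = 0,
) -> dict:
    """Empirical 95% CI coverage of the hybrid group coefficient.

    Simulates Y = X beta + N(0, sigma^2) with a balanced centered group
    contrast (+-1/2) and a standard-normal covariate, puts a N(beta_1,
    prior_var) prior on the group coefficient (truth-centered), fits the
    hybrid and checks whether the Wald 95% CI covers beta_1.
    """
    from .hybrid_core import GaussianPrior, RegressionData, hybrid_em_fit, wald_inference

    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, float)
    half = n // 2
    group = np.concatenate([np.full(half, 0.5), np.full(n - half, -0.5)])
    prior = GaussianPrior([beta[1]], [[prior_var]])
    covered = 0
    for _ in range(n_reps):
        x2 = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), group, x2])
        Y = X @ beta + sigma * rng.standard_normal(n)
        fit = hybrid_em_fit(RegressionData(X, Y), bayes_idx=[1], prior_B=prior)
        s = wald_inference(fit.estimate[1], fit.se[1])
        covered += int(s.ci_low <= beta[1] <= s.ci_high)
    coverage = covered / n_reps
    return {"coverage": coverage, "n_reps": n_reps, "n": n, "prior_var": prior_var}
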
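"""Bootstrap surrogate-data assessment of a real labeled expression matrix.

The surrogate pipeline asks how robust a pathway test is on *this* dataset at
reduced sample sizes.  A reference list is computed at full sample size (its
significant pathways are treated as true positives, the rest as true
negatives); bootstrap subsamples at smaller per-group sizes are then retested
and scored against the reference, yielding a power curve over sample size.
An ordinary least-squares regression of the distance to convergence
(1 - power) on sample size predicts where the curve would reach full power --
a method-specific optimal sample size.  Two descriptive summaries round the
pipeline off: the within-pathway correlation profile and the distribution of
detection calls estimated by per-gene t tests with Benjamini--Hochberg
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .containers import GroupedExpression, PathwayCollection
from .pathway_tests import TestResult, gene_t_statistics, test_pathways

__all__ = [
    "ReferenceList",
    "SurrogateResult",
    "RegressionFit",
    "build_reference_list",
    "bootstrap_subsample",
    "confusion_vs_reference",
    "power_curve",
    "optimal_sample_size_regression",
    "pathway_correlation_profile",
    "estimate_dc_distribution",
]


@dataclass
class ReferenceList:
    """Full-sample p-values with their significance flags (flag <=> p <= alpha)."""

    p_values: dict[str, float]
    significant: dict[str, bool]
    alpha: float
    method: str

    def __post_init__(self) -> None:
        for name, p in self.p_values.items():
            if self.significant[name] != (p <= self.alpha):
                raise ValueError(f"flag inconsistent with p-value for {name!r}")


@dataclass
class SurrogateResult:
    sample_size: int
    method: str
    power: float
    fpr: float
    n_significant: float
    sd_power: float
    sd_fpr: float
    n_bootstrap: int


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    predicted_n_at_zero: float
    f_statistic: float
    p_value: float
    undefined: bool


def build_reference_list(
    data: GroupedExpression,
    pathways: PathwayCollection,
    method: str,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ReferenceList:
    results = test_pathways(data, pathways, method, B=B, alpha=alpha, seed=seed)
    pvals = {r.pathway: r.p_value for r in results}
    flags = {r.pathway: r.p_value <= alpha for r in results}
    return ReferenceList(pvals, flags, alpha, method)


def bootstrap_subsample(
    data: GroupedExpression, m_per_group: int, seed: int
) -> GroupedExpression:
    """Draw m columns with replacement within each group (labels preserved)."""
    if m_per_group < 2:
        raise ValueError("m_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    treat = data.treatment_mask
    control_cols = np.flatnonzero(~treat)
    treat_cols = np.flatnonzero(treat)
    picked = np.concatenate([
        rng.choice(control_cols, size=m_per_group, replace=True),
        rng.choice(treat_cols, size=m_per_group, replace=True),
    ])
    return data.subset_samples(picked)


def confusion_vs_reference(
    results: Sequence[TestResult],
    reference: ReferenceList,
    alpha: float,
) -> tuple[int, int, int, int, float, float]:
    """(TP, FP, TN, FN, power, fpr) of ``results`` scored against the reference."""
    names = {r.pathway for r in results}
    if names != set(reference.p_values):
        raise ValueError("result pathways do not match the reference list")
    tp = fp = tn = fn = 0
    for res in results:
        predicted = res.p_value <= alpha
        truth = reference.significant[res.pathway]
        if predicted and truth:
            tp += 1
        elif predicted and not truth:
            fp += 1
        elif not predicted and not truth:
            tn += 1
        else:
            fn += 1
    power = tp / (tp + fn) if (tp + fn) else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    return tp, fp, tn, fn, power, fpr


def power_curve(
    data: GroupedExpression,
    pathways: PathwayCollection,
    method: str,
    sample_sizes: Sequence[int],
    n_bootstrap: int = 50,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    reference: ReferenceList | None = None,
) -> list[SurrogateResult]:
    """Confusion-averaged power/FPR per probed per-group sample size."""
    max_m = min(data.n1, data.n2)
    for m in sample_sizes:
        if m > max_m:
            raise ValueError(f"sample size {m} exceeds available per-group n {max_m}")
    if reference is None:
        reference = build_reference_list(data, pathways, method, B, alpha, seed)
    seeds = np.random.SeedSequence(seed).generate_state(
        len(sample_sizes) * n_bootstrap * 2
    ) % (2**31)
    out = []
    k = 0
    for m in sample_sizes:
        powers, fprs, counts = [], [], []
        for _ in range(n_bootstrap):
            sub = bootstrap_subsample(data, m, int(seeds[k])); k += 1
            results = test_pathways(
                sub, pathways, method, B=B, alpha=alpha, seed=int(seeds[k])
            ); k += 1
            *_, pw_est, fpr_est = confusion_vs_reference(results, reference, alpha)
            powers.append(pw_est)
            fprs.append(fpr_est)
            counts.append(sum(r.p_value <= alpha for r in results))
        out.append(
            SurrogateResult(
                sample_size=int(m),
                method=method,
                power=float(np.nanmean(powers)),
                fpr=float(np.nanmean(fprs)),
                n_significant=float(np.mean(counts)),
                sd_power=float(np.nanstd(powers, ddof=1)) if n_bootstrap > 1 else 0.0,
                sd_fpr=float(np.nanstd(fprs, ddof=1)) if n_bootstrap > 1 else 0.0,
                n_bootstrap=n_bootstrap,
            )
        )
    return out


def optimal_sample_size_regression(
    points: Sequence[tuple[float, float]],
) -> RegressionFit:
    """OLS of distance-to-convergence on sample size; zero-crossing predicts n.

    Returns the slope, intercept, the predicted sample size where the fitted
    line meets zero distance to convergence (``-intercept/slope``), and the
    regression F statistic with its p-value.  A zero slope flags the
    prediction as undefined.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (sample_size, distance) points")
    if np.unique(pts[:, 0]).size < 2:
        raise ValueError("need at least two distinct sample sizes")
    x, y = pts[:, 0], pts[:, 1]
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    undefined = slope == 0.0
    predicted = float("nan") if undefined else -intercept / slope
    fstat = float(fit.fvalue) if np.ndim(fit.fvalue) == 0 else float(np.squeeze(fit.fvalue))
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        predicted_n_at_zero=predicted,
        f_statistic=fstat,
        p_value=float(fit.f_pvalue),
        undefined=undefined,
    )


def _mean_offdiag_correlation(values: np.ndarray) -> float:
    corr = np.corrcoef(values)
    off = ~np.eye(corr.shape[0], dtype=bool)
    return float(np.nanmean(corr[off]))


def pathway_correlation_profile(
    data: GroupedExpression,
    pathways: PathwayCollection,
    max_exact_genes: int = 2000,
    n_pairs: int = 100_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Per-pathway mean pairwise Pearson correlation, plus the overall mean.

    The table is sorted descending by mean correlation.  The overall mean
    over all gene pairs is exact up to ``max_exact_genes`` genes and is
    estimated from ``n_pairs`` seeded random pairs above that.  Constant
    genes are excluded with a warning.
    """
    sd = data.values.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) excluded from correlations",
            RuntimeWarning,
            stacklevel=2,
        )
    rows = []
    for pw in pathways:
        idx = data.gene_indices(pw.genes)
        idx = idx[~constant[idx]]
        if idx.size < 2:
            rows.append((pw.name, float("nan")))
            continue
        rows.append((pw.name, _mean_offdiag_correlation(data.values[idx])))
    table = pd.DataFrame(rows, columns=["pathway", "mean_correlation"])
    table = table.sort_values("mean_correlation", ascending=False).reset_index(
        drop=True
    )

    usable = np.flatnonzero(~constant)
    if usable.size <= max_exact_genes:
        overall = _mean_offdiag_correlation(data.values[usable])
    else:
        rng = np.random.default_rng(seed)
        a = rng.choice(usable, size=n_pairs)
        b = rng.choice(usable, size=n_pairs)
        keep = a != b
        a, b = a[keep], b[keep]
        centered = data.values - data.values.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        overall = float(
            np.mean(
                np.einsum("ij,ij->i", centered[a], centered[b])
                / (norms[a] * norms[b])
            )
        )
    return table, overall


def estimate_dc_distribution(
    data: GroupedExpression,
    pathways: PathwayCollection,
    q: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Detection call per pathway from BH-corrected per-gene t tests.

    Per-gene two-sided p-values from the pooled-variance t statistic are
    corrected with Benjamini--Hochberg at level ``q``; each pathway's DC is
    the fraction of its member genes rejected, and the mean DC over pathways
    is returned alongside the table.
    """
    t = gene_t_statistics(data)
    df = data.n1 + data.n2 - 2
    pvals = 2.0 * sps.t.sf(np.abs(t), df)
    rejected = multipletests(pvals, alpha=q, method="fdr_bh")[0]
    rej_index = {g: bool(r) for g, r in zip(data.gene_ids, rejected)}
    rows = []
    for pw in pathways:
        dc = sum(rej_index[g] for g in pw.genes) / pw.size
        rows.append((pw.name, pw.size, dc))
    table = pd.DataFrame(rows, columns=["pathway", "size", "detection_call"])
    return table, float(table["detection_call"].mean()) if len(table) else float("nan")
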
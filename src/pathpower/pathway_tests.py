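"""Pathway-level differential-expression tests with permutation nulls.

Three tests over a two-group expression matrix:

* **sum of t-square** (self-contained, univariate): the sum over member
  genes of squared pooled-variance two-sample t statistics.
* **Hotelling's T^2** (self-contained, multivariate):
  ``T^2 = n1 n2 / (n1 + n2) * d' S*^{-1} d`` with ``d`` the difference of
  group mean vectors and ``S*`` the pooled covariance shrunk toward its
  diagonal (Schaefer--Strimmer analytic intensity), so the statistic exists
  even when the pathway has more genes than samples.
* **GSEA** (competitive): the enrichment score -- the extremal value of a
  weighted running sum over the ranked gene list -- scored two-sided on |ES|
  against a permutation null.

Significance of the self-contained statistics comes from sample-label
permutations.  GSEA defaults to the same sample-label null (which preserves
gene-gene correlation); a gene-label null (random member sets of the same
size) is also provided but is anti-conservative on correlated data.  All
p-values use the add-one estimator
``p = (1 + #{permuted >= observed}) / (1 + B)`` and therefore never return 0.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import comb

from .containers import GroupedExpression, PathwayCollection

__all__ = [
    "TestResult",
    "ShrinkageEstimate",
    "METHODS",
    "gene_t_statistics",
    "sum_t_square",
    "pooled_covariance",
    "shrinkage_precision",
    "hotelling_t2",
    "gsea_enrichment_score",
    "sample_label_permutation_p",
    "gene_label_permutation_p",
    "test_pathways",
]

METHODS = ("gsea", "hotelling", "sum_t_square")
_ALIASES = {"sumt2": "sum_t_square", "sum-t-square": "sum_t_square",
            "t2": "hotelling", "hotelling_t2": "hotelling"}


@dataclass
class TestResult:
    pathway: str
    method: str
    statistic: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


@dataclass
class ShrinkageEstimate:
    """Shrunk precision matrix with the analytic intensity used to build it."""

    precision: np.ndarray
    shrinkage_intensity: float


def canonical_method(method: str) -> str:
    m = method.lower().replace(" ", "_")
    m = _ALIASES.get(m, m)
    if m not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return m


# ----------------------------------------------------------------------
# gene-wise statistics
# ----------------------------------------------------------------------

def _pooled_t(values: np.ndarray, treat_mask: np.ndarray,
              warn: bool = False) -> np.ndarray:
    """Pooled-variance two-sample t per row; zero-variance rows give t = 0."""
    x = values[:, ~treat_mask]
    y = values[:, treat_mask]
    n1, n2 = x.shape[1], y.shape[1]
    diff = y.mean(axis=1) - x.mean(axis=1)
    sp2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(diff)
    ok = denom > 0
    if warn and not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} gene(s) with zero pooled variance; t set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    t[ok] = diff[ok] / denom[ok]
    return t


def gene_t_statistics(data: GroupedExpression) -> np.ndarray:
    """Pooled-variance two-sample t statistic for every gene.

    ``t_i = (ybar_i - xbar_i) / (s_p,i * sqrt(1/n1 + 1/n2))``; genes with
    zero pooled variance get t = 0 with a warning (keeps the sum-of-t-square
    statistic finite and is conservative).
    """
    if data.n1 < 2 or data.n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    return _pooled_t(data.values, data.treatment_mask, warn=True)


def sum_t_square(data: GroupedExpression, gene_set: Sequence[str]) -> float:
    """Sum over member genes of squared gene-wise t statistics."""
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    idx = data.gene_indices(gene_set)
    t = gene_t_statistics(data)
    return float(np.sum(t[idx] ** 2))


# ----------------------------------------------------------------------
# Hotelling's T^2 with shrinkage
# ----------------------------------------------------------------------

def pooled_covariance(data: GroupedExpression, gene_set: Sequence[str]
                      ) -> np.ndarray:
    """Pooled within-group covariance ``((n1-1)S1 + (n2-1)S2)/(n1+n2-2)``."""
    if data.n1 < 2 or data.n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    idx = data.gene_indices(gene_set)
    treat = data.treatment_mask
    x = data.values[np.ix_(idx, np.flatnonzero(~treat))]
    y = data.values[np.ix_(idx, np.flatnonzero(treat))]
    n1, n2 = x.shape[1], y.shape[1]
    s1 = np.atleast_2d(np.cov(x, ddof=1))
    s2 = np.atleast_2d(np.cov(y, ddof=1))
    return ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)


def _group_centered(data: GroupedExpression, idx: np.ndarray) -> np.ndarray:
    treat = data.treatment_mask
    sub = data.values[idx]
    centered = sub.copy()
    centered[:, ~treat] -= sub[:, ~treat].mean(axis=1, keepdims=True)
    centered[:, treat] -= sub[:, treat].mean(axis=1, keepdims=True)
    return centered


def shrinkage_precision(
    data: GroupedExpression,
    gene_set: Sequence[str],
    force_intensity: float | None = None,
) -> ShrinkageEstimate:
    """Inverse of the diagonally-shrunk pooled covariance.

    The pooled correlation off-diagonals are shrunk toward zero with the
    analytic intensity ``lambda* = sum var_hat(r_ij) / sum r_ij^2`` (clipped
    to [0, 1]; defined as 1 when all correlations vanish), the
    "diagonal, unequal variance" target: pooled variances are kept as they
    are.  ``force_intensity`` overrides the analytic value (0 bypasses
    shrinkage entirely).
    """
    if len(gene_set) < 1:
        raise ValueError("gene set is empty")
    idx = data.gene_indices(gene_set)
    s_pooled = pooled_covariance(data, gene_set)
    variances = np.diag(s_pooled).copy()
    degenerate = [g for g, v in zip(gene_set, variances) if v <= 0]
    if degenerate:
        raise ValueError(
            f"gene(s) with zero pooled variance (constant within groups): "
            f"{degenerate[:5]}"
        )
    p = len(gene_set)
    if p == 1:
        lam = 0.0 if force_intensity is None else float(force_intensity)
        return ShrinkageEstimate(np.array([[1.0 / variances[0]]]), lam)

    d = np.sqrt(variances)
    corr = s_pooled / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    if force_intensity is not None:
        lam = float(np.clip(force_intensity, 0.0, 1.0))
    else:
        # variance of r_ij estimated from centered standardized products
        n = data.values.shape[1]
        z = _group_centered(data, idx) / d[:, None]
        w_bar = (z @ z.T) / n
        w2 = (z**2) @ (z**2).T / n
        var_w = w2 - w_bar**2
        var_r = n**2 / (n - 1) ** 3 * var_w
        denom = float(np.sum(corr[off] ** 2))
        lam = 1.0 if denom == 0 else float(np.clip(np.sum(var_r[off]) / denom, 0, 1))
    shrunk_corr = (1.0 - lam) * corr
    np.fill_diagonal(shrunk_corr, 1.0)
    shrunk_cov = shrunk_corr * np.outer(d, d)
    precision = np.linalg.inv(shrunk_cov)
    return ShrinkageEstimate((precision + precision.T) / 2.0, lam)


def hotelling_t2(
    data: GroupedExpression,
    gene_set: Sequence[str],
    force_intensity: float | None = None,
) -> float:
    """Shrinkage Hotelling ``T^2 = n1 n2/(n1+n2) d' S*^{-1} d`` (>= 0)."""
    idx = data.gene_indices(gene_set)
    treat = data.treatment_mask
    d = (
        data.values[np.ix_(idx, np.flatnonzero(treat))].mean(axis=1)
        - data.values[np.ix_(idx, np.flatnonzero(~treat))].mean(axis=1)
    )
    est = shrinkage_precision(data, gene_set, force_intensity=force_intensity)
    n1, n2 = data.n1, data.n2
    return float(n1 * n2 / (n1 + n2) * d @ est.precision @ d)


# ----------------------------------------------------------------------
# GSEA
# ----------------------------------------------------------------------

def gsea_enrichment_score(
    ranked_stats: np.ndarray,
    set_membership: np.ndarray,
    weight_exponent: float = 1.0,
) -> float:
    """Signed extremum of the weighted running sum over a ranked gene list.

    A member at rank *i* adds ``|stat_i|^w / N_R``; a non-member subtracts
    ``1 / (N - N_H)``.  The ES is the running-sum value of maximal absolute
    deviation from zero (sign kept).
    """
    stats = np.asarray(ranked_stats, dtype=float)
    member = np.asarray(set_membership, dtype=bool)
    if stats.shape != member.shape or stats.ndim != 1:
        raise ValueError("ranked_stats and set_membership must be equal-length 1-d")
    n = stats.size
    n_hit = int(member.sum())
    if n_hit == 0:
        raise ValueError("gene set has no members in the ranked list")
    weights = np.abs(stats) ** weight_exponent
    n_r = float(weights[member].sum())
    if n_r == 0.0:
        raise ValueError(
            "all member statistics are zero; the weighted ES is undefined"
        )
    miss_pen = 1.0 / (n - n_hit) if n_hit < n else 0.0
    increments = np.where(member, weights / n_r, -miss_pen)
    running = np.cumsum(increments)
    return float(running[np.argmax(np.abs(running))])


def _es_batch(ranked_weights: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Vectorized ES for a batch of membership masks over one ranked list."""
    n = ranked_weights.size
    hit = masks * ranked_weights[None, :]
    n_r = hit.sum(axis=1, keepdims=True)
    if np.any(n_r == 0.0):
        raise ValueError("member set with all-zero statistics")
    n_hit = masks.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        miss_pen = np.where(n_hit < n, 1.0 / (n - n_hit), 0.0)
    inc = hit / n_r - (~masks) * miss_pen
    running = np.cumsum(inc, axis=1)
    pos = np.argmax(np.abs(running), axis=1)
    return running[np.arange(masks.shape[0]), pos]


# ----------------------------------------------------------------------
# permutation nulls
# ----------------------------------------------------------------------

def _permuted_masks(mask: np.ndarray, B: int, rng: np.random.Generator
                    ) -> np.ndarray:
    """B uniform label permutations of a boolean group mask (columns)."""
    n = mask.size
    out = np.empty((B, n), dtype=bool)
    for b in range(B):
        out[b] = mask[rng.permutation(n)]
    return out


def sample_label_permutation_p(
    data: GroupedExpression,
    gene_set: Sequence[str],
    statistic_fn: Callable[[GroupedExpression, Sequence[str]], float],
    B: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> float:
    """Add-one permutation p-value under uniform sample-label permutation.

    ``statistic_fn(data, gene_set)`` is recomputed in full for every
    relabeling; group sizes are preserved.  With ``exhaustive=True`` all
    distinct assignments of the treatment labels are enumerated instead of
    sampled (p becomes #{stat >= observed} / #assignments, the observed
    assignment included).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    observed = statistic_fn(data, gene_set)
    mask = data.treatment_mask
    n = mask.size

    def stat_for(mask_b: np.ndarray) -> float:
        labels = np.where(mask_b, data.treatment_label, data.control_label)
        relabeled = GroupedExpression(data.values, data.gene_ids, labels)
        return statistic_fn(relabeled, gene_set)

    if exhaustive:
        n2 = int(mask.sum())
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n2):
            mask_b = np.zeros(n, dtype=bool)
            mask_b[list(combo)] = True
            total += 1
            if stat_for(mask_b) >= observed - 1e-12:
                count += 1
        return count / total

    rng = np.random.default_rng(seed)
    exceed = 0
    for mask_b in _permuted_masks(mask, B, rng):
        if stat_for(mask_b) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + B)


def gene_label_permutation_p(
    all_gene_stats: np.ndarray,
    set_size: int,
    observed_es: float,
    B: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    exhaustive: bool = False,
) -> float:
    """Two-sided gene-label permutation p-value for a GSEA enrichment score.

    Random member sets of ``set_size`` are drawn from the ranked universe
    (equivalent to permuting gene labels for a single set); significance is
    on |ES|.  ``exhaustive=True`` enumerates every subset instead (only
    sensible for tiny universes).
    """
    stats = np.sort(np.asarray(all_gene_stats, dtype=float))[::-1]
    n = stats.size
    if not 0 < set_size < n:
        raise ValueError("set_size must satisfy 0 < set_size < universe size")
    weights = np.abs(stats) ** weight_exponent
    if exhaustive:
        total = int(comb(n, set_size, exact=True))
        masks = np.zeros((total, n), dtype=bool)
        for row, combo in enumerate(itertools.combinations(range(n), set_size)):
            masks[row, list(combo)] = True
        es = _es_batch(weights, masks)
        return (1 + int(np.sum(np.abs(es) >= abs(observed_es) - 1e-12))) / (1 + total)
    rng = np.random.default_rng(seed)
    masks = np.zeros((B, n), dtype=bool)
    for b in range(B):
        masks[b, rng.choice(n, size=set_size, replace=False)] = True
    es = _es_batch(weights, masks)
    return (1 + int(np.sum(np.abs(es) >= abs(observed_es)))) / (1 + B)


# ----------------------------------------------------------------------
# driver
# ----------------------------------------------------------------------

def _child_seeds(seed: int, k: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(k) % (2**31)]


def _rank_descending(t: np.ndarray) -> np.ndarray:
    """Order indices by descending statistic; ties break by gene order."""
    return np.argsort(-t, kind="stable")


def test_pathways(
    data: GroupedExpression,
    pathways: PathwayCollection,
    method: str,
    B: int = 1000,
    alpha: float = 0.05,
    background: GroupedExpression | None = None,
    seed: int = 0,
    weight_exponent: float = 1.0,
    gsea_null: str = "sample",
) -> list[TestResult]:
    """One :class:`TestResult` per pathway.

    For GSEA the ranked list spans the pathway universe plus the background
    genes when a background matrix is supplied (the ST I setting); otherwise
    the complement of each pathway inside ``data`` is the background.  The
    GSEA null is two-sided on |ES| and defaults to sample-label permutation
    (``gsea_null="sample"``), which preserves gene-gene correlation and keeps
    the false positive rate controlled on correlated null data; the
    gene-label (random member set) null of
    :func:`gene_label_permutation_p` is available as ``gsea_null="gene"`` but
    is anti-conservative whenever genes within a set are correlated.  The
    ``alpha`` argument is carried for downstream significance counting and
    does not influence the statistics.
    """
    del alpha  # recorded by callers; the tests themselves are level-free
    method = canonical_method(method)
    pathways.validate_against(data.gene_ids)
    seeds = _child_seeds(seed, max(len(pathways), 1))
    results: list[TestResult] = []

    if method == "sum_t_square":
        treat = data.treatment_mask
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t_obs = _pooled_t(data.values, treat)
        idx_lists = [data.gene_indices(pw.genes) for pw in pathways]
        observed = np.array([float(np.sum(t_obs[ix] ** 2)) for ix in idx_lists])
        rng = np.random.default_rng(seeds[0])
        exceed = np.zeros(len(observed), dtype=int)
        for mask_b in _permuted_masks(treat, B, rng):
            t_b = _pooled_t(data.values, mask_b)
            t2 = t_b**2
            stats_b = np.array([float(np.sum(t2[ix])) for ix in idx_lists])
            exceed += stats_b >= observed
        pvals = (1 + exceed) / (1 + B)
        for pw, stat, p in zip(pathways, observed, pvals):
            results.append(TestResult(pw.name, method, float(stat), float(p), B))
        return results

    if method == "hotelling":
        for pw, s in zip(pathways, seeds):
            stat = hotelling_t2(data, pw.genes)
            p = sample_label_permutation_p(
                data, pw.genes, lambda d, gs: hotelling_t2(d, gs), B=B, seed=s
            )
            results.append(TestResult(pw.name, method, stat, p, B))
        return results

    # GSEA
    if background is not None:
        if not np.array_equal(background.group_labels, data.group_labels):
            raise ValueError("background must share the sample labels of data")
        universe_values = np.vstack([data.values, background.values])
        universe_ids = data.gene_ids + background.gene_ids
        universe = GroupedExpression(universe_values, universe_ids, data.group_labels)
    else:
        universe = data
    member_idx = [universe.gene_indices(pw.genes) for pw in pathways]

    def es_all(treat_mask: np.ndarray) -> np.ndarray:
        t = _pooled_t(universe.values, treat_mask)
        order = _rank_descending(t)
        weights = np.abs(t[order]) ** weight_exponent
        rank_of = np.empty(universe.n_genes, dtype=int)
        rank_of[order] = np.arange(universe.n_genes)
        masks = np.zeros((len(member_idx), universe.n_genes), dtype=bool)
        for row, idx in enumerate(member_idx):
            masks[row, rank_of[idx]] = True
        return _es_batch(weights, masks)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        observed = es_all(universe.treatment_mask)
    if gsea_null == "sample":
        rng = np.random.default_rng(seeds[0])
        exceed = np.zeros(len(member_idx), dtype=int)
        for mask_b in _permuted_masks(universe.treatment_mask, B, rng):
            exceed += np.abs(es_all(mask_b)) >= np.abs(observed)
        pvals = (1 + exceed) / (1 + B)
        for pw, es, p in zip(pathways, observed, pvals):
            results.append(TestResult(pw.name, method, float(es), float(p), B))
        return results
    if gsea_null != "gene":
        raise ValueError("gsea_null must be 'sample' or 'gene'")
    t = gene_t_statistics(universe)
    ranked_stats = t[_rank_descending(t)]
    for pw, es, s in zip(pathways, observed, seeds):
        p = gene_label_permutation_p(
            ranked_stats, pw.size, float(es), B=B, seed=s,
            weight_exponent=weight_exponent,
        )
        results.append(TestResult(pw.name, method, float(es), p, B))
    return results
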
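"""Simulation of grouped expression data with known pathway-level ground truth.

Four simulation types (ST) with increasingly realistic correlation structure:

* **ST I** -- all genes drawn iid standard normal, then a single latent factor
  imposes a global pairwise correlation ``rho`` across the whole gene universe
  (pathway genes *and* an explicit null background set, used by the
  competitive GSEA test).
* **ST II** -- each pathway gets its own independent latent factor, so genes
  correlate at ``rho`` within a pathway and at 0 between pathways.
* **ST III / IV** -- samples drawn from a Gaussian graphical model whose
  precision matrix is consistent with a gene network (ST III: random-start
  projection construction; ST IV: iterative proportional scaling with a
  target edge correlation ``rho``).

Differential expression is controlled by the *detection call* DC: in every
truly-DE pathway the first ``ceil(DC * size)`` genes (in gene order, so the
subset is reproducible) receive a mean shift of ``effect_size`` in the
treatment group; for ST III/IV the shifted genes split half positive / half
negative (odd counts: the extra gene positive).  The shift is applied after
any correlation transform, so the realized mean difference is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import CONTROL, TREATMENT, GroupedExpression, Pathway, PathwayCollection
from .graph_covariance import CovarianceModel, sample_mvn

__all__ = [
    "SimulationDesign",
    "simulate_uncorrelated",
    "apply_factor_correlation",
    "simulate_type1",
    "simulate_type2",
    "simulate_network_type",
]

SIM_TYPES = ("I", "II", "III", "IV")


@dataclass
class SimulationDesign:
    """Parameters of one simulation configuration.

    ``rho`` is the global correlation for ST I, the within-pathway correlation
    for ST II and the IPF target edge correlation for ST IV (ignored for
    ST III).  ``detection_call`` (DC) is the fraction of genes per pathway
    that is differentially expressed; DC = 0 is the null configuration used
    for false-positive-rate estimation.  The default pathway grid (sizes
    20..100 in steps of 20, ten pathways per size, 7000 extra background
    genes for ST I) mirrors the study conditions and is fully overridable.
    """

    sim_type: str = "II"
    n_per_group: int = 20
    rho: float = 0.0
    detection_call: float = 0.0
    effect_size: float = 1.0
    pathway_sizes: tuple[int, ...] = (20, 40, 60, 80, 100)
    pathways_per_size: int = 10
    n_background: int = 7000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim_type not in SIM_TYPES:
            raise ValueError(f"sim_type must be one of {SIM_TYPES}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 <= self.detection_call <= 1.0:
            raise ValueError("detection_call must lie in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


def _labels(n: int) -> np.ndarray:
    return np.asarray([CONTROL] * n + [TREATMENT] * n)


def _gene_ids(n: int, prefix: str = "g") -> list[str]:
    width = max(5, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _disjoint_pathways(design: SimulationDesign) -> tuple[list[str], PathwayCollection]:
    """Non-overlapping pathways laid out consecutively over a fresh universe."""
    sizes = [s for s in design.pathway_sizes for _ in range(design.pathways_per_size)]
    total = sum(sizes)
    genes = _gene_ids(total)
    pathways = []
    cursor = 0
    counters: dict[int, int] = {}
    for size in sizes:
        counters[size] = counters.get(size, 0) + 1
        pathways.append(
            Pathway(f"pw{size}_{counters[size]:02d}", genes[cursor:cursor + size])
        )
        cursor += size
    return genes, PathwayCollection(pathways)


def _shift_treatment(
    expr: GroupedExpression,
    pathways: PathwayCollection,
    detection_call: float,
    effect_size: float,
    signed_split: bool = False,
) -> None:
    """Add the DC-controlled mean shift in place and record the truth flags."""
    treat = expr.treatment_mask
    for pw in pathways:
        k = math.ceil(detection_call * pw.size)
        pw.truly_de = k > 0
        pw.realized_detection_call = k / pw.size
        if k == 0:
            continue
        idx = expr.gene_indices(pw.genes[:k])
        if signed_split:
            n_pos = math.ceil(k / 2)
            shift = np.full(k, -effect_size)
            shift[:n_pos] = effect_size
        else:
            shift = np.full(k, float(effect_size))
        expr.values[np.ix_(idx, np.flatnonzero(treat))] += shift[:, None]


def simulate_uncorrelated(
    design: SimulationDesign,
) -> tuple[GroupedExpression, PathwayCollection]:
    """ST backbone: iid standard-normal entries, DC shift, no correlation."""
    if design.rho != 0.0:
        raise ValueError("simulate_uncorrelated requires rho = 0")
    genes, pathways = _disjoint_pathways(design)
    rng = np.random.default_rng(design.seed)
    n = design.n_per_group
    values = rng.standard_normal((len(genes), 2 * n))
    expr = GroupedExpression(values, genes, _labels(n))
    _shift_treatment(expr, pathways, design.detection_call, design.effect_size)
    return expr, pathways


def apply_factor_correlation(
    values: np.ndarray,
    rho: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Impose a common pairwise correlation via a shared per-sample factor.

    Returns ``sqrt(1 - rho) * values + sqrt(rho) * z`` with one standard
    normal ``z`` per column added to every row: any two rows then have
    population correlation ``rho`` while per-gene variances stay at 1.
    ``rho = 0`` returns the input unchanged.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    values = np.asarray(values, dtype=float)
    if rho == 0.0:
        return values
    if rng is None:
        rng = np.random.default_rng(seed)
    z = rng.standard_normal(values.shape[1])
    return math.sqrt(1.0 - rho) * values + math.sqrt(rho) * z[None, :]


def simulate_type1(
    design: SimulationDesign,
) -> tuple[GroupedExpression, PathwayCollection, GroupedExpression]:
    """ST I: global correlation plus an explicit null background data set.

    Pathway genes and background genes are generated jointly, sharing one
    latent factor, so the correlation is global across the whole universe.
    The background has no expression difference between the groups.
    """
    if design.sim_type != "I":
        raise ValueError("design.sim_type must be 'I'")
    genes, pathways = _disjoint_pathways(design)
    bg_genes = _gene_ids(design.n_background, prefix="bg")
    rng = np.random.default_rng(design.seed)
    n = design.n_per_group
    total = len(genes) + len(bg_genes)
    values = rng.standard_normal((total, 2 * n))
    values = apply_factor_correlation(values, design.rho, rng=rng)
    labels = _labels(n)
    expr = GroupedExpression(values[: len(genes)].copy(), genes, labels)
    background = GroupedExpression(values[len(genes):].copy(), bg_genes, labels)
    _shift_treatment(expr, pathways, design.detection_call, design.effect_size)
    return expr, pathways, background


def simulate_type2(
    design: SimulationDesign,
) -> tuple[GroupedExpression, PathwayCollection]:
    """ST II: an independent shared factor per pathway block.

    Population correlation is ``rho`` within a pathway and exactly 0 between
    pathways.
    """
    if design.sim_type != "II":
        raise ValueError("design.sim_type must be 'II'")
    genes, pathways = _disjoint_pathways(design)
    rng = np.random.default_rng(design.seed)
    n = design.n_per_group
    values = rng.standard_normal((len(genes), 2 * n))
    expr = GroupedExpression(values, genes, _labels(n))
    for pw in pathways:
        idx = expr.gene_indices(pw.genes)
        expr.values[idx] = apply_factor_correlation(
            expr.values[idx], design.rho, rng=rng
        )
    _shift_treatment(expr, pathways, design.detection_call, design.effect_size)
    return expr, pathways


def simulate_network_type(
    design: SimulationDesign,
    model: CovarianceModel,
    pathways: PathwayCollection,
) -> tuple[GroupedExpression, PathwayCollection]:
    """ST III/IV: sample both groups from a network-consistent GGM.

    The control group has mean zero; in the treatment group each truly-DE
    pathway contributes ``ceil(DC * size)`` shifted genes, half at
    ``+effect_size`` and half at ``-effect_size`` (odd counts: extra gene
    positive).  Pathways may overlap; when they do, assignments are written
    in pathway order, so the last pathway touching a gene wins.
    """
    if design.sim_type not in ("III", "IV"):
        raise ValueError("design.sim_type must be 'III' or 'IV'")
    genes = list(model.graph.nodes)
    universe = set(genes)
    for pw in pathways:
        missing = [g for g in pw.genes if g not in universe]
        if missing:
            raise KeyError(
                f"pathway {pw.name!r} genes absent from the covariance model: "
                f"{missing[:5]}"
            )
    pathways = pathways.copy()
    index = {g: i for i, g in enumerate(genes)}
    mu = np.zeros(len(genes))
    for pw in pathways:
        k = math.ceil(design.detection_call * pw.size)
        pw.truly_de = k > 0
        pw.realized_detection_call = k / pw.size
        if k == 0:
            continue
        n_pos = math.ceil(k / 2)
        for rank, g in enumerate(pw.genes[:k]):
            mu[index[g]] = design.effect_size if rank < n_pos else -design.effect_size

    seeds = np.random.SeedSequence(design.seed).generate_state(2) % (2**31)
    n = design.n_per_group
    control = sample_mvn(np.zeros(len(genes)), model, n, int(seeds[0]))
    treatment = sample_mvn(mu, model, n, int(seeds[1]))
    expr = GroupedExpression(
        np.hstack([control, treatment]), genes, _labels(n)
    )
    return expr, pathways
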
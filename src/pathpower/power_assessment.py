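"""Power, false-positive-rate and significance-count estimation over grids.

Power is the probability that a test rejects when the pathway is truly
differentially expressed; it is estimated by the fraction of
(truly-DE pathway, run) pairs with p <= alpha, pooled over repeated
simulations.  The FPR is the same fraction on detection-call-zero (null)
data.  Error bars are bootstrap standard deviations over the per-run
estimates (200 resamples by default).  Per-cell seeds are derived
deterministically from the master seed, so grids reproduce exactly and
parallel execution equals serial execution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GroupedExpression, PathwayCollection
from .graph_covariance import CovarianceModel
from .pathway_tests import TestResult, canonical_method, test_pathways
from .simulators import (
    SimulationDesign,
    simulate_type1,
    simulate_type2,
    simulate_network_type,
)

__all__ = [
    "AssessmentResult",
    "estimate_power",
    "estimate_fpr",
    "count_significant",
    "run_grid",
]


@dataclass
class AssessmentResult:
    design: SimulationDesign
    method: str
    power: float
    fpr: float
    n_significant: float
    sd_power: float
    sd_fpr: float
    sd_count: float
    n_runs: int
    power_by_size: dict[int, float]
    fpr_by_size: dict[int, float]


def _cell_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([int(master), int(index)]).generate_state(1)[0]
               % (2**31))


def _generate_run(
    design: SimulationDesign,
    run_seed: int,
    model: CovarianceModel | None,
    pathways: PathwayCollection | None,
) -> tuple[GroupedExpression, PathwayCollection, GroupedExpression | None]:
    d = replace(design, seed=run_seed)
    if d.sim_type == "I":
        expr, pws, bg = simulate_type1(d)  # handles rho = 0 too
        return expr, pws, bg
    if d.sim_type == "II":
        expr, pws = simulate_type2(d)
        return expr, pws, None
    if model is None or pathways is None:
        raise ValueError(
            "simulation types III/IV require a CovarianceModel and a "
            "PathwayCollection (build them once, e.g. via pathpower.fixtures)"
        )
    expr, pws = simulate_network_type(d, model, pathways)
    return expr, pws, None


def _bootstrap_sd(per_run: np.ndarray, n_boot: int, rng: np.random.Generator
                  ) -> float:
    if per_run.size < 2:
        return 0.0
    draws = rng.integers(0, per_run.size, size=(n_boot, per_run.size))
    return float(np.std(per_run[draws].mean(axis=1), ddof=1))


def _assess(
    design: SimulationDesign,
    method: str,
    n_runs: int,
    B: int,
    seed: int,
    model: CovarianceModel | None,
    pathways: PathwayCollection | None,
    n_boot: int = 200,
) -> AssessmentResult:
    method = canonical_method(method)
    run_power, run_fpr, run_count = [], [], []
    size_hits: dict[int, list[int]] = {}
    size_trials: dict[int, int] = {}
    null_size_hits: dict[int, list[int]] = {}
    for r in range(n_runs):
        run_seed = _cell_seed(seed, r)
        expr, pws, bg = _generate_run(design, run_seed, model, pathways)
        results = test_pathways(
            expr, pws, method, B=B, alpha=design.alpha,
            background=bg if method == "gsea" else None, seed=run_seed,
        )
        by_name = {res.pathway: res for res in results}
        de_hits, de_total, null_hits, null_total = 0, 0, 0, 0
        for pw in pws:
            rejected = by_name[pw.name].p_value <= design.alpha
            bucket = size_hits if pw.truly_de else null_size_hits
            bucket.setdefault(pw.size, []).append(int(rejected))
            if pw.truly_de:
                de_hits += rejected
                de_total += 1
            else:
                null_hits += rejected
                null_total += 1
        run_power.append(de_hits / de_total if de_total else np.nan)
        run_fpr.append(null_hits / null_total if null_total else np.nan)
        run_count.append(count_significant(results, design.alpha))

    rng = np.random.default_rng(_cell_seed(seed, 10_000_019))
    run_power = np.asarray(run_power, dtype=float)
    run_fpr = np.asarray(run_fpr, dtype=float)
    run_count = np.asarray(run_count, dtype=float)

    def summary(values: np.ndarray) -> tuple[float, float]:
        if np.all(np.isnan(values)):
            return float("nan"), float("nan")
        return float(np.nanmean(values)), _bootstrap_sd(
            values[~np.isnan(values)], n_boot, rng
        )

    power, sd_power = summary(run_power)
    fpr, sd_fpr = summary(run_fpr)
    count, sd_count = summary(run_count)
    return AssessmentResult(
        design=design,
        method=method,
        power=power,
        fpr=fpr,
        n_significant=count,
        sd_power=sd_power,
        sd_fpr=sd_fpr,
        sd_count=sd_count,
        n_runs=n_runs,
        power_by_size={s: float(np.mean(v)) for s, v in sorted(size_hits.items())},
        fpr_by_size={s: float(np.mean(v)) for s, v in sorted(null_size_hits.items())},
    )


def estimate_power(
    design: SimulationDesign,
    method: str,
    n_runs: int = 5,
    B: int = 1000,
    seed: int = 0,
    model: CovarianceModel | None = None,
    pathways: PathwayCollection | None = None,
) -> AssessmentResult:
    """Estimate power for one configuration (requires detection_call > 0)."""
    if design.detection_call <= 0:
        raise ValueError("detection_call must be > 0; use estimate_fpr for the null")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return _assess(design, method, n_runs, B, seed, model, pathways)


def estimate_fpr(
    design: SimulationDesign,
    method: str,
    n_runs: int = 5,
    B: int = 1000,
    seed: int = 0,
    model: CovarianceModel | None = None,
    pathways: PathwayCollection | None = None,
) -> AssessmentResult:
    """Estimate the false positive rate (detection call forced to 0)."""
    return _assess(
        replace(design, detection_call=0.0), method, n_runs, B, seed, model, pathways
    )


def count_significant(results: Sequence[TestResult], alpha: float) -> int:
    """Number of results with p <= alpha."""
    return int(sum(res.p_value <= alpha for res in results))


def _run_cell(args) -> dict:
    design, method, n_runs, B, cell_seed, model, pathways = args
    row = {
        "sim_type": design.sim_type,
        "method": canonical_method(method),
        "n_per_group": design.n_per_group,
        "detection_call": design.detection_call,
        "rho": design.rho,
        "alpha": design.alpha,
        "seed": cell_seed,
        "error": "",
    }
    try:
        if design.detection_call > 0:
            res = estimate_power(design, method, n_runs, B, cell_seed, model, pathways)
        else:
            res = estimate_fpr(design, method, n_runs, B, cell_seed, model, pathways)
        row.update(
            power=res.power, fpr=res.fpr, n_significant=res.n_significant,
            sd_power=res.sd_power, sd_fpr=res.sd_fpr, sd_count=res.sd_count,
            n_runs=res.n_runs,
        )
    except Exception as exc:  # cell failures recorded, grid continues
        row.update(
            power=np.nan, fpr=np.nan, n_significant=np.nan,
            sd_power=np.nan, sd_fpr=np.nan, sd_count=np.nan, n_runs=0,
            error=f"{type(exc).__name__}: {exc}",
        )
    return row


def run_grid(
    designs: Sequence[SimulationDesign],
    methods: Sequence[str],
    n_runs: int = 5,
    B: int = 1000,
    seed: int = 0,
    model: CovarianceModel | None = None,
    pathways: PathwayCollection | None = None,
    threads: int = 1,
) -> pd.DataFrame:
    """Cartesian product of designs x methods with per-cell derived seeds."""
    cells = []
    for index, (design, method) in enumerate(
        (d, m) for d in designs for m in methods
    ):
        cells.append(
            (design, method, n_runs, B, _cell_seed(seed, index), model, pathways)
        )
    if threads > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=threads)(delayed(_run_cell)(c) for c in cells)
    else:
        rows = [_run_cell(c) for c in cells]
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["sim_type", "method", "n_per_group", "detection_call", "rho"]
    ).reset_index(drop=True)
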
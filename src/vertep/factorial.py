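"""Full-factorial experiment over the force weights.

Runs every combination of low/high levels of the four force weights over a
phantom cohort, records per-run performance (iterations, wall time,
geometry errors, voltage, coverage), ranks the weight groups by mean time,
mean iterations and error count, and selects the group with the lowest
summed rank.  A Kruskal-Wallis rank test across groups is reported as a
convenience statistic.

The default desk-scale cohort is 9 phantoms (3 tumor locations x 3 radii in
one lumbar body); a directory of converted label volumes can be supplied for
larger cohorts.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .optimizer import OptimizerConfig, optimize
from .phantom import PhantomSpec, default_cohort, generate_phantom
from .solver import SolverConfig

#: low/high levels of the factorial design
DEFAULT_LEVELS: dict[str, tuple[float, float]] = {
    "w1": (0.7, 1.3),
    "w2": (0.1, 0.7),
    "w3": (0.02, 0.14),
    "w4": (5.0, 15.0),
}


@dataclass
class RunRecord:
    """Outcome of one optimization run."""

    phantom: str
    weights: dict[str, float]
    iterations: int
    termination_reason: str
    wall_time_s: float
    voltage_V: float
    gtv_coverage: float
    ctv_soft_coverage: float
    error: bool


@dataclass
class FactorialSummary:
    """Aggregated factorial results with rank-based group selection."""

    group_means: pd.DataFrame  # indexed by weight tuple
    ranks: pd.DataFrame
    scores: pd.Series
    selected: tuple[float, ...]
    kruskal_pvalue: float | None
    records: list[RunRecord] = field(default_factory=list)


def _phantom_id(spec: PhantomSpec) -> str:
    return f"{spec.segment}-{spec.tumor_location}-r{spec.tumor_radius:g}"


def run_factorial(
    levels: dict[str, tuple[float, ...]] | None = None,
    cohort: list[PhantomSpec] | None = None,
    base_config: OptimizerConfig | None = None,
    solver_config: SolverConfig | None = None,
    seed: int = 0,
) -> tuple[FactorialSummary, pd.DataFrame]:
    """Run the factorial experiment; returns the summary and a long-format table.

    A crash in any single run is recorded as an error-flagged
    :class:`RunRecord` rather than aborting the batch.
    """
    levels = {**DEFAULT_LEVELS, **(levels or {})}
    cohort = cohort if cohort is not None else default_cohort()
    base_config = base_config or OptimizerConfig()
    solver_config = solver_config or SolverConfig()

    names = list(levels)
    records: list[RunRecord] = []
    for combo in itertools.product(*(levels[n] for n in names)):
        weights = dict(zip(names, combo))
        cfg = replace(base_config, seed=seed, **weights)
        for spec in cohort:
            t0 = time.perf_counter()
            try:
                volume, anchors, com = generate_phantom(spec)
                plan = optimize(
                    volume, anchors, com, config=cfg, solver_config=solver_config
                )
                records.append(RunRecord(
                    phantom=_phantom_id(spec),
                    weights=weights,
                    iterations=plan.iterations,
                    termination_reason=plan.termination_reason,
                    wall_time_s=time.perf_counter() - t0,
                    voltage_V=plan.applied_voltage,
                    gtv_coverage=plan.gtv_coverage,
                    ctv_soft_coverage=plan.ctv_soft_coverage,
                    error=plan.termination_reason == "geometry_error",
                ))
            except Exception as exc:  # noqa: BLE001 - batch must not abort
                records.append(RunRecord(
                    phantom=_phantom_id(spec),
                    weights=weights,
                    iterations=0,
                    termination_reason=f"crash: {exc}",
                    wall_time_s=time.perf_counter() - t0,
                    voltage_V=float("nan"),
                    gtv_coverage=float("nan"),
                    ctv_soft_coverage=float("nan"),
                    error=True,
                ))
    table = records_to_frame(records, names)
    summary = summarize_factorial(table, names)
    summary.records = records
    return summary, table


def records_to_frame(records: list[RunRecord], weight_names: list[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {n: r.weights[n] for n in weight_names}
        row.update(
            phantom=r.phantom,
            iterations=r.iterations,
            termination_reason=r.termination_reason,
            wall_time_s=r.wall_time_s,
            voltage_V=r.voltage_V,
            gtv_coverage=r.gtv_coverage,
            ctv_soft_coverage=r.ctv_soft_coverage,
            error=r.error,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_factorial(
    table: pd.DataFrame, weight_names: list[str] | None = None
) -> FactorialSummary:
    """Rank groups by mean time, mean iterations and error count.

    Ties share the mean rank; the selected group minimizes the summed rank,
    with ties broken by the lower mean iteration count.  Reproducible from
    the long-format table alone.
    """
    weight_names = weight_names or ["w1", "w2", "w3", "w4"]
    grouped = table.groupby(weight_names, sort=True)
    means = grouped.agg(
        mean_time_s=("wall_time_s", "mean"),
        mean_iterations=("iterations", "mean"),
        n_errors=("error", "sum"),
        mean_voltage_V=("voltage_V", "mean"),
    )
    ranks = pd.DataFrame(index=means.index)
    for crit in ("mean_time_s", "mean_iterations", "n_errors"):
        ranks[crit] = scipy.stats.rankdata(means[crit].to_numpy(), method="average")
    scores = ranks.sum(axis=1)
    best = scores.min()
    candidates = means[scores == best]
    selected = candidates.sort_values("mean_iterations").index[0]
    if not isinstance(selected, tuple):
        selected = (selected,)

    pvalue = None
    if grouped.ngroups >= 2:
        samples = [g["iterations"].to_numpy() for _, g in grouped if len(g) > 0]
        try:
            pvalue = float(scipy.stats.kruskal(*samples).pvalue)
        except ValueError:
            pvalue = None
    return FactorialSummary(
        group_means=means,
        ranks=ranks,
        scores=scores,
        selected=tuple(float(x) for x in np.atleast_1d(selected)),
        kruskal_pvalue=pvalue,
    )
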
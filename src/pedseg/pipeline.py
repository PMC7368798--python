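"""Replicated end-to-end runs used by the CLI and the headline summaries.

Each replicate simulates a fresh cohort (seed = base seed + replicate
number), runs the incremental member-addition analysis with the default
site/call filters under the combined recessive + de novo model, and
collects the reduction curve.  The two headline quantities computed from
such runs are

* the percent drop in total candidates from the index-only step to the
  completed trio, and
* the mean per-step percent drop across the five additions after the trio
  (quartet through octet).

Both are summarized as medians across replicates.
"""

from __future__ import annotations

from dataclasses import replace
from statistics import fmean, median
from typing import Sequence

from .genofilter import FilterConfig
from .pedio import addition_order
from .segregation import (
    InheritanceModel,
    ReductionCurve,
    StrategyComparison,
    compare_trio_vs_sibship,
    incremental_reduction,
)
from .simulate import SimulationConfig, simulate_genotypes


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    return [(base_seed + i) % (2**31) for i in range(n)]


def run_incremental_replicates(
    n_replicates: int,
    base_seed: int,
    cfg: SimulationConfig | None = None,
    filter_cfg: FilterConfig | None = None,
    model: InheritanceModel = InheritanceModel.BOTH,
) -> list[ReductionCurve]:
    """Simulate and analyze ``n_replicates`` cohorts with consecutive seeds."""
    cfg = cfg if cfg is not None else SimulationConfig()
    curves = []
    for seed in replicate_seeds(base_seed, n_replicates):
        records, ped = simulate_genotypes(replace(cfg, seed=seed))
        plan = addition_order(ped)
        curves.append(
            incremental_reduction(records, ped, plan, model, filter_cfg)
        )
    return curves


def index_to_trio_drop(curve: ReductionCurve) -> float:
    """Percent drop in total candidates from the index step to the trio.

    The trio step is the third (index plus both parents); a zero index
    count yields a drop of 0.
    """
    totals = curve.totals()
    if len(totals) < 3:
        raise ValueError("curve has no completed trio step")
    if totals[0] == 0:
        return 0.0
    return 100.0 * (1.0 - totals[2] / totals[0])


def post_trio_mean_drop(curve: ReductionCurve) -> float:
    """Mean per-step percent drop over the additions after the trio step."""
    totals = curve.totals()
    if len(totals) < 4:
        raise ValueError("curve has no post-trio additions")
    drops = []
    for prev, cur in zip(totals[2:], totals[3:]):
        drops.append(0.0 if prev == 0 else 100.0 * (1.0 - cur / prev))
    return fmean(drops)


def headline_reductions(curves: Sequence[ReductionCurve]) -> dict[str, float]:
    """Median trio drop and median post-trio mean drop across replicates."""
    return {
        "trio_drop_median": median(index_to_trio_drop(c) for c in curves),
        "post_trio_drop_median": median(post_trio_mean_drop(c) for c in curves),
    }


def run_strategy_replicates(
    n_replicates: int,
    base_seed: int,
    cfg: SimulationConfig | None = None,
    filter_cfg: FilterConfig | None = None,
) -> list[StrategyComparison]:
    """Trio vs sibship comparison on replicate quintet cohorts."""
    cfg = cfg if cfg is not None else SimulationConfig(pedigree_template="quintet")
    comps = []
    for seed in replicate_seeds(base_seed, n_replicates):
        records, ped = simulate_genotypes(replace(cfg, seed=seed))
        comps.append(compare_trio_vs_sibship(records, ped, filter_cfg))
    return comps
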
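"""Analytic pipeline/farm service-time model for sizing the workflow.

The streaming workflow is a pipeline of stages; each stage's *service
time* ``Ts`` is the average time it needs per stream item, and the
pipeline's throughput is limited by its slowest stage.  A farm of ``n``
equivalent workers divides its worker's service time by ``n``, so farms
are sized to match the slowest purely sequential stage, and the overall
speedup is bounded by the ratio of total sequential time per item to that
bottleneck service time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "StageTiming",
    "pipeline_service_time",
    "farm_service_time",
    "optimal_workers",
    "speedup_bound",
    "node_count",
]


@dataclass(frozen=True)
class StageTiming:
    """Average service time of one pipeline stage, seconds per stream item."""

    name: str
    service_time: float

    def __post_init__(self) -> None:
        if not self.service_time > 0:
            raise ValueError(f"service time of {self.name!r} must be positive")


def pipeline_service_time(stages: Iterable[StageTiming | float]) -> float:
    """Service time of a pipeline: the maximum over its stages."""
    values = [s.service_time if isinstance(s, StageTiming) else float(s) for s in stages]
    if not values:
        raise ValueError("pipeline must have at least one stage")
    return max(values)

def farm_service_time(ts_worker: float, n: int) -> float:
    """Service time of a farm of ``n`` workers: ``Ts(worker) / n``."""
    if n < 1:
        raise ValueError("a farm needs at least one worker")
    return ts_worker / n


def optimal_workers(ts_worker: float, ts_bottleneck: float) -> int:
    """Workers needed for a farm to match the bottleneck stage.

    Nearest-integer rounding of ``Ts(worker) / Ts(bottleneck)``, at
    least 1.
    """
    if ts_worker <= 0 or ts_bottleneck <= 0:
        raise ValueError("service times must be positive")
    return max(1, round(ts_worker / ts_bottleneck))


def speedup_bound(t_total: float, ts_bottleneck: float) -> int:
    """Upper bound on workflow speedup, reported to the nearest integer.

    ``t_total`` is the total sequential execution time per stream item;
    the bound is ``t_total / Ts(bottleneck)``.
    """
    if t_total <= 0 or ts_bottleneck <= 0:
        raise ValueError("times must be positive")
    return round(t_total / ts_bottleneck)


def node_count(n_sim: int, n_stat: int) -> int:
    """Total concurrent nodes: engines plus 3 stage nodes and 4 support nodes.

    The fixed overhead counts the task-generation, alignment and
    window-generation nodes (3) and the two dispatch/gather couples (4).
    """
    if n_sim < 1 or n_stat < 1:
        raise ValueError("need at least one engine of each kind")
    return n_sim + n_stat + 3 + 4
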
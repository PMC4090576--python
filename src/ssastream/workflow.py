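"""Pipelined ensemble workflow: tasks -> workers -> alignment -> windows.

The ensemble is advanced in *simulation quanta* by a worker pool whose
schedule always prioritises the slowest (lowest-clock) tasks, keeping the
trajectories aligned in simulation time and the alignment buffer small.
Per-task chunks are merged by :class:`TrajectoryAligner` into
:class:`TimeCut` arrays — one value per trajectory per observed species at
each grid time — which stream into summary statistics and a sliding-window
generator feeding the clustering and peak-detection operators.

Because every task owns an independent random stream, the emitted results
are identical for any worker count and any quantum size; parallelism is a
throughput knob, never a source of nondeterminism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationTask, TrajectoryChunk, advance_to
from .models import Model

__all__ = [
    "TimeCut",
    "WindowBlock",
    "generate_tasks",
    "schedule_next",
    "TrajectoryAligner",
    "align",
    "sliding_windows",
    "WorkflowResult",
    "run_workflow",
]


@dataclass(frozen=True)
class TimeCut:
    """Ensemble snapshot at grid time ``t_i``: one value per trajectory."""

    index: int
    time: float
    values: dict[str, np.ndarray]  # species -> counts ordered by task_id
    task_ids: tuple[int, ...]


@dataclass(frozen=True)
class WindowBlock:
    """Δ_W consecutive time-cuts centred on ``center_index``."""

    center_index: int
    cuts: tuple[TimeCut, ...]

    @property
    def center(self) -> TimeCut:
        return self.cuts[len(self.cuts) // 2]

    @property
    def task_ids(self) -> tuple[int, ...]:
        return self.cuts[0].task_ids

    def matrix(self, species: str | None = None) -> np.ndarray:
        """Per-trajectory sample matrix, shape ``(n_traj, Δ_W)``."""
        if species is None:
            species = next(iter(self.cuts[0].values))
        return np.column_stack([c.values[species] for c in self.cuts])


def generate_tasks(
    model: Model, n: int, base_seed: int, t_end: float, delta_s: float
) -> list[SimulationTask]:
    """``n`` fresh tasks at the model's initial state with distinct seeds."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return [SimulationTask(model, i, base_seed + i, t_end, delta_s) for i in range(n)]


def schedule_next(pending: Iterable[SimulationTask]) -> SimulationTask:
    """Slowest-first dispatch: minimum clock, ties broken by lowest id."""
    alive = [t for t in pending if not t.done]
    if not alive:
        raise LookupError("no unfinished simulation tasks")
    return min(alive, key=lambda t: (t.clock, t.task_id))


class AlignmentError(RuntimeError):
    pass


class TrajectoryAligner:
    """Merges per-task chunks into complete, ordered time-cuts.

    Cut ``i`` is emitted exactly when all ``n`` tasks have delivered their
    sample ``i``; only incomplete indices are buffered.  Duplicate or
    out-of-sequence samples from a task are errors.
    """

    def __init__(self, n: int, delta_s: float, species: Sequence[str]):
        self.n = n
        self.delta_s = delta_s
        self.species = tuple(species)
        self._next_emit = 0
        self._expected = {}  # task_id -> next expected sample index
        self._buffer: dict[int, list] = {}  # index -> per-task slot list
        self._filled: dict[int, int] = {}
        self.max_buffered = 0

    def push(self, chunk: TrajectoryChunk) -> list[TimeCut]:
        out: list[TimeCut] = []
        tid = chunk.task_id
        for idx, counts in chunk.samples:
            exp = self._expected.get(tid, 0)
            if idx < exp:
                raise AlignmentError(f"duplicate sample {idx} from task {tid}")
            if idx > exp:
                raise AlignmentError(f"gap in samples from task {tid}: expected {exp}, got {idx}")
            self._expected[tid] = idx + 1
            if idx < self._next_emit:
                raise AlignmentError(f"sample {idx} from task {tid} arrived after emission")
            slots = self._buffer.get(idx)
            if slots is None:
                slots = [None] * self.n
                self._buffer[idx] = slots
                self._filled[idx] = 0
            slots[tid] = counts
            self._filled[idx] += 1
        self.max_buffered = max(self.max_buffered, len(self._buffer))
        while self._filled.get(self._next_emit, 0) == self.n:
            idx = self._next_emit
            slots = self._buffer.pop(idx)
            del self._filled[idx]
            arr = np.array(slots, dtype=np.int64)  # (n, n_species)
            out.append(
                TimeCut(
                    index=idx,
                    time=idx * self.delta_s,
                    values={sp: arr[:, k].copy() for k, sp in enumerate(self.species)},
                    task_ids=tuple(range(self.n)),
                )
            )
            self._next_emit += 1
        return out


def align(
    chunks: Iterable[TrajectoryChunk], n: int, delta_s: float, species: Sequence[str]
) -> Iterator[TimeCut]:
    """Stream adapter over :class:`TrajectoryAligner`."""
    aligner = TrajectoryAligner(n, delta_s, species)
    for chunk in chunks:
        yield from aligner.push(chunk)


def sliding_windows(
    cuts: Iterable[TimeCut], window: int, stride: int = 1
) -> Iterator[WindowBlock]:
    """Overlapping windows of Δ_W cuts; trailing partial windows dropped.

    The first window is centred at index ``(Δ_W - 1) / 2``; subsequent
    centres advance by ``stride``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    feeder = _WindowFeeder(window, stride)
    for cut in cuts:
        yield from feeder.push(cut)


@dataclass
class WorkflowResult:
    """Streamed outputs of a full simulation-analysis run."""

    stats: pd.DataFrame
    clusters: pd.DataFrame
    peaks: pd.DataFrame
    periods: pd.DataFrame
    raw: pd.DataFrame | None = None
    max_aligner_buffer: int = 0
    max_clock_lag_cuts: int = 0


def run_workflow(model: Model, config) -> WorkflowResult:
    """End-to-end pipelined run (see :class:`ssastream.io.RunConfig`).

    Task generation -> slowest-first worker pool advancing one quantum at
    a time -> trajectory alignment -> per-cut summary statistics and
    sliding-window clustering -> per-trajectory peak detection.  Outputs
    are identical for any ``workers``/``quantum`` setting at fixed seeds.
    """
    from . import analysis  # deferred: analysis imports window types from here

    n = config.n_trajectories
    ds = config.delta_s
    tasks = generate_tasks(model, n, config.base_seed, config.t_end, ds)
    aligner = TrajectoryAligner(n, ds, model.observed_species)

    window_gen = _WindowFeeder(config.window, config.stride)
    stats_rows: list[dict] = []
    cluster_rows: list[dict] = []
    series: list[list[int]] | None = None
    cluster_species = config.cluster_species or model.observed_species[0]
    want_peaks = config.peaks
    want_raw = config.store_raw
    if want_peaks or want_raw:
        series = [[] for _ in range(n)]
        peak_species_idx = model.observed_species.index(
            config.peak_species or model.observed_species[0]
        )

    max_lag_cuts = 0
    pending = list(tasks)
    while True:
        alive = [t for t in pending if not t.done]
        if not alive:
            break
        alive.sort(key=lambda t: (t.clock, t.task_id))
        batch = alive[: max(1, config.workers)]
        clocks = [t.clock for t in pending]
        lag = (max(clocks) - min(clocks)) / ds
        max_lag_cuts = max(max_lag_cuts, int(np.ceil(lag)))
        for task in batch:
            _, chunk = advance_to(task, min(task.clock + config.quantum, config.t_end))
            for cut in aligner.push(chunk):
                stats_rows.extend(_stats_rows(cut, config.quantile_levels))
                if series is not None:
                    for tid, counts in zip(cut.task_ids, _iter_rows(cut)):
                        series[tid].append(counts)
                for block in window_gen.push(cut):
                    cluster_rows.extend(
                        _cluster_rows(block, config, cluster_species, ds)
                    )

    stats = pd.DataFrame(stats_rows)
    clusters = pd.DataFrame(
        cluster_rows,
        columns=["time", "method", "trajectory_id", "label", "center", "size"],
    )

    peaks_df = pd.DataFrame(columns=["trajectory_id", "peak_time", "local_period"])
    periods_df = pd.DataFrame(columns=["time", "period_ma"])
    raw_df = None
    if series is not None:
        mat = np.array(series, dtype=np.int64)  # (n, n_cuts, n_species)
        if want_peaks:
            records = []
            for tid in range(n):
                times = analysis.detect_peaks(
                    mat[tid, :, peak_species_idx], ds,
                    sg_window=config.sg_window, sg_order=config.sg_order,
                    min_height_frac=config.peak_min_height_frac,
                    min_separation=config.peak_min_separation,
                )
                records.append(analysis.PeakRecord(tid, times))
            rows = []
            for rec in records:
                periods = (float("nan"), *rec.local_periods)
                for t, p in zip(rec.peak_times, periods):
                    rows.append({"trajectory_id": rec.trajectory_id, "peak_time": t, "local_period": p})
            if rows:
                peaks_df = pd.DataFrame(rows)
            times, ma = analysis.peak_periods(records, config.period_ma_window)
            if len(times):
                periods_df = pd.DataFrame({"time": times, "period_ma": ma})
        if want_raw:
            raw_df = pd.DataFrame(
                {
                    f"{sp}:{tid}": mat[tid, :, k]
                    for tid in range(n)
                    for k, sp in enumerate(model.observed_species)
                },
                index=pd.Index(np.arange(mat.shape[1]) * ds, name="time"),
            )
    return WorkflowResult(
        stats=stats, clusters=clusters, peaks=peaks_df, periods=periods_df,
        raw=raw_df, max_aligner_buffer=aligner.max_buffered,
        max_clock_lag_cuts=max_lag_cuts,
    )


class _WindowFeeder:
    """Push-style wrapper around :func:`sliding_windows`."""

    def __init__(self, window: int, stride: int):
        if window < 3 or window % 2 == 0:
            raise ValueError("window length must be odd and >= 3")
        self.window = window
        self.stride = stride
        self.buf: list[TimeCut] = []
        self.next_center = (window - 1) // 2

    def push(self, cut: TimeCut) -> list[WindowBlock]:
        self.buf.append(cut)
        if len(self.buf) > self.window:
            del self.buf[: len(self.buf) - self.window]
        out = []
        half = (self.window - 1) // 2
        if len(self.buf) == self.window and self.buf[-1].index - self.next_center == half:
            out.append(WindowBlock(self.next_center, tuple(self.buf)))
            self.next_center += self.stride
        return out


def _iter_rows(cut: TimeCut):
    arr = np.column_stack([cut.values[sp] for sp in cut.values])
    return arr


def _stats_rows(cut: TimeCut, levels) -> list[dict]:
    from . import analysis

    rec = analysis.summary_stats(cut, levels)
    rows = []
    for sp in cut.values:
        row = {"time": cut.time, "species": sp, "mean": rec.mean[sp], "sd": rec.std[sp]}
        for lv in levels:
            row[f"q{int(round(lv * 100)):02d}"] = rec.quantiles[sp][lv]
        rows.append(row)
    return rows


def _cluster_rows(block: WindowBlock, config, species: str, ds: float) -> list[dict]:
    from . import analysis

    if config.cluster_method is None:
        return []
    filtered = analysis.filter_and_forecast(
        block, ds, config.sg_window, config.sg_order, species
    )
    pts = analysis.features(filtered)
    t = block.center.time
    if config.cluster_method == "kmeans":
        assign = analysis.kmeans_cluster(
            pts, config.kmeans_k,
            seed=config.base_seed + 7919 * (block.center_index + 1), time=t,
        )
    elif config.cluster_method == "qt":
        assign = analysis.qt_cluster(
            pts, config.qt_threshold, config.qt_min_size, time=t
        )
    else:
        raise ValueError(f"unknown clustering method {config.cluster_method!r}")
    rows = []
    for tid, label in zip(block.task_ids, assign.labels):
        center = assign.centers[label][0] if label >= 0 else float("nan")
        size = assign.sizes[label] if label >= 0 else 0
        rows.append(
            {"time": t, "method": assign.method, "trajectory_id": tid,
             "label": label, "center": center, "size": size}
        )
    return rows
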
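"""Exact stochastic simulation (Gillespie direct method).

The engine advances independent :class:`SimulationTask` objects, each
holding its own deterministic random stream, and samples trajectories on a
fixed grid ``t_i = i * delta_s`` with right-continuous step interpolation
(the sample at ``t_i`` is the state at the largest event time <= ``t_i``).

Two properties the rest of the package relies on:

* **Quantum invariance** — a task advanced in many small quanta produces
  exactly the same event sequence and samples as one advanced in a single
  call, because a step whose waiting time overshoots the quantum target
  still fires; nothing about the dynamics depends on how far
  :func:`advance_to` was asked to go.
* **Piecewise-constant time dependence is handled exactly** — when a
  proposed firing would cross a schedule boundary the clock moves to the
  boundary without firing and the waiting time is re-drawn, which is exact
  for rates that are constant between boundaries (memorylessness).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Iterator, Mapping

import pandas as pd

from .models import MassAction, Model, RateFunction, Reaction, SystemState, validate_model

__all__ = [
    "SimulationTask",
    "TrajectoryChunk",
    "propensity",
    "make_task",
    "ssa_step",
    "advance_to",
    "run_trajectory",
]

_INF = math.inf


class SimulationError(RuntimeError):
    """Raised on impossible states (negative counts, bad rate values)."""


class CountsView(Mapping):
    """Read-only, name-keyed live view over the engine's count list."""

    __slots__ = ("_counts", "_index")

    def __init__(self, counts: list[int], index: dict[str, int]):
        self._counts = counts
        self._index = index

    def __getitem__(self, name: str) -> int:
        return self._counts[self._index[name]]

    def __iter__(self) -> Iterator[str]:
        return iter(self._index)

    def __len__(self) -> int:
        return len(self._index)


def _falling(n: int, m: int) -> float:
    """Number of ordered reactant tuples / m!: C(n, m) combinations."""
    if n < m:
        return 0.0
    if m == 1:
        return float(n)
    if m == 2:
        return n * (n - 1) / 2.0
    if m == 3:
        return n * (n - 1) * (n - 2) / 6.0
    return float(math.comb(n, m))


def propensity(reaction: Reaction, state: SystemState, t: float | None = None) -> float:
    """Propensity of ``reaction`` in ``state`` at time ``t``.

    Mass action uses the combinatorial convention
    ``c * prod_s C(n_s, m_s)`` (``n(n-1)/2`` for a homodimerisation, etc.);
    a rate function's value is the propensity itself, required finite and
    non-negative.
    """
    if t is None:
        t = state.time
    if isinstance(reaction.rate, MassAction):
        a = reaction.rate.c
        for sp, m in reaction.reactants:
            a *= _falling(state.counts.get(sp, 0), m)
            if a == 0.0:
                return 0.0
        return a
    value = reaction.rate.fn(state.counts, t)
    if not (value >= 0.0) or not math.isfinite(value):
        raise SimulationError(
            f"rate function {reaction.rate.name!r} returned {value!r} at t={t}"
        )
    return value


@dataclass(frozen=True)
class TrajectoryChunk:
    """Consecutive grid samples produced by one task in one quantum."""

    task_id: int
    samples: tuple[tuple[int, tuple[int, ...]], ...]  # (sample_index, observed counts)


class _CompiledModel:
    """Model lowered to integer-indexed arrays for the hot loop."""

    __slots__ = ("model", "species", "index", "observed_idx", "reactions", "initial")

    def __init__(self, model: Model):
        validate_model(model)
        self.model = model
        self.species = model.species
        self.index = {sp: i for i, sp in enumerate(model.species)}
        self.observed_idx = tuple(self.index[sp] for sp in model.observed_species)
        self.initial = [model.initial_state.counts.get(sp, 0) for sp in model.species]
        self.reactions = []
        for rx in model.reactions:
            reactants = tuple((self.index[sp], m) for sp, m in rx.reactants)
            deltas = tuple((self.index[sp], d) for sp, d in rx.net_change().items())
            if isinstance(rx.rate, MassAction):
                self.reactions.append((0, rx.rate.c, reactants, deltas, None, rx))
            else:
                self.reactions.append((1, 0.0, reactants, deltas, rx.rate.fn, rx))


_COMPILE_CACHE: dict[int, _CompiledModel] = {}


def _compiled(model: Model) -> _CompiledModel:
    cm = _COMPILE_CACHE.get(id(model))
    if cm is None or cm.model is not model:
        cm = _CompiledModel(model)
        _COMPILE_CACHE[id(model)] = cm
    return cm


class SimulationTask:
    """One trajectory: evolving state, clock, RNG stream and sample cursor."""

    __slots__ = (
        "task_id", "counts", "clock", "rng", "next_sample_index", "done",
        "t_end", "delta_s", "_cm", "_view", "_boundaries", "_b_ptr",
        "_max_index", "_samples",
    )

    def __init__(self, model: Model, task_id: int, seed: int, t_end: float,
                 delta_s: float, t_start: float = 0.0):
        if not t_end > t_start:
            raise ValueError("t_end must exceed the start time")
        if not delta_s > 0:
            raise ValueError("delta_s must be positive")
        cm = _compiled(model)
        self._cm = cm
        self.task_id = task_id
        self.counts = list(cm.initial)
        self.clock = t_start
        self.rng = random.Random(seed)
        self.next_sample_index = 0
        self.done = False
        self.t_end = t_end
        self.delta_s = delta_s
        self._view = CountsView(self.counts, cm.index)
        self._boundaries = model.rate_boundaries(t_end)
        self._b_ptr = 0
        self._max_index = math.floor((t_end - t_start) / delta_s + 1e-9)
        self._samples: list[tuple[int, tuple[int, ...]]] = []

    @property
    def state(self) -> SystemState:
        return SystemState(
            {sp: self.counts[i] for sp, i in self._cm.index.items()}, self.clock
        )

    # -- sampling helpers ---------------------------------------------------

    def _emit_before(self, t: float) -> None:
        """Emit grid samples strictly before ``t`` with the current state."""
        idx = self.next_sample_index
        ds = self.delta_s
        counts = self.counts
        obs = self._cm.observed_idx
        samples = self._samples
        while idx <= self._max_index and idx * ds < t:
            samples.append((idx, tuple(counts[j] for j in obs)))
            idx += 1
        self.next_sample_index = idx

    def _finalize(self) -> None:
        """Emit any remaining grid samples (state is constant up to t_end)."""
        idx = self.next_sample_index
        obs = self._cm.observed_idx
        counts = self.counts
        while idx <= self._max_index:
            self._samples.append((idx, tuple(counts[j] for j in obs)))
            idx += 1
        self.next_sample_index = idx
        self.done = True


def make_task(model: Model, task_id: int, seed: int, t_end: float, delta_s: float) -> SimulationTask:
    return SimulationTask(model, task_id, seed, t_end, delta_s)


def ssa_step(task: SimulationTask) -> SimulationTask:
    """Advance one Gillespie step (or to the next schedule boundary).

    Draws the waiting time from the total propensity at the current clock;
    if the proposed firing crosses the next schedule boundary the clock is
    moved to the boundary without firing (exact for piecewise-constant
    rates).  With zero total propensity the clock jumps to the next
    boundary, or the task absorbs at ``t_end``.
    """
    if task.done:
        raise SimulationError("ssa_step on a finished task")
    counts = task.counts
    t = task.clock
    view = task._view

    a0 = 0.0
    props = []
    for kind, c, reactants, deltas, fn, rx in task._cm.reactions:
        if kind == 0:
            a = c
            for j, m in reactants:
                n = counts[j]
                if n < m:
                    a = 0.0
                    break
                if m == 1:
                    a *= n
                elif m == 2:
                    a *= n * (n - 1) * 0.5
                else:
                    a *= _falling(n, m)
        else:
            a = fn(view, t)
            if not (a >= 0.0) or a == _INF:
                raise SimulationError(
                    f"rate function {rx.rate.name!r} returned {a!r} at t={t}"
                )
        props.append(a)
        a0 += a

    boundaries = task._boundaries
    next_b = boundaries[task._b_ptr] if task._b_ptr < len(boundaries) else _INF

    if a0 <= 0.0:
        if next_b < task.t_end:
            task._emit_before(next_b)
            task.clock = next_b
            task._b_ptr += 1
        else:
            task._emit_before(task.t_end)
            task.clock = task.t_end
            task._finalize()
        return task

    t_new = t + task.rng.expovariate(a0)
    if t_new >= next_b:
        # cross the schedule boundary without firing; re-draw next call
        task._emit_before(next_b)
        task.clock = next_b
        task._b_ptr += 1
        return task

    # select the firing reaction
    u = task.rng.random() * a0
    acc = 0.0
    chosen = len(props) - 1
    for j, a in enumerate(props):
        acc += a
        if u < acc:
            chosen = j
            break

    task._emit_before(t_new)
    for j, d in task._cm.reactions[chosen][3]:
        counts[j] += d
        if counts[j] < 0:
            rx = task._cm.reactions[chosen][5]
            raise SimulationError(
                f"negative count for {task._cm.species[j]!r} after firing "
                f"{rx.name or rx!r} at t={t_new}"
            )
    task.clock = t_new
    return task


def advance_to(task: SimulationTask, t_target: float) -> tuple[SimulationTask, TrajectoryChunk]:
    """Advance until the clock reaches ``t_target`` (one simulation quantum).

    Returns the chunk of grid samples that became determined during this
    quantum.  The final step may overshoot ``t_target``; see the module
    notes on quantum invariance.
    """
    if task.done:
        return task, TrajectoryChunk(task.task_id, ())
    while task.clock < t_target and not task.done:
        ssa_step(task)
    if task.clock >= task.t_end and not task.done:
        task._finalize()
    chunk = TrajectoryChunk(task.task_id, tuple(task._samples))
    task._samples.clear()
    return task, chunk


def run_trajectory(model: Model, seed: int, t_end: float, delta_s: float) -> pd.DataFrame:
    """Simulate a single trajectory to ``t_end``.

    Returns a DataFrame indexed by sample time with one column per observed
    species; bit-reproducible for a fixed seed.
    """
    task = SimulationTask(model, 0, seed, t_end, delta_s)
    _, chunk = advance_to(task, t_end)
    idx = [i for i, _ in chunk.samples]
    data = {
        sp: [s[k] for _, s in chunk.samples]
        for k, sp in enumerate(model.observed_species)
    }
    times = pd.Index([i * delta_s for i in idx], name="time")
    return pd.DataFrame(data, index=times)
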
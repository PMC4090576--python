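"""Model-file parsing, run configuration and tabular readers/writers.

Model text format (ASCII, ``#`` comments), one rule per line::

    # Schlögl system
    init: A=250 B=1
    buffered: B
    2*A -> 3*A @ mass_action(0.03)
    3*A -> 2*A @ mass_action(0.0001)
    B -> B + A @ mass_action(200)
    A -> @ mass_action(3.5)

Species are whitespace- or ``+``-separated names with optional integer
multiplicities (``2*A`` or ``A A``); a rate is either ``mass_action(c)``
or ``function(name)`` with ``name`` resolved from a registry of callables
``f(counts, t)``.

All writers use fixed formatting (comma separator, ``%.6g`` floats,
integer counts) so identical inputs yield byte-identical files.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml

from .models import (
    MassAction,
    Model,
    ModelError,
    RateFunction,
    Reaction,
    SystemState,
    validate_model,
)

__all__ = [
    "RunConfig",
    "ParseError",
    "parse_model_file",
    "parse_model_text",
    "write_trajectories",
    "read_trajectories",
    "write_stats",
    "write_clusters",
    "write_peaks",
    "write_periods",
]

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of a full simulation-analysis run."""

    n_trajectories: int = 10
    t_end: float = 10.0
    delta_s: float = 0.1
    quantum: float | None = None      # default 10 * delta_s
    workers: int = 1
    base_seed: int = 1
    quantile_levels: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95)
    window: int = 9                   # Δ_W, sliding window length (odd)
    stride: int = 1
    sg_window: int = 9
    sg_order: int = 3
    cluster_method: str | None = None  # "kmeans" | "qt" | None
    cluster_species: str | None = None
    kmeans_k: int = 2
    qt_threshold: float = 100.0
    qt_min_size: int = 1
    peaks: bool = False
    peak_species: str | None = None
    peak_min_height_frac: float = 0.1
    peak_min_separation: int = 2
    period_ma_window: int = 10
    store_raw: bool = False

    def __post_init__(self) -> None:
        if self.quantum is None:
            self.quantum = 10 * self.delta_s
        if self.n_trajectories < 0 or self.t_end <= 0 or self.delta_s <= 0:
            raise ValueError("n_trajectories, t_end and delta_s must be positive")
        if self.delta_s > self.quantum:
            raise ValueError("delta_s must not exceed the simulation quantum")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.window % 2 == 0 or self.sg_window % 2 == 0:
            raise ValueError("window and sg_window must be odd")
        if self.cluster_method is not None and self.sg_window > self.window:
            raise ValueError("sg_window must not exceed the sliding window Δ_W")

    @classmethod
    def from_yaml(cls, path: str | Path) -> tuple[str, "RunConfig"]:
        """Load ``(model_source, config)`` from a YAML file."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        model = doc.pop("model", None)
        if model is None:
            raise ValueError(f"{path}: missing 'model' entry")
        for key in ("quantile_levels",):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return model, cls(**doc)


# ---------------------------------------------------------------------------
# model text format


class ParseError(ValueError):
    def __init__(self, path: str, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


_RATE_RE = re.compile(r"^(mass_action|function)\s*\(\s*([^)]*?)\s*\)$")
_TERM_RE = re.compile(r"^(?:(\d+)\*)?([A-Za-z_][A-Za-z0-9_]*)$")


def _parse_side(text: str, path: str, line_no: int) -> tuple[tuple[str, int], ...]:
    terms: dict[str, int] = {}
    for token in text.replace("+", " ").split():
        m = _TERM_RE.match(token)
        if not m:
            raise ParseError(path, line_no, f"bad species term {token!r}")
        mult = int(m.group(1)) if m.group(1) else 1
        if mult < 1:
            raise ParseError(path, line_no, f"multiplicity must be >= 1 in {token!r}")
        terms[m.group(2)] = terms.get(m.group(2), 0) + mult
    return tuple(terms.items())


def parse_model_text(
    text: str,
    functions: Mapping[str, Callable] | None = None,
    name: str = "<string>",
) -> Model:
    """Parse a model from rule-file text; see the module docstring."""
    functions = functions or {}
    init: dict[str, int] = {}
    buffered: set[str] = set()
    reactions: list[Reaction] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("init:"):
            for tok in line[5:].split():
                if "=" not in tok:
                    raise ParseError(name, line_no, f"bad init entry {tok!r}")
                sp, val = tok.split("=", 1)
                try:
                    count = int(val)
                except ValueError:
                    raise ParseError(name, line_no, f"non-integer initial count {val!r}") from None
                if count < 0:
                    raise ParseError(name, line_no, f"negative initial count for {sp!r}")
                init[sp.strip()] = count
            continue
        if line.startswith("buffered:"):
            buffered.update(line[9:].split())
            continue
        if "->" not in line:
            raise ParseError(name, line_no, "expected 'reactants -> products @ rate'")
        lhs, rest = line.split("->", 1)
        if "@" not in rest:
            raise ParseError(name, line_no, "missing '@ rate' clause")
        rhs, rate_text = rest.split("@", 1)
        m = _RATE_RE.match(rate_text.strip())
        if not m:
            raise ParseError(name, line_no, f"bad rate clause {rate_text.strip()!r}")
        kind, arg = m.groups()
        if kind == "mass_action":
            try:
                c = float(arg)
            except ValueError:
                raise ParseError(name, line_no, f"bad rate constant {arg!r}") from None
            if c < 0:
                raise ParseError(name, line_no, f"negative rate constant {arg!r}")
            rate = MassAction(c)
        else:
            if arg not in functions:
                raise ParseError(name, line_no, f"unknown rate function {arg!r}")
            rate = RateFunction(functions[arg], arg)
        reactions.append(
            Reaction(
                _parse_side(lhs, name, line_no),
                _parse_side(rhs, name, line_no),
                rate,
                frozenset(buffered),
                name=f"{name}:{line_no}",
            )
        )
    if not reactions:
        raise ParseError(name, 0, "no reactions")
    species = []
    for rx in reactions:
        for sp, _ in (*rx.reactants, *rx.products):
            if sp not in species:
                species.append(sp)
    for sp in init:
        if sp not in species:
            species.append(sp)
    model = Model(
        name=name,
        species=tuple(species),
        reactions=tuple(
            Reaction(rx.reactants, rx.products, rx.rate,
                     frozenset(b for b in buffered if b in species), rx.name)
            for rx in reactions
        ),
        initial_state=SystemState({sp: init.get(sp, 0) for sp in species}),
    )
    return validate_model(model)


def parse_model_file(path: str | Path, functions: Mapping[str, Callable] | None = None) -> Model:
    """Parse and validate a model rule file; errors carry line numbers."""
    path = Path(path)
    return parse_model_text(path.read_text(), functions, name=str(path))


# ---------------------------------------------------------------------------
# trajectory store (optional raw results)


def write_trajectories(path: str | Path, frame: pd.DataFrame) -> None:
    """Write an ensemble (columns ``species:task_id``) to CSV.

    The index must be the common sampling grid; counts are written as
    integers, the time column with ``%.6g``.
    """
    out = frame.copy()
    out.index = [FLOAT_FMT % t for t in frame.index]
    out.index.name = "time"
    out.to_csv(path)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Read back an ensemble written by :func:`write_trajectories`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if not header or header[0] != "time":
            raise ValueError(f"{path}: missing 'time' header column")
        width = len(header)
        times, rows = [], []
        for row_no, row in enumerate(reader, start=1):
            if len(row) != width:
                raise ValueError(
                    f"{path}: row {row_no} has {len(row)} fields, expected {width}"
                )
            try:
                times.append(float(row[0]))
                rows.append([int(x) for x in row[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}: row {row_no}: {exc}") from None
    frame = pd.DataFrame(rows, columns=header[1:], dtype=np.int64)
    frame.index = pd.Index(times, name="time")
    return frame


# ---------------------------------------------------------------------------
# analysis CSV writers


def _write_frame(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_stats(path: str | Path, stats: pd.DataFrame) -> None:
    _write_frame(path, stats)


def write_clusters(path: str | Path, clusters: pd.DataFrame) -> None:
    _write_frame(path, clusters)


def write_peaks(path: str | Path, peaks: pd.DataFrame) -> None:
    _write_frame(path, peaks)


def write_periods(path: str | Path, periods: pd.DataFrame) -> None:
    _write_frame(path, periods)
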
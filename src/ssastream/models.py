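"""Reaction-system models in flat chemical notation.

A model is a set of species, an initial multiset of molecules and a list of
reactions.  Each reaction carries either a stochastic mass-action constant
(propensities then follow the combinatorial convention, see
:func:`ssastream.engine.propensity`) or an arbitrary *rate function* of the
current system state and time, whose value is taken directly as the
propensity.  Species may be *buffered*: their count is never changed by a
firing (a chemostat, e.g. species B of the Schlögl system).

Three built-in systems are provided via :func:`builtin_model`:

``schlogl``
    The classic bistable autocatalytic network; species ``A`` switches
    stochastically between two stable steady states.
``lambda_phage``
    A simplified lysis/lysogeny switch of bacteriophage λ: repressor CI
    dimerises and binds phage DNA at a promoting and a repressing operator
    site; the CI level shows two stable equilibria.
``neurospora``
    The circadian frq/FRQ transcription-translation oscillator of
    *Neurospora crassa* with Hill-type repression of transcription by
    nuclear FRQ and Michaelis-Menten degradations, in molecule units
    (1 nM = 100 molecules).  Transcription rate can follow an alternating
    dark/light schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

__all__ = [
    "SystemState",
    "MassAction",
    "RateFunction",
    "RateLaw",
    "Reaction",
    "PiecewiseSchedule",
    "NeurosporaParams",
    "Model",
    "ModelError",
    "validate_model",
    "builtin_model",
    "eval_schedule",
    "hill_repression_rate",
    "michaelis_rate",
]


class ModelError(ValueError):
    """Raised for inconsistent model definitions."""


@dataclass
class SystemState:
    """Molecule counts plus the current simulation clock."""

    counts: dict[str, int]
    time: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(dict(self.counts), self.time)


@dataclass(frozen=True)
class MassAction:
    """Stochastic mass-action kinetics with constant ``c`` (per time unit)."""

    c: float

    def __post_init__(self) -> None:
        if not (self.c >= 0.0) or not math.isfinite(self.c):
            raise ModelError(f"mass-action constant must be finite and >= 0, got {self.c}")


@dataclass(frozen=True)
class RateFunction:
    """State/time-dependent propensity.

    ``fn(counts, t)`` receives a read-only mapping from species name to the
    current molecule count and the simulation time; its return value *is*
    the propensity of the reaction (no additional reactant-multiplicity
    factor is applied).
    """

    fn: Callable[[Mapping[str, int], float], float]
    name: str = "rate_fn"


RateLaw = MassAction | RateFunction


@dataclass(frozen=True)
class Reaction:
    """``reactants -> products`` with a rate law.

    ``reactants``/``products`` are tuples of ``(species, multiplicity)``
    pairs with multiplicity >= 1.  Buffered species take part in propensity
    evaluation but their counts are never modified by a firing.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: RateLaw
    buffered: frozenset[str] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for sp, m in side:
                if m < 1:
                    raise ModelError(f"stoichiometric multiplicity must be >= 1 ({sp}: {m})")

    def net_change(self) -> dict[str, int]:
        """Net stoichiometric change per species, buffered species excluded."""
        delta: dict[str, int] = {}
        for sp, m in self.reactants:
            delta[sp] = delta.get(sp, 0) - m
        for sp, m in self.products:
            delta[sp] = delta.get(sp, 0) + m
        return {sp: d for sp, d in delta.items() if d != 0 and sp not in self.buffered}


@dataclass(frozen=True)
class PiecewiseSchedule:
    """Periodic two-phase schedule (e.g. dark/light transcription drive).

    The value is ``low`` on ``[2nT, (2n+1)T)`` and ``high`` on
    ``[(2n+1)T, (2n+2)T)``; intervals are closed on the left.  With
    ``T is None`` the schedule is constant at ``low``.
    """

    low: float
    high: float = 0.0
    T: float | None = None

    def __post_init__(self) -> None:
        if self.low < 0 or self.high < 0:
            raise ModelError("schedule values must be non-negative")
        if self.T is not None and not self.T > 0:
            raise ModelError("phase length T must be positive")

    @classmethod
    def constant(cls, value: float) -> "PiecewiseSchedule":
        return cls(low=value, high=value, T=None)

    @classmethod
    def alternating(cls, low: float, high: float, T: float) -> "PiecewiseSchedule":
        return cls(low=low, high=high, T=T)

    @property
    def is_constant(self) -> bool:
        return self.T is None or self.low == self.high

    def __call__(self, t: float) -> float:
        return eval_schedule(self, t)

    def boundaries(self, t_end: float) -> tuple[float, ...]:
        """Phase-change times in ``(0, t_end)``, in increasing order."""
        if self.is_constant:
            return ()
        assert self.T is not None
        out = []
        k = 1
        while k * self.T < t_end:
            out.append(k * self.T)
            k += 1
        return tuple(out)


def eval_schedule(schedule: PiecewiseSchedule, t: float) -> float:
    """Evaluate a :class:`PiecewiseSchedule` at time ``t`` (>= 0)."""
    if t < 0:
        raise ValueError(f"schedule time must be >= 0, got {t}")
    if schedule.T is None:
        return schedule.low
    phase = math.floor(t / schedule.T) % 2
    return schedule.low if phase == 0 else schedule.high


def hill_repression_rate(repressor_count: int, v_s: float, K_I: float, n: int) -> float:
    """Hill-repressed transcription rate ``v_s * K_I^n / (count^n + K_I^n)``.

    ``K_I`` is the repression threshold (the rate is halved when the
    repressor count equals ``K_I``); the Hill coefficient ``n`` sets the
    cooperativity of repression.  Strictly decreasing in the count.
    """
    if repressor_count < 0:
        raise ValueError("repressor count must be >= 0")
    kin = float(K_I) ** n
    return v_s * kin / (float(repressor_count) ** n + kin)


def michaelis_rate(count: int, v_max: float, K: float) -> float:
    """Michaelis-Menten rate ``v_max * count / (K + count)``.

    Zero at zero count and saturating at ``v_max``; ``K`` is the
    half-saturation count.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    return v_max * count / (K + count)


@dataclass(frozen=True)
class NeurosporaParams:
    """Parameters of the frq/FRQ circadian oscillator, molecule units.

    Concentrations are discretised at 1 nM = 100 molecules; rates are per
    hour.  ``v_s`` (maximum transcription rate) is a schedule: constant 160
    in constant darkness, alternating 160 (dark) / 200 (light) under
    dark/light forcing.
    """

    v_m: float = 50.5   # max mRNA degradation rate
    v_d: float = 140.0  # max FRQ degradation rate
    k_s: float = 0.5    # translation rate constant (per mRNA per hour)
    k_1: float = 0.5    # FRQ nuclear import rate constant
    k_2: float = 0.6    # FRQ nuclear export rate constant
    K_m: float = 50.0   # Michaelis constant, mRNA degradation
    K_I: float = 100.0  # repression threshold (nuclear FRQ)
    K_d: float = 13.0   # Michaelis constant, FRQ degradation
    n: int = 4          # Hill coefficient of repression
    schedule: PiecewiseSchedule = field(
        default_factory=lambda: PiecewiseSchedule.constant(160.0)
    )

    def __post_init__(self) -> None:
        for name in ("v_m", "v_d", "k_s", "k_1", "k_2", "K_m", "K_I", "K_d"):
            if not getattr(self, name) > 0:
                raise ModelError(f"Neurospora parameter {name} must be positive")
        if self.n < 1:
            raise ModelError("Hill coefficient n must be an integer >= 1")


@dataclass(frozen=True)
class Model:
    name: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    initial_state: SystemState
    observed_species: tuple[str, ...] = ()
    schedule: PiecewiseSchedule | None = None  # drives time-varying rate functions

    def __post_init__(self) -> None:
        if not self.observed_species:
            object.__setattr__(self, "observed_species", self.species)

    def rate_boundaries(self, t_end: float) -> tuple[float, ...]:
        """Times in ``(0, t_end)`` at which a rate function jumps."""
        if self.schedule is None:
            return ()
        return self.schedule.boundaries(t_end)


def validate_model(model: Model) -> Model:
    """Check internal consistency; returns the model unchanged if valid."""
    declared = set(model.species)
    for rx in model.reactions:
        for sp, _ in (*rx.reactants, *rx.products):
            if sp not in declared:
                raise ModelError(
                    f"reaction {rx.name or rx!r} references undeclared species {sp!r}"
                )
        for sp in rx.buffered:
            if sp not in declared:
                raise ModelError(f"buffered species {sp!r} is not declared")
    for sp, c in model.initial_state.counts.items():
        if sp not in declared:
            raise ModelError(f"initial count for undeclared species {sp!r}")
        if c < 0:
            raise ModelError(f"negative initial count for {sp!r}: {c}")
    for sp in model.observed_species:
        if sp not in declared:
            raise ModelError(f"observed species {sp!r} is not declared")
    return model


# ---------------------------------------------------------------------------
# Built-in models


def _schlogl() -> Model:
    buffered = frozenset({"B"})
    reactions = (
        Reaction((("A", 2),), (("A", 3),), MassAction(0.03), name="autocatalysis"),
        Reaction((("A", 3),), (("A", 2),), MassAction(0.0001), name="back-reaction"),
        Reaction((("B", 1),), (("B", 1), ("A", 1)), MassAction(200.0), buffered, name="influx"),
        Reaction((("A", 1),), (), MassAction(3.5), name="decay"),
    )
    return Model(
        name="schlogl",
        species=("A", "B"),
        reactions=reactions,
        initial_state=SystemState({"A": 250, "B": 1}),
        observed_species=("A",),
    )


def _lambda_phage() -> Model:
    """Lysis/lysogeny switch: CI dimerisation and operator binding.

    ``D_act`` is phage DNA with a CI2 dimer on the transcription-promoting
    site, ``D_rep`` with a dimer on the repressing site, ``D_both`` with
    both sites bound (globally repressed).  RNA polymerase ``P`` acts as a
    conserved catalyst; transcription from ``D_act`` yields two CI
    monomers per transcript.
    """
    MA = MassAction
    rx = (
        Reaction((("CI", 2),), (("CI2", 1),), MA(0.05), name="dimerise"),
        Reaction((("CI2", 1),), (("CI", 2),), MA(0.5), name="dissociate"),
        Reaction((("CI2", 1), ("D", 1)), (("D_act", 1),), MA(0.026), name="bind+"),
        Reaction((("D_act", 1),), (("CI2", 1), ("D", 1)), MA(0.026), name="unbind+"),
        Reaction((("CI2", 1), ("D", 1)), (("D_rep", 1),), MA(0.026), name="bind-"),
        Reaction((("D_rep", 1),), (("CI2", 1), ("D", 1)), MA(0.026), name="unbind-"),
        Reaction((("D_act", 1), ("CI2", 1)), (("D_both", 1),), MA(0.13), name="bind2nd"),
        Reaction((("D_both", 1),), (("D_act", 1), ("CI2", 1)), MA(0.13), name="unbind2nd"),
        Reaction(
            (("D_act", 1), ("P", 1)),
            (("D_act", 1), ("P", 1), ("CI", 2)),
            MA(40.0),
            name="transcribe",
        ),
        Reaction((("CI", 1),), (), MA(0.0007), name="degrade"),
    )
    return Model(
        name="lambda_phage",
        species=("CI", "CI2", "D", "D_act", "D_rep", "D_both", "P"),
        reactions=rx,
        initial_state=SystemState({"CI": 10, "CI2": 0, "D": 1, "D_act": 0, "D_rep": 0, "D_both": 0, "P": 1}),
        observed_species=("CI",),
    )


def _neurospora(condition: str = "dark", T: float = 12.0,
                params: NeurosporaParams | None = None) -> Model:
    if condition not in ("dark", "alternate"):
        raise ModelError(f"unknown Neurospora condition {condition!r}")
    if condition == "dark":
        schedule = PiecewiseSchedule.constant(160.0)
    else:
        schedule = PiecewiseSchedule.alternating(160.0, 200.0, T)
    p = params if params is not None else NeurosporaParams(schedule=schedule)
    if params is not None and condition is not None:
        p = replace(p, schedule=schedule)

    def f_frq(counts: Mapping[str, int], t: float) -> float:
        # transcription repressed by the *nuclear* form of FRQ
        return hill_repression_rate(counts["FRQin"], p.schedule(t), p.K_I, p.n)

    def f_m(counts: Mapping[str, int], t: float) -> float:
        return michaelis_rate(counts["M"], p.v_m, p.K_m)

    def f_d(counts: Mapping[str, int], t: float) -> float:
        return michaelis_rate(counts["FRQ"], p.v_d, p.K_d)

    rx = (
        Reaction((("FRQin", 1),), (("FRQin", 1), ("M", 1)),
                 RateFunction(f_frq, "f_FRQ"), name="transcription"),
        Reaction((("M", 1),), (("M", 1), ("FRQ", 1)), MassAction(p.k_s), name="translation"),
        Reaction((("M", 1),), (), RateFunction(f_m, "f_M"), name="mRNA decay"),
        Reaction((("FRQ", 1),), (), RateFunction(f_d, "f_d"), name="FRQ decay"),
        Reaction((("FRQ", 1),), (("FRQin", 1),), MassAction(p.k_1), name="import"),
        Reaction((("FRQin", 1),), (("FRQ", 1),), MassAction(p.k_2), name="export"),
    )
    return Model(
        name=f"neurospora[{condition}]",
        species=("M", "FRQ", "FRQin"),
        reactions=rx,
        initial_state=SystemState({"M": 10, "FRQ": 10, "FRQin": 10}),
        observed_species=("M", "FRQ", "FRQin"),
        schedule=None if schedule.is_constant else schedule,
    )


_BUILTINS = {"schlogl": _schlogl, "lambda_phage": _lambda_phage, "neurospora": _neurospora}


def builtin_model(name: str, **options) -> Model:
    """Return a fully parameterised built-in model.

    ``neurospora`` accepts ``condition`` ("dark" or "alternate"), the
    dark/light phase length ``T`` in hours (default 12, i.e. a 24 h forcing
    period) and an optional ``params`` override.
    """
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise ModelError(
            f"unknown builtin model {name!r}; available: {sorted(_BUILTINS)}"
        ) from None
    if options and name != "neurospora":
        raise ModelError(f"model {name!r} accepts no options")
    return validate_model(factory(**options))
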
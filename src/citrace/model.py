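"""Positional ¹³C labeling model of citrate secreted from the Krebs cycle.

The model tracks the expected fractional ¹³C excess at the six carbon
positions of citrate (first moments, not full isotopomer vectors) as label
from a ¹³C-enriched substrate enters the cycle and citrate repeatedly
re-enters it.  Two routes feed label into a newly formed citrate:

* the pyruvate-dehydrogenase (PDC) route via acetyl-CoA, which places label
  on a single citrate carbon (C2 for [1,6-¹³C₂]glucose, C1 for
  [2-¹³C]pyruvate), and
* the pyruvate-carboxylase (PC) route via oxaloacetate, which places label
  equally on C3 and C4 because of complete positional scrambling in the
  rapidly exchanging malate/fumarate/oxaloacetate pool.

Each cycle turn, a fraction ``d`` of the citrate pool diverges from the
cycle (secretion plus any other cataplerotic efflux) while the remaining
``1 - d`` is processed onward; carbons move C1→(C5,C6)/2, C2→(C3,C4)/2,
C3→(C3,C4)/2, C4→(C5,C6)/2 and C5, C6 leave as CO₂.  The secreted pool is
the geometric mixture of all generations, from which the diagnostic ratios

    R1 = ((C2 + C4) - C3) / (C2 + C4)        (glucose tracer)
    R2 = (C1 + C5) / C3                      ([2-¹³C]pyruvate tracer)

are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .errors import CitraceError, UndefinedRatioError

__all__ = [
    "TracerSpec",
    "ModelParams",
    "CitrateLabelState",
    "SecretedDistribution",
    "RatioSet",
    "TURN_TRANSITION",
    "initial_label_pattern",
    "turn_transition",
    "secreted_distribution",
    "ratio_R1",
    "ratio_R2",
    "expected_turns",
    "r1_vs_d_curve",
]

#: Default pool enrichments for the [1,6-13C2]glucose experiment: the
#: pyruvate pool is ~80% labeled (from lactate satellites) and acetyl-CoA
#: ~56% (from the glutamate C4 labeling pattern) in LNCaP cells.
GLUCOSE_F_P_DEFAULT = 0.80
GLUCOSE_F_A_DEFAULT = 0.56

#: Default pool enrichments for the [2-13C]pyruvate experiment: the pyruvate
#: pool is ~83% labeled; the acetyl-CoA enrichment was not measured in that
#: experiment, so the acetyl/pyruvate enrichment ratio of the glucose
#: experiment (0.56/0.80 = 0.70) is carried over.  Only the f_a/f_p ratio
#: enters R2, so the absolute pyruvate value drops out of the inversion.
PYRUVATE_F_P_DEFAULT = 0.83
PYRUVATE_F_A_DEFAULT = 0.83 * (GLUCOSE_F_A_DEFAULT / GLUCOSE_F_P_DEFAULT)

_ENGINE_TRACERS = ("glucose_1_6", "pyruvate_2")


@dataclass(frozen=True)
class TracerSpec:
    """Which substrate is labeled and where its carbons enter citrate.

    Parameters
    ----------
    tracer_id
        One of ``glucose_1_6``, ``pyruvate_2`` or ``glutamine_5``.
    pdc_entry_positions
        Citrate positions (1-based) receiving label via acetyl-CoA.
    pc_entry_positions
        Citrate positions receiving label via PC-derived oxaloacetate.
    f_p, f_a
        Fractional ¹³C enrichment of the pyruvate and acetyl-CoA pools.
    """

    tracer_id: str
    pdc_entry_positions: frozenset[int]
    pc_entry_positions: frozenset[int]
    f_p: float
    f_a: float

    def __post_init__(self) -> None:
        for name in ("f_p", "f_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("pdc_entry_positions", "pc_entry_positions"):
            positions = getattr(self, name)
            if not frozenset(positions) <= frozenset(range(1, 7)):
                raise ValueError(f"{name} must be a subset of {{1..6}}, got {positions}")
            object.__setattr__(self, name, frozenset(positions))

    @classmethod
    def glucose_1_6(
        cls, f_p: float = GLUCOSE_F_P_DEFAULT, f_a: float = GLUCOSE_F_A_DEFAULT
    ) -> "TracerSpec":
        """[1,6-¹³C₂]glucose: glycolysis yields [3-¹³C]pyruvate, so acetyl-CoA
        label lands on citrate C2 and PC label on C3/C4."""
        return cls("glucose_1_6", frozenset({2}), frozenset({3, 4}), f_p, f_a)

    @classmethod
    def pyruvate_2(
        cls, f_p: float = PYRUVATE_F_P_DEFAULT, f_a: float = PYRUVATE_F_A_DEFAULT
    ) -> "TracerSpec":
        """[2-¹³C]pyruvate: acetyl-CoA label lands on citrate C1, PC label on
        C3/C4."""
        return cls("pyruvate_2", frozenset({1}), frozenset({3, 4}), f_p, f_a)

    @classmethod
    def glutamine_5(cls, f_p: float = 0.0, f_a: float = 0.0) -> "TracerSpec":
        """[5-¹³C]glutamine labels citrate directly: C1 via reductive
        carboxylation, C5/C6 via the oxidative route.  This tracer is handled
        by :mod:`citrace.glutamine` and is rejected by the turn-transition
        engine (no R1/R2 are defined for it)."""
        return cls("glutamine_5", frozenset({1}), frozenset({5, 6}), f_p, f_a)


@dataclass(frozen=True)
class ModelParams:
    """Apparent per-turn secretion fraction ``d`` and PC fraction ``p``.

    ``d`` is the fraction of citrate-equivalents leaving the Krebs cycle per
    turn (an upper bound on the true citrate secretion fraction when other
    effluxes exist); ``p`` is the fraction of labeled-carbon entry events
    that arrive via PC rather than PDC.
    """

    d: float
    p: float
    max_turns: int = 200
    tol: float = 1e-12

    def __post_init__(self) -> None:
        if not 0.0 < self.d <= 1.0:
            if self.d == 0.0:
                raise CitraceError("d = 0: no secretion; distribution undefined")
            raise ValueError(f"d must lie in (0, 1], got {self.d}")
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"p must lie in [0, 1), got {self.p}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_turns < 1:
            raise ValueError("max_turns must be >= 1")


@dataclass(frozen=True)
class CitrateLabelState:
    """Expected fractional ¹³C excess at citrate C1..C6 for one generation."""

    c: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        arr = np.asarray(self.c, dtype=float)
        if arr.shape != (6,):
            raise ValueError(f"label state must have 6 positions, got shape {arr.shape}")
        if (arr < -1e-15).any() or (arr > 1 + 1e-12).any():
            raise ValueError("positional enrichments must lie in [0, 1]")
        object.__setattr__(self, "c", arr)

    def __getitem__(self, position: int) -> float:
        """1-based access: ``state[3]`` is the C3 enrichment."""
        if not 1 <= position <= 6:
            raise IndexError("citrate positions are 1..6")
        return float(self.c[position - 1])


@dataclass(frozen=True)
class SecretedDistribution:
    """Label accumulated over all secreted citrate generations."""

    s: npt.NDArray[np.float64]
    n_turns_used: int
    converged: bool

    def __post_init__(self) -> None:
        arr = np.asarray(self.s, dtype=float)
        if arr.shape != (6,):
            raise ValueError("secreted distribution must have 6 positions")
        if (arr < -1e-15).any():
            raise ValueError("secreted label must be nonnegative")
        object.__setattr__(self, "s", arr)

    def __getitem__(self, position: int) -> float:
        if not 1 <= position <= 6:
            raise IndexError("citrate positions are 1..6")
        return float(self.s[position - 1])


@dataclass(frozen=True)
class RatioSet:
    """The pair of citrate carbon integral ratios used by the inversion."""

    R1: float
    R2: float


# Per-turn carbon fate map (columns = source position, rows = destination).
# C1 -> (C5, C6)/2; C2 -> (C3, C4)/2; C3 -> (C3, C4)/2; C4 -> (C5, C6)/2;
# C5, C6 leave as CO2.  Columns 1-4 each sum to 1 (sub-stochastic map).
TURN_TRANSITION: npt.NDArray[np.float64] = np.array(
    [
        # C1   C2   C3   C4   C5   C6
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # -> C1
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # -> C2
        [0.0, 0.5, 0.5, 0.0, 0.0, 0.0],  # -> C3
        [0.0, 0.5, 0.5, 0.0, 0.0, 0.0],  # -> C4
        [0.5, 0.0, 0.0, 0.5, 0.0, 0.0],  # -> C5
        [0.5, 0.0, 0.0, 0.5, 0.0, 0.0],  # -> C6
    ]
)


def initial_label_pattern(tracer: TracerSpec, params: ModelParams) -> CitrateLabelState:
    """Generation-0 citrate labeling from one condensation event.

    A weight of ``(1 - p) * f_a`` goes on the single PDC entry position and
    ``p * f_p`` is split equally over the two PC entry positions (complete
    oxaloacetate-pool scrambling).  CO₂ refixed by PC is treated as
    unlabeled, so PC introduces label only through pyruvate carbons.
    """
    if tracer.tracer_id not in _ENGINE_TRACERS:
        raise CitraceError(
            f"tracer {tracer.tracer_id!r} is not supported by the turn-transition "
            f"engine; supported tracers: {', '.join(_ENGINE_TRACERS)}"
        )
    c = np.zeros(6)
    (pdc_pos,) = tracer.pdc_entry_positions
    c[pdc_pos - 1] = (1.0 - params.p) * tracer.f_a
    pc_weight = params.p * tracer.f_p / len(tracer.pc_entry_positions)
    for pos in tracer.pc_entry_positions:
        c[pos - 1] += pc_weight
    return CitrateLabelState(c)


def turn_transition(state: CitrateLabelState) -> CitrateLabelState:
    """Advance citrate label one Krebs-cycle turn (no fresh label added)."""
    return CitrateLabelState(TURN_TRANSITION @ state.c)


def secreted_distribution(tracer: TracerSpec, params: ModelParams) -> SecretedDistribution:
    """Accumulated positional label of citrate secreted over all generations.

    Returns ``s = Σ_k d (1-d)^k T^k L0`` where ``L0`` is the generation-0
    pattern and ``T`` the turn-transition map, truncated once the increment's
    largest entry drops below ``params.tol`` or ``params.max_turns`` is
    reached.  The converged flag records which stop condition fired.
    """
    c = initial_label_pattern(tracer, params).c
    d = params.d
    s = np.zeros(6)
    weight = d
    converged = False
    n_turns = 0
    for k in range(params.max_turns + 1):
        increment = weight * c
        s += increment
        n_turns = k
        if increment.max() < params.tol:
            converged = True
            break
        c = TURN_TRANSITION @ c
        weight *= 1.0 - d
    return SecretedDistribution(s, n_turns_used=n_turns, converged=converged)


def ratio_R1(dist: SecretedDistribution) -> float:
    """R1 = ((C2 + C4) − C3) / (C2 + C4), the apparent-divergence index."""
    c24 = dist[2] + dist[4]
    if c24 <= 0:
        raise UndefinedRatioError("R1 undefined: C2 + C4 integral is zero")
    return (c24 - dist[3]) / c24


def ratio_R2(dist: SecretedDistribution) -> float:
    """R2 = (C1 + C5) / C3; C3 can only be labeled via the PC route."""
    if dist[3] <= 0:
        raise UndefinedRatioError("R2 undefined: C3 integral is zero (p = 0 input?)")
    return (dist[1] + dist[5]) / dist[3]


def expected_turns(d: float) -> float:
    """Mean number of Krebs-cycle turns a label completes before secretion.

    The turn count is geometric with per-turn exit probability ``d``; its
    mean is ``(1 - d) / d``.
    """
    if not 0.0 < d <= 1.0:
        raise CitraceError(f"d must lie in (0, 1], got {d}")
    return (1.0 - d) / d


def r1_vs_d_curve(
    p: float, tracer: TracerSpec, d_grid: npt.NDArray[np.float64]
) -> list[tuple[float, float]]:
    """Evaluate R1 along a grid of secretion fractions at fixed PC fraction.

    For ``p > 0`` the curve has a nonzero offset from 0.5 at small ``d``
    because the PC route feeds C3 directly.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    if d_grid.size == 0:
        raise CitraceError("d_grid must not be empty")
    if ((d_grid <= 0) | (d_grid > 1)).any():
        raise CitraceError("all d values must lie in (0, 1]")
    out = []
    for d in d_grid:
        dist = secreted_distribution(tracer, ModelParams(d=float(d), p=p))
        out.append((float(d), ratio_R1(dist)))
    return out
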
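"""Invert measured citrate carbon ratios (R1, R2) to model parameters (d, p).

R1 from the [1,6-¹³C₂]glucose experiment and R2 from the [2-¹³C]pyruvate
experiment are jointly solved for the apparent per-turn secretion fraction
``d`` and the PC fraction ``p``.  R1 is strictly increasing in ``d`` (at
fixed ``p``) and R2 strictly decreasing in ``p`` (at fixed ``d``) over the
admissible region, so the solution is found as the unique intersection of
the two constraint curves p(d | R1) and p(d | R2), followed by a Newton
refinement of the 2-vector residual.

Note that ``d`` estimated here is an upper bound on the true citrate
secretion fraction ``c``: any other cataplerotic efflux (glutamate,
aspartate, malate...) also removes carbons each turn and is absorbed into
the apparent divergence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ModelRangeError, MultipleRootsError
from .model import ModelParams, TracerSpec, expected_turns, ratio_R1, ratio_R2, secreted_distribution

__all__ = ["InversionResult", "invert_ratios", "pc_vs_d_curves", "solve_p_at_fixed_d"]

logger = logging.getLogger(__name__)

_P_MAX = 0.995  # open upper bound for the PC fraction during the search
_D_MIN = 1e-4


@dataclass(frozen=True)
class InversionResult:
    """Joint solution of R1(d, p) = R1_obs and R2(d, p) = R2_obs.

    ``residual`` is the max absolute difference between modeled and observed
    ratios at the solution.  ``expected_turns`` is (1 - d_hat)/d_hat.  The
    true citrate secretion fraction c satisfies c <= d_hat.
    """

    d_hat: float
    p_hat: float
    residual: float
    expected_turns: float
    R1_obs: float
    R2_obs: float
    f_p_glucose: float
    f_a_glucose: float
    f_p_pyruvate: float
    f_a_pyruvate: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _model_r1(d: float, p: float, tracer: TracerSpec) -> float:
    return ratio_R1(secreted_distribution(tracer, ModelParams(d=d, p=p)))


def _model_r2(d: float, p: float, tracer: TracerSpec) -> float:
    return ratio_R2(secreted_distribution(tracer, ModelParams(d=d, p=p)))


def _r1_envelope(tracer: TracerSpec) -> tuple[float, float]:
    """Attainable R1 range over (d, p) in (0, 1] x [0, 1)."""
    lo = _model_r1(_D_MIN, _P_MAX, tracer)
    hi = _model_r1(1.0, 0.0, tracer)
    return lo, hi


def solve_p_at_fixed_d(
    ratio_obs: float,
    d: float,
    tracer: TracerSpec,
    which: str = "R2",
) -> float | None:
    """Solve R1(d, p) = ratio_obs or R2(d, p) = ratio_obs for p at fixed d.

    Returns None when no root exists at this d (the observed ratio is outside
    the attainable range there).  Exposed so that a PC fraction can be
    explored for a cell line whose R1 (hence d) was not measured.
    """
    fn = _model_r2 if which == "R2" else _model_r1
    lo, hi = 1e-9, _P_MAX
    f_lo = fn(d, lo, tracer) - ratio_obs
    f_hi = fn(d, hi, tracer) - ratio_obs
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        return None
    return float(optimize.brentq(lambda p: fn(d, p, tracer) - ratio_obs, lo, hi, xtol=1e-12))


def invert_ratios(
    R1_obs: float,
    R2_obs: float,
    glucose_tracer: TracerSpec | None = None,
    pyruvate_tracer: TracerSpec | None = None,
    grid_step: float = 0.01,
    tol: float = 1e-8,
) -> InversionResult:
    """Jointly solve the forward model for (d, p) from measured (R1, R2).

    Parameters
    ----------
    R1_obs
        ((C2+C4) - C3)/(C2+C4) from the glucose-tracer ¹³C spectrum; must lie
        in (0, 1] and inside the jointly attainable envelope.
    R2_obs
        (C1+C5)/C3 from the [2-¹³C]pyruvate spectrum; must be positive.
    glucose_tracer, pyruvate_tracer
        Tracer specifications carrying the pool enrichments; default to the
        measured LNCaP enrichments (f_p = 0.80, f_a = 0.56 for glucose) and
        the glucose-experiment f_a/f_p ratio carried over to pyruvate.

    Raises
    ------
    ModelRangeError
        If the observed ratios lie outside the attainable envelope; the
        message reports the attainable R1/R2 ranges.
    MultipleRootsError
        If the constraint curves intersect more than once on the grid.
    """
    glucose_tracer = glucose_tracer or TracerSpec.glucose_1_6()
    pyruvate_tracer = pyruvate_tracer or TracerSpec.pyruvate_2()

    r1_lo, r1_hi = _r1_envelope(glucose_tracer)
    if not 0.0 < R1_obs <= 1.0:
        raise ModelRangeError(
            f"R1 = {R1_obs} outside model range; attainable R1 spans "
            f"({r1_lo:.3f}, {r1_hi:.3f}]"
        )
    if R2_obs <= 0:
        raise ModelRangeError(f"R2 = {R2_obs} must be positive")

    # Constraint curves p(d | R1_obs) and p(d | R2_obs) on the d grid; their
    # intersection(s) show up as sign changes of the gap between them.
    d_grid = np.arange(grid_step, 1.0 + grid_step / 2, grid_step)
    gaps = np.full(d_grid.size, np.nan)
    for i, d in enumerate(d_grid):
        p1 = solve_p_at_fixed_d(R1_obs, float(d), glucose_tracer, which="R1")
        p2 = solve_p_at_fixed_d(R2_obs, float(d), pyruvate_tracer, which="R2")
        if p1 is not None and p2 is not None:
            gaps[i] = p1 - p2

    valid = ~np.isnan(gaps)
    if not valid.any():
        raise ModelRangeError(
            "ratios outside model range: no d admits both constraints; "
            f"attainable R1 spans ({r1_lo:.3f}, {r1_hi:.3f}]"
        )
    vi = np.flatnonzero(valid)
    sign_changes = np.flatnonzero(np.diff(np.sign(gaps[vi])) != 0)
    if sign_changes.size == 0:
        raise ModelRangeError(
            "ratios outside model range: constraint curves do not intersect in "
            f"(0, 1] x [0, 1); attainable R1 spans ({r1_lo:.3f}, {r1_hi:.3f}]"
        )

    def gap(d: float) -> float:
        p1 = solve_p_at_fixed_d(R1_obs, d, glucose_tracer, which="R1")
        p2 = solve_p_at_fixed_d(R2_obs, d, pyruvate_tracer, which="R2")
        if p1 is None or p2 is None:
            raise ModelRangeError("constraint curve left the admissible region")
        return p1 - p2

    # Refine every bracketed crossing; a shallow (near-tangent) intersection
    # can show up as two adjacent sign changes that converge to one root, so
    # candidates are deduplicated by proximity before declaring ambiguity.
    candidates: list[tuple[float, float]] = []
    for ci in sign_changes:
        d_lo, d_hi = float(d_grid[vi[ci]]), float(d_grid[vi[ci + 1]])
        d_root = float(optimize.brentq(gap, d_lo, d_hi, xtol=1e-12))
        p_root = solve_p_at_fixed_d(R1_obs, d_root, glucose_tracer, which="R1")
        if p_root is None:
            continue
        if not any(abs(d_root - dc) < 1e-6 and abs(p_root - pc) < 1e-6
                   for dc, pc in candidates):
            candidates.append((d_root, p_root))
    if not candidates:
        raise ModelRangeError(
            "ratios outside model range: no refinable intersection; "
            f"attainable R1 spans ({r1_lo:.3f}, {r1_hi:.3f}]"
        )
    if len(candidates) > 1:
        raise MultipleRootsError(
            f"multiple (d, p) candidates: {[(round(a, 4), round(b, 4)) for a, b in candidates]}"
        )
    d0, p0 = candidates[0]

    def residual(x: np.ndarray) -> list[float]:
        d, p = float(x[0]), float(x[1])
        d = min(max(d, _D_MIN), 1.0)
        p = min(max(p, 0.0), _P_MAX)
        return [
            _model_r1(d, p, glucose_tracer) - R1_obs,
            _model_r2(d, p, pyruvate_tracer) - R2_obs,
        ]

    sol = optimize.root(residual, [d0, p0], method="hybr", tol=1e-12)
    d_hat, p_hat = float(sol.x[0]), float(sol.x[1])
    res = float(np.max(np.abs(residual(sol.x))))
    if res > tol:
        raise ModelRangeError(
            f"inversion residual {res:.2e} exceeds tolerance {tol:.1e}; "
            f"attainable R1 spans ({r1_lo:.3f}, {r1_hi:.3f}]"
        )
    logger.info(
        json.dumps(
            {
                "event": "invert_ratios",
                "R1_obs": R1_obs,
                "R2_obs": R2_obs,
                "d_hat": d_hat,
                "p_hat": p_hat,
                "residual": res,
            }
        )
    )
    return InversionResult(
        d_hat=d_hat,
        p_hat=p_hat,
        residual=res,
        expected_turns=expected_turns(d_hat),
        R1_obs=R1_obs,
        R2_obs=R2_obs,
        f_p_glucose=glucose_tracer.f_p,
        f_a_glucose=glucose_tracer.f_a,
        f_p_pyruvate=pyruvate_tracer.f_p,
        f_a_pyruvate=pyruvate_tracer.f_a,
    )


def pc_vs_d_curves(
    R1_obs: float,
    R2_obs: float,
    glucose_tracer: TracerSpec | None = None,
    pyruvate_tracer: TracerSpec | None = None,
    d_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """PC-fraction-vs-d diagnostic curves whose intersection is the solution.

    For each d in the grid, the p solving R1(d, p) = R1_obs and separately
    the p solving R2(d, p) = R2_obs.  Grid points where a constraint has no
    solution are reported as NaN (and logged).  Returns a DataFrame with
    columns ``d``, ``p_R1``, ``p_R2``.
    """
    glucose_tracer = glucose_tracer or TracerSpec.glucose_1_6()
    pyruvate_tracer = pyruvate_tracer or TracerSpec.pyruvate_2()
    if d_grid is None:
        d_grid = np.arange(0.01, 1.001, 0.01)
    d_grid = np.asarray(d_grid, dtype=float)
    if d_grid.size == 0:
        raise ModelRangeError("d_grid must not be empty")
    rows = []
    for d in d_grid:
        p1 = solve_p_at_fixed_d(R1_obs, float(d), glucose_tracer, which="R1")
        p2 = solve_p_at_fixed_d(R2_obs, float(d), pyruvate_tracer, which="R2")
        if p1 is None or p2 is None:
            logger.info(
                json.dumps({"event": "pc_vs_d_no_solution", "d": float(d),
                            "p_R1": p1, "p_R2": p2})
            )
        rows.append({"d": float(d), "p_R1": p1, "p_R2": p2})
    return pd.DataFrame(rows)
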
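"""Inversion of the regression clocks into per-marker age trajectories.

The synthetic-cohort generator needs, for every marker, a linear methylation
trajectory m(a) = alpha + beta * a such that each regression clock evaluated
on those trajectories returns (approximately) the chronological age a.  This
module solves the joint inverse problem: minimise

    sum_clocks sum_grid (predict(clock, m(a)) - a)^2  +  ridge * ||params - params0||^2

over (alpha_m, beta_m) for all markers the clocks use, with the sign of
beta_m constrained to the marker's expected age-correlation direction.  The
small ridge term (1e-6) breaks ties when the problem is degenerate by
choosing the exact fit nearest the initial guess, making the result
deterministic.

Because several exact inversions usually exist (more trajectory parameters
than polynomial matching conditions), a soft hinge penalty additionally keeps
each trajectory inside [margin, 100 - margin] percent over the grid, so that
downstream simulation noise is not truncated at the 0/100 bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .clocks import ClockModel
from .markers import get_marker

__all__ = ["CalibrationResult", "CalibrationWarning", "UnderDeterminedError", "calibrate_trajectories"]

_RIDGE = 1e-6


class UnderDeterminedError(ValueError):
    """The age grid does not determine a linear trajectory."""


class CalibrationWarning(UserWarning):
    """A sign constraint was active at the optimum; best feasible fit returned."""


@dataclass
class CalibrationResult:
    """Fitted linear trajectories and per-clock inversion residuals."""

    trajectories: dict[str, tuple[float, float]]  # marker -> (alpha %, beta %/yr)
    residual_rms: dict[str, float]  # clock name -> RMS of (prediction - age), years


def _clock_residuals(clock: ClockModel, meth: dict[str, np.ndarray], ages: np.ndarray) -> np.ndarray:
    pred = np.full_like(ages, float(clock.intercept))
    for t in clock.terms:
        pred = pred + t.coefficient * meth[t.marker_id] ** t.exponent
    return pred - ages


def calibrate_trajectories(
    clocks: Sequence[ClockModel],
    age_grid: Sequence[float],
    range_margin: float = 8.0,
    min_slope: float = 0.1,
    initial_trajectories: dict[str, tuple[float, float]] | None = None,
) -> CalibrationResult:
    """Fit per-marker linear trajectories inverting the given MLR/MQR clocks.

    GBR clocks are excluded (no closed form to invert). ``range_margin`` is
    the softly-enforced distance (percent) each trajectory keeps from the
    0/100 methylation bounds over the grid; ``min_slope`` (percent/year) is
    the minimum trajectory slope magnitude, so every marker retains an age
    correlation of its expected sign in simulated data.
    ``initial_trajectories`` optionally seeds the optimizer with per-marker
    (alpha, beta) guesses; since the inverse problem usually has a manifold
    of exact solutions, the fit converges to the one nearest the guess.
    Raises
    :class:`UnderDeterminedError` for a grid with fewer than two distinct
    ages; warns (:class:`CalibrationWarning`) when a sign constraint binds.
    """
    ages = np.asarray(sorted(age_grid), dtype=float)
    if np.unique(ages).size < 2:
        raise UnderDeterminedError("age grid must contain at least two distinct ages")
    reg_clocks = [c for c in clocks if c.form != "GBR"]
    if not reg_clocks:
        raise ValueError("no MLR/MQR clocks to calibrate")

    markers = sorted({m for c in reg_clocks for m in c.required_markers})
    signs = {m: get_marker(m).expected_sign for m in markers}

    def unpack(params: np.ndarray) -> dict[str, np.ndarray]:
        return {
            m: params[2 * i] + params[2 * i + 1] * ages for i, m in enumerate(markers)
        }

    lo_bound, hi_bound = range_margin, 100.0 - range_margin
    range_w = 1.0 / np.sqrt(len(ages))

    init = initial_trajectories or {}
    x0, lower, upper = [], [], []
    for m in markers:
        a0, b0 = init.get(m, (50.0, 0.3 * signs[m]))
        if b0 * signs[m] < min_slope:
            b0 = min_slope * signs[m]
        x0 += [float(a0), float(b0)]
        lower += [-np.inf, min_slope if signs[m] > 0 else -np.inf]
        upper += [np.inf, np.inf if signs[m] > 0 else -min_slope]
    x0_arr = np.asarray(x0)

    def residuals(params: np.ndarray) -> np.ndarray:
        meth = unpack(params)
        res = [
            _clock_residuals(c, meth, ages) / np.sqrt(len(ages)) for c in reg_clocks
        ]
        for m in markers:
            res.append(range_w * np.maximum(0.0, lo_bound - meth[m]))
            res.append(range_w * np.maximum(0.0, meth[m] - hi_bound))
        # tie-break on the exact-fit manifold: smallest move from the guess
        res.append(np.sqrt(_RIDGE) * (params - x0_arr))
        return np.concatenate(res)

    sol = least_squares(
        residuals, np.asarray(x0), bounds=(np.asarray(lower), np.asarray(upper)),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20000,
    )

    params = sol.x
    meth = unpack(params)
    rms = {
        c.name: float(np.sqrt(np.mean(_clock_residuals(c, meth, ages) ** 2)))
        for c in reg_clocks
    }
    at_bound = any(
        abs(abs(params[2 * i + 1]) - min_slope) < 1e-10 for i in range(len(markers))
    )
    if at_bound and max(rms.values()) > 0.1:
        warnings.warn(
            "a sign/slope constraint prevented exact clock inversion; "
            "returning best feasible fit",
            CalibrationWarning,
            stacklevel=2,
        )
    traj = {
        m: (float(params[2 * i]), float(params[2 * i + 1])) for i, m in enumerate(markers)
    }
    return CalibrationResult(trajectories=traj, residual_rms=rms)
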
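"""Experiment planning: setpoints, density grids and anoxia screening.

The practical use of the reaction–diffusion model is inverse: given a
desired *pericellular* tension, what incubator setpoint (or density, or
vessel) achieves it?  Three utilities cover the common questions:

* ``solve_setpoint`` — root-find the gas-phase setpoint whose predicted
  pericellular O2 hits a target, exploiting (and asserting) that the
  pericellular tension increases monotonically with the setpoint.
* ``prediction_grid`` — tabulate pericellular O2 over (vessel, density)
  combinations, the standard way to see that the same culture goes anoxic
  in a 96-well long before it does in a 6-well.
* ``anoxia_check`` — screen a planned culture for silent pericellular
  anoxia, flagged whenever the predicted trace drops below 0.5 % O2 (with
  the first-crossing time).

"Steady" predictions default to a 48 h horizon — long enough for every
standard vessel to reach its quasi-steady gradient — and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import (
    DEFAULT_OPTIONS,
    GasSchedule,
    SolverOptions,
    TransportParams,
)
from .reaction import ConsumptionParams, simulate_culture
from .units import DEFAULT_CONSTANTS, MediaColumn, TensionConstants, get_vessel

__all__ = [
    "ANOXIA_THRESHOLD_PERCENT",
    "HYPOXIA_BAND_PERCENT",
    "STANDARD_FILL_ML",
    "SetpointResult",
    "AnoxiaReport",
    "solve_setpoint",
    "prediction_grid",
    "anoxia_check",
]

#: Pericellular anoxia threshold (% O2).
ANOXIA_THRESHOLD_PERCENT = 0.5
#: Pericellular hypoxia band (% O2), used for labelling only.
HYPOXIA_BAND_PERCENT = (1.0, 2.0)

#: Typical working volumes (mL) used when a grid is asked for "standard
#: fill"; all overridable per call.
STANDARD_FILL_ML = {
    "96-well": 0.2,
    "24-well": 1.0,
    "12-well": 2.0,
    "6-well": 2.0,
    "60mm-dish": 5.0,
    "T25": 5.0,
    "T75": 15.0,
}


def _pericellular_at_horizon(
    column: MediaColumn,
    transport: TransportParams,
    consumption: ConsumptionParams,
    cgas: float,
    horizon_h: float,
    constants: TensionConstants,
    options: SolverOptions,
    c0: float | None = None,
) -> float:
    """Predicted pericellular O2 after ``horizon_h`` under constant gas."""
    t_grid = np.linspace(0.0, horizon_h, max(int(horizon_h * 4), 16) + 1)
    res = simulate_culture(
        column, transport, consumption, GasSchedule.constant(cgas),
        cgas if c0 is None else c0, t_grid, constants, options,
    )
    return float(res.pericellular_percent[-1])


@dataclass
class SetpointResult:
    """Outcome of an inverse setpoint search."""

    feasible: bool
    setpoint_percent: float | None
    achieved_percent: float
    target_percent: float
    message: str = ""


def solve_setpoint(
    column: MediaColumn,
    transport: TransportParams,
    consumption: ConsumptionParams,
    target_percent: float,
    tolerance_percent: float = 0.01,
    horizon_h: float = 48.0,
    bracket_max_percent: float = 21.0,
    constants: TensionConstants = DEFAULT_CONSTANTS,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> SetpointResult:
    """Find the gas setpoint whose pericellular prediction hits a target.

    Bisection over ``[target, bracket_max]`` — without cells the setpoint
    equals the target, and consumption only pushes the required setpoint
    up.  Pericellular O2 must be monotone increasing in the setpoint over
    the bracket (asserted on a coarse scan); an unattainable target returns
    an infeasible result carrying the achievable bound instead of raising.
    """
    if target_percent < 0:
        raise ValueError("target must be >= 0")

    def peri(gas: float) -> float:
        return _pericellular_at_horizon(
            column, transport, consumption, gas, horizon_h, constants, options
        )

    lo, hi = target_percent, bracket_max_percent
    p_lo, p_hi = peri(lo), peri(hi)
    # monotonicity guard on a coarse interior scan
    scan = [p_lo, peri(0.5 * (lo + hi)), p_hi]
    if not all(b >= a - 1e-6 for a, b in zip(scan, scan[1:])):
        raise RuntimeError(
            "pericellular O2 is not monotone in the gas setpoint over the "
            f"bracket [{lo}, {hi}] %O2; cannot invert"
        )
    if p_hi < target_percent - tolerance_percent:
        return SetpointResult(
            feasible=False,
            setpoint_percent=None,
            achieved_percent=p_hi,
            target_percent=target_percent,
            message=(
                f"target {target_percent}% unreachable: even at "
                f"{hi}% gas the prediction is {p_hi:.2f}%"
            ),
        )
    if p_lo >= target_percent:  # no consumption effect at the bottom bracket
        return SetpointResult(True, lo, p_lo, target_percent)

    while hi - lo > tolerance_percent:
        mid = 0.5 * (lo + hi)
        if peri(mid) < target_percent:
            lo = mid
        else:
            hi = mid
    setpoint = 0.5 * (lo + hi)
    return SetpointResult(True, setpoint, peri(setpoint), target_percent)


def prediction_grid(
    vessels: list[str],
    densities: list[float],
    cgas_percent: float,
    transport: TransportParams,
    vmax_amol_cell_s: float = 450.0,
    km_um: float = 1.0,
    mode: str = "monolayer",
    volumes_ml: dict[str, float] | None = None,
    horizon_h: float = 48.0,
    constants: TensionConstants = DEFAULT_CONSTANTS,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> pd.DataFrame:
    """Pericellular O2 (% O2) for every (density, vessel) combination.

    Rows are densities, columns vessels, both in the order given.  Volumes
    default to the standard fill for each vessel.
    """
    volumes = dict(STANDARD_FILL_ML)
    if volumes_ml:
        volumes.update(volumes_ml)
    table = np.empty((len(densities), len(vessels)))
    for j, vessel in enumerate(vessels):
        if vessel not in volumes:
            raise KeyError(
                f"no volume given for {vessel!r}; pass volumes_ml for it"
            )
        column = MediaColumn(get_vessel(vessel), volumes[vessel])
        for i, density in enumerate(densities):
            consumption = ConsumptionParams(
                density=density, vmax_amol_cell_s=vmax_amol_cell_s,
                km_um=km_um, mode=mode,
            )
            table[i, j] = _pericellular_at_horizon(
                column, transport, consumption, cgas_percent, horizon_h,
                constants, options,
            )
    return pd.DataFrame(table, index=pd.Index(densities, name="density"),
                        columns=pd.Index(vessels, name="vessel"))


@dataclass
class AnoxiaReport:
    """Screening verdict for a planned culture."""

    anoxic: bool
    time_to_anoxia_h: float | None
    min_pericellular_percent: float
    final_pericellular_percent: float
    threshold_percent: float = ANOXIA_THRESHOLD_PERCENT

    def label(self) -> str:
        """Coarse label of the final pericellular state."""
        c = self.final_pericellular_percent
        if c < ANOXIA_THRESHOLD_PERCENT:
            return "anoxic"
        if HYPOXIA_BAND_PERCENT[0] <= c <= HYPOXIA_BAND_PERCENT[1]:
            return "hypoxic"
        return "normoxic-to-physioxic"


def anoxia_check(
    column: MediaColumn,
    transport: TransportParams,
    consumption: ConsumptionParams,
    schedule: GasSchedule,
    c0_percent: float = 18.6,
    t_end_h: float = 72.0,
    threshold_percent: float = ANOXIA_THRESHOLD_PERCENT,
    constants: TensionConstants = DEFAULT_CONSTANTS,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> AnoxiaReport:
    """Flag a culture whose pericellular O2 ever drops below the threshold."""
    t_grid = np.linspace(0.0, t_end_h, max(int(t_end_h * 10), 32) + 1)
    res = simulate_culture(
        column, transport, consumption, schedule, c0_percent, t_grid,
        constants, options,
    )
    peri = res.pericellular_percent
    below = peri < threshold_percent
    anoxic = bool(below.any())
    t_cross = None
    if anoxic:
        i = int(np.argmax(below))
        if i == 0:
            t_cross = float(res.t_h[0])
        else:  # linear interpolation of the downward crossing
            c0_, c1_ = peri[i - 1], peri[i]
            frac = (c0_ - threshold_percent) / (c0_ - c1_)
            t_cross = float(res.t_h[i - 1] + frac * (res.t_h[i] - res.t_h[i - 1]))
    return AnoxiaReport(
        anoxic=anoxic,
        time_to_anoxia_h=t_cross,
        min_pericellular_percent=float(peri.min()),
        final_pericellular_percent=float(peri[-1]),
        threshold_percent=threshold_percent,
    )
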
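"""Reaction–diffusion model: O2 diffusion plus cellular consumption.

The central model couples the diffusion problem with Michaelis–Menten
cellular O2 consumption::

    ∂C/∂t = D ∂²C/∂x² - R(C),     R(C) = Vmax · C / (Km + C)

Two consumption localisations are supported:

``monolayer``
    Adherent cells sit on the vessel bottom (x = 0); consumption acts as an
    areal sink ``density · vmax_per_cell · C_b/(Km + C_b)`` applied in the
    bottom finite-volume cell, with ``C_b`` the concentration extrapolated
    to the vessel floor.  As the grid is refined this converges to a flux
    boundary condition at x = 0.
``suspension``
    Cells are distributed through the column (e.g. dendritic cells);
    consumption is a uniform volumetric sink.

Unit chain: per-cell Vmax in amol·cell⁻¹·s⁻¹ times density gives a molar
areal (mol·cm⁻²·s⁻¹) or volumetric (mol·cm⁻³·s⁻¹) rate, converted once to
the solver's % O2 units through the tension constants; Km (µM) is likewise
converted to % O2 once per run.

Gas-phase schedules are piecewise constant and mid-run events rescale the
consumption term (scale 0 = complete inhibition, the in-silico sodium-azide
experiment); the integrator restarts at every discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_bvp

from .diffusion import (
    DEFAULT_OPTIONS,
    GasSchedule,
    OxygenField,
    SolverOptions,
    TransportParams,
    _integrate_column,
)
from .units import DEFAULT_CONSTANTS, MediaColumn, TensionConstants

__all__ = [
    "ConsumptionParams",
    "CultureSimResult",
    "consumption_term",
    "simulate_culture",
    "steady_state_profile",
    "axial_gradient",
]

_AMOL = 1e-18  # mol per amol
_S_PER_H = 3600.0


@dataclass(frozen=True)
class ConsumptionParams:
    """Michaelis–Menten O2 consumption of the cultured cells.

    vmax_amol_cell_s
        Maximum per-cell consumption rate, amol·cell⁻¹·s⁻¹ (default 450,
        a breast-cancer epithelial value).
    km_um
        Half-saturation O2 concentration, µM (default 1).
    density
        cells·cm⁻² in ``monolayer`` mode, cells·mL⁻¹ in ``suspension`` mode.
    """

    density: float
    vmax_amol_cell_s: float = 450.0
    km_um: float = 1.0
    mode: str = "monolayer"

    def __post_init__(self) -> None:
        if self.vmax_amol_cell_s < 0:
            raise ValueError("vmax must be >= 0")
        if not self.km_um > 0:
            raise ValueError("Km must be positive")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.mode not in ("monolayer", "suspension"):
            raise ValueError(
                f"unknown consumption mode {self.mode!r}; "
                "use 'monolayer' or 'suspension'"
            )

    def km_percent(self, constants: TensionConstants = DEFAULT_CONSTANTS) -> float:
        return constants.percent_from_micromolar(self.km_um)

    def saturation_rate(
        self, constants: TensionConstants = DEFAULT_CONSTANTS
    ) -> float:
        """Saturated consumption in solver units.

        Monolayer: areal rate, %O2·cm·h⁻¹.  Suspension: volumetric rate,
        %O2·h⁻¹ (density interpreted per mL = per cm³).
        """
        mol_rate = self.density * self.vmax_amol_cell_s * _AMOL * _S_PER_H
        return mol_rate / constants.mol_per_cm3_per_percent()


def _michaelis_menten(c: np.ndarray | float, km_pct: float):
    c = np.maximum(c, 0.0)
    return c / (km_pct + c)


def consumption_term(
    c: np.ndarray,
    params: ConsumptionParams,
    column: MediaColumn,
    constants: TensionConstants = DEFAULT_CONSTANTS,
    scale: float = 1.0,
) -> np.ndarray:
    """Volumetric sink profile (%O2/h, ≤ 0) on the cell-centered grid.

    ``c`` is the current concentration profile; the grid spacing is implied
    by ``len(c)`` and the column height.  The term clamps to zero wherever
    C = 0 (no substrate, no consumption).
    """
    c = np.asarray(c, dtype=float)
    n = c.size
    dx = column.height_cm / n
    km = params.km_percent(constants)
    vsat = params.saturation_rate(constants) * scale
    sink = np.zeros(n)
    if params.mode == "monolayer":
        c_b = max(1.5 * c[0] - 0.5 * c[1], 0.0)
        sink[0] = -vsat * _michaelis_menten(c_b, km) / dx
    else:
        sink = -vsat * _michaelis_menten(c, km)
    return sink


@dataclass
class CultureSimResult:
    """Output of a culture simulation.

    ``consumed_per_area`` is the cumulative O2 removed by the cells per
    unit growth area (%O2·cm), obtained by trapezoidal integration of the
    instantaneous consumption rate at the saved times.
    """

    field: OxygenField
    pericellular_percent: np.ndarray
    surface_percent: np.ndarray
    gas_percent: np.ndarray
    consumed_per_area: np.ndarray

    @property
    def t_h(self) -> np.ndarray:
        return self.field.t_h


def simulate_culture(
    column: MediaColumn,
    transport: TransportParams,
    consumption: ConsumptionParams,
    schedule: GasSchedule,
    c0_percent: float,
    t_grid: np.ndarray,
    constants: TensionConstants = DEFAULT_CONSTANTS,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> CultureSimResult:
    """Simulate a consuming culture under a gas schedule with events.

    With ``vmax = 0`` (or a scale-0 event from t = 0) the result reduces
    exactly to the cell-free diffusion solution on the same grid.
    """
    if np.isscalar(c0_percent) and c0_percent < 0:
        raise ValueError("initial O2 must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)
    for t_ev, _ in schedule.events:
        if not (t_grid[0] <= t_ev <= t_grid[-1]):
            raise ValueError(
                f"event at {t_ev} h lies outside the simulated span "
                f"[{t_grid[0]}, {t_grid[-1]}] h"
            )

    def sink(c, scale):
        return consumption_term(c, consumption, column, constants, scale)

    field = _integrate_column(
        column, transport, c0_percent, schedule, t_grid, sink=sink,
        options=options,
    )

    # instantaneous areal consumption rate at saved times -> cumulative
    dx = field.dx_cm
    rates = np.array(
        [
            -consumption_term(ci, consumption, column, constants,
                              schedule.scale_at(ti)).sum() * dx
            for ti, ci in zip(field.t_h, field.c)
        ]
    )
    consumed = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rates[1:] + rates[:-1]) * np.diff(field.t_h))]
    )

    return CultureSimResult(
        field=field,
        pericellular_percent=field.pericellular_trace(),
        surface_percent=field.surface_trace(),
        gas_percent=field.gas.copy(),
        consumed_per_area=consumed,
    )


def _steady_monolayer(
    column: MediaColumn,
    transport: TransportParams,
    consumption: ConsumptionParams,
    cgas: float,
    constants: TensionConstants,
    n_x: int,
) -> np.ndarray:
    """Closed-form steady state for a bottom-localised sink.

    At steady state the flux through every level equals the areal
    consumption F, so the profile is linear, C(x) = C_b + F x / D, and the
    bottom concentration solves the two-resistance balance
    ``kL (Cgas - C_b - F(C_b) L / D) = F(C_b)``.
    """
    from scipy.optimize import brentq

    L = column.height_cm
    d, kl = transport.d_cm2_h, transport.kl_cm_h
    km = consumption.km_percent(constants)
    a_sat = consumption.saturation_rate(constants)

    if a_sat == 0 or kl == 0:
        # no consumption -> uniform setpoint; sealed surface -> fully drained
        val = cgas if a_sat == 0 else 0.0
        return np.full(n_x, val)

    def imbalance(cb: float) -> float:
        f = a_sat * _michaelis_menten(cb, km)
        return kl * (cgas - cb - f * L / d) - f

    # supply at cb=0 is kl*cgas > 0; imbalance is strictly decreasing
    if imbalance(cgas) >= 0:
        cb = cgas
    else:
        cb = brentq(imbalance, 0.0, cgas, xtol=1e-12)
    f = a_sat * _michaelis_menten(cb, km)
    x = (np.arange(n_x) + 0.5) * (L / n_x)
    return cb + f * x / d


def _steady_suspension(
    column: MediaColumn,
    transport: TransportParams,
    consumption: ConsumptionParams,
    cgas: float,
    constants: TensionConstants,
    n_x: int,
) -> np.ndarray:
    """Steady state for a uniform volumetric sink, via a BVP solve."""
    L = column.height_cm
    d, kl = transport.d_cm2_h, transport.kl_cm_h
    km = consumption.km_percent(constants)
    vsat = consumption.saturation_rate(constants)

    if vsat == 0 or kl == 0:
        val = cgas if vsat == 0 else 0.0
        return np.full(n_x, val)

    def odes(x, y):
        return np.vstack([y[1], vsat * _michaelis_menten(y[0], km) / d])

    def bc(ya, yb):
        return np.array([ya[1], d * yb[1] - kl * (cgas - yb[0])])

    x0 = np.linspace(0.0, L, 101)
    y0 = np.vstack([np.full_like(x0, min(cgas, km)), np.zeros_like(x0)])
    sol = solve_bvp(odes, bc, x0, y0, tol=1e-8, max_nodes=20000)
    if sol.status != 0:
        raise RuntimeError(f"steady-state BVP did not converge: {sol.message}")
    x = (np.arange(n_x) + 0.5) * (L / n_x)
    return np.maximum(sol.sol(x)[0], 0.0)


def steady_state_profile(
    column: MediaColumn,
    transport: TransportParams,
    consumption: ConsumptionParams,
    cgas: float,
    constants: TensionConstants = DEFAULT_CONSTANTS,
    method: str = "bvp",
    options: SolverOptions = DEFAULT_OPTIONS,
    max_hours: float = 2000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady axial O2 profile ``(x_cm, C_percent)`` under constant gas.

    ``method="bvp"`` solves the time-independent boundary-value problem
    (closed-form two-resistance balance for a monolayer, collocation for a
    suspension).  ``method="integrate"`` marches the transient solver until
    ``max |dC/dt| < 1e-6 %O2/h``.  The two paths agreeing is a standing
    cross-check in the test suite.
    """
    if method == "bvp":
        fn = _steady_monolayer if consumption.mode == "monolayer" else _steady_suspension
        c = fn(column, transport, consumption, cgas, constants, options.n_x)
        x = (np.arange(options.n_x) + 0.5) * (column.height_cm / options.n_x)
        return x, c
    if method != "integrate":
        raise ValueError("method must be 'bvp' or 'integrate'")

    schedule = GasSchedule.constant(cgas)
    chunk = max(10.0 * column.height_cm**2 / transport.d_cm2_h, 5.0)
    state: float | np.ndarray = cgas
    elapsed = 0.0
    while elapsed < max_hours:
        t_grid = np.linspace(0.0, chunk, 25)
        field = _integrate_column(
            column, transport, state, schedule, t_grid,
            sink=lambda c, s: consumption_term(c, consumption, column, constants, s),
            options=options,
        )
        rate = np.max(np.abs(field.c[-1] - field.c[-2])) / (t_grid[-1] - t_grid[-2])
        state = field.c[-1]
        elapsed += chunk
        if rate < 1e-6:
            return field.x_cm, state
    raise RuntimeError(
        f"no steady state within {max_hours} h (last max|dC/dt| = {rate:.2e} %O2/h)"
    )


def axial_gradient(result: CultureSimResult, at_time: float) -> tuple[float, float]:
    """(bottom, top) % O2 at a given time, linearly interpolated."""
    t = result.t_h
    if not (t[0] <= at_time <= t[-1]):
        raise ValueError(f"time {at_time} h outside simulated range [{t[0]}, {t[-1]}]")
    bottom = float(np.interp(at_time, t, result.pericellular_percent))
    top = float(np.interp(at_time, t, result.surface_percent))
    return bottom, top
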
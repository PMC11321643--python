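"""Sensor-trace CSV dialect, run configuration and run manifests.

The trace dialect emulates the export of an optical dissolved-O2 sensor:
comma-separated UTF-8 with header ``time_s,o2_percent[,temperature_c]``,
times strictly increasing.  Temperature is carried through but ignored by
the model.

Run configuration is a sectioned TOML file validated with pydantic; unknown
keys are rejected (typo protection) and every applied default is recorded.
Each CLI run writes a JSON manifest with the fully resolved configuration,
package version, input checksums and any warnings, so a run can be
reproduced bit-for-bit from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .diffusion import GasSchedule, SolverOptions, TransportParams
from .reaction import ConsumptionParams
from .units import MediaColumn, TensionConstants, VesselGeometry, get_vessel

__all__ = [
    "SensorTrace",
    "read_sensor_csv",
    "write_sensor_csv",
    "RunConfig",
    "RunManifest",
]


@dataclass(frozen=True)
class SensorTrace:
    """A dissolved-O2 time series at a stated sensor depth."""

    time_s: np.ndarray
    o2_percent: np.ndarray
    temperature_c: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        o = np.asarray(self.o2_percent, dtype=float)
        if t.ndim != 1 or t.shape != o.shape:
            raise ValueError("time and O2 arrays must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("trace times must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "o2_percent", o)

    @property
    def time_h(self) -> np.ndarray:
        return self.time_s / 3600.0

    def __len__(self) -> int:
        return self.time_s.size


def read_sensor_csv(path: str | Path) -> SensorTrace:
    """Read a sensor trace, reporting parse problems with line numbers."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    if header[:2] != ["time_s", "o2_percent"]:
        raise ValueError(
            f"{path}:1: expected header 'time_s,o2_percent[,temperature_c]', "
            f"got {lines[0]!r}"
        )
    has_temp = len(header) >= 3 and header[2] == "temperature_c"
    times, o2s, temps = [], [], []
    prev_t = None
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split(",")]
        if len(cells) < 2:
            raise ValueError(f"{path}:{ln}: expected at least 2 columns")
        try:
            t = float(cells[0])
            o = float(cells[1])
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-numeric cell in {line!r}") from None
        if prev_t is not None and t <= prev_t:
            raise ValueError(
                f"{path}:{ln}: time {t} s is not strictly increasing "
                f"(previous {prev_t} s)"
            )
        prev_t = t
        times.append(t)
        o2s.append(o)
        if has_temp and len(cells) >= 3 and cells[2]:
            try:
                temps.append(float(cells[2]))
            except ValueError:
                raise ValueError(
                    f"{path}:{ln}: non-numeric temperature in {line!r}"
                ) from None
    temp_arr = np.array(temps) if has_temp and len(temps) == len(times) else None
    return SensorTrace(np.array(times), np.array(o2s), temp_arr)


def write_sensor_csv(trace: SensorTrace, path: str | Path) -> None:
    """Write a trace in the documented dialect (6 significant digits)."""
    path = Path(path)
    has_temp = trace.temperature_c is not None
    with path.open("w", encoding="utf-8") as fh:
        fh.write("time_s,o2_percent" + (",temperature_c" if has_temp else "") + "\n")
        for i in range(len(trace)):
            row = f"{trace.time_s[i]:.6g},{trace.o2_percent[i]:.6g}"
            if has_temp:
                row += f",{trace.temperature_c[i]:.6g}"
            fh.write(row + "\n")


# --------------------------------------------------------------------------
# run configuration


def _parse_timed_pairs(items: list[str], what: str) -> tuple[tuple[float, float], ...]:
    out = []
    for item in items:
        try:
            t_str, v_str = item.split(":")
            out.append((float(t_str), float(v_str)))
        except ValueError:
            raise ValueError(
                f"bad {what} entry {item!r}; expected 't_h:value'"
            ) from None
    return tuple(out)


class VesselSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str | None = None
    growth_area_cm2: float | None = None
    volume_ml: float

    @field_validator("volume_ml")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("volume_ml must be positive")
        return v


class ConstantsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mmhg_per_percent: float = 7.7
    solubility_um_per_mmhg: float = 1.27


class TransportSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    d_cm2_h: float = 0.09684
    kl_cm_h: float = 0.1


class ConsumptionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vmax_amol_s: float = 450.0
    km_um: float = 1.0
    density: float = 0.0
    mode: str = "monolayer"


class SolverSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_x: int = 64
    rtol: float = 1e-6
    atol: float = 1e-9


class RunSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    c0_percent: float = 18.6
    t_end_h: float = 72.0
    dt_out_h: float = 0.1
    seed: int = 0
    schedule: list[str] = Field(default_factory=lambda: ["0:18.6"])
    events: list[str] = Field(default_factory=list)


class RunConfig(BaseModel):
    """Validated, fully defaulted description of one simulation run."""

    model_config = ConfigDict(extra="forbid")
    vessel: VesselSection
    constants: ConstantsSection = Field(default_factory=ConstantsSection)
    transport: TransportSection = Field(default_factory=TransportSection)
    consumption: ConsumptionSection = Field(default_factory=ConsumptionSection)
    solver: SolverSection = Field(default_factory=SolverSection)
    run: RunSection = Field(default_factory=RunSection)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.model_validate(data)

    # ---- materialised model objects -------------------------------------

    def column(self) -> MediaColumn:
        v = self.vessel
        if v.name is not None:
            geom = get_vessel(v.name)
            if v.growth_area_cm2 is not None:
                geom = VesselGeometry(v.name, v.growth_area_cm2)
        elif v.growth_area_cm2 is not None:
            geom = VesselGeometry("custom", v.growth_area_cm2)
        else:
            raise ValueError("vessel section needs 'name' or 'growth_area_cm2'")
        return MediaColumn(geom, v.volume_ml)

    def tension_constants(self) -> TensionConstants:
        c = self.constants
        return TensionConstants(c.mmhg_per_percent, c.solubility_um_per_mmhg)

    def transport_params(self) -> TransportParams:
        return TransportParams(self.transport.d_cm2_h, self.transport.kl_cm_h)

    def consumption_params(self) -> ConsumptionParams:
        c = self.consumption
        return ConsumptionParams(
            density=c.density, vmax_amol_cell_s=c.vmax_amol_s,
            km_um=c.km_um, mode=c.mode,
        )

    def gas_schedule(self) -> GasSchedule:
        return GasSchedule(
            segments=_parse_timed_pairs(self.run.schedule, "schedule"),
            events=_parse_timed_pairs(self.run.events, "event"),
        )

    def solver_options(self) -> SolverOptions:
        s = self.solver
        return SolverOptions(n_x=s.n_x, rtol=s.rtol, atol=s.atol)

    def t_grid(self) -> np.ndarray:
        r = self.run
        n = int(round(r.t_end_h / r.dt_out_h)) + 1
        return np.linspace(0.0, r.t_end_h, n)


@dataclass
class RunManifest:
    """Reproducibility record written alongside every CLI output."""

    command: str
    resolved_config: dict
    seed: int | None = None
    input_checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def add_input(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_checksums[str(path)] = digest

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "version": self.version,
            "timestamp": self.timestamp,
            "seed": self.seed,
            "resolved_config": self.resolved_config,
            "input_checksums": self.input_checksums,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
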
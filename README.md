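# pericell

Predict and control **pericellular oxygen tension** in cell culture.

In O2-controlled cell culture it is usually assumed that the incubator
setpoint is the oxygen tension the cells experience.  It often is not:
cells consume O2 faster than it can diffuse down through the stagnant media
column, so a "1 % O2 hypoxia" experiment is frequently an *anoxia*
experiment at the cell layer, and a "5 % physioxia" culture can sit
anywhere between 0 and 4 % depending on vessel, fill volume and density.
`pericell` is a forward model, calibration toolkit and experiment planner
for that gap, aimed at anyone running hypoxia/physioxia cultures or
interpreting them.

## The model

Dissolved O2 `C(x, t)` (in % O2) in a 1-D media column of height
`L = volume / growth area`, with `x = 0` the vessel bottom (the cells) and
`x = L` the gas–media interface:

```
∂C/∂t = D ∂²C/∂x² − R(C)
C(x, 0) = C0
∂C/∂x = 0                      at x = 0
−D ∂C/∂x = kL (C − Cgas(t))    at x = L
```

* `D` — O2 diffusivity of medium, default 0.09684 cm²/h at 37 °C.
* `kL` — surface mass-transfer coefficient (cm/h), fitted from cell-free
  equilibration traces or defaulted to 0.1 cm/h for stagnant media.
* `Cgas(t)` — piecewise-constant incubator setpoint; mid-run events can
  rescale consumption (e.g. to 0, modelling respiration inhibition).
* `R(C) = Vmax·C/(Km + C)` — Michaelis–Menten cellular consumption, from
  per-cell `Vmax` (default 450 amol·cell⁻¹·s⁻¹), `Km` (default 1 µM) and
  cell density; localised at the vessel bottom for adherent monolayers or
  distributed uniformly for suspension cultures.

For the cell-free problem the package also carries the classical
eigenfunction series in `Θ = (C − Cgas)/(C0 − Cgas)`, `ζ = x/L`,
`τ = Dt/L²` with eigencondition `λ tan λ = Bi`, `Bi = kL·L/D`, which
cross-validates the finite-volume solver.  Unit conversions use
1 % O2 = 7.7 mmHg and a Henry-law solubility of 1.27 µM/mmHg (both
configurable).

## Worked example

A sub-confluent monolayer (21 000 cells/cm², the densities used for breast
epithelial lines) in a 24-well with 1 mL of normoxic medium, moved into a
1 % O2 incubator:

```python
import numpy as np
from pericell import (MediaColumn, TransportParams, ConsumptionParams,
                      GasSchedule, simulate_culture, anoxia_check)

column = MediaColumn.from_vessel("24-well", 1.0)   # L = 0.526 cm
transport = TransportParams()                      # D = 0.09684, kL = 0.1
cells = ConsumptionParams(density=21000.0)         # Vmax 450 amol/cell/s

report = anoxia_check(column, transport, cells, GasSchedule.constant(1.0),
                      c0_percent=18.6, t_end_h=24.0)
print(report.anoxic, round(report.time_to_anoxia_h, 2),
      round(report.final_pericellular_percent, 3))
```

prints

```
True 1.55 0.002
```

i.e. the culture is predicted to cross the 0.5 % anoxia threshold after
1.55 h and to sit at ~0 % O2 thereafter, even though the incubator reads
1 %.  The `examples/` directory walks through the other capabilities:
unit/geometry plumbing, media conditioning times, gas schedules and
consumption-off events, fitting `kL` and `Vmax` from (synthetic) sensor
traces, and inverse design (setpoint search, vessel×density grids, anoxia
screening).  A thin CLI mirrors the library:

```sh
pericell convert --value 1 --from percent --to mmHg     # -> 7.7
pericell conditioning-time --vessel 6-well --volume-ml 2 --gas 1
pericell simulate-culture --config run.toml --out trace.csv
```

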
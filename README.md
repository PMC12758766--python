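# sagitta

Quantitative tools for the trophic interaction between planktonic ambush
predators (chaetognaths, "arrow worms") and their copepod prey: analytical
predator–prey encounter-rate kernels under calm and wind-turbulent
conditions, gut-content-based feeding-rate estimation with
temperature-dependent digestion, odds-ratio diet electivity with Monte-Carlo
confidence intervals, and the permutation statistics (two-factor PERMANOVA,
BIOENV) used to relate feeding rates to environmental drivers. A
seed-deterministic synthetic survey generator makes the whole pipeline
runnable and testable without any field data.

Intended users: plankton ecologists and biological oceanographers analysing
station-grid zooplankton surveys (densities, CTD profiles, gut contents,
diet compositions).

## The models

**Encounters.** For two planktonic populations swimming at constant speeds
with isotropic headings, the expected number of prey entering a predator's
perception sphere per unit time is

```
C_GS = (π R² N / 6) · [(x + y)³ − |x − y|³] / (x y)
```

with perception radius `R` (m), prey density `N` (ind/m³), prey speed `x`
and predator speed `y` (m/s). For an ambush predator (`y = 0`) the bracket
has the algebraic limit `C = π R² N x`. Wind-induced small-scale turbulence
adds a root-mean-square velocity `w` to both swimmers
(`v → √(v² + w²)`), giving the turbulent kernel `C_RO ≥ C_GS`; for `y = 0`,

```
C_RO = π R² N · (3x² + 4w²) / (3 √(x² + w²)).
```

`w` at the surface is a first-class parameter with a closed-form calibration
from an observed enhancement ratio `C_RO/C_GS`, and decays with depth via a
configurable profile. Rates are reported per day.

**Feeding.** Counts of prey per dissected gut give the mean prey per
predator `NPC`; digestion time follows `DT(T) = 10.48 · e^(−0.086 T)` hours
at the 0–50 m integrated temperature `T`; the daily feeding rate is
`FR = (NPC / DT) · 24`.

**Electivity.** For each prey taxon, the gut proportion `g` and habitat
proportion `a` combine through the odds ratio
`O = [g/(1−g)] / [a/(1−a)]` into an index `X = O/(1+O) ∈ [0, 1]`, with
`X = 0.5` meaning prey are eaten in proportion to availability. A Beta
Monte-Carlo resample of both proportions (uniform-prior posteriors, 10 000
draws) yields a 95% interval; selection is called only when the interval
excludes 0.5.

## Worked example

```python
import sagitta as sg

params = sg.EncounterParams()          # R=3 mm, x=150 mm/s, y=0 (ambush)
c_gs = sg.gs_rate(params, 205.2)       # neritic summer copepod density
w0 = sg.calibrate_surface_w(115.1 / 75.4, params.prey_speed)
c_ro = sg.ro_rate(params, 205.2, w0)

model = sg.ThermalDigestionModel()     # DT = 10.48 exp(-0.086 T)
dt = sg.digestion_time(model, 26.36)   # summer mean 0-50 m temperature
fr = sg.feeding_rate(0.04, dt)         # summer mean prey per gut

x = sg.electivity_index(3 / 9, 4 / 40)   # Temora: 3 of 9 gut prey, 4 of 40 ambient
lo, hi = sg.beta_mc_ci(3, 9, 4, 40, seed=42)
```

prints, when the quantities are formatted:

```
calm surface encounters : 75.2 copepods/chaetognath/day
calibrated w0           : 0.132 m/s
turbulent encounters    : 114.8 copepods/chaetognath/day
digestion time at 26.36 degC : 1.09 h
feeding rate                 : 0.88 copepods/chaetognath/day
electivity index             : 0.818  (95% CI 0.456-0.957) -> none
```

Read: at a summer shelf density of 205 copepods/m³ a motionless chaetognath
encounters ~75 copepods per day in calm water; the turbulence level implied
by a 1.53× surface enhancement (`w0 ≈ 0.13` m/s) raises that to ~115. At
26.4 °C a prey item is digested in ~1.1 h, so an average gut content of 0.04
copepods corresponds to ~0.9 copepods eaten per day. *Temora* is over-
represented in guts (index 0.82), but with 9 identified gut prey the 95%
interval still includes 0.5 — no significant selection.

The same pipeline is available from the shell (`sagitta simulate`,
`encounters`, `feeding`, `electivity`, `permanova`, `bioenv`, `report`); run
`sagitta --help`.

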
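"""Seed-deterministic synthetic station surveys for exercising the pipeline.

The generator emulates the statistical structure of a seasonal shelf/open-sea
zooplankton survey: per-stratum (season x zone) temperature, salinity and
chlorophyll levels; right-skewed (log-normal) copepod and chaetognath
densities; CTD profiles whose 0-50 m trapezoidal mean hits the drawn station
value exactly; sparse gut contents (most arrow-worm guts hold zero or one
copepod, so counts are Bernoulli by default, with a Poisson mode for fuller
guts); and paired gut/habitat prey compositions with a known selection
ground truth.  Default stratum parameters follow observed Gulf-of-Mexico
seasonal means (e.g. neritic summer copepods ~205 ind/m^3, winter neritic
temperatures 18.7-22 degC, seasonal winds 2.64/2.81/3.87 m/s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .electivity import CompositionTable
from .feeding import GutSurvey, Season, StationRecord, Zone

__all__ = [
    "ScenarioConfig",
    "DEFAULT_SCENARIOS",
    "default_scenario",
    "generate_station_grid",
    "generate_gut_survey",
    "generate_diet_pair",
    "generate_full_survey",
    "DEFAULT_TAXA",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """True parameters of one season x zone stratum.

    Temperatures are drawn from a normal truncated to [t_min, t_max];
    densities are log-normal with the given arithmetic mean and coefficient
    of variation.  ``npc_true`` is the per-predator probability of holding
    one prey (Bernoulli gut model).  ``seed`` is mandatory: every generator
    is a pure function of its config.
    """

    season: Season
    zone: Zone
    n_stations: int
    seed: int
    t_mean: float
    t_sd: float
    t_min: float
    t_max: float
    s_mean: float = 36.0
    s_sd: float = 0.2
    chl_mean: float = 0.4
    chl_sd: float = 0.15
    cop_density_mean: float = 100.0
    cop_density_cv: float = 0.6
    chaet_density_mean: float = 3.0
    chaet_density_cv: float = 0.6
    npc_true: float = 0.04
    wind_speed: float = 3.0

    def __post_init__(self) -> None:
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        for name in ("t_sd", "s_sd", "chl_sd", "cop_density_mean", "cop_density_cv",
                     "chaet_density_mean", "chaet_density_cv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be < t_max")
        if not 0 <= self.npc_true:
            raise ValueError("npc_true must be >= 0")
        if self.wind_speed < 0:
            raise ValueError("wind_speed must be >= 0")
        object.__setattr__(self, "season", Season(self.season))
        object.__setattr__(self, "zone", Zone(self.zone))


def _base(season, zone, **kw) -> ScenarioConfig:
    return ScenarioConfig(season=season, zone=zone, n_stations=11, seed=0, **kw)


#: Stratum defaults: seasonal/zonal means of temperature (degC), salinity
#: (psu), chlorophyll (mg/m3), copepod density (ind/m3) and wind (m/s).
DEFAULT_SCENARIOS: dict = {
    (Season.SUMMER, Zone.NERITIC): _base(
        Season.SUMMER, Zone.NERITIC, t_mean=26.6, t_sd=0.98, t_min=24.38, t_max=29.12,
        s_mean=36.1, chl_mean=0.5, cop_density_mean=205.2, chaet_density_mean=5.0,
        npc_true=0.04, wind_speed=2.64,
    ),
    (Season.SUMMER, Zone.OCEANIC): _base(
        Season.SUMMER, Zone.OCEANIC, t_mean=26.4, t_sd=0.98, t_min=24.38, t_max=29.12,
        s_mean=36.3, chl_mean=0.3, cop_density_mean=45.3, chaet_density_mean=2.0,
        npc_true=0.04, wind_speed=2.64,
    ),
    (Season.FALL, Zone.NERITIC): _base(
        Season.FALL, Zone.NERITIC, t_mean=27.3, t_sd=0.46, t_min=26.27, t_max=28.20,
        s_mean=36.4, chl_mean=0.4, cop_density_mean=68.6, chaet_density_mean=3.0,
        npc_true=0.04, wind_speed=2.81,
    ),
    (Season.FALL, Zone.OCEANIC): _base(
        Season.FALL, Zone.OCEANIC, t_mean=27.9, t_sd=0.46, t_min=26.27, t_max=28.60,
        s_mean=36.5, chl_mean=0.3, cop_density_mean=30.6, chaet_density_mean=1.5,
        npc_true=0.04, wind_speed=2.81,
    ),
    (Season.WINTER, Zone.NERITIC): _base(
        Season.WINTER, Zone.NERITIC, t_mean=20.5, t_sd=1.10, t_min=18.7, t_max=22.0,
        s_mean=35.5, s_sd=0.5, chl_mean=0.9, cop_density_mean=151.6, chaet_density_mean=3.0,
        npc_true=0.03, wind_speed=3.87,
    ),
    (Season.WINTER, Zone.OCEANIC): _base(
        Season.WINTER, Zone.OCEANIC, t_mean=22.2, t_sd=1.10, t_min=21.7, t_max=23.1,
        s_mean=36.2, chl_mean=0.4, cop_density_mean=51.6, chaet_density_mean=2.0,
        npc_true=0.03, wind_speed=3.87,
    ),
}

#: Copepod genera used for synthetic diet/habitat compositions (habitat
#: proportions right-skewed like field aliquots).
DEFAULT_TAXA = (
    "Temora", "Calanus", "Centropages", "Acartia", "Euaugaptilus",
    "Oithona", "Candacia", "Corycaeus", "Oncaea", "Farranula",
)
_DEFAULT_HABITAT_PROBS = np.array(
    [0.20, 0.18, 0.14, 0.12, 0.10, 0.08, 0.06, 0.05, 0.04, 0.03]
)


def default_scenario(season, zone, n_stations: int = 11, seed: int = 0, **overrides) -> ScenarioConfig:
    """A stratum config from the built-in defaults, with optional overrides."""
    cfg = DEFAULT_SCENARIOS[(Season(season), Zone(zone))]
    return replace(cfg, n_stations=n_stations, seed=seed, **overrides)


def _lognormal(rng, mean: float, cv: float, size: int) -> np.ndarray:
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _ctd_profile(rng, depth_max: float, t_target: float, s_target: float, chl_target: float):
    """CTD-like profile whose 0-50 m trapezoidal mean equals each target.

    Linear gradient plus smooth noise, then shifted by the (target - mean)
    offset; the trapezoid is linear in the values, so the shift lands the
    integrated mean on the target up to float rounding.
    """
    from .feeding import integrate_upper_layer

    z = np.arange(0.0, depth_max + 1e-9, 5.0)
    if z[-1] < depth_max:
        z = np.append(z, depth_max)

    def build(target, gradient, noise_sd):
        v = target + gradient * (25.0 - z) + rng.normal(0.0, noise_sd, size=z.size)
        v = v + (target - integrate_upper_layer(z, v, 50.0))
        return v

    temp = build(t_target, gradient=0.03, noise_sd=0.05)
    sal = build(s_target, gradient=-0.002, noise_sd=0.01)
    chl = np.maximum(build(chl_target, gradient=0.004, noise_sd=0.02), 0.0)
    # clamping chl at zero can nudge the integral; re-shift only if it kept positivity
    off = chl_target - integrate_upper_layer(z, chl, 50.0)
    if np.all(chl + off >= 0):
        chl = chl + off
    return z, temp, sal, chl


def generate_station_grid(config: ScenarioConfig):
    """Stations plus matching CTD profiles for one stratum.

    Returns
    -------
    stations : list of StationRecord
        Per-station environment (0-50 m means), densities and wind.
    profiles : dict of station_id -> DataFrame
        Columns depth_m, temp_c, sal_psu, chl_mg_m3; the 0-50 m trapezoidal
        mean of each profile equals the station value.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_stations
    t = _truncated_normal(rng, config.t_mean, config.t_sd, config.t_min, config.t_max, n)
    s = rng.normal(config.s_mean, config.s_sd, size=n)
    chl = np.abs(rng.normal(config.chl_mean, config.chl_sd, size=n))
    cop = _lognormal(rng, config.cop_density_mean, config.cop_density_cv, n)
    chaet = _lognormal(rng, config.chaet_density_mean, config.chaet_density_cv, n)
    if config.zone is Zone.NERITIC:
        bottom = rng.uniform(60.0, 200.0, size=n)
        dist = rng.uniform(5.0, 60.0, size=n)
    else:
        bottom = rng.uniform(1000.0, 3500.0, size=n)
        dist = rng.uniform(60.0, 250.0, size=n)

    stations, profiles = [], {}
    for i in range(n):
        sid = f"{config.season.value[:2]}-{config.zone.value[:3]}-{i + 1:02d}"
        stations.append(
            StationRecord(
                station_id=sid,
                season=config.season,
                zone=config.zone,
                temperature=float(t[i]),
                salinity=float(s[i]),
                chlorophyll=float(chl[i]),
                bottom_depth=float(bottom[i]),
                dist_coast=float(dist[i]),
                copepod_density=float(cop[i]),
                chaetognath_density=float(chaet[i]),
                wind_speed=config.wind_speed,
            )
        )
        z, temp, sal, chlp = _ctd_profile(
            rng, min(float(bottom[i]), 200.0), float(t[i]), float(s[i]), float(chl[i])
        )
        profiles[sid] = pd.DataFrame(
            {"depth_m": z, "temp_c": temp, "sal_psu": sal, "chl_mg_m3": chlp}
        )
    return stations, profiles


def generate_gut_survey(n_predators: int, true_npc: float, seed=None, mode: str = "bernoulli") -> GutSurvey:
    """Simulated per-predator ingested-prey counts with known mean.

    ``mode="bernoulli"`` (default) draws 0/1 guts — arrow worms rarely hold
    more than a single prey — and requires ``true_npc <= 1``;
    ``mode="poisson"`` allows arbitrary positive means.
    """
    if n_predators < 1:
        raise ValueError("n_predators must be >= 1")
    if true_npc < 0:
        raise ValueError("true_npc must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "bernoulli":
        if true_npc > 1:
            raise ValueError("true_npc > 1 needs mode='poisson'")
        counts = rng.binomial(1, true_npc, size=n_predators)
    elif mode == "poisson":
        counts = rng.poisson(true_npc, size=n_predators)
    else:
        raise ValueError(f"unknown gut model {mode!r}; expected 'bernoulli' or 'poisson'")
    return GutSurvey(counts=counts)


def generate_diet_pair(
    taxa,
    habitat_probs,
    selection_odds=None,
    n_gut: int = 25,
    n_habitat: int = 40,
    seed=None,
) -> tuple[CompositionTable, CompositionTable]:
    """Paired gut/habitat compositions with a known selection ground truth.

    Habitat counts are Multinomial(n_habitat, a); gut counts are
    Multinomial(n_gut, q) with the multiplicatively tilted composition
    ``q_i = s_i a_i / sum_j s_j a_j``.  When a single taxon is tilted
    (all other s_j = 1) its realized gut/habitat odds ratio equals ``s_i``
    exactly, so its expected electivity is ``s_i / (1 + s_i)``; with all
    s = 1 the expected index is 0.5 for every taxon.
    """
    a = np.asarray(habitat_probs, dtype=float)
    taxa = tuple(taxa)
    if a.size != len(taxa):
        raise ValueError("taxa and habitat_probs length mismatch")
    if np.any(a < 0) or not np.isclose(a.sum(), 1.0):
        raise ValueError("habitat_probs must be non-negative and sum to 1")
    s = np.ones_like(a) if selection_odds is None else np.asarray(selection_odds, dtype=float)
    if s.size != a.size:
        raise ValueError("selection_odds length mismatch")
    if np.any(s <= 0):
        raise ValueError("selection odds must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = s * a
    q = q / q.sum()
    gut_counts = rng.multinomial(n_gut, q)
    habitat_counts = rng.multinomial(n_habitat, a)
    return CompositionTable(taxa, gut_counts), CompositionTable(taxa, habitat_counts)


def generate_full_survey(seed: int = 0, n_stations: int = 11, n_predators_per_station: int = 16):
    """A complete synthetic survey across all six season x zone strata.

    Returns a dict of tidy DataFrames matching the CSV schemas the analysis
    commands consume: ``stations``, ``ctd`` (long profile table), ``guts``
    (one row per dissected predator) and ``composition`` (per-season paired
    gut/habitat taxon counts, no selection: all odds 1).
    """
    from .io import stations_to_frame

    rng = np.random.default_rng(seed)
    all_stations, ctd_rows, gut_rows, comp_rows = [], [], [], []
    for (season, zone), base_cfg in DEFAULT_SCENARIOS.items():
        cfg = replace(base_cfg, n_stations=n_stations, seed=int(rng.integers(2**31 - 1)))
        stations, profiles = generate_station_grid(cfg)
        all_stations.extend(stations)
        for st in stations:
            prof = profiles[st.station_id].copy()
            prof.insert(0, "station_id", st.station_id)
            ctd_rows.append(prof)
            guts = generate_gut_survey(
                n_predators_per_station, cfg.npc_true, seed=np.random.default_rng(rng.integers(2**31 - 1))
            )
            for j, c in enumerate(guts.counts):
                gut_rows.append(
                    {
                        "predator_id": f"{st.station_id}-p{j + 1:03d}",
                        "station_id": st.station_id,
                        "n_prey_in_gut": int(c),
                        "near_mouth_excluded": 0,
                    }
                )
    for season in Season:
        gut_tab, hab_tab = generate_diet_pair(
            DEFAULT_TAXA,
            _DEFAULT_HABITAT_PROBS,
            n_gut=25,
            n_habitat=40,
            seed=np.random.default_rng(rng.integers(2**31 - 1)),
        )
        for taxon, g, h in zip(DEFAULT_TAXA, gut_tab.counts, hab_tab.counts):
            comp_rows.append(
                {"season": season.value, "taxon": taxon, "gut_count": int(g), "habitat_count": int(h)}
            )
    return {
        "stations": stations_to_frame(all_stations),
        "ctd": pd.concat(ctd_rows, ignore_index=True),
        "guts": pd.DataFrame(gut_rows),
        "composition": pd.DataFrame(comp_rows),
    }
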
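"""Shared fixtures: published reference values and reconstructed count tables."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


# Seasonal/zonal surface means: temperature (degC), salinity (psu), copepod
# density (ind/m3), calm (GS) and turbulent (RO) surface encounter rates
# (prey/predator/day) and feeding rate (prey/predator/day).
STRATUM_MEANS = {
    ("summer", "neritic"): dict(T=26.6, S=36.1, cop=205.2, gs=75.4, ro=115.1, fr=1.16),
    ("summer", "oceanic"): dict(T=26.4, S=36.3, cop=45.3, gs=16.6, ro=25.4, fr=0.57),
    ("fall", "neritic"): dict(T=27.3, S=36.4, cop=68.6, gs=25.2, ro=39.4, fr=0.94),
    ("fall", "oceanic"): dict(T=27.9, S=36.5, cop=30.6, gs=11.2, ro=17.6, fr=0.77),
    ("winter", "neritic"): dict(T=20.5, S=35.5, cop=151.6, gs=55.7, ro=100.3, fr=0.30),
    ("winter", "oceanic"): dict(T=22.2, S=36.2, cop=51.6, gs=19.0, ro=34.1, fr=0.47),
}

# Seasonal extremes of integrated temperature (degC) paired with the
# corresponding digestion-time extremes (hours): T max <-> DT min.
DT_EXTREMES = [
    (29.12, 0.86),
    (24.38, 1.29),
    (28.20, 0.93),
    (26.27, 1.09),
    (23.11, 1.44),
    (18.72, 2.09),
]

# Diet/habitat composition percentages per season (gut totals 9/23/10,
# habitat totals 40) and the published per-taxon electivity index and 95% CI
# for taxa present in both compartments.
DIET_SURVEY = {
    "summer": dict(
        gut_total=9,
        habitat_total=40,
        gut_pct={
            "Acartia danae": 11.1, "Centropages velificatus": 33.3, "Euaugaptilus": 11.1,
            "Pontellina plumata": 11.1, "Temora turbinata": 33.3,
        },
        habitat_pct={
            "Acartia danae": 5.0, "Candacia": 12.5, "Centropages furcatus": 7.5,
            "Centropages velificatus": 17.5, "Euaugaptilus": 7.5, "Farranula rostrata": 5.0,
            "Labidocera acutifrons": 2.5, "Lucicutia": 5.0, "Oithona plumifera": 2.5,
            "Onychocorycaeus catus": 2.5, "Subeucalanus subtenuis": 17.5,
            "Temora stylifera": 5.0, "Temora turbinata": 10.0,
        },
        published={
            "Acartia danae": (0.704, 0.231, 0.956),
            "Centropages velificatus": (0.702, 0.347, 0.916),
            "Euaugaptilus": (0.607, 0.176, 0.932),
            "Temora turbinata": (0.818, 0.448, 0.957),
        },
    ),
    "fall": dict(
        gut_total=23,
        habitat_total=40,
        gut_pct={
            "Calanopia americana": 4.3, "Calanus": 21.7, "Candacia pachydactyla": 4.3,
            "Corycaeus catus": 8.7, "Euaugaptilus": 8.7, "Farranula": 4.3,
            "Pontellopsis": 4.3, "Temora stylifera": 4.3, "Temora turbinata": 39.1,
        },
        habitat_pct={
            "Agetus limbatus": 2.5, "Calanus": 37.5, "Candacia pachydactyla": 2.5,
            "Corycaeus catus": 2.5, "Euaugaptilus": 10.0, "Farranula": 2.5,
            "Lucicutia flavicornis": 2.5, "Mecynocera clausi": 2.5, "Oithona plumifera": 2.5,
            "Oithona setigera": 2.5, "Oncaea mediterranea": 5.0, "Temora stylifera": 7.5,
            "Temora turbinata": 12.5, "Undinula vulgaris": 5.0, "Urocorycaeus furcifer": 2.5,
        },
        published={
            "Calanus": (0.316, 0.129, 0.594),
            "Candacia pachydactyla": (0.639, 0.146, 0.946),
            "Corycaeus catus": (0.788, 0.301, 0.966),
            "Euaugaptilus": (0.462, 0.144, 0.821),
            "Farranula": (0.639, 0.145, 0.945),
            "Temora stylifera": (0.359, 0.088, 0.819),
            "Temora turbinata": (0.818, 0.560, 0.938),
        },
    ),
    "winter": dict(
        gut_total=10,
        habitat_total=40,
        gut_pct={
            "Euaugaptilus": 10.0, "Euchaeta": 10.0, "Farranula": 10.0, "Lucicutia": 30.0,
            "Oithona": 10.0, "Oncaea": 20.0, "Pontellopsis": 10.0,
        },
        habitat_pct={
            "Calanus": 7.5, "Calocalanus": 5.0, "Candacia bispinosa": 2.5,
            "Candacia simplex": 5.0, "Candacia varicans": 5.0, "Centropages velificatus": 5.0,
            "Euaugaptilus": 10.0, "Euchaeta": 12.5, "Euchirella": 5.0, "Gaetanus kruppii": 2.5,
            "Heterorhabdus": 2.5, "Labidocera scotti": 2.5, "Nannocalanus minor": 2.5,
            "Oithona": 15.0, "Pareucalanus sewelli": 2.5, "Rhincalanus nasutus": 2.5,
            "Subeucalanus pileatus": 2.5, "Subeucalanus subtenuis": 7.5, "Temora turbinata": 2.5,
        },
        published={
            "Euaugaptilus": (0.5, 0.134, 0.887),
            "Euchaeta": (0.438, 0.111, 0.858),
            "Oithona": (0.386, 0.096, 0.830),
        },
    ),
}


@pytest.fixture
def ambush_params():
    import sagitta as sg

    return sg.EncounterParams(radius=0.003, prey_speed=0.150, predator_speed=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def published_diet_pair():
    """(gut, habitat) CompositionTable pair reconstructed for one season."""
    from sagitta import CompositionTable

    def build(season):
        block = DIET_SURVEY[season]
        gut = CompositionTable.from_percentages(block["gut_pct"], block["gut_total"])
        habitat = CompositionTable.from_percentages(block["habitat_pct"], block["habitat_total"])
        return gut, habitat

    return build
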
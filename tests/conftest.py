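import numpy as np
import pandas as pd
import pytest

from mycodiv import load_season_fixture, load_survey


@pytest.fixture(scope="session")
def winter_cf():
    return load_season_fixture("winter")


@pytest.fixture(scope="session")
def summer_cf():
    return load_season_fixture("summer")


@pytest.fixture(scope="session")
def rainy_cf():
    return load_season_fixture("rainy")


@pytest.fixture(scope="session")
def survey():
    return load_survey()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160318)


def make_balanced(rng, seasons=3, sites=6, tissues=3, r=3, mu=10.0, sd=2.0,
                  effects=None):
    """Random balanced factorial table with optional injected cell effects.

    ``effects`` maps a factor name to a dict of level -> additive shift.
    """
    season_levels = ["winter", "summer", "rainy"][:seasons]
    tissue_levels = ["leaf", "stem", "petiole"][:tissues]
    rows = []
    for a in season_levels:
        for b in range(1, sites + 1):
            for c in tissue_levels:
                shift = 0.0
                if effects:
                    shift += effects.get("season", {}).get(a, 0.0)
                    shift += effects.get("site", {}).get(b, 0.0)
                    shift += effects.get("tissue", {}).get(c, 0.0)
                for rep in range(1, r + 1):
                    rows.append((a, b, c, rep, mu + shift + sd * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["season", "site", "tissue", "replicate", "response"])
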
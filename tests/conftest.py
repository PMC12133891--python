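"""Shared fixtures: toy models, diets, and the solved 2x12 study suite."""

from __future__ import annotations

import pytest

from dietwbm import biomarkers as bm
from dietwbm import diet as dm
from dietwbm import solver
from dietwbm import synthetic_data as sd


@pytest.fixture(scope="session")
def nutrient_table():
    return sd.nutrient_table_fixture()


@pytest.fixture(scope="session")
def toy_diets():
    return sd.make_toy_diets()


@pytest.fixture(scope="session")
def male_model():
    model, manifest = sd.make_toy_wbm("male")
    return model, manifest


@pytest.fixture(scope="session")
def female_model():
    model, manifest = sd.make_toy_wbm("female")
    return model, manifest


@pytest.fixture(scope="session")
def forced_policy():
    return dm.DietApplicationPolicy(mode=dm.DietMode.FORCED_UPTAKE)


@pytest.fixture(scope="session")
def solved_suite(male_model, female_model, toy_diets, forced_policy):
    """Optimal pFBA solutions for every (sex, diet) cell of the toy study."""
    suite = {}
    for sex, (model, _manifest) in (("male", male_model), ("female", female_model)):
        for d in toy_diets:
            sol = solver.pfba(dm.apply_diet(model, d, forced_policy))
            suite[(sex, d.name)] = sol
    return suite


@pytest.fixture(scope="session")
def panels(male_model, female_model):
    return {"male": bm.resolve_panel(male_model[0]),
            "female": bm.resolve_panel(female_model[0])}
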
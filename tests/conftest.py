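import hypothesis
import pytest

import vitecal as v

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def instrument():
    return v.builtin_instrument()


@pytest.fixture(scope="session")
def fixture_db(instrument):
    """Synthetic composition DB covering every member food of the instrument."""
    return v.fixture_db_for_instrument(7, instrument)


@pytest.fixture(scope="session")
def tiny_db():
    """Three hand-built foods with simple round contents."""
    items = [
        v.FoodItem("almonds", "almonds", v.FoodGroup.NUTS,
                   v.IsoformVector(alpha_t=25.0, gamma_t=1.0)),
        v.FoodItem("sunflower_seeds", "sunflower seeds", v.FoodGroup.NUTS,
                   v.IsoformVector(alpha_t=35.0, gamma_t=3.0)),
        v.FoodItem("canola_oil", "canola oil", v.FoodGroup.FATS,
                   v.IsoformVector(alpha_t=17.0, gamma_t=27.0, delta_t3=1.0)),
    ]
    return v.CompositionDB.from_items(items)


@pytest.fixture(scope="session")
def tiny_instrument():
    items = (
        v.FFQItem("almonds_sunflower_seeds", "Almonds/sunflower seeds", v.FoodGroup.NUTS,
                  30.0, "g", "2 tablespoons", ("almonds", "sunflower_seeds")),
        v.FFQItem("canola_oil", "Canola oil", v.FoodGroup.FATS,
                  10.0, "g", "1 tablespoon", ("canola_oil",)),
    )
    return v.FFQInstrument(items=items)


@pytest.fixture
def small_cohort(instrument, fixture_db):
    """A 40-respondent paired cohort for downstream-module tests."""
    cfg = v.SynthConfig(n_respondents=40, seed=11)
    responses, record = v.gen_cohort(cfg, instrument, fixture_db)
    ffq_table = v.intake_table(v.cohort_intake(responses, instrument, fixture_db))
    return responses, ffq_table, record
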
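import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bfgrowth.synthetic import FOOD_COLS, LIQUID_COLS, TruthSpec, default_truth, generate

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_child(
    id=1,
    age_days=30,
    sex="male",
    weight_kg=4.0,
    height_cm=54.0,
    province="Punjab",
    area="rural",
    still_breastfed=1.0,
    liquids=None,
    foods=None,
    diarrhea=0.0,
    fever=0.0,
    cough=0.0,
    breathing_difficulty=0.0,
    hh_members=5.0,
    under5=2.0,
    age5_17=1.0,
    sleeping_rooms=1.0,
    singleton=True,
    full_term=True,
    birth_order=1,
    mother_smokes=False,
):
    """One fully-specified child record (all criteria passing by default)."""
    row = {
        "id": id,
        "age_days": age_days,
        "sex": sex,
        "weight_kg": weight_kg,
        "height_cm": height_cm,
        "province": province,
        "area": area,
        "still_breastfed": still_breastfed,
        "diarrhea": diarrhea,
        "fever": fever,
        "cough": cough,
        "breathing_difficulty": breathing_difficulty,
        "hh_members": hh_members,
        "under5": under5,
        "age5_17": age5_17,
        "sleeping_rooms": sleeping_rooms,
        "singleton": singleton,
        "full_term": full_term,
        "birth_order": birth_order,
        "mother_smokes": mother_smokes,
    }
    for i, c in enumerate(LIQUID_COLS):
        row[c] = (liquids or [0.0] * 9)[i]
    for i, c in enumerate(FOOD_COLS):
        row[c] = (foods or [0.0] * 15)[i]
    return row


def children_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def small_survey(truth):
    """A 2,000-record synthetic survey, shared across tests."""
    return generate(2000, truth, seed=20240601)


@pytest.fixture(scope="session")
def fitted_bcpe(truth):
    """A BCPE-ps (0,1,0) model fitted to one synthetic boys-weight sample."""
    from bfgrowth.fitting import fit_gamlss
    from bfgrowth.synthetic import sample_anthro

    rng = np.random.default_rng(11)
    t = rng.integers(0, 183, 2500)
    y = sample_anthro(t, truth, "weight", "male", seed=12)
    return fit_gamlss(t, y, family="BCPE", smoother="ps", df_spec=(0, 1, 0))
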
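import numpy as np
import pandas as pd
import pytest

import ffqval as fv


@pytest.fixture(scope="session")
def schema():
    return fv.FFQSchema.default()


@pytest.fixture(scope="session")
def mapping():
    return fv.FrequencyMapping.default()


@pytest.fixture(scope="session")
def portions():
    return fv.PortionTable.default()


@pytest.fixture(scope="session")
def composition():
    return fv.FoodCompositionTable.default()


@pytest.fixture(scope="session")
def group_mapping():
    return fv.load_food_group_mapping()


@pytest.fixture(scope="session")
def zero_error_dataset():
    """Small error-free study: both instruments read the truth exactly."""
    return fv.generate_cohort(60, fv.ErrorModel.zero(), seed=11)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-error study at a small size for pipeline-level tests."""
    return fv.generate_cohort(80, seed=7)


def complete_record(schema, level_code=4, pid="P1"):
    """A fully answered questionnaire record at one frequency level."""
    return fv.FFQRecord(
        participant_id=pid,
        responses={i: level_code for i in schema.item_ids},
        portion_indications={"starch": 2, "protein": 2, "vegetable": 2},
    )


@pytest.fixture
def make_record(schema):
    def _make(level_code=4, missing_items=(), portion_missing=(), pid="P1"):
        responses = {i: level_code for i in schema.item_ids}
        for m in missing_items:
            responses[m] = None
        indications = {"starch": 2, "protein": 2, "vegetable": 2}
        for c in portion_missing:
            indications[c] = None
        return fv.FFQRecord(
            participant_id=pid, responses=responses, portion_indications=indications
        )

    return _make
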
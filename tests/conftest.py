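import pandas as pd
import pytest

from trialanon import riskmodel
from trialanon.codebook import codebook_from_dict
from trialanon.synthdata import WorldSpec, generate_world, worked_example_tables


@pytest.fixture(scope="session")
def examples():
    return worked_example_tables()


@pytest.fixture(scope="session")
def world():
    """Default three-study world (N=2000, 200 subjects sampled, v=0.1)."""
    return generate_world(WorldSpec(seed=7))


@pytest.fixture(scope="session")
def small_world():
    return generate_world(
        WorldSpec(population_size=400, study_sizes=(40,), seed=3))


@pytest.fixture()
def high_controls_ctx():
    cfg = riskmodel.default_context_config()
    answers = {i: "high" for items in cfg["groups"].values() for i in items}
    return riskmodel.context_from_checklist(answers, v=0.1)


@pytest.fixture(scope="session")
def mini_codebook():
    """One demography-like table with a hierarchy and an acquaintance QI."""
    return codebook_from_dict({
        "tables": [{
            "name": "demography",
            "key": "subject_id",
            "subject_table": True,
            "variables": [
                {"name": "subject_id", "privacy_class": "direct_identifier",
                 "value_type": "text"},
                {"name": "age", "privacy_class": "quasi_public",
                 "value_type": "integer", "range": [0, 120],
                 "aliases": ["AGE", "age_yrs"]},
                {"name": "sex", "privacy_class": "quasi_public",
                 "value_type": "category", "categories": ["M", "F"]},
                {"name": "country", "privacy_class": "quasi_public",
                 "value_type": "category",
                 "categories": ["CH", "DE", "US", "CA"],
                 "hierarchy": [
                     {"name": "region",
                      "map": {"CH": "Western Europe", "DE": "Western Europe",
                              "US": "North America", "CA": "North America"}},
                     {"name": "continent",
                      "map": {"CH": "Europe", "DE": "Europe",
                              "US": "America", "CA": "America"}},
                 ]},
                {"name": "medical_history",
                 "privacy_class": "quasi_acquaintance",
                 "value_type": "text"},
            ],
        }]
    })
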
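import numpy as np
import pandas as pd
import pytest

from upfharmony import (
    FoodCompositionTable,
    SimulationConfig,
    default_taxonomy,
    synthesize_cohort,
)
from upfharmony.pipeline import build_analysis

ALL_SYSTEMS = ("NOVA", "IARC", "IFIC", "UNC")


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def composition():
    return FoodCompositionTable.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic cohort."""
    return synthesize_cohort(SimulationConfig(seed=7, n=600))


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    c = small_cohort
    return build_analysis(c.participants, c.ffq_categories, c.ffq_portions,
                          c.composition, c.taxonomy, c.scale,
                          systems=ALL_SYSTEMS)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def make_mini_taxonomy(rows):
    """Inline taxonomy from (item_id, nova, iarc, ific, unc) tuples."""
    from upfharmony import FoodItemRecord, TaxonomyTable

    records = tuple(
        FoodItemRecord(item_id=i, label=i, group_by_system={
            "NOVA": nova, "IARC": iarc, "IFIC": ific, "UNC": unc})
        for i, nova, iarc, ific, unc in rows
    )
    return TaxonomyTable(records)


@pytest.fixture()
def mini_taxonomy():
    return make_mini_taxonomy([
        ("a", "4", "3", "5", "4.2"),   # UPF everywhere
        ("b", "1", "2", "2", "2"),
        ("c", "3", "3", "3", "3.1"),   # UPF only under IARC
    ])
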
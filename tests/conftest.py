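import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fermentome.model import CulturomicsTable, GeneContentMatrix, PathwayMap
from fermentome.simulate import SimulationSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def small_spec() -> SimulationSpec:
    """Down-scaled planted-structure spec used across generator tests."""
    return SimulationSpec(
        seed=7,
        core_functions=50,
        unique_functions=(5,) * 8,
        accessory_functions=20,
    )


@pytest.fixture()
def tiny_gene_content() -> GeneContentMatrix:
    """3 taxa x 2 samples x 4 functions with hand-placed copies and tpm.

    fA: both taxa T1,T2 in both samples (core, redundant).
    fB: only T1, only sample S1 (unique to S1, sole contributor T1).
    fC: T2 and T3 in S2 only (unique to S2).
    fD: T3 in both samples, transcribed.
    """
    rows = [
        ("T1", "S1", "fA", 2, 5.0, "none"),
        ("T2", "S1", "fA", 1, 0.0, "none"),
        ("T1", "S2", "fA", 2, 5.0, "none"),
        ("T2", "S2", "fA", 1, 0.0, "none"),
        ("T1", "S1", "fB", 3, 1.0, "none"),
        ("T2", "S2", "fC", 1, 0.0, "none"),
        ("T3", "S2", "fC", 1, 2.0, "none"),
        ("T3", "S1", "fD", 1, 4.0, "none"),
        ("T3", "S2", "fD", 2, 4.0, "none"),
    ]
    return GeneContentMatrix(
        pd.DataFrame(
            rows,
            columns=["taxon", "sample", "function_id", "copy_number", "tpm", "phase"],
        )
    )


@pytest.fixture()
def tiny_pathways() -> PathwayMap:
    return PathwayMap(
        pd.DataFrame(
            {
                "pathway": ["glycolysis"] * 3 + ["proteolysis"],
                "mega_pathway": ["carbohydrate"] * 3 + ["nitrogen"],
                "function_id": ["fA", "fB", "fD", "fC"],
                "is_key": [True, True, False, True],
            }
        )
    )


@pytest.fixture()
def tiny_culturomics() -> CulturomicsTable:
    rows = [
        ("S1", "T1", "LAB", 10, 8.0),
        ("S1", "T2", "LAB", 5, 3.0),
        ("S1", "T3", "yeast", 5, 6.5),
        ("S2", "T1", "LAB", 12, 7.0),
        ("S2", "T2", "LAB", 4, 2.5),
        ("S2", "T4", "other_bacterium", 4, 2.0),
    ]
    return CulturomicsTable(
        pd.DataFrame(
            rows, columns=["sample", "taxon", "guild", "isolate_count", "cell_density"]
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
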
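import numpy as np
import pandas as pd
import pytest

from xcimosaic import SimCohortConfig, SurvivalSpec


def counts_from_fractions(fractions, n_cells=1000, region="cgc", stage="adult", cohort=None):
    """Build a count table with exact per-animal positive fractions."""
    rows = []
    for i, f in enumerate(fractions):
        pos = round(f * n_cells)
        rows.append(
            {
                "animal_id": f"a{i:03d}",
                "region": region,
                "stage": stage,
                "n_gfp_pos": pos,
                "n_gfp_neg": n_cells - pos,
            }
        )
    df = pd.DataFrame(
        rows, columns=["animal_id", "region", "stage", "n_gfp_pos", "n_gfp_neg"]
    )
    if cohort is not None:
        df.insert(0, "cohort", cohort)
    return df


@pytest.fixture
def wt_config():
    """Wild-type-like cohort: random XCI, full survival of both lineages."""
    return SimCohortConfig(
        n_animals=8,
        n_cells_per_region=500,
        stages=("P6", "adult"),
        survival_model=SurvivalSpec(s_base=(1.0, 1.0)),
        seed=11,
    )


@pytest.fixture
def partial_elimination_config():
    """Mosaic cohort with cumulative mutant survival 0.714 (WT Purkinje-like)."""
    return SimCohortConfig(
        n_animals=8,
        n_cells_per_region=500,
        stages=("P6", "adult"),
        survival_model=SurvivalSpec(s_base=(1.0, 0.714)),
        seed=7,
    )
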
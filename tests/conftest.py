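import numpy as np
import pandas as pd
import pytest

from lekdemog.synthetic import gen_encounter_histories, gen_lek_counts


@pytest.fixture(scope="session")
def nest_histories() -> pd.DataFrame:
    """One simulated nest dataset at package defaults (shared, read-only)."""
    return gen_encounter_histories(stage="nest", seed=101)


@pytest.fixture(scope="session")
def small_lek_sim():
    """A small lek-count simulation for fast SSM checks."""
    from lekdemog.synthetic import SSMTruth

    truth = SSMTruth(n_regions=2, n_leks=12, n_years=12, n_covariates=1,
                     mu_beta=(0.05,), sigma_beta=(0.02,),
                     missing_fraction=0.1)
    return gen_lek_counts(truth, seed=42)


@pytest.fixture()
def lek_csv(tmp_path):
    path = tmp_path / "leks.csv"
    path.write_text(
        "lek_id,region_id,year,count\n"
        "L1,R1,2010,12\n"
        "L1,R1,2011,\n"
        "L2,R1,2010,0\n"
    )
    return path
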
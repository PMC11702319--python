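import numpy as np
import pandas as pd
import pytest

from fjordapcs.geochem import standardize
from fjordapcs.factors import fit_pca, significant_loadings, varimax_rotate
from fjordapcs.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def synthetic_default():
    """One default synthetic fjord realization (n=100, 10% noise)."""
    return generate(SyntheticConfig())


@pytest.fixture(scope="session")
def synthetic_noiseless():
    return generate(SyntheticConfig(noise_sd=0.0, n_rivers=0))


@pytest.fixture(scope="session")
def synthetic_study():
    """Survey-footprint realization: 14 fjord samples + 3 rivers."""
    return generate(SyntheticConfig.study())


@pytest.fixture(scope="session")
def fitted_default(synthetic_default):
    """Standardized matrix, model, rotated model and significance for the
    default synthetic table (shared across tests; all stages deterministic)."""
    table, truth = synthetic_default
    fjord = table.subset("fjord")
    z, std = standardize(fjord)
    model = fit_pca(z)
    rotated = varimax_rotate(model, 3)
    sig = significant_loadings(rotated)
    return {"table": table, "truth": truth, "fjord": fjord, "z": z,
            "std": std, "model": model, "rotated": rotated, "sig": sig}


@pytest.fixture
def small_csv(tmp_path):
    """Tiny hand-written delimited table with censored and blank cells."""
    csv = tmp_path / "table.csv"
    csv.write_text(
        "ID,Station,Depth,Type,sal,no3,fe\n"
        "PN_3,PN,3,fjord,32.5,2.1,150\n"
        "PN_25,PN,25,fjord,34.2,<LOD,80\n"
        "F_6,F,6,fjord,33.8,1.5,\n"
        "T_10,T,10,fjord,34.8,3.0,40\n"
        "BR_0,BR,0,river,0.1,4.0,348\n"
    )
    schema = {
        "sample_id": "ID", "station": "Station", "depth": "Depth",
        "type": "Type",
        "parameters": {
            "salinity": {"column": "sal", "unit": "PSU", "kind": "property"},
            "NO3": {"column": "no3", "unit": "umol/L", "lod": 0.1},
            "dFe": {"column": "fe", "unit": "ng/L", "lod": 12.0},
        },
    }
    return csv, schema
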
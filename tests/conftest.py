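import numpy as np
import pandas as pd
import pytest

from ninflux import (
    AssayDesign,
    InfluxDataset,
    MetaboliteTable,
    NoiseModel,
    reference,
    simulate_influx,
)


@pytest.fixture(scope="session")
def ammonium_clean() -> InfluxDataset:
    """Noise-free influx assay generated from the published ammonium set."""
    return simulate_influx(reference.AMMONIUM_PARAMS,
                           AssayDesign(n_source="ammonium"),
                           NoiseModel(kind="none", seed=0))


@pytest.fixture(scope="session")
def nitrate_clean() -> InfluxDataset:
    """Noise-free influx assay generated from the published nitrate set."""
    return simulate_influx(reference.NITRATE_PARAMS,
                           AssayDesign(n_source="nitrate"),
                           NoiseModel(kind="none", seed=0))


@pytest.fixture(scope="session")
def nitrate_noisy() -> InfluxDataset:
    """Nitrate assay with 5 % multiplicative measurement noise."""
    return simulate_influx(reference.NITRATE_PARAMS,
                           AssayDesign(n_source="nitrate"),
                           NoiseModel(cv_or_sigma=0.05, seed=42))


def make_metabolite_table(values: dict) -> MetaboliteTable:
    """Small tidy table from {analyte: {treatment: [replicate values]}}."""
    rows = []
    for analyte, per_treatment in values.items():
        for treatment, reps in per_treatment.items():
            for i, val in enumerate(reps, start=1):
                rows.append((treatment, "new_leaves", i, analyte, float(val)))
    df = pd.DataFrame(rows, columns=["treatment", "organ", "replicate",
                                     "analyte", "concentration"])
    return MetaboliteTable(data=df)


@pytest.fixture()
def toy_metabolites() -> MetaboliteTable:
    """Two analytes, two treatments, two replicates; hand-checkable values."""
    return make_metabolite_table({
        "Gln": {"A": [2.0, 4.0], "B": [6.0, 2.0]},
        "Glu": {"A": [1.0, 2.0], "B": [3.0, 1.0]},
    })
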
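import numpy as np
import pandas as pd
import pytest

from rhizochron import (OtuTable, SimulationDesign, filter_prevalence,
                        normalize_per_mille, simulate_dataset)
from rhizochron.core_io import COMPARTMENT_POSITIONS, validate_metadata


def make_metadata(n, compartment="endosphere", ages=None, site="site_A",
                  genotype="M206", treatment="none", dev_stage=5,
                  prefix="s"):
    """Hand-built metadata frame with all required design columns."""
    ages = np.resize(np.asarray(ages if ages is not None else [7.0]), n)
    md = pd.DataFrame({
        "sample_id": [f"{prefix}{i}" for i in range(n)],
        "site": site, "season": "2016", "compartment": compartment,
        "position": COMPARTMENT_POSITIONS[compartment],
        "age_days": ages.astype(float), "genotype": genotype,
        "dev_stage": dev_stage, "treatment": treatment, "soil": "soil1",
        "sequencing_run": "run1",
    })
    return validate_metadata(md)


def per_mille_table(values, otu_ids=None, sample_ids=None):
    """Build a per-mille OtuTable from a 2-D array (OTUs × samples)."""
    values = np.asarray(values, dtype=float)
    otu_ids = otu_ids or [f"otu{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return OtuTable(pd.DataFrame(values, index=otu_ids, columns=sample_ids),
                    unit="per_mille")


@pytest.fixture(scope="session")
def two_site_dataset():
    """Small two-site, four-compartment season with default archetypes."""
    design = SimulationDesign(timepoints_days=tuple(range(7, 141, 14)),
                              replicates_per_cell=3, seed=5)
    return simulate_dataset(design, n_otus=300)


@pytest.fixture(scope="session")
def two_site_norm(two_site_dataset):
    filtered, _ = filter_prevalence(two_site_dataset.table)
    return normalize_per_mille(filtered)
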
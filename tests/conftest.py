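import numpy as np
import pandas as pd
import pytest

from proxilogic.proteomics import LogIntensityMatrix, ProteinQuantTable
from proxilogic.simulate import SimulationConfig, simulate_miniturbo


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study design for fast unit tests."""
    return SimulationConfig(
        seed=7, n_background_proteins=300, n_planted_per_class=5,
        n_genes=300, n_induced_genes=40, n_bait_dependent_genes=16,
        n_coregulated_genes=8, n_catalog_proteins=300, n_peaks=16,
        chromosome_length=12_000,
    )


@pytest.fixture(scope="session")
def small_miniturbo(small_config):
    return simulate_miniturbo(small_config)


@pytest.fixture()
def tiny_table():
    """Three proteins x two 3-sample groups with hand-set intensities."""
    samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
    inten = pd.DataFrame(
        [[2.0**14, 2.0**15, 2.0**16, 2.0**10, 2.0**11, 2.0**12],
         [2.0**12, 2.0**12, 2.0**12, 2.0**12, 2.0**12, 2.0**12],
         [2.0**20, 2.0**20, 2.0**20, 0.0, 0.0, 0.0]],
        index=["enriched", "flat", "absent_in_b"], columns=samples)
    ann = pd.DataFrame({
        "majority_ids": [["P1"], ["P2"], ["P3"]],
        "gene_names": [["enriched"], ["flat"], ["absent_in_b"]],
        "peptides": [5, 3, 2],
        "reverse": [False, False, False],
        "contaminant": [False, True, False],
        "site_only": [False, False, False],
    }, index=inten.index)
    return ProteinQuantTable(annotations=ann, intensities=inten)


@pytest.fixture()
def tiny_matrix(tiny_table):
    values = np.log2(tiny_table.intensities.where(
        tiny_table.intensities > 0, 2.0**9))
    mask = tiny_table.intensities == 0
    return LogIntensityMatrix(values=values, mask=mask, impute_value=9.0,
                              peptides=tiny_table.annotations["peptides"])
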
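import numpy as np
import pandas as pd
import pytest

import tpod


def make_count_matrix(counts, concentrations=None, replicates=None):
    """Build a CountMatrix from a plain array (genes x samples)."""
    counts = np.asarray(counts)
    n_genes, n_samp = counts.shape
    if concentrations is None:
        concentrations = [0.0] * n_samp
    if replicates is None:
        replicates = [f"rep{i + 1}" for i in range(n_samp)]
    sheet = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_samp)],
        "concentration_uM": concentrations,
        "replicate": replicates,
    })
    cdf = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                       columns=sheet["sample_id"])
    cdf.index.name = "gene_id"
    return tpod.CountMatrix(counts=cdf, samples=sheet)


@pytest.fixture(scope="session")
def tbbpa_design():
    """Control + 10-fold series anchored at the TBBPA EC20 (2.92 µM)."""
    return tpod.make_design(2.92, 3, 10.0, 3)


@pytest.fixture(scope="session")
def simulated_dataset(tbbpa_design):
    """Small mixed dataset shared by downstream-stage tests."""
    truth = tpod.make_truth(600, tbbpa_design, seed=42)
    counts = tpod.simulate_counts(tbbpa_design, truth, 150_000.0, seed=42)
    return truth, counts
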
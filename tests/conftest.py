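import numpy as np
import pandas as pd
import pytest

import duotrend as dt


def small_cohort_config(seed=101, **overrides):
    """A reduced cohort (100 genes, 188 samples) for fast end-to-end tests."""
    counts = {
        "concordant_up": 15,
        "mrna_down_protein_up": 10,
        "mrna_up_protein_down": 10,
        "concordant_down": 15,
        "mediated": 10,
        "null": 40,
    }
    return dt.CohortSimConfig(seed=seed, n_genes_per_class=counts, **overrides)


@pytest.fixture(scope="session")
def small_cohort():
    return dt.simulate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def trend_tables(small_cohort):
    """mRNA and protein trend tables computed once for the shared cohort."""
    mrna, protein, meta, truth = small_cohort
    sf = dt.median_ratio_size_factors(mrna)
    mrna_tab = dt.nb_trend_table(mrna, sf, meta)
    prot_rn = dt.rank_normal_matrix(protein)
    prot_tab = dt.lmm_trend_table(prot_rn.values, meta)
    return mrna_tab, prot_tab


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
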
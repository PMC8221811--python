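import warnings

import pytest

from dacuity.preprocessing import normalize_measures, standardize_baseline
from dacuity.synthetic import CohortSpec, ConnectivitySpec, generate_connectivity, generate_measure_table

warnings.filterwarnings("ignore", message="prefilter kept no features")


@pytest.fixture(scope="session")
def cohort():
    """Mid-size cohort with default (study-condition) structure."""
    spec = CohortSpec(n_subjects=500, seed=42)
    table, truth = generate_measure_table(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def standardized_baseline(cohort):
    _, table, truth = cohort
    base = table[table["wave"] == 1]
    norm, tspec = normalize_measures(base, seed=0)
    return standardize_baseline(norm, tspec), tspec, truth


@pytest.fixture(scope="session")
def scanned_cohort():
    """Small connectivity dataset with planted signal for d and IQ."""
    spec = CohortSpec(n_subjects=320, seed=7)
    table, truth = generate_measure_table(spec)
    conn = ConnectivitySpec(n_nodes=42, n_modules=14, n_signal_edges_d=10,
                            n_signal_edges_iq=10, seed=8)
    ds = generate_connectivity(conn, truth, wave=1)
    return conn, ds, truth
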
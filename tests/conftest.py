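import warnings

import numpy as np
import pandas as pd
import pytest

import conetdiff as cd


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # small permutation counts are used deliberately in fast tests
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*permutations.*")
        warnings.filterwarnings("ignore", message=".*n_perm=.*")
        warnings.filterwarnings("ignore", message=".*expected cell.*")
        warnings.filterwarnings("ignore", message=".*permutation maxima.*")
        yield


@pytest.fixture(scope="session")
def small_truth():
    """15 features, 5 planted edges at rho=0.6."""
    return cd.make_basis_network(15, 5, 0.6, seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return cd.simulate_cohort(small_truth, "C1", 120, 20_000, seed=102)


@pytest.fixture()
def species_tsv(tmp_path):
    """MetaPhlAn-style percent-scale species table."""
    df = pd.DataFrame(
        {
            "S1": [40.0, 35.0, 25.0, 60.0],
            "S2": [10.0, 50.0, 40.0, 55.0],
        },
        index=[
            "k__Bacteria|g__Dorea",
            "k__Bacteria|g__Dorea|s__Dorea_longicatena",
            "k__Bacteria|g__Faecalibacterium|s__Faecalibacterium_prausnitzii",
            "k__Bacteria|g__Dorea|s__Dorea_longicatena|t__GCF_000154065",
        ],
    )
    path = tmp_path / "species.tsv"
    df.to_csv(path, sep="\t")
    return path


@pytest.fixture()
def metadata_frame():
    meta = pd.DataFrame(
        {
            "sample": ["S1", "S2"],
            "cohort": ["A", "A"],
            "age": [30.0, 50.0],
            "sex": [0, 1],
            "read_depth": [10_000, 9_999],
        }
    )
    return meta.set_index("sample", drop=False)


def rng(seed=0):
    return np.random.default_rng(seed)
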
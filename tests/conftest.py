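import numpy as np
import pandas as pd
import pytest

from triomics import AbundanceTable, CohortDesign, CohortMetadata, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (36/64/46 samples) with planted truth."""
    return generate_cohort(CohortDesign(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """Fast 3x8-sample cohort for pipeline-level tests."""
    design = CohortDesign(
        group_sizes=(8, 8, 8), n_species=40, n_kos=120, n_modules=8,
        module_size_range=(4, 8), n_metabolites=60, n_latent_clusters=3,
        n_diff_species=4, n_enriched_modules=2, seed=11,
    )
    return generate_cohort(design)


def make_table(values, kind="species", prefix="f", samples=None):
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    index = [f"{prefix}{i + 1}" for i in range(n_feat)]
    columns = samples or [f"s{i + 1}" for i in range(n_samp)]
    return AbundanceTable(pd.DataFrame(values, index=index, columns=columns), kind)


def make_metadata(groups, **phenotypes):
    frame = pd.DataFrame({"group": list(groups)})
    frame.index = [f"s{i + 1}" for i in range(len(frame))]
    for name, vals in phenotypes.items():
        frame[name] = vals
    return CohortMetadata(frame)


@pytest.fixture
def toy_table():
    return make_table([[1, 2, 3, 4], [4, 3, 2, 1], [0, 0, 1, 1]])
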
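import pytest

from promark.pipeline import run_bundle
from promark.synthetic_data import SimConfig, simulate_dataset, simulate_null


@pytest.fixture(scope="session")
def planted_bundle():
    """Default planted world: 2000 genes, 300 shared DEGs (|log2FC| = 2),
    60% of them with concordant +-1 SD promoter-mark shifts, 8 pairs/cohort."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def planted_results(planted_bundle):
    b = planted_bundle
    return run_bundle(
        b.genes, b.cohorts, b.chip_sample_peaks, b.chip_sheet,
        master_peaks=b.master_peaks,
    )


@pytest.fixture(scope="session")
def small_null_bundle():
    return simulate_null(SimConfig(n_genes=400, n_pairs=4, seed=5))
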
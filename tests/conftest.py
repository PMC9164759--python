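import numpy as np
import pytest

from metags.popsum import summarize_population
from metags.simulate import simulate_dataset
from metags.types import GenotypePanel, PhenotypeRecords, SimScenario


@pytest.fixture(scope="session")
def small_scenario():
    """Two-population benchmark at reduced size, strong block LD."""
    return SimScenario(n_indiv=(200, 100), n_snps=400, n_chrom=2,
                       block_len=50, within_block_ld=0.8, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return simulate_dataset(small_scenario)


@pytest.fixture(scope="session")
def small_summaries(small_scenario, small_dataset):
    data, sims = small_dataset
    scen = small_scenario
    return [summarize_population(p, s.records, err_var=scen.err_var[i],
                                 dgv_var=scen.dgv_var[i],
                                 population=f"pop{i + 1}")
            for i, (p, s) in enumerate(zip(data.panels, sims))]


@pytest.fixture(scope="session")
def single_pop_scenario():
    return SimScenario(n_pops=1, n_indiv=(600,), n_snps=600, n_chrom=2,
                       block_len=100, effect_corr=np.eye(1), dgv_var=(1.0,),
                       err_var=(10.0,), mean=(1.0,), seed=5)


@pytest.fixture(scope="session")
def single_pop_dataset(single_pop_scenario):
    return simulate_dataset(single_pop_scenario)


@pytest.fixture
def tiny_panel():
    """Hand-sized panel: 4 individuals, 3 SNPs on one chromosome."""
    dosage = np.array([[2, 1, 0],
                       [0, 1, 2],
                       [1, 2, 1],
                       [1, 0, 1]])
    return GenotypePanel(snp_ids=["1:a", "1:b", "1:c"],
                         chrom=["1", "1", "1"],
                         dosage=dosage,
                         indiv_ids=["i1", "i2", "i3", "i4"])


@pytest.fixture
def tiny_records():
    return PhenotypeRecords(y=[1.0, -0.5, 2.0, 0.3],
                            n_daughters=[10, 20, 5, 40],
                            indiv_ids=["i1", "i2", "i3", "i4"])
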
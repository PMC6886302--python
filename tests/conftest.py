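import numpy as np
import pytest

from burstquant import ExperimentDesign, GeneModel, TelegraphParams, sample_population


@pytest.fixture(scope="session")
def gene10k():
    """10 kb reference gene, 4 loci, evenly spread probes."""
    return GeneModel(
        name="SYN10K",
        length_nt=10_000,
        n_loci=4,
        exon_probe_positions_nt=tuple(np.linspace(300, 9700, 30).astype(int)),
        intron_probe_positions_nt=tuple(np.linspace(200, 5000, 10).astype(int)),
    )


@pytest.fixture(scope="session")
def bursty_params():
    return TelegraphParams(k_on_basal=0.5, k_off=1.5, init_rate=160.0,
                           deg_rate=0.4, export_rate=2.4)


@pytest.fixture(scope="session")
def basal_population(gene10k, bursty_params):
    """One 1,500-cell basal-state population shared across tests."""
    design = ExperimentDesign(timepoints_h=(0.0,), treatment="untreated",
                              n_cells_per_timepoint=1_500, seed=20_260_927)
    return sample_population(gene10k, bursty_params, design), design
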
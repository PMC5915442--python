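import numpy as np
import pandas as pd
import pytest

from recsel import (
    Arm,
    GenomeLayout,
    HaplotypePanel,
    SimulationConfig,
    compute_sds,
    density_filter,
    simulate_panel,
)
from recsel.panel import SAMPLE_COLUMNS, SITE_COLUMNS


def make_panel(haps, positions=None, chrom="chr1", datasets=None, regions=None):
    """Build a small panel from an (n_sites, n_samples, 2) 0/1 array."""
    haps = np.asarray(haps, dtype=np.int8)
    n_sites, n_samples, _ = haps.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ancestral": "A",
            "derived": "G",
        },
        columns=SITE_COLUMNS,
    )
    samples = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(n_samples)],
            "dataset": datasets if datasets is not None else "d1",
            "region": regions if regions is not None else "all",
        },
        columns=SAMPLE_COLUMNS,
    )
    return HaplotypePanel(sites=sites, haplotypes=haps, samples=samples)


@pytest.fixture
def tiny_layout():
    return GenomeLayout(
        chromosomes=[("chr1", 1_000_000)],
        arms=[Arm("chr1", 0, 1_000_000, "1p")],
    )


@pytest.fixture(scope="session")
def null_scan():
    """Selection scan of a neutral synthetic cohort (3 datasets of 200).

    Session-scoped: shared by the calibration checks of the final z and of
    the trait chi-square test.
    """
    cfg = SimulationConfig(seed=1, dataset_sizes=(200, 200, 200), n_common_sites=2500)
    panel, catalog, _ = simulate_panel(cfg)
    catalog, _ = density_filter(catalog, cfg.layout)
    table = compute_sds(panel, catalog, cfg.layout)
    return cfg, table
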
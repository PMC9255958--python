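"""Shared fixtures: one study-scale synthetic cohort, genotyped once."""

import pytest

from gonomosaic.mpas_genotyper import run_genotyping
from gonomosaic.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the study conditions (3 donors, 12/13/30 gonadal variants,
    10/8/14 blastocysts with 2 low-quality, 120 SNPs)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_genotyping(default_cohort):
    c = default_cohort
    return run_genotyping(c.manifest, c.panel, c.observations)


@pytest.fixture()
def tiny_config():
    """One-donor cohort small enough for repeated simulation in a test."""
    return SimulationConfig(
        n_donors=1,
        n_mosaic_per_donor=12,
        n_soma_only_per_donor=0,
        n_snps=24,
        n_blastocysts_per_donor=10,
        n_low_quality_blastocysts=0,
        depth_mean_tissue=2000.0,
        depth_mean_blastocyst=150.0,
        seed=0,
    )
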
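"""Shared fixtures: hand-built curation fixture files and seeded simulated cohorts."""

from pathlib import Path

import numpy as np
import pytest

from mnucohort import CohortSimConfig, simulate_cohort, simulate_genome

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_vcf() -> Path:
    """Hand-enumerated 3-plant joint VCF: 12 records of which 7 survive curation."""
    return DATA / "cohort3.vcf"


@pytest.fixture(scope="session")
def fixture_mask() -> Path:
    return DATA / "mask3.bed"


@pytest.fixture(scope="session")
def toy_cohort():
    """Small default-condition cohort: 5 plants, 2 x 500 kb genome, call noise on."""
    cfg = CohortSimConfig.toy()
    rng = np.random.default_rng(11)
    genome, genes, mask = simulate_genome(cfg, rng)
    return simulate_cohort(cfg, genome, genes, mask, rng)


@pytest.fixture(scope="session")
def dense_cohort():
    """Noise-free cohort with ~10k SNVs: enough sites for context/spectrum recovery
    checks at tight sampling bounds."""
    cfg = CohortSimConfig.toy(n_plants=20, mean_snvs=500, fp_rate=0.0)
    rng = np.random.default_rng(23)
    genome, genes, mask = simulate_genome(cfg, rng)
    return simulate_cohort(cfg, genome, genes, mask, rng)
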
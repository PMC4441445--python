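import numpy as np
import pytest

from mpbpred.genodata import GenotypeMatrix, SampleRecord, SNPInfo
from mpbpred.simulate import SimulationConfig, sample_study, simulate_cohort


@pytest.fixture(scope="session")
def population():
    """One large simulated population shared across tests (seed frozen)."""
    return simulate_cohort(
        SimulationConfig(n_samples=20000, seed=20, missing_rate=0.002)
    )


@pytest.fixture(scope="session")
def study(population):
    """Discovery (176 + 129 extremes) and four-category test set (300)."""
    return sample_study(population, seed=27)


@pytest.fixture(scope="session")
def discovery(study):
    return study[0]


@pytest.fixture(scope="session")
def discovery_labels(discovery):
    return (discovery.categories() == 1).astype(int)


@pytest.fixture()
def tiny_gm():
    """Hand-built 4-sample matrix: one autosomal SNP, one X-linked SNP."""
    snps = [
        SNPInfo("rs_auto", "1", 1000, "C", "T", 0.3, risk_allele="T"),
        SNPInfo("rs_x", "X", 2000, "T", "C", 0.17, risk_allele="T"),
    ]
    samples = [
        SampleRecord("S1", 45, "IV"),
        SampleRecord("S2", 50, "II"),
        SampleRecord("S3", 30, "I"),
        SampleRecord("S4", 63, "V"),
    ]
    dosage = np.array([[0, 0], [1, 1], [2, 0], [1, 1]], dtype=np.int8)
    return GenotypeMatrix(samples, snps, dosage)
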
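import numpy as np
import pytest

from bmors import GenomicRelationship, MarkerMatrix, PhenotypeTable
from bmors.simulate import default_scenario


@pytest.fixture
def tiny_pheno_csv(tmp_path):
    """2 lines × 2 envs, 1 trait, complete grid."""
    path = tmp_path / "pheno.csv"
    path.write_text(
        "Line,Env,GY\n"
        "L1,E1,1.0\n"
        "L2,E1,2.0\n"
        "L1,E2,3.0\n"
        "L2,E2,4.0\n"
    )
    return path


@pytest.fixture
def grid_pheno():
    """3 lines × 2 envs × 2 traits, deterministic values, complete."""
    rng = np.random.default_rng(11)
    values = rng.normal(10.0, 2.0, size=(6, 2))
    return PhenotypeTable(["L1", "L2", "L3"], ["E1", "E2"],
                          ["GY", "PH"], values)


@pytest.fixture(scope="session")
def small_bundle():
    """Simulated 30-line × 2-env × 2-trait bundle shared across tests."""
    return default_scenario(J=30, I=2, L=2, p=200, gcor=0.6, seed=42)


def identity_grm(n, prefix="L"):
    return GenomicRelationship([f"{prefix}{j+1}" for j in range(n)], np.eye(n))
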
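import numpy as np
import pytest

from morphgwas import SimConfig, simulate_cohort, simulate_symmetric_3d_cohort
from morphgwas.morphometrics import gpa_object_symmetry, ild_catalog, compute_ilds


@pytest.fixture(scope="session")
def cohort():
    """Small admixed cohort with one causal SNP (index 100 -> ILD 5, 0.5 SD)."""
    cfg = SimConfig(seed=11, n_individuals=300, n_snps=800, causal_effects=((100, 5, 0.5),))
    return simulate_cohort(cfg, n_decoy_tracts=6)


@pytest.fixture(scope="session")
def face_fit(cohort):
    return gpa_object_symmetry(cohort.landmarks, cohort.template)


@pytest.fixture(scope="session")
def face_ilds(cohort, face_fit):
    return compute_ilds(face_fit, ild_catalog(cohort.template))


@pytest.fixture(scope="session")
def skull_cohort():
    """3D mouse-skull-like cohort: 17 pairs + 10 midline, 200 individuals."""
    landmarks, sym = simulate_symmetric_3d_cohort(200, pairs=17, midline=10, seed=5)
    return landmarks, sym


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
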
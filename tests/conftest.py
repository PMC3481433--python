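import numpy as np
import pytest

from psoristrat import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design cohort (34 NN + 37 paired PN/PP) shared by tests."""
    matrix, annotations, truth = generate_cohort(CohortDesign(seed=0))
    classes = np.array([a.tissue_class for a in annotations])
    return matrix, annotations, truth, classes


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced cohort for API-level tests."""
    design = CohortDesign(n_controls=8, n_patients=8, n_genes=60, de_genes=20,
                          subgroup_genes=6, seed=3)
    matrix, annotations, truth = generate_cohort(design)
    classes = np.array([a.tissue_class for a in annotations])
    return matrix, annotations, truth, classes
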
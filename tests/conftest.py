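import numpy as np
import pytest

from glpop.synthdata import (PopulationModel, SimDesign,
                             draw_population_frequencies, simulate_read_counts)
from glpop.gl_freq import genotype_likelihoods


@pytest.fixture(scope="session")
def small_cohort():
    """Two populations (c=0.1), 12 diploids each, depth 4x, 2000 sites."""
    model = PopulationModel(2, 0.1, 2000)
    truth = draw_population_frequencies(model, 11)
    counts, truth = simulate_read_counts(truth, SimDesign(12, 4.0, 0.005, 11))
    glm = genotype_likelihoods(counts, 0.005)
    return counts, truth, glm


def random_gl(rng, n_sites, n_ind):
    """Random max-scaled likelihood triples (not from any data model)."""
    gl = rng.random((n_sites, n_ind, 3))
    return gl / gl.max(axis=2, keepdims=True)
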
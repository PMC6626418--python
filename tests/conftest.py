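import math

import numpy as np
import pytest

from patternsurv.clustering import assign_clusters
from patternsurv.embedding import sweep_and_select
from patternsurv.io import load_reference_panels
from patternsurv.pattern_space import pattern_vectors_for_panel
from patternsurv.synthetic import CohortSpec, PanelSpec, simulate_cohort, toy_panel


@pytest.fixture(scope="session")
def reference_registry():
    return load_reference_panels()


@pytest.fixture(scope="session")
def small_cohort():
    """3 planted clusters, 250 samples, low noise; shared across modules."""
    spec = CohortSpec(
        n_samples=250,
        panels=(PanelSpec(panel=toy_panel("PanelA", 20), k_clusters=3, sigma=0.1),),
        hazards=(math.log(2) / 500, math.log(2) / 1500, math.log(2) / 3000),
        censor_horizon=4000.0,
        seed=42,
    )
    return spec, *simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_vectors(small_cohort):
    spec, expr, pheno, truth = small_cohort
    return pattern_vectors_for_panel(expr, spec.panels[0].panel, work_on_log_scale=True)


@pytest.fixture(scope="session")
def small_sweep(small_vectors):
    """One validated sweep result on the shared cohort (expensive; reused)."""
    result = sweep_and_select(small_vectors, [(20.0, 100.0)], seed=3)
    assert not result.rejected
    return result


@pytest.fixture(scope="session")
def small_solution(small_sweep):
    solution, attempts = assign_clusters(
        small_sweep.embedding, small_sweep.k, small_sweep.reference_labels, seed=4
    )
    return solution, attempts


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
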
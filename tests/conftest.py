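"""Shared fixtures: small synthetic cohorts and the full study run.

The expensive end-to-end study (discovery + validation at the design of the
acceptance checks) is session-scoped so the classifier, model-API and
acceptance tests share one computation.
"""

import numpy as np
import pandas as pd
import pytest

from peptipanel import (
    AmplitudeMatrix,
    SimConfig,
    run_synthetic_study,
    simulate_cohort_full,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap 10 vs 10 cohort with 60 peptides for unit-level checks."""
    return simulate_cohort_full(
        SimConfig(n_case=10, n_control=10, n_peptides=60, n_markers=6,
                  n_housekeeping=12, seed=7)
    )


@pytest.fixture(scope="session")
def study():
    """Full discovery + validation study at the design's fixed seed."""
    return run_synthetic_study(seed=1)


@pytest.fixture()
def toy_matrix():
    """Tiny deterministic matrix: 4 samples x 3 peptides with groups."""
    amp = pd.DataFrame(
        [[10.0, 0.0, 5.0],
         [12.0, 1.0, 6.0],
         [1.0, 8.0, 0.0],
         [2.0, 9.0, 1.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["p1", "p2", "p3"],
    )
    groups = pd.Series(["case", "case", "control", "control"],
                       index=amp.index, name="group")
    return AmplitudeMatrix(amp, groups)
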
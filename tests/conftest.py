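"""Shared fixtures: small seeded cohorts and confound tables."""

import numpy as np
import pandas as pd
import pytest

from metalesion import (
    GreyMatterMask,
    SyntheticCohortConfig,
    generate_metabolic_cohort,
)
from metalesion.synth import brain_compartments


def make_confounds(stack, seed=0):
    """Age / handedness / background-sum confound table for a synthetic stack."""
    grey, white, vent = brain_compartments(stack.mask.grid.shape)
    rng = np.random.default_rng(seed)
    n = stack.n_subjects
    return pd.DataFrame(
        {
            "age": rng.normal(32.0, 9.5, n),
            "handedness": rng.choice(
                ["right", "left", None], p=[0.75, 0.12, 0.13], size=n
            ),
            "global_sum": [stack.volumes[s][grey].sum() for s in range(n)],
            "white_matter_sum": [stack.volumes[s][white].sum() for s in range(n)],
            "ventricular_sum": [stack.volumes[s][vent].sum() for s in range(n)],
        },
        index=stack.subject_ids,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (n=159) with the default implanted effects."""
    cfg = SyntheticCohortConfig(seed=11)
    return generate_metabolic_cohort(cfg)


@pytest.fixture(scope="session")
def default_confounds(default_cohort):
    stack, _, _ = default_cohort
    return make_confounds(stack, seed=5)


@pytest.fixture
def tiny_mask():
    """A 4x4x4 all-true mask with 2 mm voxels."""
    grid = np.ones((4, 4, 4), dtype=bool)
    return GreyMatterMask(grid, np.diag([2.0, 2.0, 2.0, 1.0]), 2.0)
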
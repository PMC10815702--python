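"""Shared fixtures: seeded generators and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from iecat_rc.cohort import CohortData


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def make_cohort_pair(
    rng: np.random.Generator,
    n_cases: int = 60,
    n_controls: int = 60,
    n_external: int = 120,
    n_variants: int = 25,
    maf: float = 0.3,
    external_maf: float | None = None,
) -> tuple[CohortData, CohortData]:
    """Internal case-control cohort plus external control-only cohort.

    Genotypes are binomial draws; phenotypes are by design (not generative)
    since most tests only need the structural layout.
    """
    n_int = n_cases + n_controls
    g_int = rng.binomial(2, maf, size=(n_int, n_variants)).astype(float)
    y_int = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    z_int = np.column_stack([rng.standard_normal(n_int), (rng.random(n_int) < 0.5).astype(float)])
    q_ext = maf if external_maf is None else external_maf
    g_ext = rng.binomial(2, q_ext, size=(n_external, n_variants)).astype(float)
    z_ext = np.column_stack(
        [rng.standard_normal(n_external), (rng.random(n_external) < 0.5).astype(float)]
    )
    internal = CohortData(g_int, y_int, z_int, name="internal")
    external = CohortData(g_ext, np.zeros(n_external, dtype=int), z_ext, name="external")
    return internal, external


# The eight-subject fixture used for direct arithmetic verification of the
# score formulas. Printed here so the expected values can be recomputed by
# hand: Y, G, and one standard-normal covariate z.
EIGHT_SUBJECT_FIXTURE = {
    "Y": np.array([1, 0, 0, 1, 0, 1, 0, 0]),
    "G": np.array([2.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0]),
    "z": np.array([0.5, -1.2, 0.3, 1.7, -0.4, -0.9, 2.1, 0.1]),
}
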
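"""Cohort containers shared across the calibration, testing and simulation layers.

A cohort is a rectangular block of subjects: a genotype dosage matrix
(subjects x variants, entries 0/1/2 counting minor alleles), a binary
phenotype vector (1 = case), and an optional covariate matrix. Principal
components of the genotype matrix are attached lazily by the calibration
layer when needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CohortDimensions", "CohortData"]


@dataclass(frozen=True)
class CohortDimensions:
    """Sample-size bookkeeping for an internal/external study pair.

    ``n_internal`` is always ``n_internal_controls + n_internal_cases``;
    calibration additionally requires at least one external control and at
    least two internal controls.
    """

    n_internal_controls: int
    n_internal_cases: int
    n_external_controls: int

    def __post_init__(self) -> None:
        if min(self.n_internal_controls, self.n_internal_cases, self.n_external_controls) < 0:
            raise ValueError("cohort counts must be non-negative")

    @property
    def n_internal(self) -> int:
        return self.n_internal_controls + self.n_internal_cases

    def validate_for_calibration(self) -> None:
        if self.n_external_controls < 1:
            raise ValueError("calibration requires at least one external control")
        if self.n_internal_controls < 2:
            raise ValueError("calibration requires at least two internal controls")


@dataclass
class CohortData:
    """One cohort: genotypes, phenotypes, covariates and variant labels.

    Parameters
    ----------
    genotypes
        ``(n_subjects, n_variants)`` dosage matrix with entries in
        ``{0, 1, 2}`` (float to allow mean-imputed values upstream).
    phenotypes
        Length-``n_subjects`` vector of 0/1 case status. External control
        cohorts are all zeros.
    covariates
        ``(n_subjects, c)`` matrix of analysis covariates *excluding* the
        intercept (the testing layer always prepends one). May be empty.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    covariates: np.ndarray | None = None
    sample_ids: list[str] | None = None
    variant_ids: list[str] | None = None
    name: str = "cohort"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D subjects x variants matrix")
        self.phenotypes = np.asarray(self.phenotypes, dtype=int)
        n = self.genotypes.shape[0]
        if self.phenotypes.shape != (n,):
            raise ValueError("phenotype length does not match genotype rows")
        if not np.isin(self.phenotypes, [0, 1]).all():
            raise ValueError("phenotypes must be binary 0/1")
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        else:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows do not match genotype rows")
        if self.sample_ids is None:
            self.sample_ids = [f"{self.name}_{i}" for i in range(n)]
        if self.variant_ids is None:
            self.variant_ids = [f"v{j}" for j in range(self.genotypes.shape[1])]

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotypes == 1

    @property
    def control_mask(self) -> np.ndarray:
        return self.phenotypes == 0

    def variant_frame(self) -> pd.DataFrame:
        """Per-variant summary: dosage sum, frequency, missing count."""
        g = self.genotypes
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "dosage_sum": np.nansum(g, axis=0),
                "frequency": np.nanmean(g, axis=0) / 2.0,
                "n_missing": np.isnan(g).sum(axis=0),
            }
        )
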
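"""Per-variant orchestration of the three analysis strategies.

``iECAT_RC`` augments the internal case-control sample with external
controls whose genotypes have been regression-calibrated; ``iECAT_N`` pools
the raw external controls naively (the negative-control strategy); and
``Internal`` uses the internal sample alone. All three share the same
covariate-adjusted score test and the same p-value dispatch rule:

* minor-allele count below ``mac_threshold`` -> efficient resampling (ER);
* otherwise, if external controls are integrated or the case fraction is
  below 1/3 (the combined designs are unbalanced by construction), the
  saddlepoint approximation (SPA);
* otherwise the asymptotic chi-square(1) p-value.

As a numerical economy the SPA is only evaluated when the asymptotic
p-value falls below a screening threshold (default 0.25): in the
distribution bulk the saddlepoint and normal approximations coincide to
high accuracy, so screened-out variants keep the asymptotic p-value and
route label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortData
from .calibration import calibrate_external
from .score_test import NullModel, fit_null, score_components
from .pvalue_calibration import er_pvalue, spa_pvalue_batch

__all__ = [
    "CalibrationConfig",
    "DispatchConfig",
    "AnalysisRequest",
    "run_variant",
    "run_scan",
    "score_variants",
]

METHODS = ("iECAT_RC", "iECAT_N", "Internal")


@dataclass(frozen=True)
class CalibrationConfig:
    K: int = 10
    p: int = 10
    seed: int | None = None


@dataclass(frozen=True)
class DispatchConfig:
    """SPA/ER routing policy.

    ``spa_policy`` is one of ``auto`` (SPA for combined samples or case
    fraction < 1/3), ``always`` or ``never``; ``spa_screen`` is the
    asymptotic-p screening threshold below which the SPA is evaluated
    (1.0 disables screening).
    """

    mac_threshold: int = 10
    spa_policy: str = "auto"
    spa_screen: float = 0.25
    er_enum_limit: int = 100_000
    er_samples: int = 10_000
    seed: int | None = None


@dataclass
class AnalysisRequest:
    """One analysis strategy applied to an internal (+ optional external) cohort."""

    method: str
    internal: CohortData
    external: CohortData | None = None
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    dispatch: DispatchConfig = field(default_factory=DispatchConfig)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.method != "Internal" and self.external is None:
            raise ValueError(f"{self.method} requires an external cohort")


def _assemble(req: AnalysisRequest) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Build (G, Y, Z) for the requested strategy; Z excludes the intercept."""
    internal = req.internal
    if req.method == "Internal" or req.external is None:
        return internal.genotypes, internal.phenotypes, internal.covariates, False
    external = req.external
    if req.method == "iECAT_N":
        g_ext = external.genotypes
    else:
        g_ext = calibrate_external(
            internal,
            external,
            K=req.calibration.K,
            p=req.calibration.p,
            rng=req.calibration.seed,
        )
    G = np.vstack([internal.genotypes, g_ext])
    Y = np.concatenate([internal.phenotypes, np.zeros(external.n_subjects, dtype=int)])
    Z = np.vstack([internal.covariates, external.covariates])
    return G, Y, Z, True


def score_variants(
    G: np.ndarray,
    null: NullModel,
    dispatch: DispatchConfig,
    combined: bool,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Vectorized score test + SPA/ER dispatch over the columns of ``G``.

    Columns whose dosage codes the major allele (frequency > 0.5) are
    flipped to minor-allele coding before MAC accounting and testing; the
    two-sided p-value is invariant to the flip.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, v = G.shape
    freq = G.mean(axis=0) / 2.0
    G = np.where(freq[None, :] > 0.5, 2.0 - G, G)
    mac = G.sum(axis=0)

    s, var_s, gt = score_components(G, null)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(var_s > 0, s * s / var_s, 0.0)
    p = np.where(var_s > 0, stats.chi2.sf(t_stat, df=1), 1.0)
    routes = np.array(["asymptotic"] * v, dtype=object)

    mono = var_s <= 1e-12
    er_mask = (~mono) & (mac < dispatch.mac_threshold)

    if dispatch.spa_policy == "always":
        spa_trigger = True
    elif dispatch.spa_policy == "never":
        spa_trigger = False
    else:
        spa_trigger = combined or null.case_fraction < 1.0 / 3.0
    if spa_trigger:
        spa_mask = (~mono) & (~er_mask) & (p < dispatch.spa_screen)
        if spa_mask.any():
            p_spa, fb = spa_pvalue_batch(gt[:, spa_mask], null.mu_hat, s[spa_mask])
            p[spa_mask] = p_spa
            routes[spa_mask] = np.where(fb, "SPA_fallback_normal", "SPA")

    if er_mask.any():
        if rng is None:
            rng = np.random.default_rng(dispatch.seed)
        for j in np.flatnonzero(er_mask):
            res = er_pvalue(
                null.Y,
                G[:, j],
                null,
                enum_limit=dispatch.er_enum_limit,
                n_samples=dispatch.er_samples,
                rng=rng,
                G_tilde=gt[:, j],
            )
            p[j] = res.p_value
            routes[j] = "ER"

    return pd.DataFrame(
        {
            "n": n,
            "n_case": int(null.Y.sum()),
            "MAC": mac.astype(int),
            "S": s,
            "var_S": var_s,
            "T": t_stat,
            "p_value": p,
            "route": routes,
        }
    )


def run_scan(req: AnalysisRequest, variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Apply one strategy to every variant, sharing a single null model.

    Per-variant failures are recorded in the ``error`` column instead of
    aborting the scan.
    """
    G, Y, Z, combined = _assemble(req)
    null = fit_null(Y, Z if Z.shape[1] else None)
    ids = variant_ids or req.internal.variant_ids
    table = score_variants(G, null, req.dispatch, combined)
    table.insert(0, "variant_id", ids)
    table.insert(1, "method", req.method)
    table["error"] = ""
    return table


def run_variant(req: AnalysisRequest, variant_id: str) -> pd.Series:
    """Run one strategy for a single named variant.

    Identical to selecting that variant's row from :func:`run_scan` — the
    calibration PCs are computed from the full variant set either way.
    """
    ids = req.internal.variant_ids
    if variant_id not in ids:
        raise KeyError(f"variant {variant_id!r} not in cohort")
    table = run_scan(req)
    return table[table["variant_id"] == variant_id].iloc[0]
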
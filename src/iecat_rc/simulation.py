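"""Generative simulation design and the type-I-error / power harnesses.

Phenotypes follow the logistic-normal law

    logit P(Y=1 | Z, G) = a0 + 0.5*Z1 + 0.5*Z2 + b*G + eps,

with Z1 ~ N(0,1), Z2 ~ Bernoulli(0.5), eps ~ N(0,1) a latent frailty kept
in the linear predictor, G ~ Binomial(2, q) per variant, and a0 solved so
the population disease prevalence is 0.05. Internal cohorts are accrued by
rejection sampling until the design's case/control counts are reached;
external cohorts are population controls generated under external minor
allele frequencies.

Batch effects are injected at the allele-frequency level: a fraction DVS of
variants (the differential variants) receive an external-control MAF of
either 2q ("double") or a draw from Uniform(0.1q, 4q) ("uniform"). Six
canonical models combine three case:control:external ratios with the two
mechanisms:

    ===== ==================== ==========
    model n1I : n0I : n0E      mechanism
    ===== ==================== ==========
    1     5000 : 5000 : 10000  double
    2     6667 : 3333 : 10000  double
    3      500 : 5000 : 10000  double
    4     5000 : 5000 : 10000  uniform
    5     6667 : 3333 : 10000  uniform
    6      500 : 5000 : 10000  uniform
    ===== ==================== ==========

The default MAF sampler is a synthetic stand-in for an exome reference
panel's empirical spectrum (697 diploid subjects): minor-allele counts
c in {1..697} follow a truncated power law whose exponent is solved so
that 38.5% of variants are singletons, and q = c/1394. An empirical MAF
list can be supplied instead.

The type-I-error harness fixes genotypes and covariates per genotype set
and resamples the internal phenotypes from the null logistic law with the
intercept re-anchored to the design's case fraction (the retrospective
intercept-shift of case-control sampling), redrawing the frailty eps each
time. External phenotypes stay 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, roots_hermitenorm

from .cohort import CohortData
from .calibration import calibrate_external
from .methods import DispatchConfig, score_variants
from .score_test import fit_null

__all__ = [
    "SimConfig",
    "SimDataset",
    "MODEL_PRESETS",
    "sample_maf",
    "apply_batch_effect",
    "solve_intercept",
    "generate_dataset",
    "type1_error_experiment",
    "power_experiment",
]

# (n1I, n0I, n0E, mechanism)
MODEL_PRESETS = {
    1: (5000, 5000, 10000, "double"),
    2: (6667, 3333, 10000, "double"),
    3: (500, 5000, 10000, "double"),
    4: (5000, 5000, 10000, "uniform"),
    5: (6667, 3333, 10000, "uniform"),
    6: (500, 5000, 10000, "uniform"),
}

# synthetic exome-like site-frequency spectrum: 697 diploid reference
# subjects, singleton fraction anchored at 38.5%
_SFS_SUBJECTS = 697
_SFS_CHROMOSOMES = 2 * _SFS_SUBJECTS
_SFS_SINGLETON_FRACTION = 0.385


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulation scenario."""

    n1I: int
    n0I: int
    n0E: int
    batch_mechanism: str = "double"  # "double" (2q) or "uniform" (U(0.1q, 4q))
    model_id: int | None = None
    dvs: float = 0.03
    beta: float = 0.0
    prevalence: float = 0.05
    maf_source: np.ndarray | str | None = None  # empirical list; None = parametric
    n_variants: int = 100
    n_pheno_resamples: int = 100
    alpha_levels: tuple = (0.05, 0.01, 1e-3, 1e-4)
    seed: int = 0
    n_pcs: int = 10
    K: int = 10
    mac_threshold: int = 10
    accrual_budget_factor: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dvs <= 1.0:
            raise ValueError("dvs must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.batch_mechanism not in ("double", "uniform"):
            raise ValueError("batch_mechanism must be 'double' or 'uniform'")

    @classmethod
    def from_model(cls, model_id: int, **overrides) -> "SimConfig":
        n1i, n0i, n0e, mech = MODEL_PRESETS[model_id]
        base = dict(n1I=n1i, n0I=n0i, n0E=n0e, batch_mechanism=mech, model_id=model_id)
        base.update(overrides)
        return cls(**base)


@dataclass
class SimDataset:
    internal: CohortData
    external: CohortData
    truth: pd.DataFrame  # per variant: q, q_external, differential, beta
    config: SimConfig


# ---------------------------------------------------------------------------
# MAF sampling and batch mechanisms
# ---------------------------------------------------------------------------


def _sfs_pmf() -> tuple[np.ndarray, np.ndarray]:
    """Minor-allele-count pmf of the synthetic exome spectrum (cached)."""
    global _SFS_CACHE
    try:
        return _SFS_CACHE
    except NameError:
        pass
    counts = np.arange(1, _SFS_SUBJECTS + 1, dtype=float)

    def singleton_gap(gamma: float) -> float:
        w = counts**-gamma
        return w[0] / w.sum() - _SFS_SINGLETON_FRACTION

    gamma = optimize.brentq(singleton_gap, 1.01, 3.0, xtol=1e-10)
    w = counts**-gamma
    _SFS_CACHE = (counts / _SFS_CHROMOSOMES, w / w.sum())
    return _SFS_CACHE


def sample_maf(
    maf_source: np.ndarray | str | None,
    n_variants: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-variant minor allele frequencies q in (0, 0.5].

    ``maf_source`` may be an array/sequence of empirical MAFs (sampled with
    replacement), a path to a one-column text file of MAFs, or None for the
    parametric exome-spectrum stand-in.
    """
    if maf_source is None:
        q_grid, pmf = _sfs_pmf()
        return rng.choice(q_grid, size=n_variants, replace=True, p=pmf)
    if isinstance(maf_source, str):
        maf_source = np.loadtxt(maf_source, ndmin=1)
    maf = np.asarray(maf_source, dtype=float).ravel()
    if maf.size == 0:
        raise ValueError("empirical MAF list is empty")
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("MAFs must lie in (0, 0.5]")
    return rng.choice(maf, size=n_variants, replace=True)


def apply_batch_effect(
    q: np.ndarray,
    dvs: float,
    mechanism: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """External-control MAFs and differential flags for a variant set.

    ``round(dvs * n)`` variants are picked uniformly at random; their
    external MAF is 2q capped at 0.5 ("double") or a Uniform(0.1q, 4q) draw
    truncated to (0, 0.5] ("uniform"); all others keep q.
    """
    q = np.asarray(q, dtype=float)
    n = len(q)
    n_flag = int(np.floor(dvs * n + 0.5))
    flags = np.zeros(n, dtype=bool)
    if n_flag:
        flags[rng.choice(n, size=n_flag, replace=False)] = True
    q_ext = q.copy()
    if mechanism == "double":
        q_ext[flags] = np.minimum(2.0 * q[flags], 0.5)
    elif mechanism == "uniform":
        draws = rng.uniform(0.1 * q[flags], 4.0 * q[flags])
        q_ext[flags] = np.minimum(draws, 0.5)
    else:
        raise ValueError("mechanism must be 'double' or 'uniform'")
    return q_ext, flags


# ---------------------------------------------------------------------------
# phenotype law
# ---------------------------------------------------------------------------


def _default_covariate_law(n: int, rng: np.random.Generator):
    z1 = rng.standard_normal(n)
    z2 = (rng.random(n) < 0.5).astype(float)
    eps = rng.standard_normal(n)
    return 0.5 * z1 + 0.5 * z2 + eps, np.column_stack([z1, z2])


def solve_intercept(
    prevalence: float,
    beta: float = 0.0,
    q: float = 0.0,
    covariate_law=None,
    rng: np.random.Generator | int | None = None,
    n_mc: int = 1_000_000,
) -> float:
    """Intercept a0 anchoring the population prevalence.

    Solves mean(expit(a0 + L + beta*G)) = prevalence over a fixed Monte
    Carlo sample of the covariate/noise contribution L and G ~ Bin(2, q),
    by Brent's method (the mean is strictly increasing in a0). With a
    degenerate (all-zero) law and beta = 0 this returns logit(prevalence)
    exactly.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    law = _default_covariate_law if covariate_law is None else covariate_law
    out = law(n_mc, rng)
    lin = out[0] if isinstance(out, tuple) else np.asarray(out, dtype=float)
    if beta != 0.0:
        lin = lin + beta * rng.binomial(2, q, size=n_mc)
    if np.ptp(lin) == 0.0:
        return float(logit(prevalence) - lin.flat[0])

    def gap(a0: float) -> float:
        return float(expit(a0 + lin).mean() - prevalence)

    return float(optimize.brentq(gap, -40.0, 20.0, xtol=1e-6))


def _anchored_intercept(lin_fixed: np.ndarray, target_fraction: float) -> float:
    """Intercept making E[Y] equal the design case fraction for fixed covariates.

    Integrates the redrawn frailty eps ~ N(0,1) by Gauss-Hermite quadrature;
    used by the phenotype-resampling null harness (case-control sampling
    shifts only the intercept of the logistic law).
    """
    nodes, weights = roots_hermitenorm(31)
    weights = weights / weights.sum()

    def gap(a0: float) -> float:
        p = expit(a0 + lin_fixed[:, None] + nodes[None, :]) @ weights
        return float(p.mean() - target_fraction)

    return float(optimize.brentq(gap, -40.0, 20.0, xtol=1e-8))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def _accrue(
    n_cases: int,
    n_controls: int,
    a0: float,
    beta: float,
    q_causal: float,
    rng: np.random.Generator,
    budget_factor: float,
):
    """Rejection-sample a cohort with the requested case/control counts.

    Returns (covariates Z1/Z2, causal genotype or None, phenotypes) with
    cases and controls interleaved in accrual order.
    """
    case_rate = 0.05  # refined from observed draws after the first chunk
    need = {1: n_cases, 0: n_controls}
    got = {1: 0, 0: 0}
    cases_seen = 0
    rows_z, rows_g, rows_y = [], [], []
    drawn = 0
    budget = budget_factor * (n_cases / 0.03 + n_controls / 0.5 + 1000)
    while got[1] < need[1] or got[0] < need[0]:
        if drawn > budget:
            raise RuntimeError(
                f"accrual budget exhausted: have {got[1]}/{need[1]} cases, "
                f"{got[0]}/{need[0]} controls after {drawn} population draws"
            )
        chunk = int(
            min(
                max(
                    1.2 * (need[1] - got[1]) / max(case_rate, 1e-4),
                    1.2 * (need[0] - got[0]) / max(1.0 - case_rate, 1e-4),
                    1000,
                ),
                5_000_000,
            )
        )
        drawn += chunk
        lin, z = _default_covariate_law(chunk, rng)
        g = rng.binomial(2, q_causal, size=chunk).astype(float) if beta != 0.0 else None
        eta = a0 + lin + (beta * g if g is not None else 0.0)
        y = (rng.random(chunk) < expit(eta)).astype(int)
        cases_seen += int(y.sum())
        case_rate = max(cases_seen / drawn, 1e-4)
        keep = np.zeros(chunk, dtype=bool)
        for cls in (1, 0):
            idx = np.flatnonzero(y == cls)[: need[cls] - got[cls]]
            keep[idx] = True
            got[cls] += len(idx)
        rows_z.append(z[keep])
        rows_y.append(y[keep])
        if g is not None:
            rows_g.append(g[keep])
    z = np.vstack(rows_z)
    y = np.concatenate(rows_y)
    g = np.concatenate(rows_g) if rows_g else None
    return z, g, y


def generate_dataset(config: SimConfig, rng: np.random.Generator | None = None) -> SimDataset:
    """Simulate one internal + external dataset under ``config``.

    Variant MAFs are drawn from the configured source and the batch
    mechanism is applied to the DVS fraction. Under ``beta != 0`` variant 0
    is the causal variant (it enters the phenotype law; the remaining
    variants are null and exist to support the PC structure); under the
    null all genotypes are independent of the phenotype.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    q = sample_maf(config.maf_source, config.n_variants, rng)
    q_ext, flags = apply_batch_effect(q, config.dvs, config.batch_mechanism, rng)

    q_causal = q[0] if config.beta != 0.0 else 0.0
    a0 = solve_intercept(
        config.prevalence, config.beta, q_causal, rng=rng, n_mc=200_000
    )

    z_int, g0_int, y_int = _accrue(
        config.n1I, config.n0I, a0, config.beta, q_causal, rng, config.accrual_budget_factor
    )
    n_i = config.n1I + config.n0I
    g_int = rng.binomial(2, q, size=(n_i, config.n_variants)).astype(float)
    if g0_int is not None:
        g_int[:, 0] = g0_int

    q_causal_ext = q_ext[0] if config.beta != 0.0 else 0.0
    z_ext, g0_ext, _ = _accrue(
        0, config.n0E, a0, config.beta, q_causal_ext, rng, config.accrual_budget_factor
    )
    g_ext = rng.binomial(2, q_ext, size=(config.n0E, config.n_variants)).astype(float)
    if g0_ext is not None:
        g_ext[:, 0] = g0_ext

    variant_ids = [f"v{j}" for j in range(config.n_variants)]
    internal = CohortData(g_int, y_int, z_int, variant_ids=variant_ids, name="internal")
    external = CohortData(
        g_ext, np.zeros(config.n0E, dtype=int), z_ext, variant_ids=variant_ids, name="external"
    )
    truth = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "q": q,
            "q_external": q_ext,
            "differential": flags,
            "beta": np.where(
                np.arange(config.n_variants) == 0, config.beta, 0.0
            )
            if config.beta != 0.0
            else 0.0,
        }
    )
    return SimDataset(internal, external, truth, config)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


@dataclass
class TypeIErrorResult:
    table: pd.DataFrame
    route_counts: pd.DataFrame
    n_variants: int
    n_resamples: int


def _dispatch_for(config: SimConfig) -> DispatchConfig:
    return DispatchConfig(mac_threshold=config.mac_threshold, seed=config.seed)


def type1_error_experiment(
    config: SimConfig,
    methods: tuple = ("iECAT_RC", "iECAT_N", "Internal"),
    alpha_levels: tuple | None = None,
) -> TypeIErrorResult:
    """Empirical type-I-error rates under the null (``beta`` must be 0).

    Generates ``n_variants`` genotype sets once, calibrates the external
    controls once (calibration does not involve phenotypes), then resamples
    the internal phenotypes ``n_pheno_resamples`` times and scores every
    variant with every method per resample. Rates are reported pooled and
    stratified by the differential flag, with binomial Monte-Carlo standard
    errors treating variant x resample as the replicate unit.
    """
    if config.beta != 0.0:
        raise ValueError("type1_error_experiment requires beta = 0; use power_experiment")
    alphas = np.asarray(alpha_levels if alpha_levels is not None else config.alpha_levels)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    data = generate_dataset(config, rng)
    internal, external = data.internal, data.external
    flags = data.truth["differential"].to_numpy()
    v = config.n_variants
    r = config.n_pheno_resamples
    dispatch = _dispatch_for(config)

    samples: dict[str, tuple[np.ndarray, np.ndarray, bool]] = {}
    z_comb = np.vstack([internal.covariates, external.covariates])
    if "Internal" in methods:
        samples["Internal"] = (internal.genotypes, internal.covariates, False)
    if "iECAT_N" in methods:
        samples["iECAT_N"] = (
            np.vstack([internal.genotypes, external.genotypes]),
            z_comb,
            True,
        )
    if "iECAT_RC" in methods:
        calibrated = calibrate_external(
            internal, external, K=config.K, p=min(config.n_pcs, max(v - 1, 0)), rng=rng
        )
        samples["iECAT_RC"] = (
            np.vstack([internal.genotypes, calibrated]),
            z_comb,
            True,
        )

    lin_fixed = internal.covariates @ np.array([0.5, 0.5])
    a_star = _anchored_intercept(lin_fixed, config.n1I / internal.n_subjects)
    y_ext = np.zeros(external.n_subjects, dtype=int)

    hits = {m: np.zeros((v, len(alphas))) for m in methods}
    route_tallies: dict[tuple[str, str], int] = {}
    for _ in range(r):
        eps = rng.standard_normal(internal.n_subjects)
        y_int = (rng.random(internal.n_subjects) < expit(a_star + lin_fixed + eps)).astype(int)
        if y_int.min() == y_int.max():  # pragma: no cover - absurd draw
            continue
        for m in methods:
            g, z, combined = samples[m]
            y = np.concatenate([y_int, y_ext]) if combined else y_int
            null = fit_null(y, z)
            res = score_variants(g, null, dispatch, combined, rng=rng)
            pv = res["p_value"].to_numpy()
            hits[m] += pv[:, None] < alphas[None, :]
            for route, cnt in res["route"].value_counts().items():
                route_tallies[(m, route)] = route_tallies.get((m, route), 0) + int(cnt)

    rows = []
    for m in methods:
        for a_idx, alpha in enumerate(alphas):
            h = hits[m][:, a_idx]
            for label, mask in (
                ("pooled", np.ones(v, dtype=bool)),
                ("differential", flags),
                ("non_differential", ~flags),
            ):
                n_rep = int(mask.sum()) * r
                rate = float(h[mask].sum() / n_rep) if n_rep else np.nan
                rows.append(
                    {
                        "method": m,
                        "alpha": float(alpha),
                        "stratum": label,
                        "rejection_rate": rate,
                        "n_replicates": n_rep,
                        "mc_se": float(np.sqrt(rate * (1 - rate) / n_rep)) if n_rep else np.nan,
                    }
                )
    route_df = pd.DataFrame(
        [{"method": m, "route": rte, "count": c} for (m, rte), c in sorted(route_tallies.items())]
    )
    return TypeIErrorResult(pd.DataFrame(rows), route_df, v, r)


def power_experiment(
    config: SimConfig,
    methods: tuple = ("iECAT_RC", "iECAT_N", "Internal"),
    alpha: float = 5e-8,
    n_replicates: int = 500,
) -> pd.DataFrame:
    """Empirical power at level ``alpha`` (``beta`` must be > 0).

    Each replicate generates an independent dataset whose variant 0 is
    causal with log odds ratio ``beta`` and scores it with every method;
    the remaining ``n_variants - 1`` null variants support the calibration
    PCs. Returns per-method rejection fractions with standard errors.
    """
    if config.beta <= 0.0:
        raise ValueError("power_experiment requires beta > 0; use type1_error_experiment")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    dispatch = _dispatch_for(config)
    hits = {m: 0 for m in methods}
    for _ in range(n_replicates):
        data = generate_dataset(config, rng)
        internal, external = data.internal, data.external
        z_comb = np.vstack([internal.covariates, external.covariates])
        y_comb = np.concatenate([internal.phenotypes, external.phenotypes])
        for m in methods:
            if m == "Internal":
                g, z, y, combined = (
                    internal.genotypes[:, :1],
                    internal.covariates,
                    internal.phenotypes,
                    False,
                )
            elif m == "iECAT_N":
                g = np.vstack([internal.genotypes[:, :1], external.genotypes[:, :1]])
                z, y, combined = z_comb, y_comb, True
            else:
                calibrated = calibrate_external(
                    internal,
                    external,
                    K=config.K,
                    p=min(config.n_pcs, max(config.n_variants - 1, 0)),
                    rng=rng,
                    variant_indices=[0],
                )
                g = np.vstack([internal.genotypes[:, :1], calibrated])
                z, y, combined = z_comb, y_comb, True
            null = fit_null(y, z)
            res = score_variants(g, null, dispatch, combined, rng=rng)
            hits[m] += int(res["p_value"].iloc[0] < alpha)
    rows = []
    for m in methods:
        pw = hits[m] / n_replicates
        rows.append(
            {
                "method": m,
                "alpha": alpha,
                "beta": config.beta,
                "power": pw,
                "mc_se": float(np.sqrt(pw * (1 - pw) / n_replicates)),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
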
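"""Regression calibration of external-control genotypes.

External control samples genotyped on a different platform (or called with a
different pipeline) carry systematic allele-frequency shifts relative to the
internal study — the batch effect. This module maps external genotypes, per
variant, onto the distribution of the internal-control genotypes:

1. External controls are processed in blocks of at most ``n0I`` subjects.
   Within a block, K independent random pairings of external and internal
   control subjects are drawn; for each pairing an ordinary least-squares
   regression of the internal-control genotype on the paired external
   genotype plus principal components (internal PCs of the internal subject,
   external PCs of the paired external subject) is fitted.
2. The K coefficient vectors are averaged and used to predict a continuous
   calibrated genotype for every external subject in the block.
3. The continuous predictions are discretized back to {0, 1, 2} with
   thresholds (a0, a1) chosen so that the genotype-category frequencies of
   the calibrated block match those of the internal controls.

Since external subjects have no coordinates in the internal PC space, they
are projected onto the internal PC loadings for the prediction step; their
own external PCs supply the second covariate block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortData

__all__ = [
    "PCMatrix",
    "CalibrationCoefficients",
    "CalibrationModel",
    "CalibratedGenotypes",
    "CalibrationError",
    "SingularFitError",
    "InsufficientExternalSampleError",
    "compute_pcs",
    "fit_one_repeat",
    "discretize_by_internal_frequency",
    "calibrate_block",
    "calibrate_external",
]


class CalibrationError(RuntimeError):
    """Base class for calibration failures."""


class SingularFitError(CalibrationError):
    """Raised when the pairing design matrix is rank deficient."""


class InsufficientExternalSampleError(CalibrationError):
    """Raised when fewer external than internal controls are offered to a repeat."""


@dataclass
class PCMatrix:
    """Principal-component scores for one cohort.

    ``values`` is subjects x p, columns ordered by decreasing explained
    variance (singular value). ``loadings`` (variants x p) and the column
    ``means`` used for centering are retained so that subjects from another
    cohort can be projected into the same space.
    """

    values: np.ndarray
    p: int
    loadings: np.ndarray | None = None
    means: np.ndarray | None = None
    singular_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.p:
            raise ValueError("PC score matrix must be subjects x p")

    def project(self, genotype_matrix: np.ndarray) -> "PCMatrix":
        """Project new subjects (same variants) onto this PC basis."""
        if self.p == 0:
            return PCMatrix(np.empty((np.asarray(genotype_matrix).shape[0], 0)), 0)
        if self.loadings is None or self.means is None:
            raise ValueError("PCMatrix lacks loadings; cannot project new subjects")
        x = np.asarray(genotype_matrix, dtype=float) - self.means
        return PCMatrix(x @ self.loadings, self.p, self.loadings, self.means)


@dataclass(frozen=True)
class CalibrationCoefficients:
    """OLS estimate (beta0, beta1, alphaI, alphaE) from one pairing repeat."""

    beta0: float
    beta1: float
    alphaI: np.ndarray
    alphaE: np.ndarray

    @property
    def p(self) -> int:
        return len(self.alphaI)

    def as_array(self) -> np.ndarray:
        return np.concatenate(([self.beta0, self.beta1], self.alphaI, self.alphaE))

    @staticmethod
    def from_array(arr: np.ndarray, p: int) -> "CalibrationCoefficients":
        arr = np.asarray(arr, dtype=float)
        return CalibrationCoefficients(arr[0], arr[1], arr[2 : 2 + p], arr[2 + p : 2 + 2 * p])


@dataclass
class CalibrationModel:
    """Averaged calibration regression plus the discretization thresholds."""

    mean_coefficients: CalibrationCoefficients
    K: int
    a0: float
    a1: float
    seed: int | None = None
    degenerate: bool = False


@dataclass
class CalibratedGenotypes:
    """Discrete calibrated genotypes plus the pre-discretization predictions."""

    values: np.ndarray
    continuous_values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.continuous_values = np.asarray(self.continuous_values, dtype=float)
        if self.values.shape != self.continuous_values.shape:
            raise ValueError("discrete and continuous calibrated vectors differ in length")


def compute_pcs(genotype_matrix: np.ndarray, p: int) -> PCMatrix:
    """Top-``p`` principal components of a subjects x variants dosage matrix.

    Column-mean-centers and takes the leading left singular vectors scaled by
    their singular values. The sign of each component is fixed by forcing its
    largest-magnitude variant loading to be positive, so the decomposition is
    deterministic.
    """
    g = np.asarray(genotype_matrix, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotype matrix must be 2-D")
    n, v = g.shape
    if p == 0:
        return PCMatrix(np.empty((n, 0)), 0, np.empty((v, 0)), np.zeros(v), np.empty(0))
    if p > min(n, v):
        raise ValueError(f"p={p} exceeds min(subjects, variants)={min(n, v)}")
    if np.isnan(g).any():
        raise ValueError("genotype matrix contains missing values; impute first")
    means = g.mean(axis=0)
    xc = g - means
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * max(n, v) * np.finfo(float).eps).sum()) if s.size else 0
    if p > rank:
        raise ValueError(f"p={p} exceeds the matrix rank {rank}")
    u, s, vt = u[:, :p], s[:p], vt[:p]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(p), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    return PCMatrix(u * s, p, vt.T.copy(), means, s.copy())


def _empty_pcs(n: int) -> PCMatrix:
    return PCMatrix(np.empty((n, 0)), 0)


def _pc_values(pcs: PCMatrix | None, n: int) -> np.ndarray:
    if pcs is None:
        return np.empty((n, 0))
    if pcs.values.shape[0] != n:
        raise ValueError("PC matrix row count does not match cohort size")
    return pcs.values


def _ols_pairing(
    g_internal: np.ndarray,
    g_paired_external: np.ndarray,
    xi: np.ndarray,
    xe_paired: np.ndarray,
) -> CalibrationCoefficients:
    """OLS of internal genotype on [1, paired external genotype, PCs].

    Constant predictor columns (e.g. a monomorphic external block at a rare
    variant) carry no information and are dropped with coefficient 0 — the
    intercept absorbs them; a design that is still rank deficient after
    that (genuinely collinear PCs) raises :class:`SingularFitError`.
    """
    n = len(g_internal)
    p = xi.shape[1]
    design = np.column_stack([np.ones(n), g_paired_external, xi, xe_paired])
    keep = np.ones(design.shape[1], dtype=bool)
    keep[1:] = np.ptp(design[:, 1:], axis=0) > 0.0
    coef = np.zeros(design.shape[1])
    sub = design[:, keep]
    # normal equations with a Cholesky solve (fast path); fall back to a
    # rank-revealing least squares on numerically singular designs
    gram = sub.T @ sub
    rhs = sub.T @ g_internal
    try:
        fit = np.linalg.solve(gram, rhs)
        if not np.isfinite(fit).all() or np.linalg.cond(gram) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        fit, _, rank, _ = np.linalg.lstsq(sub, g_internal, rcond=None)
        if rank < sub.shape[1]:
            raise SingularFitError(
                f"rank-deficient calibration design (rank {rank} < {sub.shape[1]})"
            ) from None
    coef[keep] = fit
    return CalibrationCoefficients.from_array(coef, p)


def fit_one_repeat(
    internal_control_genotypes: np.ndarray,
    external_genotypes: np.ndarray,
    internal_pcs: PCMatrix | None,
    external_pcs: PCMatrix | None,
    rng: np.random.Generator,
) -> CalibrationCoefficients:
    """One random pairing repeat of the calibration regression.

    Draws ``n0I`` external subjects without replacement, pairs them with the
    internal controls in internal-subject order, and returns the OLS estimate
    of (beta0, beta1, alphaI, alphaE) from regressing the internal-control
    genotype on the paired external genotype and the two PC blocks.
    """
    g_int = np.asarray(internal_control_genotypes, dtype=float)
    g_ext = np.asarray(external_genotypes, dtype=float)
    n0i, n0e = len(g_int), len(g_ext)
    if n0e < n0i:
        raise InsufficientExternalSampleError(
            f"need at least {n0i} external controls for a repeat, got {n0e}"
        )
    xi = _pc_values(internal_pcs, n0i)
    xe = _pc_values(external_pcs, n0e)
    idx = rng.choice(n0e, size=n0i, replace=False)
    return _ols_pairing(g_int, g_ext[idx], xi, xe[idx])


def _fit_repeat_either_side(
    g_int: np.ndarray,
    g_ext: np.ndarray,
    xi: np.ndarray,
    xe: np.ndarray,
    rng: np.random.Generator,
) -> CalibrationCoefficients:
    """Pairing repeat that subsamples whichever side is larger.

    Full blocks have as many external subjects as internal controls, so this
    reduces to a random permutation pairing; a final partial block instead
    pairs its external subjects with an equal-sized random subsample of the
    internal controls.
    """
    if len(g_ext) >= len(g_int):
        idx = rng.choice(len(g_ext), size=len(g_int), replace=False)
        return _ols_pairing(g_int, g_ext[idx], xi, xe[idx])
    idx = rng.choice(len(g_int), size=len(g_ext), replace=False)
    return _ols_pairing(g_int[idx], g_ext, xi[idx], xe)


def discretize_by_internal_frequency(
    continuous_predictions: np.ndarray,
    internal_control_genotypes: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Frequency-matched discretization of continuous calibrated genotypes.

    The thresholds are empirical quantiles of the predictions: ``a0`` at the
    internal-control frequency of genotype 0 and ``a1`` at the cumulative
    frequency of genotypes {0, 1}. Classification follows the interval rules
    ``pred < a0 -> 0``, ``a0 <= pred <= a1 -> 1``, ``pred > a1 -> 2`` (a tie
    with a threshold goes to category 1). When the predictions are all
    identical, frequency matching is impossible and every subject receives
    the internal-control modal genotype.
    """
    preds = np.asarray(continuous_predictions, dtype=float)
    g_int = np.asarray(internal_control_genotypes)
    m = len(preds)
    if m < 1:
        raise ValueError("need at least one prediction")
    if np.ptp(preds) == 0.0:
        mode = np.bincount(g_int.astype(int), minlength=3).argmax()
        return float(preds[0]), float(preds[0]), np.full(m, float(mode))
    f0 = float(np.mean(g_int == 0))
    f1 = float(np.mean(g_int == 1))
    n0 = int(np.floor(f0 * m + 0.5))
    n01 = int(np.floor((f0 + f1) * m + 0.5))
    n0 = min(max(n0, 0), m)
    n01 = min(max(n01, n0), m)
    sp = np.sort(preds)
    a0 = sp[n0] if n0 < m else np.inf
    if n0 >= m:
        a1 = np.inf
    elif n01 > 0:
        a1 = sp[n01 - 1]
    else:
        a1 = -np.inf
    discrete = np.where(preds < a0, 0.0, np.where(preds <= a1, 1.0, 2.0))
    return float(a0), float(a1), discrete


def calibrate_block(
    internal_control_genotypes: np.ndarray,
    external_block_genotypes: np.ndarray,
    internal_pcs: PCMatrix | None = None,
    external_block_pcs: PCMatrix | None = None,
    external_block_internal_pcs: np.ndarray | None = None,
    K: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[CalibrationModel, CalibratedGenotypes]:
    """Calibrate one block of external controls against the internal controls.

    Runs ``K`` pairing repeats, averages the coefficient vectors element-wise,
    predicts a continuous calibrated genotype for every external subject in
    the block (using the block subjects' internal-PC projections for the
    ``alphaI`` term and their own external PCs for ``alphaE``), and
    discretizes by internal-control frequency matching.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    g_int = np.asarray(internal_control_genotypes, dtype=float)
    g_blk = np.asarray(external_block_genotypes, dtype=float)
    xi = _pc_values(internal_pcs, len(g_int))
    xe = _pc_values(external_block_pcs, len(g_blk))
    p = xi.shape[1]
    if xe.shape[1] != p:
        raise ValueError("internal and external PC matrices must share p")
    if external_block_internal_pcs is None:
        if p > 0:
            raise ValueError("p > 0 requires internal-PC projections for the external block")
        xblk_int = np.empty((len(g_blk), 0))
    else:
        xblk_int = np.asarray(external_block_internal_pcs, dtype=float)
        if xblk_int.shape != (len(g_blk), p):
            raise ValueError("external-block internal-PC projection has wrong shape")

    stacked = np.stack(
        [_fit_repeat_either_side(g_int, g_blk, xi, xe, rng).as_array() for _ in range(K)]
    )
    mean_coef = CalibrationCoefficients.from_array(stacked.mean(axis=0), p)
    continuous = (
        mean_coef.beta0
        + mean_coef.beta1 * g_blk
        + xblk_int @ mean_coef.alphaI
        + xe @ mean_coef.alphaE
    )
    a0, a1, discrete = discretize_by_internal_frequency(continuous, g_int)
    degenerate = bool(np.ptp(continuous) == 0.0)
    model = CalibrationModel(mean_coef, K, a0, a1, degenerate=degenerate)
    return model, CalibratedGenotypes(discrete, continuous)


def _iter_blocks(n0e: int, n0i: int):
    start = 0
    while start < n0e:
        yield start, min(start + n0i, n0e)
        start += n0i


def calibrate_external(
    internal: CohortData,
    external: CohortData,
    K: int = 10,
    p: int = 10,
    rng: np.random.Generator | int | None = None,
    return_reports: bool = False,
    variant_indices=None,
):
    """Calibrate every external-control genotype, per variant.

    Partitions the external cohort into consecutive blocks of at most
    ``n0I`` subjects, calibrates each block for each variant, and returns the
    calibrated genotype matrix in original external-subject order. PCs are
    fitted once on each cohort's full genotype matrix; external subjects are
    additionally projected onto the internal loadings.

    Returns ``calibrated`` (n0E x n_variants) and, when ``return_reports``,
    a list of per-(variant, block) report dicts. ``variant_indices``
    restricts calibration to a subset of columns (the PCs are still fitted
    on the full matrices); the returned matrix then has one column per
    requested variant, in the requested order.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    ctrl = internal.control_mask
    n0i = int(ctrl.sum())
    n0e = external.n_subjects
    if n0i < 2:
        raise ValueError("calibration requires at least two internal controls")
    if internal.n_variants != external.n_variants:
        raise ValueError("internal and external cohorts must share the variant set")

    if p > 0:
        pcs_int = compute_pcs(internal.genotypes, p)
        pcs_ext = compute_pcs(external.genotypes, p)
        proj_int = pcs_int.project(external.genotypes)
        xi_ctrl = PCMatrix(pcs_int.values[ctrl], p)
    else:
        pcs_ext = _empty_pcs(n0e)
        proj_int = _empty_pcs(n0e)
        xi_ctrl = _empty_pcs(n0i)

    cols = (
        list(range(internal.n_variants))
        if variant_indices is None
        else [int(j) for j in variant_indices]
    )
    calibrated = np.empty((n0e, len(cols)))
    reports = []
    for out_j, j in enumerate(cols):
        g_int = internal.genotypes[ctrl, j]
        for lo, hi in _iter_blocks(n0e, n0i):
            try:
                model, cal = calibrate_block(
                    g_int,
                    external.genotypes[lo:hi, j],
                    xi_ctrl,
                    PCMatrix(pcs_ext.values[lo:hi], p) if p else None,
                    proj_int.values[lo:hi] if p else None,
                    K=K,
                    rng=rng,
                )
            except CalibrationError as err:
                raise type(err)(f"variant {internal.variant_ids[j]}: {err}") from err
            calibrated[lo:hi, out_j] = cal.values
            if return_reports:
                reports.append(
                    {
                        "variant_id": internal.variant_ids[j],
                        "block": lo // n0i,
                        "beta0": model.mean_coefficients.beta0,
                        "beta1": model.mean_coefficients.beta1,
                        "a0": model.a0,
                        "a1": model.a1,
                        "K": K,
                    }
                )
    if return_reports:
        return calibrated, reports
    return calibrated
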